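"""Shared fixtures: small phantom cohorts reused across the test modules."""

import warnings

import numpy as np
import pytest

from rsnmap import (
    GroupDataStack,
    LesionEffect,
    PhantomConfig,
    RunConfig,
    make_subject_series,
    make_template_networks,
    reduce_and_concatenate,
    run_pipeline,
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """K=3 noiseless phantom: truth, vectorized control series, whitened data."""
    cfg = PhantomConfig(
        grid_shape=(14, 14, 14),
        n_components=3,
        n_timepoints=100,
        n_controls=4,
        n_patients=1,
        noise_sd=0.0,
        seed=7,
        lesion_spec=((LesionEffect(component=0, attenuation=0.0),),),
    )
    truth = make_template_networks(cfg)
    controls = [
        truth.grid.vectorize(make_subject_series(truth, "control", i, cfg))
        for i in range(cfg.n_controls)
    ]
    reduction = reduce_and_concatenate(
        GroupDataStack(subjects=controls), n_subject_pcs=3, n_group_pcs=3
    )
    return cfg, truth, controls, reduction


@pytest.fixture(scope="session")
def pipeline_result():
    """Default-scale noisy pipeline run with planted lesions (reused widely)."""
    cfg = RunConfig(
        phantom=PhantomConfig(
            grid_shape=(12, 12, 12),
            n_components=5,
            n_timepoints=120,
            n_controls=10,
            n_patients=3,
            noise_sd=0.6,
            seed=11,
            lesion_spec=(
                (LesionEffect(component=0, attenuation=0.0),),
                (LesionEffect(component=1, attenuation=0.25),),
                (),
            ),
        ),
        n_icasso_runs=5,
        min_cluster_voxels=10,
        n_perm=5000,
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
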