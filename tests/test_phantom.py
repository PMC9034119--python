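"""Phantom generator: planted structure, determinism, lesion semantics."""

import numpy as np
import pytest

from rsnmap import (
    BehaviorSpec,
    LesionEffect,
    PhantomConfig,
    make_behavior_scores,
    make_subject_series,
    make_template_networks,
)
from rsnmap.phantom import PlacementError, effective_maps


def test_planted_maps_weakly_correlated_and_zscored(noiseless_phantom):
    _, truth, _, _ = noiseless_phantom
    maps = truth.true_maps
    corr = np.corrcoef(maps)
    off = np.abs(corr[~np.eye(maps.shape[0], dtype=bool)])
    assert off.max() < 0.3
    np.testing.assert_allclose(maps.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(maps.std(axis=1), 1, atol=1e-12)


def test_single_component_zscored():
    cfg = PhantomConfig(grid_shape=(12, 12, 12), n_components=1, seed=3)
    truth = make_template_networks(cfg)
    assert truth.true_maps.shape[0] == 1
    assert abs(truth.true_maps[0].mean()) < 1e-12
    assert abs(truth.true_maps[0].std() - 1) < 1e-12


def test_same_seed_bit_identical():
    cfg = PhantomConfig(seed=42)
    a = make_template_networks(cfg)
    b = make_template_networks(cfg)
    np.testing.assert_array_equal(a.true_maps, b.true_maps)
    sa = make_subject_series(a, "control", 0, cfg)
    sb = make_subject_series(b, "control", 0, cfg)
    np.testing.assert_array_equal(sa, sb)


def test_grid_too_small_raises():
    with pytest.raises(PlacementError):
        make_template_networks(
            PhantomConfig(grid_shape=(4, 4, 4), n_components=6, seed=0)
        )


def test_noiseless_mixture_has_rank_k(noiseless_phantom):
    cfg, truth, controls, _ = noiseless_phantom
    assert np.linalg.matrix_rank(controls[0]) == cfg.n_components


def test_attenuation_zero_leaves_only_noise_at_node(noiseless_phantom):
    """A fully deleted node contributes nothing: control and matched patient
    differ exactly on the attenuated node's voxels and nowhere else."""
    cfg, truth, _, _ = noiseless_phantom
    ctrl = make_subject_series(truth, "control", 0, cfg)
    pat = make_subject_series(truth, "patient", 0, cfg)
    diff = np.abs(ctrl - pat).sum(axis=3)
    changed = diff > 1e-9
    # changed voxels lie inside the (numerically) supported deleted nodes
    deleted = np.zeros(truth.grid.shape, dtype=bool)
    for blob in truth.node_maps[0][1:]:
        deleted |= blob > 1e-13
    deleted &= truth.grid.mask
    assert changed[~deleted].sum() == 0
    assert changed.sum() > 0


def test_lesion_bad_component_raises():
    cfg = PhantomConfig(
        n_components=2,
        lesion_spec=((LesionEffect(component=5, attenuation=0.5),),),
        n_patients=1,
    )
    with pytest.raises(IndexError):
        make_template_networks(cfg)


def test_true_altered_matches_lesion_spec():
    cfg = PhantomConfig(
        n_components=3,
        n_patients=2,
        lesion_spec=(
            (
                LesionEffect(component=0, attenuation=0.0),
                LesionEffect(component=2, attenuation=0.5),
            ),
            (),
        ),
        seed=5,
    )
    truth = make_template_networks(cfg)
    assert truth.true_altered == {0: frozenset({0, 2})}
    assert 0 in truth.lesion_masks and 1 not in truth.lesion_masks
    tm, tm_o = truth.lesion_masks[0]
    assert np.all(tm_o[tm])  # core inside core+oedema


def test_effective_map_attenuation_scales_nodes(noiseless_phantom):
    _, truth, _, _ = noiseless_phantom
    full = effective_maps(truth, None)
    half = effective_maps(
        truth, (LesionEffect(component=1, attenuation=0.5, nodes=(0,)),)
    )
    np.testing.assert_array_equal(full[0], half[0])
    node0 = truth.grid.vectorize(truth.node_maps[1][0])
    np.testing.assert_allclose(full[1] - half[1], 0.5 * node0, atol=1e-12)


def test_attenuation_bounds_validated():
    with pytest.raises(ValueError):
        LesionEffect(component=0, attenuation=1.5)


def test_behavior_scores_identities(noiseless_phantom):
    _, truth, _, _ = noiseless_phantom
    cfg = PhantomConfig(n_components=3, seed=1)
    delta = np.array([[0.0, -2.0, 1.0], [1.0, -4.0, 0.5], [-1.0, 0.0, 0.0]])

    truth.true_behavior_coefs = {"memory": BehaviorSpec(coefs=(0.0, 0.0, 0.0), intercept=2.5)}
    scores = make_behavior_scores(truth, delta, cfg)
    np.testing.assert_allclose(scores["memory"], 2.5)

    truth.true_behavior_coefs = {"attention": BehaviorSpec(coefs=(0.0, 1.5, 0.0))}
    scores = make_behavior_scores(truth, delta, cfg)
    np.testing.assert_allclose(scores["attention"], 1.5 * delta[:, 1])

    truth.true_behavior_coefs = {"language": BehaviorSpec(coefs=(1.0, 0.0, 0.0), noise_sd=0.5)}
    noisy = make_behavior_scores(truth, delta, cfg)["language"]
    r2 = np.corrcoef(noisy, delta[:, 0])[0, 1] ** 2
    assert r2 < 1.0


def test_negative_planted_coefficient_rejected():
    with pytest.raises(ValueError):
        BehaviorSpec(coefs=(0.5, -0.1))
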