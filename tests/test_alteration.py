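"""Alteration statistics: masks, cosine similarity, permutation test."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsnmap import (
    AnalysisGrid,
    CSRecord,
    MaskParams,
    build_component_mask,
    control_distribution,
    cosine_similarity,
    delta_cs,
    exhaustive_flagged_fraction,
    patient_alteration_matrix,
    permutation_test,
)
from rsnmap.alteration import AlterationResult
from rsnmap.template_ica import TemplateComponent


@pytest.fixture()
def flat_grid():
    return AnalysisGrid(shape=(20, 20, 20), mask=np.ones((20, 20, 20), dtype=bool))


def _template_with_clusters(grid, sizes, z_high=2.0, z_low=-0.1):
    """Map with one box cluster per size, separated along x."""
    vol = np.full(grid.shape, z_low)
    x0 = 0
    for size in sizes:
        nx = int(np.ceil(size / 25))
        box = np.zeros(grid.shape, dtype=bool)
        count = 0
        for x in range(x0, x0 + nx):
            for y in range(5):
                for z in range(5):
                    if count < size:
                        box[x, y, z] = True
                        count += 1
        vol[box] = z_high
        x0 += nx + 2  # gap keeps clusters disconnected
    return TemplateComponent(id=0, map=grid.vectorize(vol))


def test_cluster_filter_keeps_only_large_clusters(flat_grid):
    tpl = _template_with_clusters(flat_grid, [250, 150])
    cmask = build_component_mask(
        tpl, flat_grid, MaskParams(min_cluster_voxels=200)
    )
    assert cmask.voxel_count == 250


def test_cluster_at_exact_minimum_survives(flat_grid):
    tpl = _template_with_clusters(flat_grid, [200])
    cmask = build_component_mask(tpl, flat_grid, MaskParams(min_cluster_voxels=200))
    assert cmask.voxel_count == 200


def test_exclusion_applied_after_cluster_filter(flat_grid):
    tpl = _template_with_clusters(flat_grid, [250])
    excl = np.zeros(flat_grid.shape, dtype=bool)
    excl[:, :, :] = True  # exclude everything
    cmask = build_component_mask(
        tpl, flat_grid, MaskParams(min_cluster_voxels=200, exclusion_mask=excl)
    )
    assert not cmask.usable and cmask.voxel_count == 0


def test_cosine_similarity_identities(flat_grid):
    tpl = _template_with_clusters(flat_grid, [250])
    cmask = build_component_mask(tpl, flat_grid, MaskParams(min_cluster_voxels=200))
    sel = flat_grid.vectorize(cmask.mask).astype(bool)
    x = np.zeros(flat_grid.n_voxels)
    x[sel] = np.linspace(1, 2, sel.sum())
    assert cosine_similarity(x, x, cmask, flat_grid).cs == pytest.approx(1.0)
    y = np.zeros(flat_grid.n_voxels)
    idx = np.flatnonzero(sel)
    x2 = np.zeros_like(x)
    x2[idx[0]] = 1.0
    y[idx[1]] = 1.0
    assert cosine_similarity(x2, y, cmask, flat_grid).cs == pytest.approx(0.0)


def test_cosine_similarity_hand_case(flat_grid):
    """[1,2,2] . [2,1,2] / (3 * 3) = 8/9."""
    vol = np.full(flat_grid.shape, -0.1)
    vol[0:3, 0, 0] = 2.0
    tpl = TemplateComponent(id=0, map=flat_grid.vectorize(vol))
    cmask = build_component_mask(tpl, flat_grid, MaskParams(min_cluster_voxels=1))
    assert cmask.voxel_count == 3
    sel = np.flatnonzero(flat_grid.vectorize(cmask.mask))
    t = np.zeros(flat_grid.n_voxels)
    s = np.zeros(flat_grid.n_voxels)
    t[sel] = [1, 2, 2]
    s[sel] = [2, 1, 2]
    assert cosine_similarity(t, s, cmask, flat_grid).cs == pytest.approx(8 / 9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_cs_invariant_to_positive_rescaling(scale):
    grid = AnalysisGrid(shape=(6, 6, 6), mask=np.ones((6, 6, 6), dtype=bool))
    vol = np.full(grid.shape, -0.1)
    vol[:3, :3, 0] = 2.0
    tpl = TemplateComponent(id=0, map=grid.vectorize(vol))
    cmask = build_component_mask(tpl, grid, MaskParams(min_cluster_voxels=1))
    rng = np.random.default_rng(0)
    s = rng.standard_normal(grid.n_voxels)
    base = cosine_similarity(tpl.map, s, cmask, grid).cs
    scaled = cosine_similarity(tpl.map * scale, s * scale, cmask, grid).cs
    assert scaled == pytest.approx(base, abs=1e-9)


def test_zero_norm_vector_is_error(flat_grid):
    tpl = _template_with_clusters(flat_grid, [250])
    cmask = build_component_mask(tpl, flat_grid, MaskParams(min_cluster_voxels=200))
    zeros = np.zeros(flat_grid.n_voxels)
    with pytest.raises(ValueError, match="zero-norm"):
        cosine_similarity(tpl.map, zeros, cmask, flat_grid, "subj")


def test_control_distribution_hand_values():
    recs = [CSRecord(f"c{i}", 0, v) for i, v in enumerate([0.8, 0.9, 1.0])]
    dist = control_distribution(recs, 0)
    assert dist.mean == pytest.approx(0.9)
    assert dist.sd == pytest.approx(0.1)
    with pytest.raises(ValueError):
        control_distribution(recs[:1], 0)
    tied = [CSRecord(f"c{i}", 1, 0.9) for i in range(5)]
    assert not control_distribution(tied, 1).usable


def test_delta_cs_hand_case():
    recs = [CSRecord(f"c{i}", 0, v) for i, v in enumerate([0.8, 0.9, 1.0])]
    dist = control_distribution(recs, 0)
    assert delta_cs(0.9, dist) == pytest.approx(0.0)
    dist.mean, dist.sd = 0.9, 0.05
    assert delta_cs(0.7, dist) == pytest.approx(-4.0)


@pytest.fixture(scope="module")
def control_dist():
    rng = np.random.default_rng(0)
    vals = 0.9 + 0.03 * rng.standard_normal(10)
    return control_distribution(
        [CSRecord(f"c{i}", 0, v) for i, v in enumerate(vals)], 0
    )


def test_permutation_center_of_null_not_flagged(control_dist):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = permutation_test(
            CSRecord("p", 0, control_dist.mean), control_dist, n_perm=2000, seed=1
        )
    assert res.flagged_fraction < 0.01 and not res.significant


def test_permutation_extreme_case_fully_flagged(control_dist):
    cs = control_dist.mean - 100 * control_dist.sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = permutation_test(CSRecord("p", 0, cs), control_dist, n_perm=2000, seed=1)
    assert res.flagged_fraction == 1.0 and res.significant


def test_monte_carlo_matches_exhaustive_enumeration(control_dist):
    """For 10 controls the subsample shrinks to 7 and all C(10,7)=120
    subsamples can be enumerated; Monte-Carlo converges to that fraction."""
    cs = control_dist.mean - 2 * control_dist.sd  # boundary-ish case
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exact = exhaustive_flagged_fraction(cs, control_dist, subsample=200)
        res = permutation_test(
            CSRecord("p", 0, cs), control_dist, n_perm=50_000, subsample=200, seed=3
        )
    assert abs(res.flagged_fraction - exact) < 0.01


def test_permutation_reproducible_and_tight(control_dist):
    cs = control_dist.mean - 2 * control_dist.sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = permutation_test(CSRecord("p", 0, cs), control_dist, n_perm=50_000, seed=5)
        b = permutation_test(CSRecord("p", 0, cs), control_dist, n_perm=50_000, seed=5)
        c = permutation_test(CSRecord("p", 0, cs), control_dist, n_perm=50_000, seed=6)
    assert a.flagged_fraction == b.flagged_fraction
    assert abs(a.flagged_fraction - c.flagged_fraction) < 0.01


def test_unusable_distribution_marks_untestable():
    tied = [CSRecord(f"c{i}", 0, 0.9) for i in range(5)]
    dist = control_distribution(tied, 0)
    res = permutation_test(CSRecord("p", 0, 0.5), dist, n_perm=10, seed=0)
    assert not res.testable and not res.significant


def test_alteration_matrix_and_network_aggregation():
    def res(pid, comp, sig):
        return AlterationResult(pid, comp, 0.9, -1.0, 1.0 if sig else 0.0, sig)

    results = [
        res("p0", 0, True),
        res("p0", 1, True),
        res("p0", 2, False),
        res("p0", 3, False),
        res("p1", 0, False),
        res("p1", 1, False),
        res("p1", 2, False),
        res("p1", 3, False),
    ]
    nets = {0: "VIS", 1: "VIS", 2: "VIS", 3: "VIS"}
    mat, agg = patient_alteration_matrix(results, nets)
    assert mat.loc[0, "p0"] and not mat.loc[0, "p1"]
    # p0 has 2 of 4 VIS components altered, p1 none
    assert agg.loc["VIS", "pct_patients_affected"] == pytest.approx(50.0)
    assert agg.loc["VIS", "mean_pct_components_altered"] == pytest.approx(25.0)
    empty, _ = patient_alteration_matrix(
        [res("p0", 0, False)], None
    )
    assert not empty.to_numpy().any()
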