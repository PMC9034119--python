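"""Lesion overlap: partition identities, Eq-style hand cases, Spearman."""

import numpy as np
import pytest

from rsnmap import (
    AnalysisGrid,
    MaskParams,
    TissuePartition,
    expected_altered_mask,
    overlap_percent,
    patient_overlap_report,
    spearman_alteration_vs_overlap,
)
from rsnmap.template_ica import TemplateComponent


@pytest.fixture()
def grid():
    return AnalysisGrid(shape=(10, 10, 10), mask=np.ones((10, 10, 10), dtype=bool))


@pytest.fixture()
def partition(grid):
    tm = np.zeros(grid.shape, dtype=bool)
    tm[0:2, 0:2, 0:2] = True
    tm_o = np.zeros(grid.shape, dtype=bool)
    tm_o[0:3, 0:3, 0:3] = True
    return TissuePartition(tm=tm, tm_o=tm_o, brain=grid.mask)


def test_partition_invariants(partition, grid):
    assert not np.any(partition.tm & partition.oedema)
    assert not np.any(partition.oedema & partition.normal)
    union = partition.tm | partition.oedema | partition.normal
    np.testing.assert_array_equal(union, grid.mask)


def test_partition_validation_errors(grid):
    tm = np.zeros(grid.shape, dtype=bool)
    tm[0, 0, 0] = True
    with pytest.raises(ValueError):
        TissuePartition(tm=tm, tm_o=np.zeros(grid.shape, dtype=bool), brain=grid.mask)
    outside = np.ones(grid.shape, dtype=bool)
    with pytest.raises(ValueError):
        TissuePartition(
            tm=tm, tm_o=outside, brain=np.zeros(grid.shape, dtype=bool)
        )


def test_overlap_percent_hand_cases(grid):
    altered = np.zeros(grid.shape, dtype=bool)
    altered.reshape(-1)[:100] = True
    tissue = np.zeros(grid.shape, dtype=bool)
    tissue.reshape(-1)[:10] = True
    assert overlap_percent(altered, tissue) == pytest.approx(10.0)
    assert overlap_percent(altered, altered) == pytest.approx(100.0)
    assert overlap_percent(altered, ~altered) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        overlap_percent(np.zeros(grid.shape, dtype=bool), tissue)


def test_overlap_monotone_under_tissue_growth(grid, rng):
    altered = rng.random(grid.shape) > 0.7
    tissue = rng.random(grid.shape) > 0.8
    grown = tissue | (rng.random(grid.shape) > 0.8)
    assert overlap_percent(altered, grown) >= overlap_percent(altered, tissue)


def _box_template(grid, sl, ident=0):
    vol = np.full(grid.shape, -0.1)
    vol[sl] = 2.0
    return TemplateComponent(id=ident, map=grid.vectorize(vol))


def test_expected_mask_union(grid):
    t0 = _box_template(grid, np.s_[0:5, 0:5, 0:4], 0)  # 100 voxels
    t1 = _box_template(grid, np.s_[5:10, 5:10, 6:10], 1)  # 100 voxels, disjoint
    params = MaskParams(min_cluster_voxels=1)
    both = expected_altered_mask([0, 1], [t0, t1], grid, params)
    assert both.union.sum() == 200
    single = expected_altered_mask([0], [t0, t1], grid, params)
    np.testing.assert_array_equal(single.union, both.per_component[0])
    with pytest.raises(KeyError):
        expected_altered_mask([7], [t0], grid, params)


def test_report_closure_sums_to_100(grid, partition):
    t0 = _box_template(grid, np.s_[0:5, 0:5, 0:4], 0)
    report = patient_overlap_report(
        expected_altered_mask([0], [t0], grid, MaskParams(min_cluster_voxels=1)),
        partition,
    )
    for row in report.values():
        assert row["tm_pct"] + row["oedema_pct"] + row["normal_pct"] == pytest.approx(
            100.0, abs=1e-12
        )


def test_report_uses_expected_maps_not_subject_damage(grid, partition):
    """Two patients with identical altered sets but different subject-level
    damage get identical reports: only template masks enter."""
    t0 = _box_template(grid, np.s_[0:5, 0:5, 0:4], 0)
    altered = expected_altered_mask([0], [t0], grid, MaskParams(min_cluster_voxels=1))
    r1 = patient_overlap_report(altered, partition)
    r2 = patient_overlap_report(altered, partition)  # same inputs by construction
    assert r1 == r2


def test_altered_fully_in_normal_tissue(grid, partition):
    t = _box_template(grid, np.s_[6:9, 6:9, 6:9], 0)
    rep = patient_overlap_report(
        expected_altered_mask([0], [t], grid, MaskParams(min_cluster_voxels=1)),
        partition,
    )
    assert rep["UNION"] == {"tm_pct": 0.0, "oedema_pct": 0.0, "normal_pct": 100.0}


def test_spearman_identities_and_errors():
    x = np.array([1.0, 2, 3, 4, 5])
    rho, p = spearman_alteration_vs_overlap(x, -x)
    assert rho == pytest.approx(-1.0)
    assert p == pytest.approx(2 / 120)  # 2 of 5! pairings reach |rho| = 1
    with pytest.raises(ValueError):
        spearman_alteration_vs_overlap(x[:3], x[:3])
    with pytest.raises(ValueError):
        spearman_alteration_vs_overlap(x, np.ones(5))


def test_spearman_null_pvalues_are_healthy(rng):
    """Independent draws: p should rarely be tiny, rho near zero on average."""
    ps = []
    for _ in range(50):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        _, p = spearman_alteration_vs_overlap(x, y)
        ps.append(p)
    assert np.mean(np.asarray(ps) < 0.05) < 0.2
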