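"""Lesion anatomy of altered networks: tumour / oedema / normal overlap.

Because a patient's own altered component may be partially or completely
missing, the anatomical footprint of an alteration is taken from the
*expected* (template) map: each altered component's template map is binarized
with the same component-mask rules, and the per-patient altered-network mask
is the union of those binary maps.  Overlap with a tissue compartment is
expressed as a percentage of the altered mask:

    overlap% = 100 * |altered mask  intersect  tissue mask| / |altered mask|

With the brain partitioned into tumour core, oedema (TM+O minus TM) and
normal-appearing tissue, the three percentages sum to exactly 100 for every
altered mask inside the brain.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .alteration import ComponentMask, MaskParams, build_component_mask
from .grid import AnalysisGrid, GridMismatchError
from .template_ica import TemplateComponent

logger = logging.getLogger("rsnmap")


@dataclass(frozen=True)
class TissuePartition:
    """Tumour-core / oedema / normal-appearing partition of the brain mask.

    Requires ``tm`` subset of ``tm_o`` subset of ``brain``; oedema and normal
    tissue are derived by set difference, so the three compartments are
    pairwise disjoint and cover the brain exactly.
    """

    tm: np.ndarray
    tm_o: np.ndarray
    brain: np.ndarray

    def __post_init__(self) -> None:
        tm = np.asarray(self.tm, dtype=bool)
        tm_o = np.asarray(self.tm_o, dtype=bool)
        brain = np.asarray(self.brain, dtype=bool)
        if tm.shape != brain.shape or tm_o.shape != brain.shape:
            raise GridMismatchError("tissue masks live on different grids")
        if np.any(tm & ~tm_o):
            raise ValueError("tumour core must be contained in tumour+oedema mask")
        if np.any(tm_o & ~brain):
            raise ValueError("tumour+oedema mask must be contained in brain mask")
        object.__setattr__(self, "tm", tm)
        object.__setattr__(self, "tm_o", tm_o)
        object.__setattr__(self, "brain", brain)

    @property
    def oedema(self) -> np.ndarray:
        return self.tm_o & ~self.tm

    @property
    def normal(self) -> np.ndarray:
        return self.brain & ~self.tm_o


@dataclass
class AlteredMaskSet:
    """Expected (template-derived) binary masks of the altered components."""

    per_component: dict[int, np.ndarray]
    union: np.ndarray


def expected_altered_mask(
    altered_ids: list[int],
    templates: list[TemplateComponent],
    grid: AnalysisGrid,
    params: MaskParams,
) -> AlteredMaskSet:
    """Binarize each altered component's *template* map; union them."""
    by_id = {t.id: t for t in templates}
    missing = [i for i in altered_ids if i not in by_id]
    if missing:
        raise KeyError(f"altered ids without template: {missing}")
    per = {}
    union = np.zeros(grid.shape, dtype=bool)
    for cid in altered_ids:
        cmask: ComponentMask = build_component_mask(by_id[cid], grid, params)
        per[cid] = cmask.mask
        union |= cmask.mask
    if not altered_ids:
        warnings.warn("empty altered set: empty altered-network mask")
    return AlteredMaskSet(per_component=per, union=union)


def overlap_percent(altered_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """``100 * |altered & tissue| / |altered|`` (altered mask as reference)."""
    altered = np.asarray(altered_mask, dtype=bool)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if altered.shape != tissue.shape:
        raise GridMismatchError("altered and tissue masks on different grids")
    n = int(altered.sum())
    if n == 0:
        raise ValueError("overlap undefined for an empty altered mask")
    return 100.0 * int((altered & tissue).sum()) / n


def patient_overlap_report(
    altered: AlteredMaskSet, partition: TissuePartition
) -> dict[str, dict[str, float]]:
    """TM / oedema / normal overlap percentages, per component and union.

    Keys are ``str(component_id)`` plus ``"UNION"``; each value holds
    ``tm_pct``, ``oedema_pct``, ``normal_pct`` (summing to 100).  Altered
    voxels outside the brain mask indicate a grid/registration problem and
    raise.
    """
    report: dict[str, dict[str, float]] = {}
    items = [(str(cid), m) for cid, m in sorted(altered.per_component.items())]
    if altered.union.any():
        items.append(("UNION", altered.union))
    for name, mask in items:
        if np.any(mask & ~partition.brain):
            raise ValueError(
                f"altered mask {name} has voxels outside the brain mask"
            )
        report[name] = {
            "tm_pct": overlap_percent(mask, partition.tm),
            "oedema_pct": overlap_percent(mask, partition.oedema),
            "normal_pct": overlap_percent(mask, partition.normal),
        }
    return report


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (all n! pairings)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    total = math.factorial(n)
    count = 0
    chunk: list[list[float]] = []
    target = abs(rho) - 1e-12
    for perm in permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            r = np.asarray(chunk) @ rx / n
            count += int(np.count_nonzero(np.abs(r) >= target))
            chunk = []
    if chunk:
        r = np.asarray(chunk) @ rx / n
        count += int(np.count_nonzero(np.abs(r) >= target))
    return count / total


def spearman_alteration_vs_overlap(
    delta_cs_values: np.ndarray, overlap_percents: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between alteration depth and tissue overlap.

    Tie-corrected ranks; two-sided p by exact permutation enumeration for
    n <= 10, asymptotic otherwise.
    """
    x = np.asarray(delta_cs_values, dtype=float)
    y = np.asarray(overlap_percents, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1D arrays required")
    if len(x) < 4:
        raise ValueError("need n >= 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p_asym = stats.spearmanr(x, y)
    if len(x) <= 10:
        return float(rho), _spearman_exact_p(x, y, float(rho))
    return float(rho), float(p_asym)
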