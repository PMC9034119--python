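"""Single-subject network alteration statistics.

The statistical core of the method.  For each template component:

1. a *component mask* is built from the template map (Z > 1, connected
   clusters of at least ``min_cluster_voxels`` voxels, optional exclusion
   mask, e.g. cerebellum);
2. the cosine similarity ``CS = <t, s> / (||t|| ||s||)`` between the
   mask-restricted template and subject maps measures how well the subject
   expresses the component -- sensitive to both topography and strength;
3. the healthy-control CS values define a normative distribution (mean mu,
   sd sigma, n-1 denominator);
4. a patient is flagged *altered* on that component by a subsampled
   permutation test: each of ``n_perm`` iterations draws a subsample of
   controls without replacement and checks ``|CS_patient - mu*| > 3 sigma*``
   (two-sided, strict); the component is significant when the exceedance
   holds in at least ``1 - alpha`` of iterations;
5. the standardized distance ``delta_cs_sigma = (CS - mu) / sigma`` grades
   the alteration depth (strongly negative = topography/strength loss).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import AnalysisGrid
from .template_ica import TemplateComponent

logger = logging.getLogger("rsnmap")


@dataclass(frozen=True)
class MaskParams:
    """Component-mask construction rules.

    Defaults follow the full-scale convention (Z > 1, clusters of at least
    200 connected voxels); phantoms on small grids pass a smaller
    ``min_cluster_voxels``.  ``connectivity`` is the scipy convention:
    1 = faces, 2 = +edges, 3 = +corners.
    """

    z_thresh: float = 1.0
    min_cluster_voxels: int = 200
    exclusion_mask: np.ndarray | None = None
    connectivity: int = 1

    def __post_init__(self) -> None:
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")


@dataclass
class ComponentMask:
    component_id: int
    mask: np.ndarray  # 3D boolean
    voxel_count: int
    usable: bool


@dataclass(frozen=True)
class CSRecord:
    subject_id: str
    component_id: int
    cs: float


@dataclass
class CSDistribution:
    """Healthy-control cosine-similarity distribution for one component."""

    component_id: int
    values: np.ndarray
    mean: float
    sd: float
    usable: bool


@dataclass
class AlterationResult:
    patient_id: str
    component_id: int
    cs: float
    delta_cs_sigma: float
    flagged_fraction: float
    significant: bool
    testable: bool = True


def build_component_mask(
    template: TemplateComponent, grid: AnalysisGrid, params: MaskParams
) -> ComponentMask:
    """Threshold, cluster-filter and exclusion-trim one template map.

    Order: threshold at Z > z_thresh, connected-component labelling, drop
    clusters below ``min_cluster_voxels`` ("at least" semantics: a cluster
    exactly at the minimum survives), then remove exclusion voxels.  An
    empty final mask marks the component unusable (CS undefined).
    """
    vol = grid.devectorize(template.map)
    binary = (vol > params.z_thresh) & grid.mask
    structure = ndimage.generate_binary_structure(3, params.connectivity)
    labels, n_lab = ndimage.label(binary, structure=structure)
    keep = np.zeros_like(binary)
    dropped = 0
    for lab in range(1, n_lab + 1):
        cluster = labels == lab
        if int(cluster.sum()) >= params.min_cluster_voxels:
            keep |= cluster
        else:
            dropped += 1
    if dropped:
        logger.info("component %d: dropped %d small clusters", template.id, dropped)
    if params.exclusion_mask is not None:
        excl = grid.validate(np.asarray(params.exclusion_mask, dtype=bool), "exclusion")
        removed = int((keep & excl).sum())
        keep &= ~excl
        if removed:
            logger.info(
                "component %d: removed %d excluded voxels", template.id, removed
            )
    count = int(keep.sum())
    usable = count > 0
    if not usable:
        logger.warning("component %d: empty mask, marked unusable", template.id)
    return ComponentMask(
        component_id=template.id, mask=keep, voxel_count=count, usable=usable
    )


def cosine_similarity(
    template_map: np.ndarray,
    subject_map: np.ndarray,
    cmask: ComponentMask,
    grid: AnalysisGrid,
    subject_id: str = "",
) -> CSRecord:
    """CS of the two mask-restricted map vectors (Z values, not binarized)."""
    if not cmask.usable:
        raise ValueError(f"component {cmask.component_id}: unusable mask")
    # restrict the vectorized maps to component-mask voxels
    sel = grid.vectorize(cmask.mask).astype(bool)
    t = np.asarray(template_map, dtype=float)[sel]
    s = np.asarray(subject_map, dtype=float)[sel]
    nt, ns = np.linalg.norm(t), np.linalg.norm(s)
    if nt == 0 or ns == 0:
        raise ValueError(
            f"zero-norm vector for subject {subject_id!r}, "
            f"component {cmask.component_id}"
        )
    return CSRecord(
        subject_id=subject_id,
        component_id=cmask.component_id,
        cs=float(t @ s / (nt * ns)),
    )


def outside_mask_fraction(
    subject_map: np.ndarray,
    cmask: ComponentMask,
    grid: AnalysisGrid,
    z_thresh: float = 1.0,
) -> float:
    """Fraction of subject suprathreshold voxels falling outside the mask.

    Automated version of the manual post-hoc check that flagged components
    are not simply displaced outside the component mask; meant for human
    review of high values.
    """
    supra = np.asarray(subject_map) > z_thresh
    n = int(supra.sum())
    if n == 0:
        return 0.0
    sel = grid.vectorize(cmask.mask).astype(bool)
    return float((supra & ~sel).sum() / n)


def control_distribution(records: list[CSRecord], component_id: int) -> CSDistribution:
    """Mean/sd (n-1) of control CS values for one component."""
    values = np.array(
        [r.cs for r in records if r.component_id == component_id], dtype=float
    )
    if values.size < 3:
        raise ValueError(
            f"component {component_id}: need >= 3 control CS values, "
            f"got {values.size}"
        )
    sd = float(values.std(ddof=1))
    usable = sd > 0
    if not usable:
        logger.warning("component %d: sigma = 0, unusable for testing", component_id)
    return CSDistribution(
        component_id=component_id,
        values=values,
        mean=float(values.mean()),
        sd=sd,
        usable=usable,
    )


def delta_cs(patient_cs: float, dist: CSDistribution) -> float:
    """Standardized distance (CS - mu) / sigma from the control distribution."""
    if dist.sd == 0:
        raise ValueError(f"component {dist.component_id}: sigma = 0")
    return (patient_cs - dist.mean) / dist.sd


def _resolve_subsample(n_controls: int, subsample: int) -> int:
    if subsample < n_controls:
        return subsample
    reduced = max(2, math.ceil(0.65 * n_controls))
    warnings.warn(
        f"subsample {subsample} >= controls {n_controls}; "
        f"reduced to ceil(0.65 n) = {reduced}",
        RuntimeWarning,
    )
    return reduced


def permutation_test(
    patient: CSRecord,
    dist: CSDistribution,
    n_perm: int = 50_000,
    subsample: int = 200,
    sd_mult: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> AlterationResult:
    """Subsampled permutation test of one patient CS against controls.

    Each iteration draws ``subsample`` controls without replacement and
    records whether ``|CS - mu*| > sd_mult * sigma*`` (strict).  The
    component is significant when the exceedance holds in at least
    ``1 - alpha`` of iterations.  If fewer controls than ``subsample`` are
    available the subsample shrinks to ``ceil(0.65 n)`` with a warning.
    """
    if not dist.usable:
        return AlterationResult(
            patient_id=patient.subject_id,
            component_id=patient.component_id,
            cs=patient.cs,
            delta_cs_sigma=float("nan"),
            flagged_fraction=float("nan"),
            significant=False,
            testable=False,
        )
    values = dist.values
    n = values.size
    k = _resolve_subsample(n, subsample)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # without-replacement subsample per iteration via random-key argpartition
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        sub = values[idx]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        exceed += int(np.count_nonzero(np.abs(patient.cs - mu) > sd_mult * sd))
        done += m
    frac = exceed / n_perm
    return AlterationResult(
        patient_id=patient.subject_id,
        component_id=patient.component_id,
        cs=patient.cs,
        delta_cs_sigma=delta_cs(patient.cs, dist),
        flagged_fraction=frac,
        significant=frac >= 1.0 - alpha,
    )


def exhaustive_flagged_fraction(
    patient_cs: float,
    dist: CSDistribution,
    subsample: int | None = None,
    sd_mult: float = 3.0,
) -> float:
    """Exact exceedance fraction over *all* C(n, k) control subsamples.

    Brute-force oracle for small control sets; the Monte-Carlo
    ``flagged_fraction`` converges to this value.
    """
    values = dist.values
    n = values.size
    k = _resolve_subsample(n, subsample if subsample is not None else n)
    total = 0
    exceed = 0
    for comb in combinations(range(n), k):
        sub = values[list(comb)]
        total += 1
        if abs(patient_cs - sub.mean()) > sd_mult * sub.std(ddof=1):
            exceed += 1
    return exceed / total


def patient_alteration_matrix(
    results: list[AlterationResult],
    component_networks: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Components x patients boolean alteration matrix + network aggregation.

    The aggregation reports, per network: the percentage of patients with at
    least one altered component, and the mean percentage of that network's
    components altered per patient.
    """
    rows = sorted({r.component_id for r in results})
    cols = sorted({r.patient_id for r in results})
    mat = pd.DataFrame(False, index=rows, columns=cols)
    for r in results:
        if r.significant:
            mat.loc[r.component_id, r.patient_id] = True
    if component_networks is None:
        return mat, None
    agg_rows = []
    for net in sorted(set(component_networks.values())):
        comp_ids = [c for c in rows if component_networks.get(c) == net]
        if not comp_ids:
            continue
        sub = mat.loc[comp_ids]
        pct_patients = 100.0 * sub.any(axis=0).mean()
        pct_components = 100.0 * sub.mean(axis=0).mean()
        agg_rows.append(
            {
                "network": net,
                "pct_patients_affected": pct_patients,
                "mean_pct_components_altered": pct_components,
            }
        )
    return mat, pd.DataFrame(agg_rows).set_index("network")
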