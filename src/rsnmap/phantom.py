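"""Synthetic resting-state phantom with planted network lesions.

Emulates, at desk scale, the ingredients of a template-guided network
alteration study: K spatially smooth "resting-state network" maps on a common
grid, control and patient BOLD-like time series generated as linear mixtures
of those maps, focal lesions that delete or attenuate network nodes *distal*
to the lesion site (the disconnection phenomenology), and behaviour scores
generated from a sparse non-negative linear model on standardized network
distances.

Every downstream stage of the pipeline is testable against the planted truth
stored in :class:`PhantomTruth`.  All randomness flows from ``config.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter1d
from scipy.optimize import linear_sum_assignment

from .grid import AnalysisGrid

logger = logging.getLogger("rsnmap")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PlacementError(RuntimeError):
    """Grid too small to place the requested component nodes."""


@dataclass(frozen=True)
class LesionEffect:
    """One planted alteration: attenuate some nodes of one component.

    ``attenuation`` multiplies the spatial weight of the selected nodes:
    0 deletes them entirely, 1 leaves them untouched.  ``nodes`` lists the
    node indices affected; ``None`` means every node except node 0 (the
    "proximal" node near the lesion, which stays intact -- networks lose
    their distal nodes, not the cortex over the tumour).
    """

    component: int
    attenuation: float
    nodes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError(f"attenuation must be in [0, 1], got {self.attenuation}")


@dataclass(frozen=True)
class BehaviorSpec:
    """Planted linear model for one cognitive domain.

    ``coefs`` are non-negative weights over components applied to the
    patients' standardized network distances; planting a negative weight is a
    configuration error.
    """

    coefs: tuple[float, ...]
    intercept: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.coefs):
            raise ValueError("planted behaviour coefficients must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the desk-scale phantom used throughout the test suite:
    a 12^3 grid with an inscribed ellipsoidal brain, K=5 networks of 2-5
    Gaussian nodes, T=120 frames, 10 controls and 3 patients.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_components: int = 5
    n_timepoints: int = 120
    n_controls: int = 10
    n_patients: int = 3
    smoothness_fwhm: float = 2.5
    noise_sd: float = 0.6
    lesion_spec: tuple[tuple[LesionEffect, ...], ...] = ()
    behavior_spec: dict[str, BehaviorSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if len(self.lesion_spec) > self.n_patients:
            raise ValueError("lesion_spec longer than n_patients")


@dataclass
class PhantomTruth:
    """Planted ground truth for one phantom cohort."""

    grid: AnalysisGrid
    cerebellum_mask: np.ndarray
    node_maps: list[list[np.ndarray]]  # per component, per node, 3D raw blobs
    true_maps: np.ndarray  # K x n_voxels, Z-scored within brain mask
    lesion_masks: dict[int, tuple[np.ndarray, np.ndarray]]  # patient -> (tm, tm_o)
    true_altered: dict[int, frozenset[int]]  # patient -> planted component set
    true_behavior_coefs: dict[str, BehaviorSpec]
    timecourses: dict[str, np.ndarray] = field(default_factory=dict)  # K x T


def _rng(config: PhantomConfig, *stream: int) -> np.random.Generator:
    """Derive an independent generator for one purpose from config.seed."""
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot Z-score a constant vector")
    return (v - v.mean()) / sd


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.asarray(shape) / 2.0
    idx = np.indices(shape)
    d2 = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def make_grid(config: PhantomConfig) -> tuple[AnalysisGrid, np.ndarray]:
    """Brain grid (inscribed ellipsoid) plus a 'cerebellum' sub-region.

    The cerebellum stand-in is the inferior cap of the ellipsoid (lowest ~20%
    of in-mask z-slices); it exists so exclusion-mask logic is exercisable.
    """
    mask = _ellipsoid_mask(config.grid_shape)
    zs = np.nonzero(mask.any(axis=(0, 1)))[0]
    n_cereb = max(1, int(round(0.2 * len(zs))))
    cereb = np.zeros_like(mask)
    cereb[:, :, zs[:n_cereb]] = True
    cereb &= mask
    grid = AnalysisGrid(shape=tuple(config.grid_shape), mask=mask)
    return grid, cereb


def _gaussian_blob(shape, center, sigma) -> np.ndarray:
    idx = np.indices(shape)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return np.exp(-d2 / (2.0 * sigma**2))


def make_template_networks(config: PhantomConfig) -> PhantomTruth:
    """Plant K smooth network maps, each a union of 2-5 Gaussian nodes.

    Node centres are drawn inside the brain mask with a minimum separation
    between components so pairwise spatial correlation stays below 0.3.
    Raises :class:`PlacementError` when the grid cannot host the request.
    """
    grid, cereb = make_grid(config)
    rng = _rng(config, 0)
    sigma = config.smoothness_fwhm * FWHM_TO_SIGMA
    # Candidate centres: in-mask voxels outside the cerebellum cap.
    cand = np.argwhere(grid.mask & ~cereb)
    min_sep = max(2.0, 2.5 * sigma)

    centers: list[np.ndarray] = []  # all accepted node centres
    node_maps: list[list[np.ndarray]] = []
    for k in range(config.n_components):
        n_nodes = int(rng.integers(2, 6)) if config.n_components > 1 else 3
        comp_nodes: list[np.ndarray] = []
        for _ in range(n_nodes):
            placed = False
            for _ in range(2000):
                c = cand[rng.integers(len(cand))]
                if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                    centers.append(c)
                    comp_nodes.append(c)
                    placed = True
                    break
            if not placed:
                if len(comp_nodes) >= 2:
                    break  # this component keeps the nodes it has
                raise PlacementError(
                    f"grid {config.grid_shape} too small for component {k}: "
                    f"cannot place node with separation {min_sep:.1f}"
                )
        blobs = [_gaussian_blob(config.grid_shape, c, sigma) for c in comp_nodes]
        # equalize component energies (unit RMS over the brain mask) so no
        # source dominates the mixture and noise_sd has a fixed meaning
        rms = np.linalg.norm(grid.vectorize(np.sum(blobs, axis=0))) / np.sqrt(
            grid.n_voxels
        )
        node_maps.append([b / rms for b in blobs])

    true_maps = np.empty((config.n_components, grid.n_voxels))
    for k, nodes in enumerate(node_maps):
        raw = np.sum(nodes, axis=0)
        true_maps[k] = _zscore(grid.vectorize(raw))

    if config.n_components > 1:
        corr = np.corrcoef(true_maps)
        off = np.abs(corr[~np.eye(config.n_components, dtype=bool)])
        if off.max() >= 0.3:
            raise PlacementError(
                f"planted maps too correlated (max |r| = {off.max():.2f}); "
                "enlarge the grid or reduce n_components"
            )

    truth = PhantomTruth(
        grid=grid,
        cerebellum_mask=cereb,
        node_maps=node_maps,
        true_maps=true_maps,
        lesion_masks={},
        true_altered={},
        true_behavior_coefs=dict(config.behavior_spec),
    )
    _plant_lesions(truth, config)
    return truth


def _plant_lesions(truth: PhantomTruth, config: PhantomConfig) -> None:
    """Derive per-patient tumour masks and the planted altered-component sets.

    The tumour core is a small ball at the *proximal* node (node 0) of the
    first lesioned component; the oedema ring is one binary dilation of the
    core.  The attenuated nodes are typically distal to it.
    """
    sigma = config.smoothness_fwhm * FWHM_TO_SIGMA
    for p, effects in enumerate(config.lesion_spec):
        if not effects:
            continue
        for eff in effects:
            if not 0 <= eff.component < config.n_components:
                raise IndexError(
                    f"lesion for patient {p} references component "
                    f"{eff.component}, but K = {config.n_components}"
                )
        first = effects[0]
        # centre of node 0 of the first lesioned component
        blob = truth.node_maps[first.component][0]
        center = np.unravel_index(np.argmax(blob), blob.shape)
        tm = _gaussian_blob(config.grid_shape, center, sigma) > 0.5
        tm &= truth.grid.mask
        tm_o = binary_dilation(tm) & truth.grid.mask
        truth.lesion_masks[p] = (tm, tm_o)
        truth.true_altered[p] = frozenset(e.component for e in effects)


def _smooth_timecourses(K: int, T: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian processes, Gram-Schmidt to near-orthogonality."""
    tc = gaussian_filter1d(rng.standard_normal((K, T)), sigma=2.0, axis=1)
    tc -= tc.mean(axis=1, keepdims=True)
    # Gram-Schmidt: mutual orthogonality aids ICA identifiability at tiny T.
    for k in range(K):
        for j in range(k):
            tc[k] -= (tc[k] @ tc[j]) / (tc[j] @ tc[j]) * tc[j]
        nrm = np.linalg.norm(tc[k])
        if nrm == 0:
            raise RuntimeError("degenerate time course draw")
        tc[k] *= np.sqrt(T) / nrm  # unit variance
    return tc


def effective_maps(
    truth: PhantomTruth, effects: tuple[LesionEffect, ...] | None
) -> np.ndarray:
    """K x n_voxels mixing maps after applying lesion attenuations (raw scale)."""
    K = len(truth.node_maps)
    out = np.empty((K, truth.grid.n_voxels))
    atten: dict[int, dict[int, float]] = {}
    for eff in effects or ():
        nodes = eff.nodes
        if nodes is None:
            nodes = tuple(range(1, len(truth.node_maps[eff.component])))
        for nd in nodes:
            if not 0 <= nd < len(truth.node_maps[eff.component]):
                raise IndexError(
                    f"node {nd} out of range for component {eff.component}"
                )
            atten.setdefault(eff.component, {})[nd] = eff.attenuation
    for k, nodes in enumerate(truth.node_maps):
        raw = np.zeros(truth.grid.shape)
        for nd, blob in enumerate(nodes):
            raw += atten.get(k, {}).get(nd, 1.0) * blob
        out[k] = truth.grid.vectorize(raw)
    return out


def make_subject_series(
    truth: PhantomTruth,
    subject_kind: str,
    subject_index: int,
    config: PhantomConfig,
) -> np.ndarray:
    """Generate one subject's 4D series: mixture of maps plus Gaussian noise.

    ``subject_kind`` is ``"control"`` or ``"patient"``; for patients the
    lesion effects of ``config.lesion_spec[subject_index]`` multiply the
    selected nodes of the selected components.  Noise and time courses are
    reproducible functions of ``(config.seed, kind, index)`` -- a control and
    a patient with the same index share noise, so they differ only inside
    attenuated nodes.
    """
    if subject_kind not in ("control", "patient"):
        raise ValueError(f"unknown subject_kind {subject_kind!r}")
    effects: tuple[LesionEffect, ...] | None = None
    if subject_kind == "patient" and subject_index < len(config.lesion_spec):
        effects = tuple(config.lesion_spec[subject_index])
    # stream 1: time courses / noise, keyed by index only (kind-independent)
    # so matched-seed control/patient pairs are voxelwise comparable.
    rng = _rng(config, 1, subject_index)
    K, T = config.n_components, config.n_timepoints
    tc = _smooth_timecourses(K, T, rng)
    truth.timecourses[f"{subject_kind}-{subject_index:02d}"] = tc
    maps = effective_maps(truth, effects)
    data = maps.T @ tc  # n_voxels x T
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal(data.shape)
    return truth.grid.devectorize(data)


def make_motion_params(
    config: PhantomConfig, subject_kind: str, subject_index: int
) -> np.ndarray:
    """Synthetic realignment parameters (T x 6): slow random drifts.

    Translations in mm, rotations in radians, scaled so mean frame-wise
    displacement lands near the 0.1-0.2 mm range typical of compliant
    subjects.
    """
    rng = _rng(config, 2, 0 if subject_kind == "control" else 1, subject_index)
    steps = rng.standard_normal((config.n_timepoints, 6))
    steps[:, :3] *= 0.05  # mm per frame
    steps[:, 3:] *= 0.001  # rad per frame
    return gaussian_filter1d(np.cumsum(steps, axis=0), sigma=3.0, axis=0)


def make_behavior_scores(
    truth: PhantomTruth,
    delta_cs_matrix: np.ndarray,
    config: PhantomConfig,
) -> "pd.DataFrame":
    """Domain scores from the planted sparse non-negative linear model.

    ``score[p, domain] = intercept + coefs . delta_cs_matrix[p] + noise``.
    """
    import pandas as pd

    delta = np.asarray(delta_cs_matrix, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta_cs_matrix must be finite")
    rng = _rng(config, 3)
    cols = {}
    for domain, spec in truth.true_behavior_coefs.items():
        beta = np.asarray(spec.coefs, dtype=float)
        if beta.shape[0] != delta.shape[1]:
            raise ValueError(
                f"behaviour spec for {domain!r} has {beta.shape[0]} coefficients "
                f"but delta matrix has {delta.shape[1]} components"
            )
        y = spec.intercept + delta @ beta
        if spec.noise_sd > 0:
            y = y + spec.noise_sd * rng.standard_normal(delta.shape[0])
        cols[domain] = y
    return pd.DataFrame(cols, index=[f"patient-{p:02d}" for p in range(delta.shape[0])])


def match_components(estimated: np.ndarray, true_maps: np.ndarray):
    """Match estimated to planted maps by maximal |correlation| (Hungarian).

    Returns ``(perm, corrs)``: ``perm[j]`` is the estimated row assigned to
    true row ``j`` and ``corrs[j]`` the achieved |Pearson r|.
    """
    K = true_maps.shape[0]
    est = np.asarray(estimated)
    corr = np.corrcoef(est, true_maps)[: est.shape[0], est.shape[0] :]
    cost = -np.abs(corr)
    ri, ci = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    corrs = np.empty(K)
    for r, c in zip(ri, ci):
        perm[c] = r
        corrs[c] = abs(corr[r, c])
    return perm, corrs


def default_lesion_spec(attenuations=(0.0, 0.5), components=(0, 1)):
    """Convenience: one lesioned patient per (component, attenuation) pair."""
    return tuple(
        (LesionEffect(component=c, attenuation=a),)
        for c, a in zip(components, attenuations)
    )
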