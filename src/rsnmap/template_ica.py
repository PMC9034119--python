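"""Group template components: PCA reduction, Infomax ICA, ICASSO stability.

The normative reference of the whole method is a set of *template* spatial
independent components estimated once on a healthy-control cohort.  The
estimation follows the standard group spatial-ICA recipe: subject-level
temporal PCA, concatenation, group-level PCA with whitening, natural-gradient
Infomax ICA, and an ICASSO-style stability analysis that repeats the
decomposition from several random initializations, clusters the pooled
components by absolute spatial correlation, scores each cluster with the
quality index Iq (mean intra-cluster minus mean extra-cluster similarity) and
returns the centrotype of each cluster as the central solution.

Numerical conventions fixed here (and relied on by the Iq identities):

* the whitened group matrix has voxel-mean-free rows with identity
  covariance, so any orthonormal unmixing yields *exactly* decorrelated
  spatial sources;
* after Infomax converges the unmixing matrix is symmetrically decorrelated,
  making distinct components of one run orthogonal -- duplicate-seed ICASSO
  therefore yields Iq = 1 to machine precision;
* each map is oriented so its skewness is positive ("activation is
  positive"), then Z-scored over mask voxels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew

logger = logging.getLogger("rsnmap")


class ReductionError(ValueError):
    """Requested PCA dimensions exceed the available rank."""


class ClusteringError(RuntimeError):
    """ICASSO clustering produced a degenerate partition."""


@dataclass
class GroupDataStack:
    """Per-subject voxel x time matrices on a shared mask and voxel order.

    Zero-variance voxels inside the mask are detected at construction and
    reported; callers should drop them from the mask before stacking.
    """

    subjects: list[np.ndarray]
    n_voxels: int = 0

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("empty stack")
        self.n_voxels = self.subjects[0].shape[0]
        for i, s in enumerate(self.subjects):
            if s.shape[0] != self.n_voxels:
                raise ValueError(f"subject {i} voxel count differs")
        for i, s in enumerate(self.subjects):
            dead = np.flatnonzero(s.std(axis=1) == 0)
            if dead.size:
                logger.warning(
                    "subject %d: %d zero-variance voxels inside mask", i, dead.size
                )


@dataclass
class Reduction:
    """Whitened group matrix plus back-projection bookkeeping."""

    whitened: np.ndarray  # n_group_pcs x n_voxels, rows zero-mean, cov = I
    explained_variance: float
    subject_bases: list[np.ndarray]  # per-subject V x n_subject_pcs scores


@dataclass
class InfomaxResult:
    unmixing: np.ndarray  # n_components x n_components (on whitened rows)
    maps: np.ndarray  # n_components x n_voxels, Z-scored, positive skew
    converged: bool
    n_iter: int
    final_change: float


@dataclass
class StabilityCluster:
    """One ICASSO cluster of pooled run components."""

    members: list[tuple[int, int]]  # (run, component) indices
    centrotype: tuple[int, int]
    iq: float


@dataclass
class TemplateComponent:
    """Group-level Z-scored spatial map: the normative reference."""

    id: int
    map: np.ndarray  # vector over mask voxels, mean 0 sd 1
    iq: float = float("nan")
    label: str = "network-candidate"


def _center_rows(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=1, keepdims=True)


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    sd = m.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot Z-score constant component map")
    return (m - m.mean(axis=1, keepdims=True)) / sd


def _positive_skew(maps: np.ndarray) -> np.ndarray:
    signs = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    return maps * signs[:, None]


def reduce_and_concatenate(
    stack: GroupDataStack, n_subject_pcs: int, n_group_pcs: int
) -> Reduction:
    """Two-stage PCA: subject temporal reduction, then group whitening.

    Each subject matrix is voxel-mean centred per frame (spatial sources are
    zero-mean), reduced to its top ``n_subject_pcs`` spatial score vectors,
    and the score matrices are concatenated and reduced again.  The returned
    whitened matrix ``Z`` (``n_group_pcs x n_voxels``) satisfies
    ``Z @ Z.T / n_voxels = I`` with zero-mean rows.
    """
    rel_tol = 1e-10
    scores = []
    for i, subj in enumerate(stack.subjects):
        if n_subject_pcs > subj.shape[1]:
            raise ReductionError(
                f"subject {i}: n_subject_pcs={n_subject_pcs} > T={subj.shape[1]}"
            )
        X = _center_rows(subj.T).T  # center each frame across voxels
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        if s[n_subject_pcs - 1] <= rel_tol * s[0]:
            raise ReductionError(
                f"subject {i}: rank < n_subject_pcs={n_subject_pcs}"
            )
        scores.append(U[:, :n_subject_pcs] * s[:n_subject_pcs])
    Y = np.concatenate(scores, axis=1)  # V x (m * n_subject_pcs)
    if n_group_pcs > Y.shape[1]:
        raise ReductionError(
            f"n_group_pcs={n_group_pcs} > concatenated dimension {Y.shape[1]}"
        )
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    if s[n_group_pcs - 1] <= rel_tol * s[0]:
        raise ReductionError(f"group rank < n_group_pcs={n_group_pcs}")
    V = Y.shape[0]
    whitened = np.sqrt(V) * U[:, :n_group_pcs].T
    explained = float((s[:n_group_pcs] ** 2).sum() / (s**2).sum())
    return Reduction(whitened=whitened, explained_variance=explained, subject_bases=scores)


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^{-1/2} W (closest orthonormal matrix)."""
    u, _, vt = np.linalg.svd(W)
    return u @ vt


def infomax_ica(
    reduced: np.ndarray,
    n_components: int,
    seed: int = 0,
    lr: float | None = None,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> InfomaxResult:
    """Natural-gradient Infomax spatial ICA with logistic nonlinearity.

    Full-batch natural-gradient ascent.  The learning rate starts at
    ``0.005 / ln(n_components)`` (unless given) and is annealed (x 0.98)
    whenever the update direction turns by more than 60 degrees, which damps
    oscillation without freezing progress; convergence is declared when the
    *learning-rate-independent* natural-gradient magnitude
    ``||G W|| / ||W||`` drops below ``tol``.  Numerical blow-up triggers a
    rate cut and weight reset, and raises if persistent.  On exit the
    unmixing matrix is symmetrically decorrelated (distinct sources exactly
    uncorrelated) and each source map is sign-oriented (positive skewness)
    and Z-scored.
    """
    Z = np.asarray(reduced, dtype=float)
    if n_components > Z.shape[0]:
        raise ReductionError(
            f"n_components={n_components} > whitened rows {Z.shape[0]}"
        )
    Z = Z[:n_components]
    n, V = Z.shape
    if lr is None:
        lr = 0.005 / max(np.log(n), 1.0)
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((n, n)))
    W0 = W.copy()
    eye = np.eye(n)
    prev_dW: np.ndarray | None = None
    change = np.inf
    converged = False
    resets = 0
    it = 0
    for it in range(1, max_iter + 1):
        U = W @ Z
        Y = 1.0 / (1.0 + np.exp(-U))
        natgrad = (eye + (1.0 - 2.0 * Y) @ U.T / V) @ W
        if not np.all(np.isfinite(natgrad)):
            resets += 1
            if resets > 8:
                raise FloatingPointError("Infomax diverged despite annealing")
            lr *= 0.1
            W = W0.copy()
            prev_dW = None
            continue
        change = float(np.linalg.norm(natgrad) / np.linalg.norm(W))
        if change < tol:
            converged = True
            break
        dW = lr * natgrad
        if prev_dW is not None:
            denom = np.linalg.norm(dW) * np.linalg.norm(prev_dW)
            if denom > 0 and (dW.ravel() @ prev_dW.ravel()) / denom < 0.5:
                lr *= 0.98  # direction turned by > 60 degrees
        prev_dW = dW
        W = W + dW
    if not converged:
        warnings.warn(
            f"Infomax did not converge in {max_iter} iterations "
            f"(last gradient magnitude {change:.2e})",
            RuntimeWarning,
        )
    W = _sym_decorrelate(W)
    maps = _zscore_rows(_positive_skew(W @ Z))
    return InfomaxResult(
        unmixing=W, maps=maps, converged=converged, n_iter=it, final_change=change
    )


def _abs_corr(maps: np.ndarray) -> np.ndarray:
    return np.abs(np.corrcoef(maps))


def icasso_stability(
    reduced: np.ndarray,
    n_components: int,
    n_runs: int = 10,
    seed: int = 0,
    seeds: list[int] | None = None,
    **infomax_kwargs,
) -> tuple[list[StabilityCluster], list[TemplateComponent]]:
    """Repeat Infomax, cluster pooled components, return the central solution.

    Similarity is absolute Pearson correlation over mask voxels; clustering
    is agglomerative with average linkage cut at ``n_components`` clusters.
    Per cluster, ``iq`` is mean intra-cluster similarity minus mean
    similarity to non-members, and the centrotype is the member maximizing
    summed intra-cluster similarity (ties broken by lowest run index).
    """
    if n_runs < 2:
        raise ValueError("ICASSO needs n_runs >= 2")
    if seeds is None:
        seeds = [int(np.random.default_rng([seed & 0x7FFFFFFF, r]).integers(2**31))
                 for r in range(n_runs)]
    elif len(seeds) != n_runs:
        raise ValueError("len(seeds) != n_runs")

    runs = [
        infomax_ica(reduced, n_components, seed=s, **infomax_kwargs) for s in seeds
    ]
    pooled = np.concatenate([r.maps for r in runs], axis=0)
    index = [(r, c) for r in range(n_runs) for c in range(n_components)]
    sim = _abs_corr(pooled)
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - np.clip(sim, 0.0, 1.0), checks=False)
    labels = fcluster(linkage(dist, method="average"), n_components, criterion="maxclust")
    if len(np.unique(labels)) != n_components:
        raise ClusteringError(
            f"expected {n_components} clusters, got {len(np.unique(labels))}"
        )

    clusters: list[StabilityCluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        inside = sim[np.ix_(idx, idx)]
        n_in = len(idx)
        intra = 1.0 if n_in == 1 else float(
            (inside.sum() - n_in) / (n_in * (n_in - 1))
        )
        outside_idx = np.flatnonzero(labels != lab)
        extra = float(sim[np.ix_(idx, outside_idx)].mean()) if outside_idx.size else 0.0
        iq = intra - extra
        # centrotype: maximal summed intra similarity; ties -> lowest run index
        sums = inside.sum(axis=1)
        best = idx[np.lexsort((idx, -sums))[0]]
        clusters.append(
            StabilityCluster(
                members=[index[i] for i in idx],
                centrotype=index[best],
                iq=iq,
            )
        )
    # deterministic template order: by centrotype (run, component) index
    clusters.sort(key=lambda c: c.centrotype)
    templates = []
    for cid, cl in enumerate(clusters):
        run, comp = cl.centrotype
        templates.append(TemplateComponent(id=cid, map=runs[run].maps[comp].copy(), iq=cl.iq))
    return clusters, templates


def select_network_components(
    templates: list[TemplateComponent], labels: dict[int, str]
) -> list[TemplateComponent]:
    """Filter templates to those labelled network candidates.

    ``labels`` maps template id to ``"artifact"`` or ``"network"`` (the
    labelling itself is manual and consumed as input).  Missing ids raise.
    """
    missing = [t.id for t in templates if t.id not in labels]
    if missing:
        raise KeyError(f"no label for template ids {missing}")
    bad = {v for v in labels.values() if v not in ("artifact", "network")}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    kept = []
    for t in templates:
        if labels[t.id] == "network":
            t.label = "network-candidate"
            kept.append(t)
        else:
            t.label = "artifact"
    if not kept:
        warnings.warn("all components labelled artifact: empty template set")
    return kept
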