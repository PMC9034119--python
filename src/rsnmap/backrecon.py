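"""Template-guided one-unit ICA back-reconstruction of subject components.

Each template component is re-estimated in an individual subject by a
one-unit ICA with a spatial reference: the estimate ``y = w^T B`` (``B`` the
subject's whitened spatial basis) maximizes a weighted sum of

* negentropy ``J(y) = (E[G(y)] - E[G(nu)])^2`` with ``G = log cosh``
  (independence / non-Gaussianity of the subject component), and
* squared Pearson correlation ``rho(y, template)^2`` (correspondence with
  the group template),

``F(w) = lambda * J(y) + (1 - lambda) * rho^2`` over the unit sphere
``||w|| = 1``.  The iteration starts from the projection of the template onto
the whitened basis (the dual-regression direction), so as ``lambda -> 0`` the
result converges to the dual-regression spatial map.  Component identity is
inherited from the template, which guarantees that component *i* of every
subject is compared against template *i* downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .template_ica import ReductionError, TemplateComponent

logger = logging.getLogger("rsnmap")

def _logcosh(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(cosh(x)) = |x| + log1p(exp(-2|x|)) - log 2."""
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


# E[log cosh(nu)] for standard normal nu, the Gaussian baseline of J.
_GAUSS_LOGCOSH: float = quad(
    lambda x: _logcosh(x) * np.exp(-x * x / 2) / np.sqrt(2 * np.pi),
    -np.inf,
    np.inf,
)[0]


@dataclass(frozen=True)
class GigConfig:
    """Optimizer settings for guided one-unit ICA.

    ``lambda_weight`` mixes negentropy (at 1) against template
    correspondence (at 0) and must lie strictly inside (0, 1).
    """

    lambda_weight: float = 0.5
    nonlinearity: str = "logcosh"
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_weight < 1.0:
            raise ValueError("lambda_weight must be strictly inside (0, 1)")
        if self.nonlinearity != "logcosh":
            raise ValueError("only the log-cosh contrast is implemented")


@dataclass
class SubjectComponentMap:
    """Back-reconstructed Z-scored spatial map for one component."""

    id: int
    map: np.ndarray  # vector over mask voxels, mean 0, sd 1
    correspondence: float  # Pearson r with the template
    negentropy: float  # J(y) >= 0
    converged: bool
    n_iter: int


def whiten_subject(series: np.ndarray, n_pcs: int) -> np.ndarray:
    """Whitened spatial basis ``B`` (``n_pcs x n_voxels``) of one subject.

    Frames are voxel-mean centred; the rows of ``B`` are zero-mean with
    ``B @ B.T / n_voxels = I``, spanning the top spatial PCs.
    """
    V, T = series.shape
    if n_pcs > T:
        raise ReductionError(f"n_pcs={n_pcs} > T={T}")
    X = series - series.mean(axis=0, keepdims=True)  # center across voxels
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s[n_pcs - 1] <= 1e-10 * s[0]:
        raise ReductionError(f"data rank < n_pcs={n_pcs}")
    return np.sqrt(V) * U[:, :n_pcs].T


def _negentropy(y: np.ndarray) -> float:
    return float((np.mean(_logcosh(y)) - _GAUSS_LOGCOSH) ** 2)


def guided_one_unit(
    whitened: np.ndarray, template: TemplateComponent, config: GigConfig
) -> SubjectComponentMap:
    """Maximize ``F(w) = lambda*J(y) + (1-lambda)*rho(y, t)^2`` on ``||w||=1``.

    Gradient ascent with backtracking and per-step renormalization;
    initialization is the normalized projection of the template map onto the
    whitened basis.  A negative final correspondence triggers a sign flip
    (logged); non-convergence returns the last iterate flagged.
    """
    B = whitened
    n, V = B.shape
    t = np.asarray(template.map, dtype=float)
    tsd = t.std()
    if tsd == 0:
        raise ValueError("constant template map")
    t = (t - t.mean()) / tsd
    c = B @ t / V  # rho(y, t) = w . c for unit-variance y
    lam = config.lambda_weight

    w = c / np.linalg.norm(c) if np.linalg.norm(c) > 0 else np.full(n, 1 / np.sqrt(n))

    def objective(wv: np.ndarray) -> tuple[float, np.ndarray, float, float]:
        y = wv @ B
        gamma = np.mean(_logcosh(y)) - _GAUSS_LOGCOSH
        rho = float(wv @ c)
        grad = lam * 2.0 * gamma * (B @ np.tanh(y)) / V + (1 - lam) * 2.0 * rho * c
        return lam * gamma**2 + (1 - lam) * rho**2, grad, rho, gamma**2

    step = 1.0
    F, grad, rho, J = objective(w)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        moved = False
        while step > 1e-12:
            w_new = w + step * grad
            w_new /= np.linalg.norm(w_new)
            F_new, grad_new, rho_new, J_new = objective(w_new)
            if F_new >= F:
                moved = True
                break
            step *= 0.5
        if not moved:
            converged = True  # no ascent direction left at float resolution
            break
        delta = min(
            np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)
        )  # sign-invariant step size
        w, F, grad, rho, J = w_new, F_new, grad_new, rho_new, J_new
        step = min(step * 2.0, 1.0)
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"guided one-unit ICA did not converge for component {template.id}",
            RuntimeWarning,
        )
    if rho < 0:
        logger.info("component %d: negative correspondence, sign flipped", template.id)
        w = -w
        rho = -rho
    y = w @ B
    y = (y - y.mean()) / y.std()
    return SubjectComponentMap(
        id=template.id,
        map=y,
        correspondence=float(rho),
        negentropy=_negentropy(y),
        converged=converged,
        n_iter=it,
    )


def dual_regression_map(series: np.ndarray, template_map: np.ndarray) -> np.ndarray:
    """Independent two-step spatial-regression estimate (oracle for tests).

    Regress the series on the template map to get a time course, then
    regress the series on that time course to get a map; returned Z-scored.
    """
    X = series - series.mean(axis=0, keepdims=True)
    t = np.asarray(template_map, dtype=float)
    t = (t - t.mean()) / t.std()
    tau = X.T @ t / (t @ t)
    tau = tau - tau.mean()
    m = X @ tau / (tau @ tau)
    return (m - m.mean()) / m.std()


def backreconstruct_all(
    series: np.ndarray,
    templates: list[TemplateComponent],
    config: GigConfig,
    n_pcs: int | None = None,
) -> list[SubjectComponentMap]:
    """Back-reconstruct every template component in one subject.

    The subject is whitened once (default order: number of templates + 5,
    capped at T); failures of single components are recorded and skipped,
    but if every component fails an error is raised.
    """
    if not templates:
        raise ValueError("no templates supplied")
    if n_pcs is None:
        n_pcs = min(len(templates) + 5, series.shape[1])
    B = whiten_subject(series, n_pcs)
    out: list[SubjectComponentMap] = []
    failures: list[tuple[int, Exception]] = []
    for tpl in templates:
        try:
            out.append(guided_one_unit(B, tpl, config))
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("component %d failed: %s", tpl.id, exc)
            failures.append((tpl.id, exc))
    if not out:
        raise RuntimeError(f"back-reconstruction failed for all components: {failures}")
    return out
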