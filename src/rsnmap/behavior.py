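"""Brain-behaviour linkage: domain aggregation and non-negative regression.

Neuropsychological test Z-scores are averaged into four cognitive domain
scores (memory, language, executive, attention; positive = good
performance).  Each domain score is then predicted from the patients'
standardized component distances (delta CS sigma) with a sign-constrained
least-squares model:

    minimize ||y - X beta - beta0||^2   subject to beta >= 0,

where the non-negativity constraint acts as an implicit feature selector
(most coefficients land exactly at zero).  The intercept is unconstrained;
optional demographic covariates (age, education) enter as +/- column pairs
so the same solver can express either sign.  A model is *accepted* as
evidence of a real brain-behaviour relationship only when the in-sample
R-squared (squared Pearson correlation of prediction vs observation) reaches
0.5 and every nonzero coefficient's bootstrap coefficient of variation stays
below 200%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger("rsnmap")

DOMAINS = ("memory", "language", "executive", "attention")


@dataclass
class DomainScore:
    patient_id: str
    domain: str
    aggregate_z: float
    n_tests: int


@dataclass
class NNLSModel:
    """Sign-constrained sparse regression for one cognitive domain."""

    domain: str
    coefficients: np.ndarray  # >= 0, one per component
    intercept: float
    demographic_coefs: dict[str, float] = field(default_factory=dict)
    support: tuple[int, ...] = ()
    r_squared: float = float("nan")
    cv_percent: dict[int, float] = field(default_factory=dict)
    accepted: bool = False

    def predict(self, X: np.ndarray, demographics: pd.DataFrame | None = None) -> np.ndarray:
        y = X @ self.coefficients + self.intercept
        if self.demographic_coefs:
            if demographics is None:
                raise ValueError("model includes demographics; none supplied")
            for name, coef in self.demographic_coefs.items():
                y = y + coef * demographics[name].to_numpy(dtype=float)
        return y


def aggregate_domains(
    test_z: pd.DataFrame, domain_assignment: dict[str, str]
) -> pd.DataFrame:
    """Per-patient, per-domain mean of the available test Z-scores.

    ``test_z`` is patients x tests (NaN = missing).  Every test column must
    be assigned to exactly one domain.  Patients with no completed test at
    all are excluded (logged); a domain with no completed test for a patient
    stays NaN (undefined).
    """
    unknown = [t for t in test_z.columns if t not in domain_assignment]
    if unknown:
        raise KeyError(f"tests without domain assignment: {unknown}")
    bad = {d for d in domain_assignment.values() if d not in DOMAINS}
    if bad:
        raise ValueError(f"unknown domains {sorted(bad)}; expected {DOMAINS}")
    empty = test_z.index[test_z.isna().all(axis=1)]
    if len(empty):
        logger.info("excluding patients with no completed tests: %s", list(empty))
        test_z = test_z.drop(index=empty)
    out = {}
    for domain in DOMAINS:
        tests = [t for t in test_z.columns if domain_assignment[t] == domain]
        if tests:
            out[domain] = test_z[tests].mean(axis=1, skipna=True)
    return pd.DataFrame(out)


def _design(
    X: np.ndarray, demographics: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    """Augment component columns with intercept and demographic +/- pairs."""
    n = X.shape[0]
    cols = [X]
    names: list[str] = []
    if demographics is not None:
        for name in demographics.columns:
            v = demographics[name].to_numpy(dtype=float)[:, None]
            cols.extend([v, -v])
            names.append(name)
    cols.extend([np.ones((n, 1)), -np.ones((n, 1))])
    return np.hstack(cols), names


def _solve(design: np.ndarray, y: np.ndarray, p: int, demo_names: list[str]):
    beta, _ = nnls(design, y)
    coefs = beta[:p]
    demo = {}
    for j, name in enumerate(demo_names):
        demo[name] = beta[p + 2 * j] - beta[p + 2 * j + 1]
    intercept = beta[-2] - beta[-1]
    return coefs, demo, intercept


def nnls_fit(
    delta_cs_matrix: np.ndarray,
    scores: pd.Series,
    include_demographics: bool = False,
    demographics: pd.DataFrame | None = None,
    domain: str = "",
) -> NNLSModel:
    """Fit the sign-constrained model of one domain score.

    ``delta_cs_matrix`` is patients x components; ``scores`` the domain's
    aggregate Z per patient (same order).  Requires at least 5 patients.
    """
    X = np.asarray(delta_cs_matrix, dtype=float)
    y = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("delta_cs_matrix and scores have mismatched patients")
    if X.shape[0] < 5:
        raise ValueError(f"need >= 5 patients, got {X.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite predictors or scores")
    if np.all(X == 0):
        raise ValueError("rank-0 design matrix")
    # duplicate predictor columns split weight arbitrarily; flag for the log
    if X.shape[1] > 1:
        corr = np.corrcoef(X.T)
        dup = np.argwhere(np.triu(np.isclose(corr, 1.0, atol=1e-12), k=1))
        for i, j in dup:
            if np.allclose(X[:, i], X[:, j]):
                logger.warning(
                    "duplicate predictor columns %d and %d: coefficient split "
                    "is arbitrary, prediction unaffected", i, j
                )
    demo = demographics if include_demographics else None
    design, demo_names = _design(X, demo)
    coefs, demo_coefs, intercept = _solve(design, y, X.shape[1], demo_names)
    # numerically-zero coefficients do not count as selected features
    tol = 1e-10 * max(1.0, float(coefs.max(initial=0.0)))
    coefs[coefs <= tol] = 0.0
    support = tuple(int(k) for k in np.flatnonzero(coefs > 0))
    if not support:
        warnings.warn(f"domain {domain!r}: all-zero solution, empty support")
    return NNLSModel(
        domain=domain,
        coefficients=coefs,
        intercept=intercept,
        demographic_coefs=demo_coefs,
        support=support,
    )


def model_diagnostics(
    model: NNLSModel,
    delta_cs_matrix: np.ndarray,
    scores: pd.Series,
    demographics: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> NNLSModel:
    """R-squared and bootstrap coefficient CVs; sets the acceptance flag.

    R^2 is the squared Pearson correlation between prediction and
    observation.  CVs come from a case-resampling bootstrap (patients drawn
    with replacement); a support coefficient that is zero in more than half
    of the resamples gets CV = +inf and the model is rejected.  Acceptance
    requires R^2 >= 0.5 and every support CV < 200%.
    """
    X = np.asarray(delta_cs_matrix, dtype=float)
    y = np.asarray(scores, dtype=float)
    yhat = model.predict(X, demographics)
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        model.r_squared = 0.0
    else:
        model.r_squared = float(np.corrcoef(yhat, y)[0, 1] ** 2)

    cv: dict[int, float] = {}
    if model.support:
        rng = np.random.default_rng(seed)
        n, p = X.shape
        demo = demographics
        design_full, demo_names = _design(X, demo)
        boots = np.empty((n_boot, p))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            coefs_b, _, _ = _solve(design_full[idx], y[idx], p, demo_names)
            boots[b] = coefs_b
        for k in model.support:
            zero_frac = float(np.mean(boots[:, k] == 0))
            if zero_frac > 0.5:
                cv[k] = float("inf")
            else:
                cv[k] = float(100.0 * boots[:, k].std(ddof=1) / abs(model.coefficients[k]))
    model.cv_percent = cv
    model.accepted = (
        model.r_squared >= 0.5
        and bool(model.support)
        and all(v < 200.0 for v in cv.values())
    )
    return model


def fit_all_domains(
    delta_cs_matrix: np.ndarray,
    domain_scores: pd.DataFrame,
    include_demographics: bool = False,
    demographics: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, NNLSModel]:
    """One accepted/rejected model per available domain column."""
    models = {}
    for d, domain in enumerate(domain_scores.columns):
        y = domain_scores[domain]
        ok = y.notna()
        model = nnls_fit(
            delta_cs_matrix[ok.to_numpy()],
            y[ok],
            include_demographics=include_demographics,
            demographics=demographics.loc[ok] if demographics is not None else None,
            domain=domain,
        )
        models[domain] = model_diagnostics(
            model,
            delta_cs_matrix[ok.to_numpy()],
            y[ok],
            demographics=demographics.loc[ok] if demographics is not None else None,
            n_boot=n_boot,
            seed=seed + d,
        )
    return models
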