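"""Head-motion quality control: frame-wise displacement and group comparison.

Frame-wise displacement (FD) summarises rigid-body realignment parameters as

    FD_t = |dx_t| + |dy_t| + |dz_t| + r * (|da_t| + |db_t| + |dg_t|)

with backward differences, translations in mm, rotations in radians
converted to arc length at a head radius of r = 50 mm.  The first frame has
FD = 0 by convention, so the series has one value per volume.  Group motion
is compared with the two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact
for small tie-free samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("rsnmap")


@dataclass
class MotionTrace:
    """Realignment parameters and their FD summary for one subject."""

    params: np.ndarray  # T x 6: 3 translations (mm), 3 rotations (rad)
    fd: np.ndarray  # length T, leading 0
    mean_fd: float
    median_fd: float


def framewise_displacement(
    params: np.ndarray, head_radius_mm: float = 50.0
) -> MotionTrace:
    """FD series from a T x 6 realignment-parameter matrix.

    Emits a warning when any rotation exceeds pi in magnitude (parameters
    plausibly in degrees rather than radians).
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"expected T x 6 parameters, got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if np.any(np.abs(params[:, 3:]) > np.pi):
        warnings.warn(
            "rotation magnitudes exceed pi; parameters may be in degrees",
            RuntimeWarning,
        )
    diff = np.abs(np.diff(params, axis=0))
    fd_tail = diff[:, :3].sum(axis=1) + head_radius_mm * diff[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_tail])
    return MotionTrace(
        params=params,
        fd=fd,
        mean_fd=float(fd.mean()),
        median_fd=float(np.median(fd)),
    )


def read_realignment_params(path) -> np.ndarray:
    """Read a 6-column whitespace-delimited realignment parameter file."""
    params = np.loadtxt(str(path))
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got shape {params.shape}")
    return params


def compare_motion(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-subject FD summaries.

    Returns ``(statistic, p)`` where the statistic is the Mann-Whitney U of
    the first group.  Exact null distribution for small tie-free samples,
    tie-corrected normal approximation otherwise.  All values tied across
    both groups yields p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all FD values tied across groups; p = 1", RuntimeWarning)
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
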