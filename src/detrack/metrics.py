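"""Tracking evaluation: success rate, RMSE, missing frames, paired tests.

The tracking success rate (TSR) is the percentage of *tracked* frames
whose 2D Euclidean error against the (estimated or simulated) ground
truth is strictly below 2 mm; missing frames are reported separately as
a percentage of all frames.  RMSE is the root-mean-square 2D error over
the tracked frames.  Technique comparisons use the two-sided Wilcoxon
matched-pair signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport",
    "compute_tsr",
    "compute_rmse",
    "compute_missing",
    "evaluate_tracking",
    "paired_signed_rank",
    "SignedRankResult",
]


@dataclass
class MetricReport:
    tsr: float            # % of tracked frames with error < threshold (NaN if none tracked)
    rmse: float           # mm over tracked frames (NaN if none tracked)
    missing: float        # % of all frames untracked
    n_tracked: int
    n_total: int
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.n_tracked > self.n_total:
            raise ValueError("n_tracked cannot exceed n_total")


def _paired_errors(track, gt) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame 2D errors (mm) and the tracked (non-missing) mask."""
    pos = np.asarray(track.positions(), dtype=float)
    gt_pos = np.asarray(gt.positions(), dtype=float)
    if pos.shape != gt_pos.shape:
        raise ValueError("track and ground truth must align frame by frame")
    tracked = ~np.asarray(track.missing, dtype=bool)
    err = np.linalg.norm(pos - gt_pos, axis=1)
    return err, tracked


def compute_tsr(track, gt, threshold: float = 2.0) -> float:
    """% of tracked frames with error strictly below ``threshold`` mm.

    Missing frames are excluded from numerator and denominator; with no
    tracked frames the rate is undefined and NaN is returned.
    """
    err, tracked = _paired_errors(track, gt)
    n_tracked = int(tracked.sum())
    if n_tracked == 0:
        return float("nan")
    return 100.0 * float(np.sum(err[tracked] < threshold)) / n_tracked


def compute_rmse(track, gt) -> float:
    """Root-mean-square 2D error (mm) over tracked frames."""
    err, tracked = _paired_errors(track, gt)
    if not tracked.any():
        return float("nan")
    return float(np.sqrt(np.mean(err[tracked] ** 2)))


def compute_missing(track) -> float:
    """% of all frames the tracker declared missing."""
    missing = np.asarray(track.missing, dtype=bool)
    return 100.0 * float(missing.sum()) / len(missing)


def evaluate_tracking(track, gt, threshold: float = 2.0) -> MetricReport:
    err, tracked = _paired_errors(track, gt)
    return MetricReport(
        tsr=compute_tsr(track, gt, threshold),
        rmse=compute_rmse(track, gt),
        missing=compute_missing(track),
        n_tracked=int(tracked.sum()),
        n_total=len(tracked),
        threshold=threshold,
    )


@dataclass
class SignedRankResult:
    statistic: float
    pvalue: float
    n_pairs: int
    degenerate: bool = False  # all paired differences were zero


def paired_signed_rank(metric_a, metric_b) -> SignedRankResult:
    """Two-sided Wilcoxon matched-pair signed-rank test.

    Uses the exact null distribution for up to 25 nonzero-difference
    pairs and the normal approximation with continuity correction
    above; pairs with zero difference are dropped.  If every difference
    is zero the test is degenerate and p = 1 is reported with a flag.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    nonzero = diff != 0
    if not nonzero.any():
        return SignedRankResult(statistic=0.0, pvalue=1.0, n_pairs=len(a), degenerate=True)
    n_eff = int(nonzero.sum())
    method = "exact" if n_eff <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.wilcoxon(
                a, b, zero_method="wilcox", correction=True, alternative="two-sided", method=method
            )
        except ValueError:
            res = stats.wilcoxon(
                a, b, zero_method="wilcox", correction=True, alternative="two-sided", method="approx"
            )
    return SignedRankResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), n_pairs=len(a)
    )
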