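"""Agreement metrics between two calibrated fields.

The headline statistic is the root mean square relative error normalized by
the pairwise mean of the two compared values,

    RMSRE = sqrt( (1/n) * sum_i ((x_i - xhat_i) / xbar_i)^2 ),
    xbar_i = (x_i + xhat_i) / 2,

which is symmetric in its arguments. Point-to-point relative differences use
the same pairwise-mean normalizer (in %), so the RMSRE equals the RMS of the
relative differences when nothing is excluded. Outlier trimming for summary
statistics uses the 1.5*IQR fence rule with linearly interpolated quartiles;
it never touches the RMSRE itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonReport",
    "rmsre",
    "relative_differences",
    "iqr_filter",
    "regression_agreement",
    "compare_fields",
]


def _paired(x, x_hat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(x_hat, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("need at least one pair")
    mean = (a + b) / 2.0
    zero = np.flatnonzero(mean == 0)
    if zero.size:
        raise ValueError(
            f"pairwise mean is zero at index {int(zero[0])}; relative error undefined"
        )
    return a, b, mean


def rmsre(x, x_hat) -> float:
    """Root mean square relative error with pairwise-mean normalization.

    Returned as a fraction (multiply by 100 for %). Symmetric in (x, x_hat),
    zero iff the inputs are identical.
    """
    a, b, mean = _paired(x, x_hat)
    return float(np.sqrt(np.mean(((a - b) / mean) ** 2)))


def relative_differences(x, x_hat) -> np.ndarray:
    """Per-item 100 * |x_i - xhat_i| / xbar_i (%), pairwise-mean normalizer."""
    a, b, mean = _paired(x, x_hat)
    return 100.0 * np.abs(a - b) / mean


def iqr_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by the 1.5*IQR fence rule.

    Q1/Q3 are the 25th/75th percentiles under the linear-interpolation
    convention; fences are computed once on the full input (not iterated).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise ValueError(f"need at least 4 values for quartile fences, got {v.size}")
    q1, q3 = np.percentile(v, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def regression_agreement(x, y) -> tuple[float, float, float]:
    """OLS of y on x: (slope, intercept, r_squared)."""
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError(f"need at least 3 points, got {a.size}")
    if np.ptp(a) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(a, b)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class ComparisonReport:
    """Agreement summary between two calibrated fields.

    ``rmsre`` is a fraction; ``rmsre_percent`` and the relative-difference
    summaries are in %. ``n_outliers_removed`` counts points dropped by the
    IQR rule from the summary statistics only.
    """

    rmsre: float
    mean_rel_diff: float
    max_rel_diff: float
    n_total: int
    n_outliers_removed: int
    r_squared: float
    per_item_diffs: np.ndarray = field(repr=False)

    @property
    def rmsre_percent(self) -> float:
        return 100.0 * self.rmsre

    def to_dict(self) -> dict:
        return {
            "rmsre": self.rmsre,
            "rmsre_percent": self.rmsre_percent,
            "mean_rel_diff_percent": self.mean_rel_diff,
            "max_rel_diff_percent": self.max_rel_diff,
            "n_total": int(self.n_total),
            "n_outliers_removed": int(self.n_outliers_removed),
            "r_squared": self.r_squared,
        }


def compare_fields(
    e_phantom, e_phantomless, with_outlier_removal: bool = True
) -> ComparisonReport:
    """Compare two scalar fields sampled on the same mask.

    RMSRE is always computed on all pairs; the mean/max relative-difference
    summaries optionally exclude IQR outliers; R^2 comes from the OLS of the
    second field on the first. A constant first field admits no regression:
    R^2 is reported as 1 when the fields agree exactly and NaN otherwise.
    """
    a = np.asarray(e_phantom, dtype=float).ravel()
    b = np.asarray(e_phantomless, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"fields are defined on different masks ({a.size} vs {b.size} voxels)"
        )
    diffs = relative_differences(a, b)
    err = rmsre(a, b)
    removed = 0
    summary = diffs
    if with_outlier_removal and diffs.size >= 4:
        summary, dropped = iqr_filter(diffs)
        removed = int(dropped.size)
    if np.ptp(a) == 0:
        r2 = 1.0 if np.array_equal(a, b) else float("nan")
    else:
        _, _, r2 = regression_agreement(a, b)
    return ComparisonReport(
        rmsre=err,
        mean_rel_diff=float(summary.mean()),
        max_rel_diff=float(summary.max()),
        n_total=int(a.size),
        n_outliers_removed=removed,
        r_squared=r2,
        per_item_diffs=diffs,
    )
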