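"""Accuracy metrics for scoring estimators against observed targets.

Three complementary metrics, each computed across rating sessions:

* **directional r², dr² = r·|r|** — the Pearson correlation squared with
  its sign retained; gauges *predictive* accuracy (does the estimator
  co-vary with its estimand?).  A two-sided pretest p-value from the
  exact t transform of r accompanies each dr².
* **mean of errors, m_e = mean(|x − y|)** — the average absolute
  deviation; gauges *approximating* accuracy against fixed benchmarks.
* **error of means, e_m = mean(x) − mean(y)** — the systematic bias of
  the estimator.  Always |e_m| ≤ m_e.

Benchmark verdicts: dr² > .8 (primary) and dr² > .67 (tentative) for
prediction, m_e < .2 (secondary) for approximation.

Undefined estimates (NaN) are excluded pairwise and the number of
sessions actually used is reported.  A constant vector has no defined
correlation (e.g. the constant chance estimate of percent agreement);
dr² is then NaN and the verdict "not assessable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Benchmarks",
    "DEFAULT_BENCHMARKS",
    "DirectionalR2",
    "ErrorSummary",
    "BiasSummary",
    "directional_r2",
    "mean_of_errors",
    "error_of_means",
    "benchmark",
    "pretest_stars",
]


@dataclass(frozen=True)
class Benchmarks:
    """Verdict thresholds for the evaluation report."""

    primary_dr2: float = 0.8
    tentative_dr2: float = 0.67
    secondary_me: float = 0.2


DEFAULT_BENCHMARKS = Benchmarks()


@dataclass(frozen=True)
class DirectionalR2:
    dr2: float
    r: float
    p_pretest: float
    n_used: int


@dataclass(frozen=True)
class ErrorSummary:
    """Mean absolute error with its dispersion and normal 95% CI."""

    m_e: float
    sd: float
    ci_low: float
    ci_high: float
    n_used: int


@dataclass(frozen=True)
class BiasSummary:
    """Error of means (mean estimate − mean target) with normal 95% CI."""

    e_m: float
    ci_low: float
    ci_high: float
    n_used: int


def _paired_finite(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def directional_r2(x, y) -> DirectionalR2:
    """Signed squared Pearson correlation, dr² = r·|r|, with pretest p.

    Returns NaN fields when fewer than 3 finite pairs remain or either
    vector is constant (no correlation is defined — notably any constant
    chance estimator).
    """
    xf, yf = _paired_finite(x, y)
    n = xf.size
    if n < 3 or np.ptp(xf) == 0.0 or np.ptp(yf) == 0.0:
        return DirectionalR2(math.nan, math.nan, math.nan, n)
    res = stats.pearsonr(xf, yf)
    r = float(res.statistic)
    return DirectionalR2(r * abs(r), r, float(res.pvalue), n)


def mean_of_errors(x, y) -> ErrorSummary:
    """Mean absolute deviation of estimates from targets, m_e."""
    xf, yf = _paired_finite(x, y)
    if xf.size == 0:
        raise ValueError("no finite paired values")
    err = np.abs(xf - yf)
    m = float(err.mean())
    sd = float(err.std(ddof=1)) if err.size > 1 else 0.0
    half = 1.96 * sd / math.sqrt(err.size)
    return ErrorSummary(m, sd, m - half, m + half, int(err.size))


def error_of_means(x, y) -> BiasSummary:
    """Mean estimate minus mean target, e_m, with CI from the paired diffs."""
    xf, yf = _paired_finite(x, y)
    if xf.size == 0:
        raise ValueError("no finite paired values")
    diff = xf - yf
    e = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    half = 1.96 * sd / math.sqrt(diff.size)
    return BiasSummary(e, e - half, e + half, int(diff.size))


def benchmark(
    dr2: float, m_e: float, benchmarks: Benchmarks = DEFAULT_BENCHMARKS
) -> dict[str, bool | None]:
    """Verdicts against the fixed benchmarks; None = not assessable."""
    return {
        "primary": None if math.isnan(dr2) else dr2 > benchmarks.primary_dr2,
        "tentative": (
            None if math.isnan(dr2) else dr2 > benchmarks.tentative_dr2
        ),
        "secondary": (
            None if math.isnan(m_e) else m_e < benchmarks.secondary_me
        ),
    }


def pretest_stars(p: float) -> str:
    """Conventional pretest tier labels for a p-value (never 'significance')."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
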