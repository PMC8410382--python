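"""Descriptive statistics and normality screening for dose samples.

Dose distributions in historical prescriptions are right-skewed with heavy
ties, so the summary is median/IQR based.  The 95% interval is a seeded
bootstrap percentile interval of the mean by default (switchable to the
median).  Normality is screened with a Kolmogorov–Smirnov test against a
normal with sample-estimated mean/sd — whose p-value is Lilliefors-corrected
by seeded Monte-Carlo simulation of the null, since the naive KS p is badly
conservative when parameters are estimated — plus a Shapiro–Wilk test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["DescriptiveSummary", "NormalityResult", "describe", "normality_tests"]


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    median: float
    iqr: float
    ci_low: float
    ci_high: float
    ci_method: str


@dataclass(frozen=True)
class NormalityResult:
    test: str
    statistic: float
    df: int
    p_value: float
    #: For the KS test, the uncorrected (naive) p-value is kept for transparency.
    p_value_naive: float | None = None


def describe(
    doses,
    ci_method: str = "bootstrap-mean",
    n_boot: int = 10_000,
    seed: int = 0,
) -> DescriptiveSummary:
    """Median, IQR (Hazen linear-interpolation quartiles) and a bootstrap 95% CI.

    ``ci_method`` selects the bootstrapped statistic: ``"bootstrap-mean"``
    (default) or ``"bootstrap-median"``.  The interval is the 2.5/97.5
    percentile of ``n_boot`` seeded resamples.
    """
    x = np.asarray(doses, dtype=float).ravel()
    if x.size < 5:
        raise ValueError(f"need at least 5 doses, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("doses must be finite")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="hazen")
    if ci_method == "bootstrap-mean":
        stat = np.mean
    elif ci_method == "bootstrap-median":
        stat = np.median
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = stat(x[idx], axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return DescriptiveSummary(
        n=int(x.size),
        median=float(med),
        iqr=float(q3 - q1),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_method=ci_method,
    )


def _lilliefors_pvalue(stat: float, n: int, n_sim: int, rng: np.random.Generator) -> float:
    """Monte-Carlo null distribution of the KS statistic with estimated parameters."""
    z = rng.standard_normal(size=(n_sim, n))
    mean = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    std = np.sort((z - mean) / sd, axis=1)
    grid = np.arange(1, n + 1) / n
    cdf = sps.norm.cdf(std)
    d_plus = np.max(grid - cdf, axis=1)
    d_minus = np.max(cdf - (np.arange(n) / n), axis=1)
    null = np.maximum(d_plus, d_minus)
    return float((np.sum(null >= stat) + 1) / (n_sim + 1))


def normality_tests(
    doses, seed: int = 0, n_sim: int = 2000
) -> tuple[NormalityResult, NormalityResult]:
    """KS (Lilliefors-corrected, seeded Monte-Carlo p) and Shapiro–Wilk tests.

    Returns ``(ks_result, shapiro_result)``.  Requires 5 ≤ n ≤ 5000 and a
    non-degenerate sample.
    """
    x = np.asarray(doses, dtype=float).ravel()
    if not (5 <= x.size <= 5000):
        raise ValueError(f"need 5 <= n <= 5000 doses, got {x.size}")
    if np.std(x) == 0:
        raise ValueError("zero-variance sample: normality tests undefined")
    n = x.size
    ks_stat, ks_p_naive = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    rng = np.random.default_rng(seed)
    ks_p = _lilliefors_pvalue(float(ks_stat), n, n_sim, rng)
    sw_stat, sw_p = sps.shapiro(x)
    return (
        NormalityResult("KS", float(ks_stat), n, ks_p, p_value_naive=float(ks_p_naive)),
        NormalityResult("ShapiroWilk", float(sw_stat), n, float(sw_p)),
    )
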