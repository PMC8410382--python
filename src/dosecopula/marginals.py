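"""Marginal distribution estimates and pseudo-observations.

Copula fitting separates the margins from the dependence: each dose sample
is first mapped to the unit interval through an estimate of its own CDF.
Two estimators are provided:

* the empirical CDF (step function), and
* a Gaussian-kernel smoothed CDF, which avoids the discreteness of the ECDF
  on heavily tied dose data (doses cluster at round gram values).

Pseudo-observations are the mapped values (u_i, v_i) = (F̂_A(x_i), F̂_B(y_i)),
clamped away from {0, 1} so copula log-densities stay finite.  A rank-based
alternative (midranks / (n + 1)) is included because dose data carries heavy
ties and ranks keep the margins exactly exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "EmpiricalCDF",
    "KernelMarginal",
    "PseudoObservations",
    "fit_ecdf",
    "fit_kernel_marginal",
    "silverman_bandwidth",
    "to_pseudo_observations",
]


def _validate_doses(doses, min_n: int, positive: bool = True) -> np.ndarray:
    x = np.asarray(doses, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} doses, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("doses must be finite")
    if positive and np.any(x <= 0):
        raise ValueError("doses must be strictly positive grams")
    return x


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous step CDF: F_n(x) = (1/n) · #{x_i ≤ x}."""

    sorted_support: np.ndarray
    step_heights: np.ndarray

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.sorted_support, np.asarray(x, dtype=float), side="right")
        heights = np.concatenate([[0.0], self.step_heights])
        return heights[idx]


def fit_ecdf(doses) -> EmpiricalCDF:
    """Fit the empirical CDF of a positive dose sample (n ≥ 2)."""
    x = _validate_doses(doses, min_n=2)
    xs = np.sort(x)
    n = xs.size
    return EmpiricalCDF(sorted_support=xs, step_heights=np.arange(1, n + 1) / n)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 · min(sd, IQR/1.34) · n^(−1/5) (grams)."""
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError(
            "zero-variance sample: kernel bandwidth undefined; jitter the data or use the rank method"
        )
    return 0.9 * scale * x.size ** (-0.2)


@dataclass(frozen=True)
class KernelMarginal:
    """Gaussian-kernel CDF/PDF estimate for one dose variable.

    CDF(x) = (1/n) Σ Φ((x − x_i)/h);  PDF(x) = (1/(nh)) Σ φ((x − x_i)/h).
    """

    sample: np.ndarray
    bandwidth: float
    kernel: str = field(default="gaussian")

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.sample) / self.bandwidth
        return sps.norm.cdf(z).mean(axis=-1)

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.sample) / self.bandwidth
        return sps.norm.pdf(z).mean(axis=-1) / self.bandwidth

    def __call__(self, x) -> np.ndarray:
        return self.cdf(x)


def fit_kernel_marginal(doses, bandwidth: float | None = None) -> KernelMarginal:
    """Fit a Gaussian-kernel CDF to a positive dose sample (n ≥ 5).

    ``bandwidth`` defaults to Silverman's rule of thumb on the sample; a
    zero-variance sample is rejected with a pointer to the rank method.
    """
    x = _validate_doses(doses, min_n=5)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    elif not (np.isfinite(bandwidth) and bandwidth > 0):
        raise ValueError(f"bandwidth must be positive, got {bandwidth!r}")
    return KernelMarginal(sample=np.sort(x), bandwidth=float(bandwidth))


@dataclass(frozen=True)
class PseudoObservations:
    """Paired unit-square observations (u_i, v_i), each strictly inside (0, 1)."""

    u: np.ndarray
    v: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same length")
        for name, arr in (("u", self.u), ("v", self.v)):
            if np.any((arr <= 0) | (arr >= 1)):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")

    def __len__(self) -> int:
        return self.u.size


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def to_pseudo_observations(x, y, method: str = "kernel-cdf", bandwidth: float | None = None) -> PseudoObservations:
    """Map paired dose samples to the unit square.

    method="kernel-cdf": u_i = F̂_A(x_i) with the kernel CDF fitted to x, then
    clamped to [1/(2n), 1 − 1/(2n)] (and likewise v from y).
    method="rank": u_i = midrank(x_i)/(n + 1), which lies inside (0, 1) by
    construction and is exactly invariant to monotone transforms.
    """
    x = _validate_doses(x, min_n=5)
    y = _validate_doses(y, min_n=5)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if method == "rank":
        u = _midranks(x) / (n + 1)
        v = _midranks(y) / (n + 1)
    elif method == "kernel-cdf":
        u = fit_kernel_marginal(x, bandwidth).cdf(x)
        v = fit_kernel_marginal(y, bandwidth).cdf(y)
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        u = np.clip(u, lo, hi)
        v = np.clip(v, lo, hi)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'kernel-cdf' or 'rank'")
    return PseudoObservations(u=u, v=v, method=method)
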