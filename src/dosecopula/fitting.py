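"""Copula estimation and family selection for paired dose data.

Parameters are estimated by canonical pseudo-maximum likelihood: maximise
Σ log c_θ(u_i, v_i) over the family's parameter space, with the pseudo-
observations (u_i, v_i) treated as the data.  One-parameter families are
initialised (and bracketed) by inverting the closed-form Kendall-τ relation
at the tie-adjusted sample τ; the Student-t copula is profiled over a grid
of degrees of freedom and then refined jointly over (ρ, ν).

Families are ranked by the squared Euclidean distance between the fitted
copula and the empirical copula evaluated at the sample pseudo-observations,

    d² = Σ_i [C_n(u_i, v_i) − C_θ(u_i, v_i)]²,

the empirical-copula goodness-of-fit criterion: the best family is the one
with the smallest distance.  Reported τ/ρ_S are model-implied (computed from
the fitted parameters), not sample statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .copulas import (
    FAMILY_ORDER,
    ClaytonCopula,
    Copula,
    FrankCopula,
    GaussianCopula,
    GumbelCopula,
    StudentTCopula,
)
from .marginals import PseudoObservations

__all__ = [
    "EmpiricalCopula",
    "FitError",
    "FitResult",
    "FitReport",
    "empirical_copula",
    "fit_family",
    "squared_euclidean_distance",
    "select_best",
    "tau_inversion",
]

_RHO_BOUND = 0.9999
_NU_BOUNDS = (1.0, 100.0)
_NU_PROFILE_GRID = (2.0, 3.0, 5.0, 8.0, 12.0, 20.0, 40.0)


class FitError(RuntimeError):
    """Estimation failure; carries the best iterate found, if any."""

    def __init__(self, message: str, best: Copula | None = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class EmpiricalCopula:
    """Rank-based nonparametric copula estimate C_n(u,v) = (1/n)·#{u_i ≤ u, v_i ≤ v}."""

    pseudo: PseudoObservations

    def __call__(self, u, v) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        ui = self.pseudo.u
        vi = self.pseudo.v
        counts = ((ui[None, :] <= u[:, None]) & (vi[None, :] <= v[:, None])).sum(axis=1)
        return counts / len(self.pseudo)


def empirical_copula(pseudo: PseudoObservations) -> EmpiricalCopula:
    """Build the empirical copula; requires n ≥ 10 for a stable distance ranking."""
    if len(pseudo) < 10:
        raise ValueError(f"need at least 10 pseudo-observations, got {len(pseudo)}")
    return EmpiricalCopula(pseudo)


def _sample_tau(pseudo: PseudoObservations) -> float:
    """Tie-adjusted (tau-b) sample Kendall correlation of the pseudo-observations."""
    return float(sps.kendalltau(pseudo.u, pseudo.v).statistic)


def tau_inversion(family: str, tau: float) -> dict[str, float]:
    """Moment-style initial parameters from the closed-form τ(θ) relations."""
    if family == "Clayton":
        t = min(max(tau, 1e-3), 0.999)
        return {"alpha": 2.0 * t / (1.0 - t)}
    if family == "Gumbel":
        t = min(max(tau, 0.0), 0.999)
        return {"alpha": 1.0 / (1.0 - t)}
    if family == "Frank":
        t = min(max(abs(tau), 1e-3), 0.999)
        alpha = optimize.brentq(lambda a: FrankCopula(a).kendall_tau() - t, 1e-4, 500.0)
        return {"alpha": math.copysign(alpha, tau) if tau != 0 else alpha}
    if family in ("Gaussian", "StudentT"):
        rho = min(max(math.sin(math.pi * tau / 2.0), -_RHO_BOUND), _RHO_BOUND)
        out = {"rho": rho}
        if family == "StudentT":
            out["nu"] = 8.0
        return out
    raise ValueError(f"unknown family {family!r}")


def _neg_loglik(model: Copula, pseudo: PseudoObservations) -> float:
    ll = model.logpdf(pseudo.u, pseudo.v)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(ll.sum())


def _fit_scalar(family: str, pseudo: PseudoObservations, tau_hat: float) -> tuple[Copula, float, bool]:
    """Bounded derivative-free search for one-parameter families."""
    init = tau_inversion(family, tau_hat)
    if family == "Clayton":
        theta0 = init["alpha"]
        lo, hi = max(1e-4, theta0 / 4.0), max(1.0, theta0 * 4.0)
        build = lambda a: ClaytonCopula(a)
    elif family == "Gumbel":
        theta0 = init["alpha"]
        lo, hi = max(1.0, theta0 / 4.0), max(2.0, theta0 * 4.0)
        build = lambda a: GumbelCopula(a)
    elif family == "Frank":
        theta0 = init["alpha"]
        lo, hi = sorted((theta0 / 4.0, theta0 * 4.0))
        if lo == hi:
            lo, hi = -1.0, 1.0
        build = lambda a: FrankCopula(a)
    elif family == "Gaussian":
        lo, hi = -_RHO_BOUND, _RHO_BOUND
        build = lambda r: GaussianCopula(r)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(family)

    res = optimize.minimize_scalar(
        lambda th: _neg_loglik(build(th), pseudo),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    model = build(float(res.x))
    at_boundary = min(res.x - lo, hi - res.x) < 1e-4 * (hi - lo)
    return model, float(res.fun), bool(res.success) and not at_boundary


def _fit_student_t(pseudo: PseudoObservations, tau_hat: float) -> tuple[Copula, float, bool]:
    """Profile ν over a coarse grid, then refine jointly over (ρ, log ν)."""
    rho0 = tau_inversion("StudentT", tau_hat)["rho"]
    best: tuple[float, float, float] | None = None  # (nll, rho, nu)
    for nu in _NU_PROFILE_GRID:
        res = optimize.minimize_scalar(
            lambda r: _neg_loglik(StudentTCopula(r, nu), pseudo),
            bounds=(-_RHO_BOUND, _RHO_BOUND),
            method="bounded",
            options={"xatol": 1e-5},
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), float(res.x), nu)
    assert best is not None
    _, rho_p, nu_p = best

    def objective(theta: np.ndarray) -> float:
        rho, log_nu = theta
        return _neg_loglik(StudentTCopula(rho, math.exp(log_nu)), pseudo)

    res = optimize.minimize(
        objective,
        x0=np.array([rho_p if abs(rho_p) > 1e-3 else rho0, math.log(nu_p)]),
        method="L-BFGS-B",
        bounds=[(-_RHO_BOUND, _RHO_BOUND), (math.log(_NU_BOUNDS[0]), math.log(_NU_BOUNDS[1]))],
        options={"ftol": 1e-10, "gtol": 1e-8},
    )
    rho_hat = float(res.x[0])
    nu_hat = float(math.exp(res.x[1]))
    model = StudentTCopula(rho_hat, nu_hat)
    at_boundary = abs(rho_hat) > _RHO_BOUND - 1e-4
    return model, float(res.fun), bool(res.success) and not at_boundary


def fit_family(family: str, pseudo: PseudoObservations) -> Copula:
    """Pseudo-maximum-likelihood fit of one family; deterministic given inputs.

    Raises :class:`FitError` (carrying the best iterate) when the optimiser
    fails or the estimate lands on the parameter boundary, as happens for
    degenerate comonotone data where the likelihood diverges.
    """
    model, _, ok = _fit_family_full(family, pseudo)
    if not ok:
        raise FitError(f"{family} fit did not converge (boundary or optimiser failure)", best=model)
    return model


def _fit_family_full(family: str, pseudo: PseudoObservations) -> tuple[Copula, float, bool]:
    if family not in FAMILY_ORDER:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILY_ORDER}")
    tau_hat = _sample_tau(pseudo)
    if family == "StudentT":
        return _fit_student_t(pseudo, tau_hat)
    return _fit_scalar(family, pseudo, tau_hat)


def squared_euclidean_distance(model: Copula, empirical: EmpiricalCopula) -> float:
    """d² = Σ_i [C_n(u_i, v_i) − C_θ(u_i, v_i)]² over the sample pseudo-observations."""
    u, v = empirical.pseudo.u, empirical.pseudo.v
    return float(np.sum((empirical(u, v) - model.cdf(u, v)) ** 2))


@dataclass(frozen=True)
class FitResult:
    """One family's row of the selection report."""

    family: str
    model: Copula | None
    distance: float
    tau: float
    rho_s: float
    loglik: float
    converged: bool
    message: str = ""

    def parameter_string(self) -> str:
        if self.model is None:
            return ""
        return ", ".join(f"{k}={val:.4f}" for k, val in self.model.params.items())


@dataclass(frozen=True)
class FitReport:
    """All family fits plus the distance-minimising best family."""

    results: tuple[FitResult, ...] = field(default_factory=tuple)

    @property
    def best(self) -> FitResult:
        ranked = self.ranked()
        if not ranked:
            raise FitError("no family converged; cannot select a best copula")
        return ranked[0]

    def ranked(self) -> list[FitResult]:
        """Converged fits sorted by distance, ties by log-likelihood then family order."""
        ok = [r for r in self.results if r.converged]
        return sorted(ok, key=lambda r: (r.distance, -r.loglik, FAMILY_ORDER.index(r.family)))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "family": r.family,
                "squared_euclidean_distance": round(r.distance, 4) if r.converged else float("nan"),
                "parameters": r.parameter_string(),
                "kendall_tau": round(r.tau, 4) if r.converged else float("nan"),
                "spearman_rho": round(r.rho_s, 4) if r.converged else float("nan"),
                "converged": r.converged,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "families": json.loads(self.to_dataframe().to_json(orient="records")),
            "best": self.best.family,
        }
        return json.dumps(payload, indent=2)


def select_best(pseudo: PseudoObservations, families: tuple[str, ...] = FAMILY_ORDER) -> FitReport:
    """Fit every requested family, rank by squared Euclidean distance.

    A family that fails to converge is retained in the report with a failure
    flag and excluded from the ranking — never silently dropped.
    """
    if not families:
        raise ValueError("families must be non-empty")
    emp = empirical_copula(pseudo)
    results = []
    for family in families:
        try:
            model, nll, ok = _fit_family_full(family, pseudo)
            dist = squared_euclidean_distance(model, emp)
            results.append(
                FitResult(
                    family=family,
                    model=model,
                    distance=dist,
                    tau=model.kendall_tau(),
                    rho_s=model.spearman_rho(),
                    loglik=-nll,
                    converged=ok,
                    message="" if ok else "boundary or non-convergence",
                )
            )
        except Exception as exc:  # estimation blew up entirely
            results.append(
                FitResult(
                    family=family,
                    model=None,
                    distance=float("inf"),
                    tau=float("nan"),
                    rho_s=float("nan"),
                    loglik=-float("inf"),
                    converged=False,
                    message=str(exc),
                )
            )
    return FitReport(results=tuple(results))
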