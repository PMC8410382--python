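"""End-to-end dose-correlation analysis on a prescription CSV.

The pipeline reproduces the study workflow on any compliant table:
load and validate records, filter to one indication, convert historical
dose strings to grams, summarise and normality-screen each drug's doses,
map to pseudo-observations, fit the five copula families, rank them by
squared Euclidean distance to the empirical copula, and write a JSON/CSV
report (optionally with diagnostic figures).

The method is drug-pair agnostic: the two dose columns are generic
``drug A`` / ``drug B`` and configurable at the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitReport, select_best
from .marginals import fit_ecdf, fit_kernel_marginal, to_pseudo_observations
from .records import PrescriptionRecord, records_to_dataframe
from .stats import describe, normality_tests
from .units import DoseParseError, UnitError, parse_dose, to_grams

logger = logging.getLogger("dosecopula")

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "LoadResult",
    "load_prescriptions",
    "filter_records",
    "run_analysis",
]

_REQUIRED_COLUMNS = ("indication",)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for one analysis run; the single seed feeds every random step."""

    pseudo_method: str = "kernel-cdf"
    bandwidth: float | None = None
    families: tuple[str, ...] = ("Clayton", "Frank", "Gumbel", "Gaussian", "StudentT")
    seed: int = 0
    ci_method: str = "bootstrap-mean"
    output_dir: str | None = None
    make_figures: bool = False

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("families must be non-empty")

    def split_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the config seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class LoadResult:
    records: tuple[PrescriptionRecord, ...]
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())


def _resolve_grams(raw: str | None, grams, dynasty: str) -> float | None:
    if grams is not None and not (isinstance(grams, float) and np.isnan(grams)):
        return float(grams)
    if raw:
        return to_grams(parse_dose(raw), dynasty)
    return None


def load_prescriptions(
    path,
    drug_a_col: str = "dose_a",
    drug_b_col: str = "dose_b",
    convert_units: bool = True,
) -> LoadResult:
    """Read a prescription CSV into validated records.

    Dose columns may be ``<col>_raw`` historical strings and/or ``<col>_g``
    gram values; raw strings are converted via the dynasty unit table when
    grams are absent (unless ``convert_units`` is off, for pre-metric data).
    Rows failing validation are logged and counted per reason, never
    silently dropped.
    """
    df = pd.read_csv(path)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    colmap = {
        "a_raw": f"{drug_a_col}_raw",
        "b_raw": f"{drug_b_col}_raw",
        "a_g": f"{drug_a_col}_g",
        "b_g": f"{drug_b_col}_g",
    }
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if not any(c in df.columns for c in (colmap["a_raw"], colmap["a_g"])):
        missing.append(f"{colmap['a_raw']} or {colmap['a_g']}")
    if not any(c in df.columns for c in (colmap["b_raw"], colmap["b_g"])):
        missing.append(f"{colmap['b_raw']} or {colmap['b_g']}")
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")

    records: list[PrescriptionRecord] = []
    rejections: dict[str, int] = {}

    def _get(row, col):
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return val

    for i, row in enumerate(df.to_dict(orient="records")):
        dynasty = _get(row, "dynasty") or "modern"
        try:
            a_raw = _get(row, colmap["a_raw"])
            b_raw = _get(row, colmap["b_raw"])
            a_g = _get(row, colmap["a_g"])
            b_g = _get(row, colmap["b_g"])
            if convert_units:
                a_g = _resolve_grams(a_raw, a_g, dynasty)
                b_g = _resolve_grams(b_raw, b_g, dynasty)
            records.append(
                PrescriptionRecord(
                    indication=str(_get(row, "indication") or "").strip().lower(),
                    dynasty=str(dynasty),
                    prescription_name=str(_get(row, "prescription_name") or ""),
                    source=str(_get(row, "source") or ""),
                    dose_a_raw=a_raw,
                    dose_b_raw=b_raw,
                    dose_a_g=a_g,
                    dose_b_g=b_g,
                )
            )
        except (DoseParseError, UnitError, ValueError) as exc:
            reason = f"{type(exc).__name__}: {exc}"
            key = reason.split(" in ")[0]
            rejections[key] = rejections.get(key, 0) + 1
            logger.warning("row %d rejected: %s", i, reason)
    return LoadResult(records=tuple(records), rejections=rejections)


def filter_records(
    records,
    indication: str,
    require_both_drugs: bool = True,
    dynasties: tuple[str, ...] | None = None,
) -> tuple[list[PrescriptionRecord], dict[str, int]]:
    """Keep records of one indication with both doses resolvable to grams.

    Matching is exact on the normalised lowercase label.  Returns the kept
    list and per-reason rejection counts (kept + rejected = input size).
    """
    label = indication.strip().lower()
    kept: list[PrescriptionRecord] = []
    rejected: dict[str, int] = {}

    def reject(reason: str) -> None:
        rejected[reason] = rejected.get(reason, 0) + 1

    for rec in records:
        if rec.indication.strip().lower() != label:
            reject("indication mismatch")
        elif dynasties is not None and rec.dynasty not in dynasties:
            reject("dynasty excluded")
        elif require_both_drugs and (rec.dose_a_g is None or rec.dose_b_g is None):
            reject("missing dose")
        else:
            kept.append(rec)
    return kept, rejected


@dataclass(frozen=True)
class AnalysisReport:
    """Everything the analysis produced, serialisable to JSON."""

    indication: str
    n: int
    descriptives: dict
    normality: dict
    fit_report: FitReport
    best_family: str
    dependence: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "indication": self.indication,
            "n": self.n,
            "descriptives": self.descriptives,
            "normality": self.normality,
            "families": json.loads(self.fit_report.to_dataframe().to_json(orient="records")),
            "best_family": self.best_family,
            "dependence": self.dependence,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _input_digest(records) -> str:
    payload = records_to_dataframe(list(records)).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def run_analysis(records, config: AnalysisConfig | None = None, indication: str = "") -> AnalysisReport:
    """Run stats → marginals → copula selection on filtered records.

    Refuses fewer than 10 usable records.  With ``config.output_dir`` set,
    writes ``report.json`` and per-table CSVs (and PNG figures when
    ``make_figures`` is on).  Identical records + config reproduce an
    identical report, timestamps aside.
    """
    config = config or AnalysisConfig()
    records = list(records)
    if len(records) < 10:
        raise ValueError(f"need at least 10 usable records, got {len(records)}")
    a = np.array([r.dose_a_g for r in records], dtype=float)
    b = np.array([r.dose_b_g for r in records], dtype=float)

    stage = "descriptives"
    try:
        desc = {
            "drug_a": dataclasses.asdict(
                describe(a, ci_method=config.ci_method, seed=config.split_seed("boot_a"))
            ),
            "drug_b": dataclasses.asdict(
                describe(b, ci_method=config.ci_method, seed=config.split_seed("boot_b"))
            ),
        }
        stage = "normality"
        norm = {}
        for name, x in (("drug_a", a), ("drug_b", b)):
            ks, sw = normality_tests(x, seed=config.split_seed(f"lilliefors_{name}"))
            norm[name] = {"ks": dataclasses.asdict(ks), "shapiro": dataclasses.asdict(sw)}
        stage = "marginals"
        pseudo = to_pseudo_observations(a, b, method=config.pseudo_method, bandwidth=config.bandwidth)
        stage = "fitting"
        report = select_best(pseudo, families=tuple(config.families))
        best = report.best
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc

    analysis = AnalysisReport(
        indication=indication,
        n=len(records),
        descriptives=desc,
        normality=norm,
        fit_report=report,
        best_family=best.family,
        dependence={"kendall_tau": round(best.tau, 4), "spearman_rho": round(best.rho_s, 4)},
        provenance={
            "software": f"dosecopula {__version__}",
            "config": {
                "pseudo_method": config.pseudo_method,
                "bandwidth": config.bandwidth,
                "families": list(config.families),
                "seed": config.seed,
                "ci_method": config.ci_method,
            },
            "input_digest": _input_digest(records),
        },
    )

    if config.output_dir:
        _write_outputs(analysis, records, a, b, config)
    return analysis


def _write_outputs(analysis: AnalysisReport, records, a, b, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(analysis.to_json())
    analysis.fit_report.to_dataframe().to_csv(out / "tables" / "copula_fits.csv", index=False)
    pd.DataFrame(
        [
            {"drug": k, **v}
            for k, v in analysis.descriptives.items()
        ]
    ).to_csv(out / "tables" / "descriptives.csv", index=False)
    rows = []
    for drug, tests in analysis.normality.items():
        for test_name, res in tests.items():
            rows.append({"drug": drug, **res})
    pd.DataFrame(rows).to_csv(out / "tables" / "normality.csv", index=False)
    if config.make_figures:
        _write_figures(out, a, b, analysis, config)


def _write_figures(out: Path, a, b, analysis: AnalysisReport, config: AnalysisConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    # kernel CDF vs empirical CDF overlay, one panel per drug
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, x, name in ((axes[0], a, "drug A"), (axes[1], b, "drug B")):
        ecdf = fit_ecdf(x)
        km = fit_kernel_marginal(x, config.bandwidth)
        grid = np.linspace(x.min() * 0.8, x.max() * 1.1, 300)
        ax.step(ecdf.sorted_support, ecdf.step_heights, where="post", label="empirical CDF")
        ax.plot(grid, km.cdf(grid), label="kernel CDF")
        ax.set_xlabel(f"{name} dose (g)")
        ax.set_ylabel("CDF")
        ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "marginal_cdf.png", dpi=120)
    plt.close(fig)

    # pseudo-observation histograms
    pseudo = to_pseudo_observations(a, b, method=config.pseudo_method, bandwidth=config.bandwidth)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].hist(pseudo.u, bins=20, range=(0, 1))
    axes[0].set_xlabel("u (drug A)")
    axes[1].hist(pseudo.v, bins=20, range=(0, 1))
    axes[1].set_xlabel("v (drug B)")
    fig.tight_layout()
    fig.savefig(figdir / "pseudo_observations.png", dpi=120)
    plt.close(fig)

    # fitted-copula density surface for the best family
    best_model = next(r.model for r in analysis.fit_report.ranked())
    g = np.linspace(0.02, 0.98, 60)
    U, V = np.meshgrid(g, g)
    Z = best_model.pdf(U, V)
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(U, V, Z, cmap="viridis", linewidth=0)
    ax.set_xlabel("u")
    ax.set_ylabel("v")
    ax.set_title(f"{best_model.family} copula density")
    fig.tight_layout()
    fig.savefig(figdir / "copula_density.png", dpi=120)
    plt.close(fig)
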