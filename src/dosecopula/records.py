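"""The prescription record: one row of the analysis input table."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

__all__ = ["PrescriptionRecord", "records_to_dataframe"]

#: CSV column names shared by the loader, the pipeline and the generator.
COLUMNS = (
    "indication",
    "dynasty",
    "prescription_name",
    "source",
    "dose_a_raw",
    "dose_b_raw",
    "dose_a_g",
    "dose_b_g",
)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One prescription: indication, provenance, and the paired drug doses.

    Each drug dose may be given as a historical unit string (``dose_*_raw``,
    e.g. ``"1 Liang and 3 Qian"``), as grams (``dose_*_g``), or both.
    """

    indication: str
    dynasty: str = "modern"
    prescription_name: str = ""
    source: str = ""
    dose_a_raw: str | None = None
    dose_b_raw: str | None = None
    dose_a_g: float | None = None
    dose_b_g: float | None = None

    def __post_init__(self) -> None:
        for side in ("a", "b"):
            raw = getattr(self, f"dose_{side}_raw")
            grams = getattr(self, f"dose_{side}_g")
            if raw is None and grams is None:
                raise ValueError(f"drug {side}: need a raw dose string or a gram value")
            if grams is not None and not grams > 0:
                raise ValueError(f"drug {side}: grams must be > 0, got {grams!r}")


def records_to_dataframe(records: list[PrescriptionRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=list(COLUMNS))
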