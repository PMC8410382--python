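"""Historical Chinese dose-unit parsing and conversion to grams.

Prescription books record drug doses in dynasty-era mass units (Jin, Liang,
Qian, Fen) whose gram equivalents changed between dynasties.  This module
parses dose expressions such as ``"1 Liang and 3 Qian"`` and converts them to
modern grams using a per-dynasty conversion table shipped as a versioned JSON
config file (``data/unit_table.json``), so the table can be amended without
code changes.

The conversion is linear: ``grams = sum(quantity_i * grams_per_unit_i)``.
Unknown units and dynasties raise errors rather than being guessed — a silent
misconversion is worse than a failure.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from math import isfinite

__all__ = [
    "UNIT_NAMES",
    "DYNASTIES",
    "DoseExpression",
    "UnitSystem",
    "UnitError",
    "DoseParseError",
    "load_unit_table",
    "parse_dose",
    "to_grams",
    "grams_to_expression",
]

UNIT_NAMES = ("Jin", "Liang", "Qian", "Fen")


class UnitError(ValueError):
    """Unknown dynasty or invalid unit-table entry."""


class DoseParseError(ValueError):
    """Raised when a raw dose string cannot be parsed."""


@dataclass(frozen=True)
class DoseExpression:
    """An ordered list of ``(quantity, unit)`` components, e.g. 1 Liang + 3 Qian."""

    components: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise DoseParseError("dose expression must have at least one component")
        for qty, unit in self.components:
            if not isfinite(qty) or qty < 0:
                raise DoseParseError(f"quantity {qty!r} must be finite and >= 0")
            if unit not in UNIT_NAMES:
                raise UnitError(f"unknown unit {unit!r}; expected one of {UNIT_NAMES}")

    def __add__(self, other: "DoseExpression") -> "DoseExpression":
        return DoseExpression(self.components + other.components)

    def scaled(self, k: float) -> "DoseExpression":
        return DoseExpression(tuple((k * q, u) for q, u in self.components))


@dataclass(frozen=True)
class UnitSystem:
    """Gram equivalents of the four historical units for one dynasty."""

    dynasty: str
    grams_per_unit: dict[str, float]

    def __post_init__(self) -> None:
        missing = [u for u in UNIT_NAMES if u not in self.grams_per_unit]
        if missing:
            raise UnitError(f"{self.dynasty}: missing unit values for {missing}")
        for unit, g in self.grams_per_unit.items():
            if not (isfinite(g) and g > 0):
                raise UnitError(f"{self.dynasty}: {unit} = {g!r} is not a positive gram value")


def load_unit_table(path: str | None = None) -> dict[str, UnitSystem]:
    """Load the dynasty conversion table from JSON (the packaged default, or *path*)."""
    if path is None:
        text = resources.files("dosecopula.data").joinpath("unit_table.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    return {
        dynasty: UnitSystem(dynasty, {u: float(g) for u, g in units.items()})
        for dynasty, units in raw["dynasties"].items()
    }


_UNIT_TABLE: dict[str, UnitSystem] | None = None


def _table() -> dict[str, UnitSystem]:
    global _UNIT_TABLE
    if _UNIT_TABLE is None:
        _UNIT_TABLE = load_unit_table()
    return _UNIT_TABLE


DYNASTIES = ("Tang", "Song", "Yuan", "Ming", "Qing")

_CANONICAL_UNIT = {u.lower(): u for u in UNIT_NAMES}
_COMPONENT_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s+([A-Za-z]+)\s*$")


def parse_dose(text: str) -> DoseExpression:
    """Parse a raw dose string like ``"3 Liang"`` or ``"1 Liang and 3 Qian"``.

    Unit names are matched case-insensitively.  Components are joined by the
    word ``and``.  Decimal quantities are accepted ("7.5 Qian", "0.5 Liang").

    Raises
    ------
    DoseParseError
        If the string is empty, garbled, or names an unknown unit.
    """
    if not isinstance(text, str) or not text.strip():
        raise DoseParseError("empty dose string")
    components: list[tuple[float, str]] = []
    for part in re.split(r"\band\b", text, flags=re.IGNORECASE):
        m = _COMPONENT_RE.match(part)
        if m is None:
            raise DoseParseError(f"cannot parse dose component {part.strip()!r} in {text!r}")
        qty = float(m.group(1))
        unit_tok = m.group(2)
        unit = _CANONICAL_UNIT.get(unit_tok.lower())
        if unit is None:
            raise DoseParseError(f"unknown unit {unit_tok!r} in {text!r}")
        components.append((qty, unit))
    return DoseExpression(tuple(components))


def to_grams(expr: DoseExpression, dynasty: str, table: dict[str, UnitSystem] | None = None) -> float:
    """Convert a parsed dose expression to grams under *dynasty*'s unit system.

    The result is the exact linear combination; rounding is a reporting
    concern and is never applied here.
    """
    tab = table if table is not None else _table()
    try:
        system = tab[dynasty]
    except KeyError:
        raise UnitError(f"unknown dynasty {dynasty!r}; expected one of {sorted(tab)}") from None
    return float(sum(q * system.grams_per_unit[u] for q, u in expr.components))


def grams_to_expression(grams: float, dynasty: str, table: dict[str, UnitSystem] | None = None) -> DoseExpression:
    """Express a gram dose in dynasty units by greedy Liang/Qian/Fen decomposition.

    Whole-number Liang and Qian are peeled off greedily and the remainder is
    expressed as a (possibly fractional) number of Fen, so the round trip
    through :func:`to_grams` is exact up to floating-point rounding.  Used by
    the synthetic generator to emit realistic compound dose strings.
    """
    if not (isfinite(grams) and grams >= 0):
        raise ValueError(f"grams must be finite and >= 0, got {grams!r}")
    tab = table if table is not None else _table()
    try:
        gpu = tab[dynasty].grams_per_unit
    except KeyError:
        raise UnitError(f"unknown dynasty {dynasty!r}; expected one of {sorted(tab)}") from None
    components: list[tuple[float, str]] = []
    rem = grams
    for unit in ("Liang", "Qian"):
        qty = int(rem // gpu[unit])
        if qty > 0:
            components.append((float(qty), unit))
            rem -= qty * gpu[unit]
    if rem > 1e-12 or not components:
        components.append((round(rem / gpu["Fen"], 10), "Fen"))
    return DoseExpression(tuple(components))


def format_expression(expr: DoseExpression) -> str:
    """Render an expression back to the canonical string form."""
    def fmt(q: float) -> str:
        return f"{q:.12g}"

    return " and ".join(f"{fmt(q)} {u}" for q, u in expr.components)
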