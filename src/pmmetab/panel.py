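"""Analyte panel registry: molecular formulas, monoisotopic masses, metadata.

The shipped reversed-phase panel covers 38 endogenous compounds routinely
integrated from postmortem femoral-blood LC-HRMS runs (amino acids,
acylcarnitines C0-C18, phospholipids, bile acids, steroids and others),
together with their physicochemical metadata: sum formula, accurate mass,
logP (experimental or predicted), and retention times in reversed-phase and
HILIC chromatography.

Monoisotopic masses are computed from the sum formula using a fixed table of
lightest-isotope atomic masses (AME2020/CODATA values, truncated to 8-9
significant figures) so that results are bit-reproducible.  Long-chain
acylcarnitines are conventionally reported as their protonated cations in
positive-mode ESI; panel rows whose printed accurate mass matches the cation
m/z of the printed formula (i.e. neutral formula mass minus one electron
mass) are flagged ``mass_convention="cation"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "AnalyteSpec",
    "FormulaError",
    "PanelError",
    "parse_formula",
    "canonical_formula",
    "monoisotopic_mass",
    "load_panel",
    "default_panel_path",
]

#: Lightest-isotope atomic masses in Da (1H, 12C, 14N, 16O, 32S, 31P).
#: Source: AME2020 atomic mass evaluation / CODATA recommended values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307400,
    "O": 15.99491462,
    "S": 31.97207100,
    "P": 30.97376200,
}

#: Electron rest mass in Da; separates neutral masses from cation m/z values.
ELECTRON_MASS = 5.48579909e-4

#: Tolerance for matching a computed mass against a printed accurate mass.
MASS_MATCH_TOL = 2e-5

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a sum formula cannot be parsed."""


class PanelError(ValueError):
    """Raised when a panel table violates its contract."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style sum formula into an element -> count mapping.

    Only the bioorganic elements C, H, N, O, S, P are accepted; implicit
    counts of one are allowed ("S" -> {S: 1}).

    >>> parse_formula("C3H7NO2")
    {'C': 3, 'H': 7, 'N': 1, 'O': 2}
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"unparsable token {formula[pos:match.start()]!r} in {formula!r}"
            )
        pos = match.end()
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {formula!r}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(f"non-positive count for {element} in {formula!r}")
        counts[element] = counts.get(element, 0) + count
    if pos != len(formula):
        raise FormulaError(f"unparsable trailing {formula[pos:]!r} in {formula!r}")
    if not counts:
        raise FormulaError(f"no elements found in {formula!r}")
    return counts


def canonical_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a canonical Hill-order string.

    Hill order: C first, H second, then the remaining elements
    alphabetically; unit counts are implicit.
    """
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    parts = []
    for element in order:
        n = counts[element]
        if n <= 0:
            raise FormulaError(f"non-positive count for {element}")
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass of a sum formula in Da.

    Sum of lightest-isotope atomic masses over all atoms; deterministic and
    additive over formula concatenation.

    >>> round(monoisotopic_mass("C3H7NO2"), 6)
    89.047678
    """
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class AnalyteSpec:
    """One panel entry with physicochemical metadata.

    ``accurate_mass`` is stored exactly as printed in the panel table; for
    rows following the cation convention it is the [M+H]+ m/z of the printed
    (already protonated) formula, recorded by ``mass_convention``.
    ``mw`` is the computed monoisotopic mass of ``sum_formula`` (None when
    the formula is absent, e.g. lipids listed by class shorthand only).
    """

    name: str
    compound_class: str
    sum_formula: str | None = None
    accurate_mass: float | None = None
    logp: float | None = None
    logp_predicted: bool = False
    rt_rp: float | None = None
    rt_hilic: float | None = None
    mw: float | None = field(default=None)
    mass_convention: str = "neutral"
    paired_median_pct: float | None = None
    paired_code: str | None = None
    unpaired_highest_pct: float | None = None
    unpaired_highest_group: str | None = None
    unpaired_code: str | None = None
    pattern: str | None = None


def default_panel_path() -> Path:
    """Path of the shipped 38-compound reversed-phase panel."""
    return Path(str(resources.files("pmmetab").joinpath("data/panel_rp.csv")))


def _optional_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", "n.d", "n.d.", "n.e", "n.e.", "NA"):
            return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise PanelError(
            f"malformed numeric cell {value!r} in column {column!r}, row {row}"
        ) from exc


def load_panel(path: str | Path | None = None) -> list[AnalyteSpec]:
    """Load an analyte panel table into a list of :class:`AnalyteSpec`.

    Required columns: ``name`` and ``compound_class``.  All other columns are
    optional metadata; empty cells (and the "n.d"/"n.e" markers used for
    retention times) map to absent values, never to zero.  The monoisotopic
    mass is computed for every row with a sum formula; a row whose printed
    accurate mass matches the cation m/z instead of the neutral mass gets
    ``mass_convention="cation"``.

    Raises :class:`PanelError` on duplicate analyte names or malformed
    numeric cells.
    """
    path = Path(path) if path is not None else default_panel_path()
    table = pd.read_csv(path, dtype=str)
    for required in ("name", "compound_class"):
        if required not in table.columns:
            raise PanelError(f"panel table missing required column {required!r}")
    names = table["name"].str.strip()
    duplicated = names[names.duplicated()].tolist()
    if duplicated:
        raise PanelError(f"duplicate analyte names in panel: {sorted(set(duplicated))}")

    specs: list[AnalyteSpec] = []
    for idx, row in table.iterrows():
        formula = row.get("sum_formula")
        if isinstance(formula, str):
            formula = formula.strip() or None
        elif pd.isna(formula):
            formula = None
        printed = _optional_float(row.get("accurate_mass"), idx, "accurate_mass")
        mw = None
        convention = "neutral"
        if formula is not None:
            mw = monoisotopic_mass(formula)
            if printed is not None:
                if abs(mw - printed) <= MASS_MATCH_TOL:
                    convention = "neutral"
                elif abs((mw - ELECTRON_MASS) - printed) <= MASS_MATCH_TOL:
                    convention = "cation"
                else:
                    raise PanelError(
                        f"accurate mass {printed} of {row['name']!r} matches neither "
                        f"the neutral ({mw:.6f}) nor the cation "
                        f"({mw - ELECTRON_MASS:.6f}) mass of {formula}"
                    )
        predicted_raw = row.get("logp_predicted")
        predicted = str(predicted_raw).strip() in ("1", "True", "true", "yes")
        specs.append(
            AnalyteSpec(
                name=str(row["name"]).strip(),
                compound_class=str(row["compound_class"]).strip(),
                sum_formula=formula,
                accurate_mass=printed,
                logp=_optional_float(row.get("logp"), idx, "logp"),
                logp_predicted=predicted,
                rt_rp=_optional_float(row.get("rt_rp_min"), idx, "rt_rp_min"),
                rt_hilic=_optional_float(row.get("rt_hilic_min"), idx, "rt_hilic_min"),
                mw=mw,
                mass_convention=convention,
                paired_median_pct=_optional_float(
                    row.get("paired_median_pct"), idx, "paired_median_pct"
                ),
                paired_code=(str(row["paired_code"]).strip()
                             if "paired_code" in row and pd.notna(row["paired_code"])
                             else None),
                unpaired_highest_pct=_optional_float(
                    row.get("unpaired_highest_pct"), idx, "unpaired_highest_pct"
                ),
                unpaired_highest_group=(
                    str(row["unpaired_highest_group"]).strip()
                    if "unpaired_highest_group" in row
                    and pd.notna(row["unpaired_highest_group"])
                    else None
                ),
                unpaired_code=(str(row["unpaired_code"]).strip()
                               if "unpaired_code" in row
                               and pd.notna(row["unpaired_code"])
                               else None),
                pattern=(str(row["pattern"]).strip()
                         if "pattern" in row and pd.notna(row["pattern"])
                         else None),
            )
        )
    return specs
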