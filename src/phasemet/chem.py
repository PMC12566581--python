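"""Elemental formula arithmetic for protonated LC-MS adducts.

All mass bookkeeping in the package flows through this module: Hill-notation
formula parsing, exact monoisotopic mass summation, [M+H]+ m/z and signed
ppm error. Atomic masses are the most-abundant-isotope values (AME2020 /
NIST) shipped as a delimited resource so the table is inspectable and
replaceable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "AdductSpec",
    "PROTON_MASS",
    "M_PLUS_H",
    "monoisotopic_mass_table",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_difference",
]

#: Mass of the proton (not the hydrogen atom), Da.  Using the proton keeps
#: electron bookkeeping correct for +1 ions.
PROTON_MASS = 1.007276466

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass_table() -> Dict[str, float]:
    """Most-abundant-isotope mass per supported element, in Da."""
    text = (
        resources.files("phasemet.data").joinpath("monoisotopic_masses.tsv").read_text()
    )
    table: Dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        element, mass = line.split("\t")
        table[element] = float(mass)
    return table


_MASSES = monoisotopic_mass_table()


class FormulaError(ValueError):
    """Raised for malformed or unsupported formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map; zero-count elements are never stored.

    Instances are immutable and hashable; arithmetic (`+`, applying signed
    deltas) returns new instances.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
            if el not in _MASSES:
                raise FormulaError(f"unsupported element symbol: {el!r}")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def apply_delta(self, delta: Mapping[str, int]) -> "ElementalFormula":
        """Apply a signed element-count change; raises FormulaError if any
        count would go negative (the caller decides whether that prunes a
        candidate or is a user error)."""
        merged = dict(self.counts)
        for el, n in delta.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def hill(self) -> str:
        """Canonical Hill-order rendering: C, then H, then the rest
        alphabetically (fully alphabetical when no carbon)."""
        items = dict(self.counts)
        parts = []
        order = []
        if "C" in items:
            order = ["C"] + (["H"] if "H" in items else [])
        order += sorted(el for el in items if el not in order)
        for el in order:
            n = items[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C15H17Cl2N3O2"``.

    Repeated element symbols are summed.  Unknown symbols, embedded
    separators and the empty string are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in _MASSES:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        if digits == "0":
            raise FormulaError(f"explicit zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int]) -> float:
    """Exact monoisotopic (most-abundant-isotope) mass in Da.

    Accepts a signed mapping as well, so rule deltas reuse the same sum.
    """
    counts = formula.counts if isinstance(formula, ElementalFormula) else formula
    total = 0.0
    for el, n in counts.items():
        if el not in _MASSES:
            raise FormulaError(f"element {el!r} missing from the mass table")
        total += n * _MASSES[el]
    return total


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: m/z = (M + mass_shift) / charge."""

    name: str = "[M+H]+"
    mass_shift: float = PROTON_MASS
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("adduct charge must be >= 1")


#: The study's anticipated ionization for every target.
M_PLUS_H = AdductSpec()


def adduct_mz(formula: ElementalFormula, adduct: AdductSpec = M_PLUS_H) -> float:
    """m/z of the given adduct of the neutral formula (full precision;
    round to 4 dp only for exported tables)."""
    return (monoisotopic_mass(formula) + adduct.mass_shift) / adduct.charge


def ppm_difference(observed: float, theoretical: float) -> float:
    """Signed relative mass error, 1e6 * (observed - theoretical) / theoretical."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
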