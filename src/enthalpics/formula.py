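"""Chemical formulas of CaHbNcOd compounds and molar masses.

Formulas are restricted to the four elements that occur in the
combustion stoichiometry handled here (C, H, N, O).  Parsing accepts
Hill-notation strings such as ``"C5H7NO"``; the canonical text form is
Hill order (C first, then H, then the remaining elements alphabetically).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Tuple

from .constants import ConstantsTable, CONSTANTS
from .quantities import Quantity

__all__ = ["ChemicalFormula", "FormulaError", "parse_formula", "molar_mass"]

ALLOWED_ELEMENTS = ("C", "H", "N", "O")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or unsupported chemical formula."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Element counts of a C/H/N/O compound.

    Counts are non-negative integers; zero-count elements are dropped.
    """

    counts: Tuple[Tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ChemicalFormula":
        clean = {}
        for el, n in counts.items():
            if el not in ALLOWED_ELEMENTS:
                raise FormulaError(f"unsupported element {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el!r}")
            if n:
                clean[el] = n
        if not clean:
            raise FormulaError("empty formula")
        order = {el: i for i, el in enumerate(ALLOWED_ELEMENTS)}
        return cls(tuple(sorted(clean.items(), key=lambda kv: order[kv[0]])))

    def count(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ChemicalFormula.from_counts(merged)

    def hill(self) -> str:
        """Canonical Hill-order text (C, H, then alphabetical)."""
        parts = []
        d = dict(self.counts)
        for el in ("C", "H"):
            if el in d:
                n = d.pop(el)
                parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(d):
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string restricted to C/H/N/O.

    >>> parse_formula("C5H7NO").counts
    (('C', 5), ('H', 7), ('N', 1), ('O', 1))
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"unparseable token {text[pos:m.start()]!r} in {text!r}"
            )
        pos = m.end()
        el, digits = m.groups()
        if el not in ALLOWED_ELEMENTS:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
    if pos != len(text):
        raise FormulaError(f"unparseable token {text[pos:]!r} in {text!r}")
    return ChemicalFormula.from_counts(counts)


def molar_mass(
    formula: ChemicalFormula, constants: ConstantsTable = CONSTANTS
) -> Quantity:
    """Molar mass in g·mol⁻¹ from the configured atomic masses.

    Atomic-mass uncertainties are neglected (they never enter the
    uncertainty budget of combustion-derived enthalpies), so ``u = 0``.
    """
    m = sum(n * constants.atomic_mass(el) for el, n in formula)
    return Quantity(m, 0.0, "g·mol⁻¹")
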