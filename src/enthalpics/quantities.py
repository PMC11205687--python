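"""Values with standard uncertainties and unit tags.

Every derived thermochemical quantity in this package is a value paired
with a *standard* uncertainty (one sigma, same unit).  Uncertainty
propagation follows the root-sum-square (RSS) convention used throughout
experimental thermochemistry: components are treated as independent, so
the uncertainty of a sum is the RSS of the component uncertainties and
relative uncertainties combine in quadrature under multiplication.

Units are symbolic tags (``"J·g⁻¹"``, ``"kJ·mol⁻¹"``, ...).  Addition and
subtraction between different tags is rejected; no automatic conversion
is attempted — conversions are explicit at the call sites that need them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Union

__all__ = ["Quantity", "UnitError", "rss_combine"]

Number = Union[int, float]


class UnitError(ValueError):
    """Arithmetic attempted between quantities of incompatible units."""


def rss_combine(components: Iterable[Number]) -> float:
    """Root-sum-square combination of uncertainty components.

    Parameters
    ----------
    components
        Non-negative standard uncertainties (or relative uncertainties —
        the combination is scale-agnostic).

    Returns
    -------
    float
        ``sqrt(sum(c_i**2))``.

    Raises
    ------
    ValueError
        If any component is negative.
    """
    comps = list(components)
    for c in comps:
        if c < 0:
            raise ValueError(f"negative uncertainty component: {c!r}")
    return math.sqrt(math.fsum(c * c for c in comps))


@dataclass(frozen=True)
class Quantity:
    """A value with a standard uncertainty and a symbolic unit tag.

    Attributes
    ----------
    value : float
        Numerical value in ``unit``.
    u : float
        Standard uncertainty in the same unit (>= 0).
    unit : str
        Symbolic unit tag; compared verbatim.
    """

    value: float
    u: float = 0.0
    unit: str = ""

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ValueError(f"standard uncertainty must be >= 0, got {self.u}")

    # ------------------------------------------------------------------ sums
    def _check_unit(self, other: "Quantity") -> None:
        if self.unit != other.unit:
            raise UnitError(
                f"incompatible units: {self.unit!r} and {other.unit!r}"
            )

    def __add__(self, other: "Quantity") -> "Quantity":
        if not isinstance(other, Quantity):
            return NotImplemented
        self._check_unit(other)
        return Quantity(self.value + other.value,
                        rss_combine([self.u, other.u]), self.unit)

    def __sub__(self, other: "Quantity") -> "Quantity":
        if not isinstance(other, Quantity):
            return NotImplemented
        self._check_unit(other)
        return Quantity(self.value - other.value,
                        rss_combine([self.u, other.u]), self.unit)

    def __neg__(self) -> "Quantity":
        return replace(self, value=-self.value)

    # ---------------------------------------------------------- scalar scale
    def __mul__(self, k: Number) -> "Quantity":
        if not isinstance(k, (int, float)):
            return NotImplemented
        return Quantity(self.value * k, self.u * abs(k), self.unit)

    __rmul__ = __mul__

    def __truediv__(self, k: Number) -> "Quantity":
        if not isinstance(k, (int, float)):
            return NotImplemented
        return Quantity(self.value / k, self.u / abs(k), self.unit)

    def with_unit(self, unit: str, factor: float = 1.0) -> "Quantity":
        """Explicit unit relabel/conversion by a multiplicative factor."""
        return Quantity(self.value * factor, self.u * abs(factor), unit)

    # ------------------------------------------------------------ formatting
    def round(self, decimals: int = 1) -> "Quantity":
        return Quantity(builtin_round(self.value, decimals),
                        builtin_round(self.u, decimals), self.unit)

    def format(self, decimals: int = 1) -> str:
        """Table-style ``value ± u`` string, rounded to *decimals*.

        Matches the convention of thermochemical tables, where both the
        value and its uncertainty are printed to one decimal in
        kJ·mol⁻¹ contexts.
        """
        v = f"{self.value:.{decimals}f}"
        if self.u > 0:
            return f"{v} ± {self.u:.{decimals}f}"
        return v

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self.format()
        return f"{s} {self.unit}".strip()


builtin_round = round
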