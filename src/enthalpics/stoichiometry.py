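"""Idealized combustion stoichiometry of CaHbNcOd fuels.

A condensed-phase fuel burns in oxygen to CO2(g), H2O(l) and N2(g):

    CaHbNcOd (l) + (a + b/4 − d/2) O2 (g)
        -> a CO2 (g) + (b/2) H2O (l) + (c/2) N2 (g)

Coefficients are kept as exact rationals until final numeric use so the
Δn(gas)·R·T work term carries no rounding.  Δn(gas) counts only gaseous
species (fuel and product water are condensed):

    Δn(gas) = ν(CO2) + ν(N2) − ν(O2)
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .constants import ConstantsTable, CONSTANTS
from .formula import ChemicalFormula

__all__ = [
    "CombustionReaction",
    "InvalidFuelError",
    "balance_combustion",
    "delta_n_gas",
    "theoretical_co2_mass",
    "mass_from_co2",
]


class InvalidFuelError(ValueError):
    """Formula cannot represent a combustible CaHbNcOd fuel."""


@dataclass(frozen=True)
class CombustionReaction:
    """Balanced combustion of one mole of a CaHbNcOd fuel."""

    fuel: ChemicalFormula
    nu_O2: Fraction
    nu_CO2: Fraction
    nu_H2O: Fraction
    nu_N2: Fraction

    @property
    def delta_n_gas(self) -> Fraction:
        """Net change in moles of gas per mole of (liquid) fuel."""
        return self.nu_CO2 + self.nu_N2 - self.nu_O2


def balance_combustion(fuel: ChemicalFormula) -> CombustionReaction:
    """Balance the idealized combustion reaction of *fuel*.

    Raises
    ------
    InvalidFuelError
        If the fuel contains neither C nor H, or carries more oxygen
        than the products CO2 and H2O can hold (negative ν(O2)).
    """
    a, b = fuel.count("C"), fuel.count("H")
    c, d = fuel.count("N"), fuel.count("O")
    if a == 0 and b == 0:
        raise InvalidFuelError(f"{fuel} has no C or H to oxidize")
    if b % 2:
        # odd H count is fine (fractional H2O coefficient)
        pass
    nu_O2 = Fraction(a) + Fraction(b, 4) - Fraction(d, 2)
    if nu_O2 < 0:
        raise InvalidFuelError(
            f"{fuel}: oxygen content d={d} exceeds 2a + b/2 = {2 * a + b / 2}"
        )
    return CombustionReaction(
        fuel=fuel,
        nu_O2=nu_O2,
        nu_CO2=Fraction(a),
        nu_H2O=Fraction(b, 2),
        nu_N2=Fraction(c, 2),
    )


def delta_n_gas(reaction: CombustionReaction) -> Fraction:
    """Δn(gas) of a balanced combustion reaction (exact rational)."""
    return reaction.delta_n_gas


def theoretical_co2_mass(
    fuel: ChemicalFormula,
    sample_mass: float,
    constants: ConstantsTable = CONSTANTS,
) -> float:
    """Mass of CO2 (g) produced by complete combustion of *sample_mass* g.

    ``m(CO2) = m · ν(CO2) · M(CO2) / M(fuel)``; inverse of
    :func:`mass_from_co2`.
    """
    if sample_mass < 0:
        raise ValueError("sample mass must be >= 0")
    a = fuel.count("C")
    if a == 0:
        raise InvalidFuelError(f"{fuel} contains no carbon")
    from .formula import molar_mass

    M_fuel = molar_mass(fuel, constants).value
    return sample_mass * a * constants.molar_mass_CO2 / M_fuel


def mass_from_co2(
    fuel: ChemicalFormula,
    co2_mass: float,
    constants: ConstantsTable = CONSTANTS,
) -> float:
    """Sample mass (g) that produced *co2_mass* g of CO2 (exact inverse)."""
    if co2_mass < 0:
        raise ValueError("CO2 mass must be >= 0")
    a = fuel.count("C")
    if a == 0:
        raise InvalidFuelError(f"{fuel} contains no carbon")
    from .formula import molar_mass

    M_fuel = molar_mass(fuel, constants).value
    return co2_mass * M_fuel / (a * constants.molar_mass_CO2)
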