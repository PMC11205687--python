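"""Physical constants and reference thermochemical data.

Defaults follow the conventions of combustion-thermochemistry practice:
CODATA key values for the standard molar enthalpies of formation of
CO2(g) and H2O(l) at 298.15 K, and the IUPAC 2013 conventional relative
atomic masses for C, H, N and O.  Everything is overridable, either in
code or from a JSON config file (see :meth:`ConstantsTable.from_json`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

from .quantities import Quantity

__all__ = [
    "ConstantsTable",
    "CONSTANTS",
    "KJ_PER_MOL",
    "J_PER_G",
    "HARTREE_TO_KJ_PER_MOL",
]

KJ_PER_MOL = "kJ·mol⁻¹"
J_PER_G = "J·g⁻¹"

#: Conversion factor from hartree to kJ·mol⁻¹ — the only place
#: quantum-chemistry units enter the package.
HARTREE_TO_KJ_PER_MOL = 2625.4997

#: IUPAC 2013 conventional relative atomic masses (abridged to the
#: elements that occur in CaHbNcOd combustion stoichiometry).
IUPAC_2013_ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
}


@dataclass(frozen=True)
class ConstantsTable:
    """Physical constants used across the reduction chain.

    Attributes
    ----------
    R : float
        Molar gas constant, J·K⁻¹·mol⁻¹.
    T_ref : float
        Thermochemical reference temperature, K.
    dfH_CO2_gas, dfH_H2O_liquid : Quantity
        CODATA standard molar enthalpies of formation at ``T_ref``
        (kJ·mol⁻¹); the Hess anchors for deriving formation enthalpies
        from combustion enthalpies.
    atomic_masses : mapping
        Element symbol -> relative atomic mass (g·mol⁻¹ per atom count).
    cp_water : float
        Massic heat capacity of liquid water, J·g⁻¹·K⁻¹, used for the
        calorimeter-water mass deviation term.
    hartree_to_kJ_per_mol : float
        Energy conversion for computed absolute enthalpies.
    """

    R: float = 8.314462
    T_ref: float = 298.15
    dfH_CO2_gas: Quantity = Quantity(-393.51, 0.13, KJ_PER_MOL)
    dfH_H2O_liquid: Quantity = Quantity(-285.830, 0.040, KJ_PER_MOL)
    atomic_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(IUPAC_2013_ATOMIC_MASSES)
    )
    cp_water: float = 4.184
    hartree_to_kJ_per_mol: float = HARTREE_TO_KJ_PER_MOL

    @property
    def RT_ref_kJ(self) -> float:
        """R·T_ref in kJ·mol⁻¹ (the Δn(gas) work-term factor)."""
        return self.R * self.T_ref / 1000.0

    def atomic_mass(self, element: str) -> float:
        try:
            return self.atomic_masses[element]
        except KeyError:
            raise KeyError(
                f"no atomic mass configured for element {element!r}"
            ) from None

    @property
    def molar_mass_CO2(self) -> float:
        return self.atomic_mass("C") + 2 * self.atomic_mass("O")

    # ------------------------------------------------------------ config IO
    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ConstantsTable":
        """Load overrides from a JSON file.

        Recognised keys: ``R``, ``T_ref``, ``cp_water``,
        ``hartree_to_kJ_per_mol``, ``atomic_masses`` (object), and
        ``dfH_CO2_gas`` / ``dfH_H2O_liquid`` as ``[value, u]`` pairs in
        kJ·mol⁻¹.  Unspecified keys keep their defaults.
        """
        raw = json.loads(Path(path).read_text())
        base = cls()
        updates: dict = {}
        for key in ("R", "T_ref", "cp_water", "hartree_to_kJ_per_mol"):
            if key in raw:
                updates[key] = float(raw[key])
        if "atomic_masses" in raw:
            masses = dict(base.atomic_masses)
            masses.update({k: float(v) for k, v in raw["atomic_masses"].items()})
            updates["atomic_masses"] = masses
        for key in ("dfH_CO2_gas", "dfH_H2O_liquid"):
            if key in raw:
                v, u = raw[key]
                updates[key] = Quantity(float(v), float(u), KJ_PER_MOL)
        return replace(base, **updates)


#: Module-level default table.
CONSTANTS = ConstantsTable()
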