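"""Reference inputs for the bundled furfurylamine study.

These are the printed inputs of the combustion/vaporization study of
furfurylamine (C5H7NO) and 5-methylfurfurylamine (C6H9NO) that the
demo report reproduces end to end: replicate massic combustion
energies, calorimeter calibration constants, observed Calvet
enthalpies, computed (G3-class) gas-phase values, literature comparison
values, and the transferable substitution increments used for the
thiophene analogues.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .calvet import CpPolynomial
from .gasphase import Increment
from .quantities import Quantity
from .constants import KJ_PER_MOL
from .synthetic import (
    SYNTHETIC_CP_FURFURYLAMINE,
    SYNTHETIC_CP_METHYLFURFURYLAMINE,
)

__all__ = [
    "FURFURYLAMINE",
    "METHYLFURFURYLAMINE",
    "COMPOUNDS",
    "O_TO_S_FURAN",
    "O_TO_S_METHYLFURAN",
    "DIMERIZATION_ENTHALPY",
]


class CompoundStudy:
    """Printed inputs for one compound of the bundled study."""

    def __init__(
        self,
        name: str,
        formula: str,
        massic_energies: Tuple[float, ...],
        eps_cal: Quantity,
        calvet_observed: Quantity,
        calvet_T_oven: float,
        cp: CpPolynomial,
        dfH_gas_computed: Quantity,
    ) -> None:
        self.name = name
        self.formula = formula
        #: replicate Δc u° values, J·g⁻¹
        self.massic_energies = massic_energies
        #: energy equivalent used for this compound's series, J·K⁻¹
        self.eps_cal = eps_cal
        #: mean ± sdom observed molar enthalpy at the oven temperature
        self.calvet_observed = calvet_observed
        self.calvet_T_oven = calvet_T_oven
        self.cp = cp
        #: computed (composite ab initio) gas-phase formation enthalpy,
        #: mean ± sdom over estimation reactions
        self.dfH_gas_computed = dfH_gas_computed


FURFURYLAMINE = CompoundStudy(
    name="furfurylamine",
    formula="C5H7NO",
    massic_energies=(
        -29591.73, -29582.70, -29589.96, -29589.56, -29593.49, -29581.42,
    ),
    eps_cal=Quantity(15907.1, 0.7, "J·K⁻¹"),
    calvet_observed=Quantity(54.5, 0.4, KJ_PER_MOL),
    calvet_T_oven=344.5,
    cp=SYNTHETIC_CP_FURFURYLAMINE,
    dfH_gas_computed=Quantity(-38.9, 0.6, KJ_PER_MOL),
)

METHYLFURFURYLAMINE = CompoundStudy(
    name="5-methylfurfurylamine",
    formula="C6H9NO",
    massic_energies=(
        -31577.92, -31568.06, -31562.26, -31577.61,
        -31586.75, -31579.48, -31589.80, -31584.93,
    ),
    eps_cal=Quantity(15917.0, 1.4, "J·K⁻¹"),
    calvet_observed=Quantity(59.3, 0.4, KJ_PER_MOL),
    calvet_T_oven=339.9,
    cp=SYNTHETIC_CP_METHYLFURFURYLAMINE,
    dfH_gas_computed=Quantity(-81.9, 0.9, KJ_PER_MOL),
)

COMPOUNDS: Dict[str, CompoundStudy] = {
    FURFURYLAMINE.name: FURFURYLAMINE,
    METHYLFURFURYLAMINE.name: METHYLFURFURYLAMINE,
}

#: Benzoic-acid certificate massic energy (NBS SRM 39j class), J·g⁻¹.
BENZOIC_CERTIFICATE = Quantity(-26434.0, 3.0, "J·g⁻¹")

#: Enthalpy increment for ring O → S substitution in 2-substituted
#: furans, kJ·mol⁻¹ (transferable to furfuryl derivatives).
O_TO_S_FURAN = Increment("O->S substitution (furans)", Quantity(147.3, 4.5, KJ_PER_MOL))

#: Same substitution increment evaluated on 5-methylfurans.
O_TO_S_METHYLFURAN = Increment(
    "O->S substitution (5-methylfurans)", Quantity(159.4, 5.0, KJ_PER_MOL)
)

#: Gas-phase dimerization enthalpy (2 monomers → dimer) assumed for
#: furfurylamine in the monomer/dimer cycle, kJ·mol⁻¹.
DIMERIZATION_ENTHALPY = Quantity(-24.0, 0.0, KJ_PER_MOL)

#: Earlier literature determination of Δf H°m(l) of furfurylamine,
#: kJ·mol⁻¹ — the comparison column of the dimer-cycle table.
LITERATURE_DFH_LIQUID_FURFURYLAMINE = Quantity(-105.4, 8.6, KJ_PER_MOL)
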