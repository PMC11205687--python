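"""Model/Results interface over the reduction chain.

The two estimation problems of the package are exposed as model objects
in the statsmodels idiom: a model is constructed from data, ``fit()``
performs the reduction and returns a results object carrying the
estimates, their uncertainties and a ``summary()`` table.

* :class:`CombustionStudy` — replicate bomb experiments (raw records or
  already-reduced massic energies) → standard molar energy/enthalpy of
  combustion and the liquid-phase formation enthalpy.
* :class:`VaporizationStudy` — Calvet drop runs (raw records or an
  observed mean) → standard molar vaporization enthalpy at 298.15 K.

``gas_phase_formation`` combines the two results into Δf H°m(g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from . import bomb as _bomb
from .bomb import BombExperiment, CalibrationResult, Corrections
from .calvet import (
    CalvetRun,
    CalvetSummary,
    CpPolynomial,
    summarize_calvet,
    vaporization_enthalpy,
)
from .constants import ConstantsTable, CONSTANTS, KJ_PER_MOL
from .formation import (
    DEFAULT_AUX_RELATIVE,
    ReplicateSet,
    default_relative_budget,
    enthalpy_from_energy,
    expanded_uncertainty,
    formation_gas,
    formation_liquid,
    molar_combustion_energy,
    summarize_replicates,
)
from .formula import ChemicalFormula, molar_mass, parse_formula
from .quantities import Quantity
from .stoichiometry import CombustionReaction, balance_combustion

__all__ = [
    "CombustionStudy",
    "CombustionResults",
    "VaporizationStudy",
    "VaporizationResults",
    "gas_phase_formation",
]


def _as_formula(fuel) -> ChemicalFormula:
    return fuel if isinstance(fuel, ChemicalFormula) else parse_formula(fuel)


@dataclass(frozen=True)
class CombustionResults:
    """Estimates from a set of replicate combustion experiments.

    All enthalpic quantities are signed (negative = exothermic);
    ``summary()`` prints the −Δ magnitudes the way thermochemical
    tables do.
    """

    name: str
    fuel: ChemicalFormula
    reaction: CombustionReaction
    replicates: ReplicateSet
    massic_energy: Quantity  # J·g⁻¹, mean ± sdom
    molar_mass: Quantity  # g·mol⁻¹
    dcU: Quantity  # kJ·mol⁻¹, expanded uncertainty
    dcH: Quantity  # kJ·mol⁻¹
    dfH_liquid: Quantity  # kJ·mol⁻¹
    uncertainty_budget: Tuple[float, ...]  # relative components

    def summary(self) -> str:
        r = self.reaction
        lines = [
            f"Combustion study: {self.name} ({self.fuel})",
            f"  runs: {self.replicates.n}   M = {self.molar_mass.value:.3f} g·mol⁻¹",
            f"  reaction: {self.fuel}(l) + {float(r.nu_O2):g} O2(g) -> "
            f"{float(r.nu_CO2):g} CO2(g) + {float(r.nu_H2O):g} H2O(l) + "
            f"{float(r.nu_N2):g} N2(g)   Δn(gas) = {float(r.delta_n_gas):g}",
            f"  Δc u°        = {self.massic_energy.format(1)} J·g⁻¹ (mean ± sdom)",
            f"  −Δc U°m(l)   = {(-self.dcU).format(1)} kJ·mol⁻¹",
            f"  −Δc H°m(l)   = {(-self.dcH).format(1)} kJ·mol⁻¹",
            f"  −Δf H°m(l)   = {(-self.dfH_liquid).format(1)} kJ·mol⁻¹",
            "  uncertainty budget (relative): "
            + ", ".join(f"{c:.3e}" for c in self.uncertainty_budget),
        ]
        return "\n".join(lines)


class CombustionStudy:
    """Replicate bomb-combustion experiments for one fuel.

    Parameters
    ----------
    massic_energies
        Already-reduced replicate Δc u° values (J·g⁻¹); alternatively
        construct with :meth:`from_experiments` from raw records.
    fuel
        Formula of the combusted compound (string or
        :class:`ChemicalFormula`).
    calibration
        :class:`CalibrationResult` (or a Quantity ε_cal in J·K⁻¹).
    certificate_relative
        Relative uncertainty of the reference-material certificate
        entering the expanded-uncertainty budget.
    aux_relative
        Relative components for the auxiliary-material energies.
    """

    def __init__(
        self,
        massic_energies: Sequence[float],
        fuel,
        calibration: Optional[CalibrationResult] = None,
        eps_cal: Optional[Quantity] = None,
        constants: ConstantsTable = CONSTANTS,
        certificate_relative: float = 3.0 / 26434.0,
        aux_relative: Sequence[float] = (DEFAULT_AUX_RELATIVE,),
        name: str = "",
    ) -> None:
        if calibration is not None:
            eps_cal = calibration.eps_cal
        if eps_cal is None:
            raise ValueError("a calibration (or eps_cal) is required")
        self.massic_energies = tuple(float(v) for v in massic_energies)
        self.fuel = _as_formula(fuel)
        self.eps_cal = eps_cal
        self.constants = constants
        self.certificate_relative = certificate_relative
        self.aux_relative = tuple(aux_relative)
        self.name = name or self.fuel.hill()

    @classmethod
    def from_experiments(
        cls,
        experiments: Sequence[BombExperiment],
        fuel,
        calibration: CalibrationResult,
        constants: ConstantsTable = CONSTANTS,
        corrections: Corrections = Corrections(),
        name: str = "",
        **kwargs,
    ) -> "CombustionStudy":
        """Reduce raw bomb records to massic energies first."""
        fuel_f = _as_formula(fuel)
        values = [
            _bomb.massic_energy(
                exp, fuel_f, calibration, constants, corrections=corrections
            ).value
            for exp in experiments
        ]
        return cls(
            values, fuel_f, calibration=calibration, constants=constants,
            name=name, **kwargs,
        )

    def fit(self) -> CombustionResults:
        reps = summarize_replicates(self.massic_energies)
        M = molar_mass(self.fuel, self.constants)
        budget = default_relative_budget(
            reps,
            calibration_relative=self.eps_cal.u / self.eps_cal.value,
            certificate_relative=self.certificate_relative,
            aux_relative=self.aux_relative,
        )
        dcU_value = reps.mean * M.value / 1000.0
        u_exp = expanded_uncertainty(dcU_value, budget)
        dcU = molar_combustion_energy(reps.mean, M, u_expanded=u_exp)
        reaction = balance_combustion(self.fuel)
        dcH = enthalpy_from_energy(
            dcU, float(reaction.delta_n_gas), self.constants
        )
        dfH_l = formation_liquid(dcH, reaction, self.constants)
        return CombustionResults(
            name=self.name,
            fuel=self.fuel,
            reaction=reaction,
            replicates=reps,
            massic_energy=Quantity(reps.mean, reps.sdom, reps.unit),
            molar_mass=M,
            dcU=dcU,
            dcH=dcH,
            dfH_liquid=dfH_l,
            uncertainty_budget=tuple(budget),
        )


@dataclass(frozen=True)
class VaporizationResults:
    """Standard molar vaporization enthalpy from Calvet drops."""

    name: str
    at_oven: Quantity  # kJ·mol⁻¹, mean ± sdom at T_oven
    T_oven: float
    heating_correction: float  # kJ·mol⁻¹, ∫Cp dT
    dvapH: Quantity  # kJ·mol⁻¹ at 298.15 K, expanded uncertainty
    n_runs: int
    calibration_factor: float

    def summary(self) -> str:
        return "\n".join(
            [
                f"Vaporization study: {self.name}",
                f"  runs: {self.n_runs}   T(oven) = {self.T_oven:.1f} K   "
                f"k(cal) = {self.calibration_factor:.4f}",
                f"  ΔH_obs(298.15 K → T, g) = {self.at_oven.format(1)} kJ·mol⁻¹",
                f"  ∫Cp,m°(g) dT            = {self.heating_correction:.1f} kJ·mol⁻¹",
                f"  Δvap H°m(298.15 K)      = {self.dvapH.format(1)} kJ·mol⁻¹",
            ]
        )


class VaporizationStudy:
    """Calvet drop-microcalorimetry series for one liquid compound.

    Construct either from raw runs (``runs=[CalvetRun, ...]``) or from
    an already-summarized observed enthalpy (``observed`` as a Quantity
    mean ± sdom at ``T_oven``).
    """

    def __init__(
        self,
        cp: CpPolynomial,
        runs: Optional[Sequence[CalvetRun]] = None,
        observed: Optional[Quantity] = None,
        T_oven: Optional[float] = None,
        calibration_factor: float = 1.0,
        u_calibration: float = 0.0,
        name: str = "",
    ) -> None:
        if (runs is None) == (observed is None):
            raise ValueError("provide exactly one of runs or observed")
        if observed is not None and T_oven is None:
            raise ValueError("observed values need an oven temperature")
        self.cp = cp
        self.runs = list(runs) if runs is not None else None
        self.observed = observed
        self.T_oven = T_oven
        self.calibration_factor = calibration_factor
        self.u_calibration = u_calibration
        self.name = name

    def fit(self) -> VaporizationResults:
        if self.runs is not None:
            summary = summarize_calvet(
                self.runs, self.calibration_factor, self.u_calibration
            )
        else:
            summary = CalvetSummary(
                at_oven=self.observed,
                T_oven=float(self.T_oven),
                n_runs=0,
                calibration_factor=self.calibration_factor,
                u_calibration=self.u_calibration,
            )
        dvapH = vaporization_enthalpy(summary, self.cp)
        return VaporizationResults(
            name=self.name,
            at_oven=summary.at_oven,
            T_oven=summary.T_oven,
            heating_correction=self.cp.integral(298.15, summary.T_oven),
            dvapH=dvapH,
            n_runs=summary.n_runs,
            calibration_factor=summary.calibration_factor,
        )


def gas_phase_formation(
    combustion: CombustionResults, vaporization: VaporizationResults
) -> Quantity:
    """Δf H°m(g) = Δf H°m(l) + Δvap H°m (RSS uncertainties)."""
    return formation_gas(combustion.dfH_liquid, vaporization.dvapH)
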