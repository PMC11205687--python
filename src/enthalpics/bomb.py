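"""Reduction of static-bomb combustion experiments.

One experiment is reduced to a standard massic energy of combustion
Δc u° (J·g⁻¹) in the following steps:

1.  The corrected adiabatic temperature rise ΔT_ad is extracted from the
    fore/main/after temperature–time record (Regnault–Pfaundler heat
    -exchange correction, with Dickinson extrapolation as an
    alternative), unless supplied directly.
2.  The energy of the isothermal bomb process is formed as

        ΔU(IPB) = −{ε_cal + Δm(H2O)·cp(H2O,l) + ε_f}·ΔT_ad + ΔU(ign)

    where ΔU(ign) is the electrical ignition energy (capacitor
    discharge, ½·C·(V1² − V2²)).  ΔU(IPB) is the chemical energy of the
    bomb process: the electrical input is netted out by the +ΔU(ign)
    term.
3.  The energies of the auxiliary materials (cotton-thread fuse,
    Melinex sample bag corrected for its water mass fraction), the
    nitric-acid formation energy, and a simplified standard-state
    (Washburn) correction are subtracted; division by the sample mass
    gives Δc u°.

The sample mass is either weighed directly or recovered from the total
collected CO2 after accounting for the CO2 produced by the fuse and the
Melinex.  The energy equivalent ε_cal comes from benzoic-acid
calibration runs, normalized to the reference calorimeter-water mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .constants import ConstantsTable, CONSTANTS
from .formula import ChemicalFormula, molar_mass
from .quantities import Quantity
from .stoichiometry import mass_from_co2, theoretical_co2_mass

__all__ = [
    "AuxiliaryMaterial",
    "MELINEX",
    "COTTON_FUSE",
    "TemperatureTrace",
    "TraceReduction",
    "BombExperiment",
    "CalibrationResult",
    "Corrections",
    "MassicEnergyResult",
    "IncompleteRecordError",
    "InconsistentRecordError",
    "ignition_energy",
    "reduce_trace",
    "energy_ipb",
    "massic_energy",
    "sample_mass_from_co2",
    "calibrate",
]

#: Molar energy of formation of 0.1 mol·dm⁻³ HNO3(aq) from N2, O2 and
#: H2O(l), J·mol⁻¹ — the basis of the nitric-acid correction.
HNO3_FORMATION_ENERGY = -59.7e3

#: Default bomb oxygen pressure, MPa.
DEFAULT_BOMB_PRESSURE = 3.04

#: Standard pressure, MPa.
STANDARD_PRESSURE = 0.1

#: Reference mass of calorimeter water to which ε_cal is normalized, g.
REFERENCE_WATER_MASS = 3119.6

#: Pressure coefficient of massic energy assumed for generic organic
#: samples, J·g⁻¹·MPa⁻¹.
DEFAULT_SAMPLE_DU_DP = -0.2


class IncompleteRecordError(ValueError):
    """An experiment record lacks data required for the reduction."""


class InconsistentRecordError(ValueError):
    """An experiment record is internally inconsistent."""


def _co2_per_gram(
    counts: Mapping[str, float], constants: ConstantsTable = CONSTANTS
) -> float:
    """Grams of CO2 per gram of material with (possibly fractional)
    empirical-formula element counts."""
    m = sum(n * constants.atomic_mass(el) for el, n in counts.items())
    return counts.get("C", 0.0) * constants.molar_mass_CO2 / m


@dataclass(frozen=True)
class AuxiliaryMaterial:
    """A combustible auxiliary (fuse, sample bag) burned alongside the sample.

    Attributes
    ----------
    massic_energy : float
        Standard massic energy of combustion Δc u°, J·g⁻¹ (negative).
    u_massic_energy : float
        Standard uncertainty of ``massic_energy``, J·g⁻¹.
    water_fraction : float
        Mass fraction of water to strip before energy accounting.
    cp : float
        Massic heat capacity, J·g⁻¹·K⁻¹ (metadata for ε_f estimates).
    du_dp : float
        Pressure coefficient (∂u/∂p)_T, J·g⁻¹·MPa⁻¹.
    density : float
        g·cm⁻³ (metadata).
    empirical_formula : mapping
        Element -> count per "monomer unit"; may be fractional (e.g.
        cotton CH1.686O0.843).  Used for CO2 accounting.
    """

    name: str
    massic_energy: float
    u_massic_energy: float = 0.0
    water_fraction: float = 0.0
    cp: float = 0.0
    du_dp: float = 0.0
    density: float = 0.0
    empirical_formula: Mapping[str, float] = field(default_factory=dict)

    def co2_per_gram(self, constants: ConstantsTable = CONSTANTS) -> float:
        if not self.empirical_formula:
            return 0.0
        return _co2_per_gram(self.empirical_formula, constants)


#: Melinex (polyethylene terephthalate) sample-bag material.
MELINEX = AuxiliaryMaterial(
    name="melinex",
    massic_energy=-22902.0,
    u_massic_energy=5.0,
    water_fraction=0.0032,
    cp=1.3,
    du_dp=-0.03,
    density=1.38,
    empirical_formula={"C": 10, "H": 8, "O": 4},
)

#: Cotton-thread ignition fuse, empirical formula CH1.686O0.843.
COTTON_FUSE = AuxiliaryMaterial(
    name="cotton fuse",
    massic_energy=-16240.0,
    water_fraction=0.0,
    cp=1.67,
    du_dp=-0.29,
    density=1.50,
    empirical_formula={"C": 1, "H": 1.686, "O": 0.843},
)


# --------------------------------------------------------------------------
# temperature traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TemperatureTrace:
    """Fore/main/after temperature–time record of one combustion run.

    ``ignition_index`` is the last reading of the fore (rating) period;
    ``main_end_index`` is the first reading of the after period.
    Readings are typically at 10 s intervals with ~1e−4 K resolution.
    """

    time: np.ndarray
    temperature: np.ndarray
    ignition_index: int
    main_end_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        T = np.asarray(self.temperature, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "temperature", T)
        if t.shape != T.shape or t.ndim != 1:
            raise ValueError("time and temperature must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (0 < self.ignition_index < self.main_end_index < len(t)):
            raise ValueError(
                "period boundaries must satisfy 0 < ignition < main_end < n"
            )


@dataclass(frozen=True)
class TraceReduction:
    """Outcome of reducing a temperature trace."""

    dT_ad: float
    drift_fore: float
    drift_after: float
    cooling_constant: float
    convergence_temperature: float
    method: str


def _linear_drift(t: np.ndarray, T: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares drift (K·s⁻¹), mean time and mean temperature."""
    if len(t) < 3:
        raise ValueError("rating period needs at least 3 readings")
    slope, _ = np.polyfit(t, T, 1)
    return float(slope), float(t.mean()), float(T.mean())


def reduce_trace(
    trace: TemperatureTrace, method: str = "regnault-pfaundler"
) -> TraceReduction:
    """Extract the corrected adiabatic temperature rise ΔT_ad.

    The Regnault–Pfaundler method models heat exchange with the jacket
    as Newtonian, ``dT/dt = k·(T∞ − T)``.  Linear drifts fitted to the
    fore and after rating periods give the cooling constant
    ``k = (g_fore − g_after) / (T̄_after − T̄_fore)`` and the
    convergence temperature ``T∞``; the heat-exchange contribution over
    the main period is the trapezoidal integral of ``k·(T∞ − T(t))``,
    subtracted from the observed rise.

    The Dickinson alternative replaces the integral by extrapolating the
    fore and after drifts to the time at which the temperature has
    completed 60 % of the observed rise.
    """
    t, T = trace.time, trace.temperature
    i, j = trace.ignition_index, trace.main_end_index
    g_i, _, Ti = _linear_drift(t[: i + 1], T[: i + 1])
    g_f, _, Tf = _linear_drift(t[j:], T[j:])

    t_b, t_e = t[i], t[j]
    T_b, T_e = T[i], T[j]
    dT_obs = float(T_e - T_b)

    if abs(Tf - Ti) < 1e-9:
        # degenerate: no usable temperature lever arm -> constant drift
        k = 0.0
        T_inf = math.nan
        leak = 0.5 * (g_i + g_f) * (t_e - t_b)
    else:
        k = (g_i - g_f) / (Tf - Ti)
        if not math.isfinite(k):
            raise ValueError("drift fit failed: non-finite cooling constant")
        if abs(k) < 1e-16:
            T_inf = math.nan
            leak = g_i * (t_e - t_b)
        else:
            T_inf = Ti + g_i / k
            main_t = t[i : j + 1]
            main_T = T[i : j + 1]
            if method == "dickinson":
                target = T_b + 0.6 * dT_obs
                t_m = float(np.interp(target, main_T, main_t))
                leak = g_i * (t_m - t_b) + g_f * (t_e - t_m)
            else:
                leak = float(np.trapezoid(k * (T_inf - main_T), main_t))
    if method not in ("regnault-pfaundler", "dickinson"):
        raise ValueError(f"unknown trace-reduction method {method!r}")
    return TraceReduction(
        dT_ad=dT_obs - leak,
        drift_fore=g_i,
        drift_after=g_f,
        cooling_constant=k,
        convergence_temperature=T_inf,
        method=method,
    )


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

def ignition_energy(capacitance: float, v_before: float, v_after: float) -> float:
    """Electrical ignition energy of a capacitor discharge, J.

    ``ΔU(ign) = ½·C·(V1² − V2²)`` for a capacitor of *capacitance* F
    discharged from *v_before* to *v_after* volts.
    """
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    if v_after > v_before:
        raise InconsistentRecordError(
            f"capacitor voltage rose during discharge ({v_before} -> {v_after} V)"
        )
    return 0.5 * capacitance * (v_before**2 - v_after**2)


#: Capacitance of the standard ignition unit, F.
DEFAULT_CAPACITANCE = 1400e-6


@dataclass
class BombExperiment:
    """Raw record of one static-bomb combustion run.

    Masses in g; ``delta_m_h2o`` is the deviation of the calorimeter
    water from the reference mass (g); ``eps_f`` is the energy
    equivalent of the bomb contents after ignition (J·K⁻¹).  The
    ignition energy may be given directly (``du_ign``, J) or as a
    capacitor record ``(C, V_before, V_after)``.  ``dT_ad`` may be given
    directly or left to be reduced from ``trace``.
    """

    m_sample: Optional[float] = None
    m_fuse: float = 0.0
    m_melinex: float = 0.0
    delta_m_h2o: float = 0.0
    dT_ad: Optional[float] = None
    trace: Optional[TemperatureTrace] = None
    du_ign: Optional[float] = None
    capacitor: Optional[Tuple[float, float, float]] = None
    n_hno3: float = 0.0
    m_co2: Optional[float] = None
    eps_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_sample", "m_fuse", "m_melinex", "n_hno3", "m_co2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.capacitor is not None:
            c, v1, v2 = self.capacitor
            if v2 > v1:
                raise InconsistentRecordError("V_after exceeds V_before")

    def ignition(self) -> float:
        """Ignition energy ΔU(ign) in J."""
        if self.du_ign is not None:
            return self.du_ign
        if self.capacitor is not None:
            return ignition_energy(*self.capacitor)
        return 0.0

    def adiabatic_rise(self, method: str = "regnault-pfaundler") -> float:
        if self.dT_ad is not None:
            return self.dT_ad
        if self.trace is not None:
            return reduce_trace(self.trace, method=method).dT_ad
        raise IncompleteRecordError(
            "experiment has neither dT_ad nor a temperature trace"
        )


@dataclass(frozen=True)
class CalibrationResult:
    """Energy equivalent of the calorimeter from benzoic-acid runs."""

    eps_cal: Quantity  # J·K⁻¹, normalized to the reference water mass
    n_runs: int
    certificate: Quantity  # J·g⁻¹

    def __post_init__(self) -> None:
        if self.eps_cal.value <= 0:
            raise ValueError("energy equivalent must be positive")


@dataclass(frozen=True)
class Corrections:
    """Switches for the individual energy corrections.

    With everything off, the massic energy degenerates to
    ΔU(IPB) / m_sample.
    """

    fuse: bool = True
    melinex: bool = True
    hno3: bool = True
    standard_state: bool = True


def energy_ipb(
    exp: BombExperiment,
    eps_cal: float,
    cp_water: float = CONSTANTS.cp_water,
    dT_ad: Optional[float] = None,
) -> float:
    """Energy of the isothermal bomb process, J.

    ``ΔU(IPB) = −{ε_cal + Δm(H2O)·cp(H2O,l) + ε_f}·ΔT_ad + ΔU(ign)``.
    Negative for an exothermic combustion.
    """
    if dT_ad is None:
        dT_ad = exp.adiabatic_rise()
    eps_total = eps_cal + exp.delta_m_h2o * cp_water + exp.eps_f
    return -eps_total * dT_ad + exp.ignition()


def standard_state_correction(
    m_sample: float,
    m_melinex_dry: float,
    m_fuse: float,
    pressure: float = DEFAULT_BOMB_PRESSURE,
    sample_du_dp: float = DEFAULT_SAMPLE_DU_DP,
    melinex: AuxiliaryMaterial = MELINEX,
    fuse: AuxiliaryMaterial = COTTON_FUSE,
) -> float:
    """Simplified Washburn correction ΔU_Σ, J.

    Only the pressure term ``m·(∂u/∂p)_T·(p − p°)`` is retained, summed
    over sample, Melinex and fuse.  A user-supplied callable can replace
    this via the ``standard_state_hook`` argument of
    :func:`massic_energy`.
    """
    dp = pressure - STANDARD_PRESSURE
    return (
        m_sample * sample_du_dp
        + m_melinex_dry * melinex.du_dp
        + m_fuse * fuse.du_dp
    ) * dp


def sample_mass_from_co2(
    m_co2_total: float,
    fuel: ChemicalFormula,
    m_fuse: float = 0.0,
    m_melinex_dry: float = 0.0,
    fuse: AuxiliaryMaterial = COTTON_FUSE,
    melinex: AuxiliaryMaterial = MELINEX,
    constants: ConstantsTable = CONSTANTS,
) -> float:
    """Sample mass from total collected CO2, net of fuse and Melinex CO2."""
    residual = (
        m_co2_total
        - m_fuse * fuse.co2_per_gram(constants)
        - m_melinex_dry * melinex.co2_per_gram(constants)
    )
    if residual < -1e-12:
        raise InconsistentRecordError(
            "collected CO2 is less than the auxiliary materials alone produce"
        )
    return mass_from_co2(fuel, max(residual, 0.0), constants)


@dataclass(frozen=True)
class MassicEnergyResult:
    """Standard massic energy of combustion of one run, with bookkeeping."""

    value: float  # J·g⁻¹
    m_sample: float  # g
    du_ipb: float  # J
    components: Mapping[str, float]  # J, each subtracted correction
    co2_recovery: Optional[float]
    warnings: Tuple[str, ...]


def massic_energy(
    exp: BombExperiment,
    fuel: ChemicalFormula,
    calibration: CalibrationResult,
    constants: ConstantsTable = CONSTANTS,
    melinex: AuxiliaryMaterial = MELINEX,
    fuse: AuxiliaryMaterial = COTTON_FUSE,
    sample_du_dp: float = DEFAULT_SAMPLE_DU_DP,
    pressure: float = DEFAULT_BOMB_PRESSURE,
    buoyancy_factor: float = 1.0,
    corrections: Corrections = Corrections(),
    standard_state_hook: Optional[Callable[..., float]] = None,
    trace_method: str = "regnault-pfaundler",
) -> MassicEnergyResult:
    """Reduce one combustion run to the standard massic energy Δc u°.

    ``Δc u° = (ΔU(IPB) − E_fuse − E_Melinex − E_HNO3 − ΔU_Σ) / m``

    The Melinex energy uses the dry mass ``m·(1 − w)``; the nitric-acid
    term is ``n(HNO3)·(−59.7 kJ·mol⁻¹)``; ΔU_Σ is the simplified
    standard-state correction (or the ``standard_state_hook`` result).
    The sample mass is the weighed mass times ``buoyancy_factor``, or is
    recovered from the collected CO2 when no weighed mass is present.
    """
    warnings: List[str] = []
    dT_ad = exp.adiabatic_rise(method=trace_method)
    du_ipb = energy_ipb(exp, calibration.eps_cal.value, constants.cp_water, dT_ad)

    m_mel_dry = exp.m_melinex * (1.0 - melinex.water_fraction)
    e_fuse = exp.m_fuse * fuse.massic_energy if corrections.fuse else 0.0
    e_mel = m_mel_dry * melinex.massic_energy if corrections.melinex else 0.0
    e_hno3 = exp.n_hno3 * HNO3_FORMATION_ENERGY if corrections.hno3 else 0.0

    if exp.m_sample is not None:
        m_sample = exp.m_sample * buoyancy_factor
    elif exp.m_co2 is not None:
        m_sample = sample_mass_from_co2(
            exp.m_co2, fuel, exp.m_fuse, m_mel_dry, fuse, melinex, constants
        )
    else:
        raise IncompleteRecordError(
            "experiment has neither a weighed sample mass nor a CO2 mass"
        )
    if m_sample <= 0:
        raise InconsistentRecordError("non-positive sample mass")

    if corrections.standard_state:
        if standard_state_hook is not None:
            du_sigma = standard_state_hook(
                m_sample=m_sample,
                m_melinex_dry=m_mel_dry,
                m_fuse=exp.m_fuse,
                pressure=pressure,
            )
        else:
            du_sigma = standard_state_correction(
                m_sample, m_mel_dry, exp.m_fuse, pressure, sample_du_dp,
                melinex, fuse,
            )
    else:
        du_sigma = 0.0

    co2_recovery = None
    if exp.m_co2 is not None and exp.m_sample is not None:
        predicted = (
            theoretical_co2_mass(fuel, m_sample, constants)
            + exp.m_fuse * fuse.co2_per_gram(constants)
            + m_mel_dry * melinex.co2_per_gram(constants)
        )
        co2_recovery = exp.m_co2 / predicted
        if not 0.99 <= co2_recovery <= 1.01:
            warnings.append(
                f"CO2 recovery ratio {co2_recovery:.4f} outside [0.99, 1.01]"
            )

    value = (du_ipb - e_fuse - e_mel - e_hno3 - du_sigma) / m_sample
    return MassicEnergyResult(
        value=value,
        m_sample=m_sample,
        du_ipb=du_ipb,
        components={
            "fuse": e_fuse,
            "melinex": e_mel,
            "hno3": e_hno3,
            "standard_state": du_sigma,
            "ignition": exp.ignition(),
        },
        co2_recovery=co2_recovery,
        warnings=tuple(warnings),
    )


def calibrate(
    runs: Sequence[BombExperiment],
    certificate: Quantity = Quantity(-26434.0, 3.0, "J·g⁻¹"),
    constants: ConstantsTable = CONSTANTS,
    fuse: AuxiliaryMaterial = COTTON_FUSE,
) -> CalibrationResult:
    """Energy equivalent ε_cal from benzoic-acid calibration runs.

    Each run's total energy equivalent follows from the energy balance
    of Eq.-(3) form: ``ε_total = (−ΔU_chem + ΔU(ign)) / ΔT_ad`` with
    ``ΔU_chem = m·Δc u°(cert) + E_fuse + E_HNO3``.  Subtracting the
    water-mass deviation term and ε_f normalizes each run to the
    reference calorimeter-water mass; the result is the mean with the
    standard deviation of the mean as its uncertainty.
    """
    if len(runs) < 2:
        raise ValueError(
            "calibration needs at least 2 runs to report an uncertainty"
        )
    values = []
    for exp in runs:
        if exp.m_sample is None:
            raise IncompleteRecordError("calibration run lacks a sample mass")
        dT_ad = exp.adiabatic_rise()
        if dT_ad <= 0:
            raise InconsistentRecordError("non-positive temperature rise")
        du_chem = (
            exp.m_sample * certificate.value
            + exp.m_fuse * fuse.massic_energy
            + exp.n_hno3 * HNO3_FORMATION_ENERGY
        )
        eps_total = (-du_chem + exp.ignition()) / dT_ad
        values.append(
            eps_total - exp.delta_m_h2o * constants.cp_water - exp.eps_f
        )
    arr = np.asarray(values)
    mean = float(arr.mean())
    sdom = float(arr.std(ddof=1) / math.sqrt(len(arr)))
    return CalibrationResult(
        eps_cal=Quantity(mean, sdom, "J·K⁻¹"),
        n_runs=len(runs),
        certificate=certificate,
    )
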