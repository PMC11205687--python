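"""Synthetic experiment generators.

Every stage of the reduction chain can be exercised without laboratory
data: the generators here produce bomb-combustion records (including
fore/main/after temperature traces) and Calvet drop records from
declared "true" values, so that generator → reducer is a round trip.

The temperature-trace model is Newtonian heat exchange with the jacket,

    dT/dt = k·(T_conv − T) + q(t),

with the main-period energy release modeled as a fast exponential,
``q(t) = ΔT_ad·λ·exp(−λt)``.  The closed-form solution is sampled at
the reading interval; this is a *model choice* sufficient to validate
the Regnault–Pfaundler extraction, not a claim about instrument
physics.  Noise defaults mirror typical instrument resolutions
(±1e−4 K temperature readings at 10 s intervals).

All randomness flows from one seeded generator per call; the seed is a
mandatory config field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bomb import (
    BombExperiment,
    COTTON_FUSE,
    DEFAULT_BOMB_PRESSURE,
    DEFAULT_CAPACITANCE,
    DEFAULT_SAMPLE_DU_DP,
    HNO3_FORMATION_ENERGY,
    MELINEX,
    STANDARD_PRESSURE,
    TemperatureTrace,
    ignition_energy,
)
from .calvet import CalvetRun, CpPolynomial
from .constants import ConstantsTable, CONSTANTS
from .formula import ChemicalFormula, parse_formula
from .stoichiometry import theoretical_co2_mass

__all__ = [
    "SyntheticBombConfig",
    "SyntheticCalvetConfig",
    "generate_bomb_experiments",
    "generate_calibration_runs",
    "generate_calvet_runs",
    "synthetic_trace",
    "SYNTHETIC_CP_FURFURYLAMINE",
    "SYNTHETIC_CP_METHYLFURFURYLAMINE",
]

# ---------------------------------------------------------------------------
# synthetic gas-phase heat-capacity polynomials
# ---------------------------------------------------------------------------

#: Synthetic stand-in for the furfurylamine Cp,m°(g) polynomial (the
#: DFT-derived coefficients are not distributed with the package).  The
#: linear form was back-solved so that the 0.965-scaled integral from
#: 298.15 K to the 344.5 K oven temperature equals 5.400 kJ·mol⁻¹, the
#: documented correction term for this compound; the slope is a typical
#: value for a molecule of this size.
SYNTHETIC_CP_FURFURYLAMINE = CpPolynomial(
    coefficients=(24.332919035162686, 0.30), scale_factor=0.965
)

#: Synthetic stand-in for the 5-methylfurfurylamine Cp,m°(g) polynomial;
#: back-solved so the scaled integral from 298.15 K to 339.9 K equals
#: 6.000 kJ·mol⁻¹.
SYNTHETIC_CP_METHYLFURFURYLAMINE = CpPolynomial(
    coefficients=(46.836948031398364, 0.32), scale_factor=0.965
)


# ---------------------------------------------------------------------------
# bomb experiments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBombConfig:
    """Conditions for generating synthetic bomb-combustion runs.

    Defaults emulate a Parr-1108-class static bomb: ~0.5 g liquid
    samples sealed in Melinex bags, cotton-thread fuses, 3.04 MPa
    oxygen, ε_cal ≈ 15.9 kJ·K⁻¹, readings every 10 s resolved to
    1e−4 K.  ``massic_noise`` is a per-run scatter on the true massic
    energy (J·g⁻¹); 5 J·g⁻¹ reproduces the few-J·g⁻¹ sdom typical of
    six-run series.
    """

    seed: int
    true_massic_energy: float = -29588.1  # J·g⁻¹
    fuel: str = "C5H7NO"
    n_runs: int = 6
    sample_mass_range: Tuple[float, float] = (0.45, 0.65)  # g
    fuse_mass_range: Tuple[float, float] = (0.002, 0.004)  # g
    melinex_mass_range: Tuple[float, float] = (0.04, 0.06)  # g
    delta_m_h2o_range: Tuple[float, float] = (-1.5, 1.5)  # g
    n_hno3_range: Tuple[float, float] = (2e-5, 8e-5)  # mol
    eps_cal: float = 15907.1  # J·K⁻¹
    eps_f: float = 16.0  # J·K⁻¹
    pressure: float = DEFAULT_BOMB_PRESSURE  # MPa
    sample_du_dp: float = DEFAULT_SAMPLE_DU_DP
    cooling_constant: float = 1.5e-3  # min⁻¹
    convergence_temperature: float = 298.35  # K
    ignition_temperature: float = 298.150  # K
    release_rate: float = 1.0 / 60.0  # s⁻¹, main-period time constant
    reading_interval: float = 10.0  # s
    n_fore: int = 100
    n_main: int = 100
    n_after: int = 100
    temperature_noise: float = 1e-4  # K
    massic_noise: float = 5.0  # J·g⁻¹
    capacitor_v1: float = 40.0  # V
    capacitor_v2_range: Tuple[float, float] = (18.0, 22.0)  # V

    def __post_init__(self) -> None:
        for name in (
            "eps_cal", "eps_f", "pressure", "cooling_constant",
            "release_rate", "reading_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def synthetic_trace(
    dT_ad: float,
    cfg: SyntheticBombConfig,
    rng: Optional[np.random.Generator] = None,
) -> TemperatureTrace:
    """Closed-form Newtonian fore/main/after trace with a known ΔT_ad."""
    k = cfg.cooling_constant / 60.0  # s⁻¹
    lam = cfg.release_rate
    dt = cfg.reading_interval
    T_conv = cfg.convergence_temperature
    T_ign = cfg.ignition_temperature

    n_total = cfg.n_fore + cfg.n_main + cfg.n_after
    t = np.arange(n_total) * dt
    t_ign = (cfg.n_fore - 1) * dt

    T = np.empty(n_total)
    fore = t <= t_ign
    # backwards extrapolation of the Newtonian approach through T_ign
    T[fore] = T_conv + (T_ign - T_conv) * np.exp(-k * (t[fore] - t_ign))
    tau = t[~fore] - t_ign
    T[~fore] = (
        T_conv
        + (T_ign - T_conv) * np.exp(-k * tau)
        + dT_ad * lam / (lam - k) * (np.exp(-k * tau) - np.exp(-lam * tau))
    )
    if rng is not None and cfg.temperature_noise > 0:
        T = T + rng.normal(0.0, cfg.temperature_noise, size=n_total)
    return TemperatureTrace(
        time=t,
        temperature=T,
        ignition_index=cfg.n_fore - 1,
        main_end_index=cfg.n_fore + cfg.n_main - 1,
    )


def generate_bomb_experiments(
    cfg: SyntheticBombConfig,
    constants: ConstantsTable = CONSTANTS,
) -> Tuple[List[BombExperiment], List[float]]:
    """Generate bomb runs consistent with a declared true massic energy.

    Returns the experiments and the per-run true massic energies (the
    declared value plus the run-level scatter), so round-trip tests can
    compare against exactly what each run encodes.
    """
    rng = np.random.default_rng(cfg.seed)
    fuel = parse_formula(cfg.fuel)
    dp = cfg.pressure - STANDARD_PRESSURE

    experiments: List[BombExperiment] = []
    truths: List[float] = []
    for _ in range(cfg.n_runs):
        du_run = cfg.true_massic_energy + (
            rng.normal(0.0, cfg.massic_noise) if cfg.massic_noise > 0 else 0.0
        )
        m_s = rng.uniform(*cfg.sample_mass_range)
        m_fuse = rng.uniform(*cfg.fuse_mass_range)
        m_mel = rng.uniform(*cfg.melinex_mass_range)
        m_mel_dry = m_mel * (1.0 - MELINEX.water_fraction)
        dm_h2o = rng.uniform(*cfg.delta_m_h2o_range)
        n_hno3 = rng.uniform(*cfg.n_hno3_range)
        v2 = rng.uniform(*cfg.capacitor_v2_range)
        du_ign = ignition_energy(DEFAULT_CAPACITANCE, cfg.capacitor_v1, v2)

        du_sigma = (
            m_s * cfg.sample_du_dp
            + m_mel_dry * MELINEX.du_dp
            + m_fuse * COTTON_FUSE.du_dp
        ) * dp
        du_ipb = (
            m_s * du_run
            + m_fuse * COTTON_FUSE.massic_energy
            + m_mel_dry * MELINEX.massic_energy
            + n_hno3 * HNO3_FORMATION_ENERGY
            + du_sigma
        )
        eps_total = cfg.eps_cal + dm_h2o * constants.cp_water + cfg.eps_f
        dT_ad = (-du_ipb + du_ign) / eps_total

        m_co2 = (
            theoretical_co2_mass(fuel, m_s, constants)
            + m_fuse * COTTON_FUSE.co2_per_gram(constants)
            + m_mel_dry * MELINEX.co2_per_gram(constants)
        )
        trace = synthetic_trace(
            dT_ad, cfg, rng if cfg.temperature_noise > 0 else None
        )
        experiments.append(
            BombExperiment(
                m_sample=m_s,
                m_fuse=m_fuse,
                m_melinex=m_mel,
                delta_m_h2o=dm_h2o,
                trace=trace,
                capacitor=(DEFAULT_CAPACITANCE, cfg.capacitor_v1, v2),
                n_hno3=n_hno3,
                m_co2=m_co2,
                eps_f=cfg.eps_f,
            )
        )
        truths.append(du_run)
    return experiments, truths


def generate_calibration_runs(
    seed: int,
    eps_cal_true: float = 15907.1,
    n_runs: int = 6,
    certificate_massic_energy: float = -26434.0,
    sample_mass_range: Tuple[float, float] = (0.6, 0.8),
    fuse_mass_range: Tuple[float, float] = (0.002, 0.004),
    eps_f: float = 15.0,
    delta_m_h2o_range: Tuple[float, float] = (-1.5, 1.5),
    dT_noise: float = 0.0,
    constants: ConstantsTable = CONSTANTS,
) -> List[BombExperiment]:
    """Benzoic-acid calibration runs encoding a true energy equivalent."""
    rng = np.random.default_rng(seed)
    runs: List[BombExperiment] = []
    for _ in range(n_runs):
        m_ba = rng.uniform(*sample_mass_range)
        m_fuse = rng.uniform(*fuse_mass_range)
        dm_h2o = rng.uniform(*delta_m_h2o_range)
        v2 = rng.uniform(18.0, 22.0)
        du_ign = ignition_energy(DEFAULT_CAPACITANCE, 40.0, v2)
        du_chem = (
            m_ba * certificate_massic_energy + m_fuse * COTTON_FUSE.massic_energy
        )
        eps_total = eps_cal_true + dm_h2o * constants.cp_water + eps_f
        dT_ad = (-du_chem + du_ign) / eps_total
        if dT_noise > 0:
            dT_ad += rng.normal(0.0, dT_noise)
        runs.append(
            BombExperiment(
                m_sample=m_ba,
                m_fuse=m_fuse,
                delta_m_h2o=dm_h2o,
                dT_ad=dT_ad,
                capacitor=(DEFAULT_CAPACITANCE, 40.0, v2),
                eps_f=eps_f,
            )
        )
    return runs


# ---------------------------------------------------------------------------
# Calvet drops
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCalvetConfig:
    """Conditions for generating synthetic Calvet drop runs.

    Six independent drops per series is the standard protocol this
    emulates; ``noise_sd`` is the run-to-run scatter of the observed
    molar enthalpy (kJ·mol⁻¹).  ``bias`` multiplies the observed values
    and models an instrument sensitivity offset that in-situ
    calibration should remove.
    """

    seed: int
    true_dvapH: float = 49.1  # kJ·mol⁻¹ at 298.15 K
    cp: CpPolynomial = field(
        default_factory=lambda: SYNTHETIC_CP_FURFURYLAMINE
    )
    T_oven: float = 344.5  # K
    n_runs: int = 6
    mass_range: Tuple[float, float] = (3.0, 7.0)  # mg
    noise_sd: float = 0.98  # kJ·mol⁻¹
    bias: float = 1.0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


def generate_calvet_runs(cfg: SyntheticCalvetConfig) -> List[CalvetRun]:
    """Drop runs: observed = true + ∫Cp dT + noise, times the bias."""
    rng = np.random.default_rng(cfg.seed)
    heating = cfg.cp.integral(298.15, cfg.T_oven)
    runs: List[CalvetRun] = []
    for _ in range(cfg.n_runs):
        noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
        runs.append(
            CalvetRun(
                m_sample=rng.uniform(*cfg.mass_range),
                T_oven=cfg.T_oven,
                dH_observed=cfg.bias * (cfg.true_dvapH + heating + noise),
            )
        )
    return runs
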