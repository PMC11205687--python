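"""Calvet high-temperature drop microcalorimetry reduction.

A few mg of liquid, in a thin glass capillary, are dropped at room
temperature into the hot cell of a Calvet microcalorimeter held at T and
removed by vacuum evaporation.  The observed molar enthalpy change
(after blank-capillary correction) covers heating the liquid from
298.15 K to T *and* vaporizing it; the standard molar vaporization
enthalpy at 298.15 K follows by subtracting the gas-phase heating
enthalpy:

    Δvap H°m(298.15 K) = ΔH_obs(298.15 K → T, g) − ∫_298.15^T Cp,m°(g) dT

Cp,m°(g) is supplied as a polynomial in T (typically from scaled DFT
frequencies); the integral is analytic.  The instrument is calibrated
in situ against a reference compound of known vaporization enthalpy
(n-decane / n-undecane class), yielding a dimensionless factor applied
multiplicatively to the observed enthalpies.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import ConstantsTable, CONSTANTS, KJ_PER_MOL
from .quantities import Quantity, rss_combine

__all__ = [
    "CalvetRun",
    "CpPolynomial",
    "CalvetSummary",
    "CalibrationWarning",
    "calibration_constant",
    "cp_integral",
    "correct_to_reference_T",
    "summarize_calvet",
    "vaporization_enthalpy",
]

T_REF = 298.15


class CalibrationWarning(UserWarning):
    """Calibration factor unexpectedly far from unity."""


@dataclass(frozen=True)
class CalvetRun:
    """One drop experiment.

    Attributes
    ----------
    m_sample : float
        Sample mass, mg (plausibility window 1–20 mg; 3–7 mg typical).
    T_oven : float
        Hot-cell temperature, K (standard uncertainty 0.1 K).
    dH_observed : float
        Observed molar enthalpy change at ``T_oven`` after blank
        correction, kJ·mol⁻¹.
    blank_correction : float
        The blank-capillary correction already applied, J (metadata).
    """

    m_sample: float
    T_oven: float
    dH_observed: float
    blank_correction: float = 0.0

    def __post_init__(self) -> None:
        if self.T_oven <= T_REF:
            raise ValueError("oven temperature must exceed 298.15 K")
        if not 1.0 <= self.m_sample <= 20.0:
            raise ValueError(
                f"sample mass {self.m_sample} mg outside the 1-20 mg window"
            )


@dataclass(frozen=True)
class CpPolynomial:
    """Gas-phase molar heat capacity Cp,m°(g) as a polynomial in T.

    ``coefficients`` are ascending powers of T (J·K⁻¹·mol⁻¹ per Kⁿ);
    ``scale_factor`` is the harmonic-frequency scaling applied to the
    whole polynomial (default 0.965, the common B3LYP scaling).
    """

    coefficients: Tuple[float, ...]
    scale_factor: float = 0.965
    t_min: float = 250.0
    t_max: float = 500.0

    def cp(self, T: float) -> float:
        """Scaled Cp,m°(g) at T, J·K⁻¹·mol⁻¹."""
        self._check_range(T)
        return self.scale_factor * sum(
            c * T**i for i, c in enumerate(self.coefficients)
        )

    def _check_range(self, T: float) -> None:
        if not self.t_min <= T <= self.t_max:
            raise ValueError(
                f"T = {T} K outside the polynomial's validity range "
                f"[{self.t_min}, {self.t_max}] K"
            )

    def integral(self, T_low: float, T_high: float) -> float:
        """Analytic ∫ Cp dT between T_low and T_high, in kJ·mol⁻¹."""
        self._check_range(T_low)
        self._check_range(T_high)
        total = 0.0
        for i, c in enumerate(self.coefficients):
            total += c * (T_high ** (i + 1) - T_low ** (i + 1)) / (i + 1)
        return self.scale_factor * total / 1000.0


def cp_integral(p: CpPolynomial, T_low: float, T_high: float) -> float:
    """Heat-capacity integral ∫_{T_low}^{T_high} Cp,m°(g) dT, kJ·mol⁻¹."""
    return p.integral(T_low, T_high)


def calibration_constant(
    reference_runs: Sequence[CalvetRun],
    reference_literature: float,
) -> float:
    """In-situ calibration factor k = literature / mean(observed).

    Applied multiplicatively to compound runs.  A factor outside
    [0.95, 1.05] triggers a :class:`CalibrationWarning`.
    """
    if len(reference_runs) < 2:
        raise ValueError("calibration needs at least 2 reference runs")
    t0 = reference_runs[0].T_oven
    if any(abs(r.T_oven - t0) > 0.5 for r in reference_runs):
        raise ValueError("reference runs must share the oven temperature")
    observed = np.mean([r.dH_observed for r in reference_runs])
    k = reference_literature / float(observed)
    if not 0.95 <= k <= 1.05:
        _warnings.warn(
            f"calibration constant {k:.4f} outside [0.95, 1.05]",
            CalibrationWarning,
        )
    return k


def correct_to_reference_T(
    dH_obs_at_T: float, p: CpPolynomial, T: float
) -> float:
    """Reduce an observed enthalpy at T to Δvap H°m(298.15 K), kJ·mol⁻¹.

    Subtracts the gas-phase heating enthalpy ∫_298.15^T Cp,m°(g) dT.
    """
    if T <= T_REF:
        raise ValueError("oven temperature must exceed 298.15 K")
    return dH_obs_at_T - p.integral(T_REF, T)


@dataclass(frozen=True)
class CalvetSummary:
    """Summary of a set of drop runs at one oven temperature."""

    at_oven: Quantity  # mean ± sdom, at T_oven
    T_oven: float
    n_runs: int
    calibration_factor: float
    u_calibration: float  # kJ·mol⁻¹


def summarize_calvet(
    runs: Sequence[CalvetRun],
    k: float = 1.0,
    u_calibration: float = 0.0,
) -> CalvetSummary:
    """Mean ± sdom of calibration-corrected drop runs.

    Requires >= 2 runs at a common oven temperature; observed
    enthalpies are multiplied by the calibration factor *k* first.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a standard deviation")
    t0 = runs[0].T_oven
    if any(abs(r.T_oven - t0) > 0.5 for r in runs):
        raise ValueError("runs must share the oven temperature")
    corrected = np.asarray([k * r.dH_observed for r in runs])
    mean = float(corrected.mean())
    sdom = float(corrected.std(ddof=1) / math.sqrt(len(corrected)))
    return CalvetSummary(
        at_oven=Quantity(mean, sdom, KJ_PER_MOL),
        T_oven=t0,
        n_runs=len(runs),
        calibration_factor=k,
        u_calibration=u_calibration,
    )


def vaporization_enthalpy(
    summary: CalvetSummary,
    p: CpPolynomial,
    constants: ConstantsTable = CONSTANTS,
) -> Quantity:
    """Standard molar vaporization enthalpy at 298.15 K.

    The value is the oven-temperature mean minus the heat-capacity
    integral; the final uncertainty is twice the RSS of the sdom and
    the calibration contribution (the Cp integral is treated as exact).
    """
    value = correct_to_reference_T(summary.at_oven.value, p, summary.T_oven)
    u = 2.0 * rss_combine([summary.at_oven.u, summary.u_calibration])
    return Quantity(value, u, KJ_PER_MOL)
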