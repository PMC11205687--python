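# enthalpics

Data reduction for classical combustion thermochemistry: from raw
static-bomb calorimetry and Calvet drop-microcalorimetry records to
standard (p° = 0.1 MPa) molar enthalpies of formation in the liquid and
gas phases at 298.15 K, with the uncertainty conventions of the field.

It is written for experimental thermochemists and for anyone who needs
to audit or reproduce a combustion-calorimetry determination: every
intermediate of the chain is an explicit, testable function, and a
synthetic-data module generates statistically faithful bomb and Calvet
experiments so the whole pipeline round-trips without laboratory data.
The bundled demo study covers two furan-derived platform chemicals,
furfurylamine (C5H7NO) and 5-methylfurfurylamine (C6H9NO).

## The reduction chain

A combustion run in a static bomb is reduced in the classical way.  The
corrected adiabatic temperature rise ΔT_ad is extracted from the
fore/main/after temperature record by the Regnault–Pfaundler
heat-exchange correction (Newtonian exchange, `dT/dt = k(T∞ − T)`);
the energy of the isothermal bomb process is

    ΔU(IPB) = −{ε_cal + Δm(H₂O)·c_p(H₂O,l) + ε_f}·ΔT_ad + ΔU(ign),

with the ignition energy ΔU(ign) = ½C(V₁² − V₂²) from a capacitor
discharge and ε_cal from benzoic-acid calibration.  Subtracting the
cotton-fuse and Melinex-bag combustion energies, the nitric-acid
formation term (−59.7 kJ·mol⁻¹ per mole of HNO₃) and a simplified
standard-state (Washburn) pressure correction, and dividing by the
sample mass (weighed, or recovered from the collected CO₂) gives the
standard massic energy of combustion Δ_c u°.

Replicates are summarized as mean ± sdom, and the chain continues

    Δ_c U°_m = Δ_c u° · M            (expanded uncertainty: 2 × RSS of
                                      relative components)
    Δ_c H°_m = Δ_c U°_m + Δn(g)·R·T  (Δn from the balanced reaction,
                                      fuel and product water condensed)
    Δ_f H°_m(l) = ν_CO₂·Δ_f H°[CO₂(g)] + ν_H₂O·Δ_f H°[H₂O(l)] − Δ_c H°_m
    Δ_f H°_m(g) = Δ_f H°_m(l) + Δ_vap H°_m

Vaporization enthalpies come from Calvet drop microcalorimetry:
`Δ_vap H°_m(298.15 K) = ΔH_obs(298.15 K → T, g) − ∫ C_p,m°(g) dT`, with
the gas-phase heat capacity as a polynomial in T and in-situ
calibration against a reference liquid.  A gas-phase estimation toolkit
(Boltzmann conformer weighting, isodesmic-reaction solving from
computed absolute enthalpies, transferable substitution increments, and
the monomer/dimer vaporization cycle) rounds out the chain.

## Worked example

```python
from enthalpics.datasets import FURFURYLAMINE
from enthalpics.models import CombustionStudy, VaporizationStudy, gas_phase_formation

combustion = CombustionStudy(
    FURFURYLAMINE.massic_energies,       # six replicate Δc u°, J·g⁻¹
    FURFURYLAMINE.formula,               # "C5H7NO"
    eps_cal=FURFURYLAMINE.eps_cal,       # 15907.1 ± 0.7 J·K⁻¹
    name="furfurylamine",
).fit()
print(combustion.summary())

vaporization = VaporizationStudy(
    cp=FURFURYLAMINE.cp,
    observed=FURFURYLAMINE.calvet_observed,   # 54.5 ± 0.4 kJ·mol⁻¹ at 344.5 K
    T_oven=FURFURYLAMINE.calvet_T_oven,
    name="furfurylamine",
).fit()
print(vaporization.summary())
print("Δf H°m(g) =", gas_phase_formation(combustion, vaporization).format(1))
```

prints

```
Combustion study: furfurylamine (C5H7NO)
  runs: 6   M = 97.117 g·mol⁻¹
  reaction: C5H7NO(l) + 6.25 O2(g) -> 5 CO2(g) + 3.5 H2O(l) + 0.5 N2(g)   Δn(gas) = -0.75
  Δc u°        = -29588.1 ± 2.0 J·g⁻¹ (mean ± sdom)
  −Δc U°m(l)   = 2873.5 ± 0.9 kJ·mol⁻¹
  −Δc H°m(l)   = 2875.4 ± 0.9 kJ·mol⁻¹
  −Δf H°m(l)   = 92.6 ± 1.1 kJ·mol⁻¹
  uncertainty budget (relative): 6.804e-05, 4.401e-05, 1.135e-04, 6.000e-05
Vaporization study: furfurylamine
  runs: 0   T(oven) = 344.5 K   k(cal) = 1.0000
  ΔH_obs(298.15 K → T, g) = 54.5 ± 0.4 kJ·mol⁻¹
  ∫Cp,m°(g) dT            = 5.4 kJ·mol⁻¹
  Δvap H°m(298.15 K)      = 49.1 ± 0.8 kJ·mol⁻¹
Δf H°m(g) = -43.5 ± 1.4
```

Reading: six replicate combustions give a massic energy of
−29 588.1 J·g⁻¹; scaled by the molar mass and the Δn·RT work term this
is a molar combustion enthalpy of −2875.4 kJ·mol⁻¹, which with the
CODATA CO₂/H₂O anchors yields a liquid-phase formation enthalpy of
−92.6 ± 1.1 kJ·mol⁻¹.  Adding the Calvet vaporization enthalpy
(49.1 ± 0.8) gives the gas-phase formation enthalpy
−43.5 ± 1.4 kJ·mol⁻¹.

A command-line interface mirrors the same stages
(`enthalpics calibrate / reduce-bomb / derive / vaporization /
estimate / synth / report`); `enthalpics report --out tables/` writes
the five demo-study tables as CSV.

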