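# Methods

This note documents the models, conventions, numerical choices and
limitations behind `enthalpics`.  It covers what each stage assumes,
which parameters matter (with units and defaults), what the synthetic
generators emulate, and where the design was genuinely open.

## Quantities and uncertainty algebra

Every derived quantity is a `(value, u, unit)` triple with *u* a
standard (1σ) uncertainty.  Propagation is plain independent
root-sum-square (RSS) throughout, which is the convention of
experimental thermochemistry: correlations between components are
neglected because the budgets are constructed from independent sources
(replicate scatter, calibration, reference-material certificates,
auxiliary-material energies, CODATA anchors).  Unit tags are symbolic
and compared verbatim; no automatic conversion is performed — energies
are carried in J internally and reported in kJ·mol⁻¹, with a single
formatting layer doing the one-decimal table-style rounding.  Signs
are physical (negative = exothermic); the positive "−Δ" columns of
conventional tables are produced only at the presentation layer.

Atomic masses are the IUPAC 2013 conventional values for C (12.011),
H (1.008), N (14.007) and O (15.999); their uncertainties are
neglected, as they never appear in combustion uncertainty budgets.
R = 8.314462 J·K⁻¹·mol⁻¹, T_ref = 298.15 K, and the CODATA anchors are
Δ_f H°[CO₂(g)] = −393.51 ± 0.13 and Δ_f H°[H₂O(l)] = −285.830 ± 0.040
kJ·mol⁻¹ (all overridable via `ConstantsTable`).

## Bomb-experiment reduction

**Stoichiometry.**  A C_aH_bN_cO_d fuel burns to CO₂(g), H₂O(l) and
N₂(g) with ν(O₂) = a + b/4 − d/2.  Coefficients are exact `Fraction`s
until final numeric use, so Δn(gas)·R·T carries no rounding.  The fuel
and product water are treated as condensed phases, matching the
standard-state convention.

**Trace reduction.**  Heat exchange with the jacket is modeled as
Newtonian.  Linear least-squares drifts g_i, g_f over the fore and
after rating periods give the cooling constant
k = (g_i − g_f)/(T̄_f − T̄_i) and the convergence temperature
T∞ = T̄_i + g_i/k; the heat-leak contribution over the main period is
the trapezoidal integral of k(T∞ − T(t)) at the 10 s reading interval,
subtracted from the observed rise.  With ~100 readings per period and
k of order 10⁻³ min⁻¹ the linearization and quadrature errors are a
few 10⁻⁶ K on a ~1 K rise — two orders below the 10⁻⁴ K reading
resolution.  Degenerate records (no temperature lever arm between the
rating periods) fall back to a constant-drift correction.  A Dickinson
60 %-rise extrapolation is available via `method="dickinson"` as a
cross-check; both are standard for this instrument class, and the
choice between them was genuinely open.

**Energy bookkeeping.**  ΔU(IPB) = −{ε_cal + Δm(H₂O)·c_p + ε_f}·ΔT_ad
+ ΔU(ign) is the *chemical* energy of the isothermal bomb process: the
electrical ignition energy heats the calorimeter alongside the
combustion, so adding ΔU(ign) nets it out and no further ignition
subtraction appears downstream.  The massic energy is

    Δ_c u° = (ΔU(IPB) − E_fuse − E_Melinex − E_HNO₃ − ΔU_Σ) / m.

Built-in auxiliary materials: Melinex (Δ_c u° = −22 902 ± 5 J·g⁻¹,
water mass fraction w = 0.0032 stripped before the energy and CO₂
accounting, (∂u/∂p)_T = −0.03 J·g⁻¹·MPa⁻¹, empirical formula C₁₀H₈O₄)
and cotton fuse (−16 240 J·g⁻¹, (∂u/∂p)_T = −0.29, CH₁.₆₈₆O₀.₈₄₃).
The nitric-acid term uses −59.7 kJ·mol⁻¹ for formation of
0.1 mol·dm⁻³ HNO₃(aq); the amount is accepted as moles directly or as
titre volume × molarity.  Each correction is individually switchable;
with all off the reduction degenerates to ΔU(IPB)/m.

**Standard-state (Washburn) correction.**  Only the leading pressure
term is implemented: ΔU_Σ = Σ m_i·(∂u/∂p)_T,i·(p − 0.1 MPa) over
sample (default coefficient −0.2 J·g⁻¹·MPa⁻¹, the typical organic
value), Melinex and fuse, at the default bomb pressure p = 3.04 MPa.
This is deliberate: replicate tables of this class are published
already standard-state-corrected, the full iterative procedure needs
per-run bomb compositions that are not part of the package's inputs,
and the retained term is the dominant one (sub-J on a ~15 kJ run).  A
`standard_state_hook` accepts a user-supplied full correction.
Buoyancy is a configurable multiplicative factor on the sample mass,
default 1.

**Sample mass from CO₂.**  When no weighed mass is present the sample
mass is recovered from the collected CO₂ after subtracting the fuse
and Melinex contributions (computed from their empirical formulas);
the CO₂ recovery ratio is attached to every result and a deviation
beyond ±1 % raises a warning rather than an error.

**Calibration.**  Benzoic-acid runs (certificate value
−26 434 ± 3 J·g⁻¹) are reduced to per-run energy equivalents,
normalized to the reference calorimeter-water mass (3119.6 g) by
subtracting the Δm·c_p and ε_f terms, and summarized as mean ± sdom;
a single run is refused because no uncertainty can be stated.

## Replicates and the expanded uncertainty

Replicate massic energies are summarized as mean ± sdom
(sample standard deviation / √n, n ≥ 2).  The expanded uncertainty of
the molar combustion energy follows the Rossini/Olofsson convention:
twice the RSS of *relative* components.  The default budget has four
components: replicate sdom, calibration (u(ε_cal)/ε_cal),
reference-material certificate (3/26 434 = 1.135 × 10⁻⁴), and one
combined auxiliary-material component covering the Melinex, fuse and
nitric-acid energies.  The auxiliary component is plain config with
default 6.0 × 10⁻⁵: per-run auxiliary masses are not part of the
package inputs, so the component cannot be built bottom-up; the
default is the value consistent with the published uncertainty
convention for run series of this class, and any list of components
can be substituted.  Every downstream step (Hess combination, gas
phase) reports an uncertainty no smaller than the RSS of its inputs.

## Calvet vaporization

The observed molar enthalpy of a drop experiment at oven temperature T
covers heating from 298.15 K plus vaporization; subtracting the
analytic integral of the gas-phase C_p polynomial reduces it to
298.15 K.  C_p,m°(g) is supplied as ascending polynomial coefficients
with a global frequency-scaling factor (default 0.965) and a validity
range; integrals outside the range are refused.  In-situ calibration
is a dimensionless factor k = literature/mean(observed) over reference
runs at the same oven temperature, applied multiplicatively; k outside
[0.95, 1.05] warns.  The final uncertainty is twice the RSS of the
run sdom and the calibration contribution; the C_p integral is treated
as exact.  Sample masses outside a 1–20 mg plausibility window are
rejected (3–7 mg is the typical protocol).  The blank-capillary
correction is accepted as a per-run additive input; capillary mass
matching is metadata, not computed.

The two bundled C_p polynomials are **synthetic stand-ins** (see
`synthetic.py`): linear forms back-solved so their scaled integrals
from 298.15 K to the respective oven temperatures (344.5 K, 339.9 K)
equal the documented correction terms 5.4 and 6.0 kJ·mol⁻¹, with
slopes typical for molecules of this size.  The printed correction
column is the reproducible surface; the DFT-derived coefficients
themselves are not distributed.

## Gas-phase estimation

Boltzmann populations use p_i ∝ exp(−ΔG_i/RT) with ΔG in kJ·mol⁻¹ (the
minimum is subtracted before exponentiation for numerical stability);
conformer-averaged absolute enthalpies are the population-weighted
sums.  Reaction enthalpies from absolute enthalpies use the fixed
conversion 1 hartree = 2625.4997 kJ·mol⁻¹ — the only place
quantum-chemistry units enter.  Element balance is *mandatory* and
checked before any arithmetic; bond-type (isodesmic) balance is the
user's responsibility, since enforcing it would require a bond
perception the package does not attempt.  Solving the unknown of a
reaction propagates the known participants' uncertainties weighted by
|ν_i/ν_u| (the computed Δ_r H is treated as exact); multi-reaction
estimates are summarized as mean ± sdom.  Substitution increments
(e.g. ring O → S: 147.3 ± 4.5 kJ·mol⁻¹ for 2-substituted furans,
159.4 ± 5.0 for the 5-methyl analogues) are added with RSS
uncertainties.  The monomer/dimer cycle uses
Δ_vap H(mon) = Δ_f H°(g) − Δ_f H°(l) and
Δ_vap H(dim) = 2Δ_f H°(g) − 2Δ_f H°(l) + Δ_dim H°, with the
dimerization enthalpy defined for 2 monomers → dimer (negative =
exothermic, default −24 kJ·mol⁻¹ in the bundled study).

## Synthetic data

The generators define the study conditions the tests run under.

*Bomb runs* (defaults): 6 runs of 0.45–0.65 g samples, 2–4 mg fuses,
40–60 mg Melinex bags, ε_cal = 15 907.1 J·K⁻¹, ε_f = 16 J·K⁻¹,
3.04 MPa, capacitor ignition (1400 µF, 40 V → ~20 V), cooling constant
1.5 × 10⁻³ min⁻¹, convergence temperature 298.35 K, ignition at
298.150 K, 100 readings per period at 10 s, temperature noise
1 × 10⁻⁴ K (the reading resolution), and a per-run massic-energy
scatter of 5 J·g⁻¹ chosen to reproduce the few-J·g⁻¹ sdom of published
six-run series.  The trace is the closed-form solution of
dT/dt = k(T_conv − T) + ΔT_ad·λ·e^(−λt) with λ = 1/60 s⁻¹; this is a
model sufficient to validate the Regnault–Pfaundler extraction, not a
claim about flame kinetics or bomb pressure dynamics.  The CO₂ mass is
exact by construction, so perfect accounting yields a recovery ratio
of exactly 1.

*Calvet runs* (defaults): 6 drops of 3–7 mg, observed enthalpy = true
Δ_vap H + ∫C_p dT + N(0, 0.98 kJ·mol⁻¹), with an optional
multiplicative sensitivity bias that in-situ calibration must remove.

All randomness flows from one `numpy` generator seeded per call; the
seed is a mandatory field.  In the noise-free limit every generator is
the exact inverse of its reducer (bomb runs round-trip to ~4 × 10⁻⁶
relative, bounded by the trace quadrature; Calvet runs to machine
precision).  What passing these tests shows is that the *bookkeeping*
is self-consistent at realistic magnitudes; it does not validate the
Newtonian-exchange model against a real instrument, incomplete
combustion, or real vapor non-ideality.

## Problem sizes and test budgets

The round-trip tests use the 6-run defaults; the coverage check of the
Calvet chain uses 10 000 repeated 6-run series (success = reduced value
within twice the nominal sdom of the truth, expected coverage 95.45 %
for a correctly propagated mean), a repeat count chosen so the binomial
sampling error of the observed rate is well below the margin over the
95 % threshold.  The whole suite runs in well under a minute on one
CPU.

## Known limitations

* The Washburn correction is the single pressure term, not the full
  iterative bomb-composition procedure (hook provided).
* ε_f is a per-experiment input, not modeled thermodynamically.
* Only C/H/N/O fuels are balanced; sulfur chemistry appears solely as
  a transferable increment label, never in stoichiometry.
* The demo chain's chained summary table combines rounded predecessor
  entries, matching how such tables are conventionally presented; the
  results objects carry full precision and the two can differ by one
  unit in the last digit.
* Expanded-uncertainty budgets are explicit config; the default
  auxiliary component is a documented stand-in for per-run auxiliary
  records the package does not ship.
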