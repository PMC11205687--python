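"""Gas-phase estimation toolkit.

Four pieces of estimation machinery for gas-phase standard molar
formation enthalpies:

* **Boltzmann conformer weighting** — populations proportional to
  exp(−ΔG/RT) at 298.15 K, used to average computed absolute enthalpies
  over the conformers present in a gas-phase sample.
* **Isodesmic-reaction solving** — given a balanced reaction with
  exactly one species of unknown Δf H°m(g), the reaction enthalpy
  computed from absolute enthalpies (hartree, converted at
  2625.4997 kJ·mol⁻¹) combined with the experimental formation
  enthalpies of the remaining participants yields the unknown.
  Element balance is mandatory; bond-type (isodesmic) balance is the
  user's responsibility and only advisable.
* **Substitution increments** — transferable enthalpy increments
  (e.g. ring O → S substitution, methylation) added to a known
  formation enthalpy, uncertainties by RSS.
* **Monomer/dimer vaporization cycle** — if the vapor were fully
  dimerized, the apparent vaporization enthalpy would be
  2·[Δf H°(g) − Δf H°(l)] + Δdim H°; comparing the monomer and dimer
  routes against the measured value discriminates the vapor-phase
  species.
"""

from __future__ import annotations

import math
import re
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .constants import ConstantsTable, CONSTANTS, KJ_PER_MOL
from .formula import ChemicalFormula, parse_formula
from .quantities import Quantity, rss_combine

__all__ = [
    "Conformer",
    "SpeciesRecord",
    "Reaction",
    "Increment",
    "ReactionError",
    "boltzmann_populations",
    "conformer_weighted_enthalpy",
    "reaction_enthalpy",
    "solve_unknown_formation",
    "increment_estimate",
    "dimer_cycle",
    "parse_reaction",
]


class ReactionError(ValueError):
    """Reaction is unbalanced or has the wrong number of unknowns."""


@dataclass(frozen=True)
class Conformer:
    """One conformer: relative free energy (selects the population) and,
    optionally, its absolute enthalpy."""

    label: str
    dG_rel: float  # kJ·mol⁻¹, min over conformers should be 0
    dH_rel: float = 0.0  # kJ·mol⁻¹
    H_absolute: Optional[float] = None  # hartree


@dataclass(frozen=True)
class SpeciesRecord:
    """A chemical species participating in estimation reactions.

    To take part in a reaction a species needs either an experimental
    gas-phase formation enthalpy or a computed absolute enthalpy
    (single value, or conformer-resolved for Boltzmann averaging).
    """

    name: str
    formula: ChemicalFormula
    dfH_gas: Optional[Quantity] = None  # kJ·mol⁻¹
    H_absolute: Optional[float] = None  # hartree
    conformers: Tuple[Conformer, ...] = ()

    def absolute_enthalpy(
        self, T: float = CONSTANTS.T_ref, R: float = CONSTANTS.R
    ) -> float:
        """Conformer-weighted absolute enthalpy in hartree."""
        if self.conformers and all(
            c.H_absolute is not None for c in self.conformers
        ):
            return conformer_weighted_enthalpy(self.conformers, T, R)
        if self.H_absolute is None:
            raise ValueError(f"species {self.name!r} has no absolute enthalpy")
        return self.H_absolute


def boltzmann_populations(
    dG_rel: Sequence[float],
    T: float = CONSTANTS.T_ref,
    R: float = CONSTANTS.R,
) -> np.ndarray:
    """Boltzmann populations from relative free energies.

    ``p_i = exp(−ΔG_i/RT) / Σ_j exp(−ΔG_j/RT)`` with ΔG in kJ·mol⁻¹.
    Always sums to 1; shifting all ΔG by a constant leaves the result
    unchanged (the minimum is subtracted for numerical stability).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    g = np.asarray(dG_rel, dtype=float)
    if g.size == 0:
        raise ValueError("need at least one conformer")
    w = np.exp(-(g - g.min()) * 1000.0 / (R * T))
    return w / w.sum()


def conformer_weighted_enthalpy(
    conformers: Sequence[Conformer],
    T: float = CONSTANTS.T_ref,
    R: float = CONSTANTS.R,
) -> float:
    """Population-weighted absolute enthalpy, hartree."""
    if not conformers:
        raise ValueError("need at least one conformer")
    for c in conformers:
        if c.H_absolute is None:
            raise ValueError(f"conformer {c.label!r} lacks an absolute enthalpy")
    p = boltzmann_populations([c.dG_rel for c in conformers], T, R)
    return float(np.dot(p, [c.H_absolute for c in conformers]))


# --------------------------------------------------------------------------
# reactions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """A balanced estimation reaction with exactly one unknown species.

    ``reactants`` and ``products`` are (coefficient, species-name)
    pairs; ``unknown`` names the species whose Δf H°m(g) is sought.
    """

    reactants: Tuple[Tuple[float, str], ...]
    products: Tuple[Tuple[float, str], ...]
    unknown: str

    def participants(self):
        for coef, name in self.reactants:
            yield -coef, name
        for coef, name in self.products:
            yield coef, name

    def signed_coefficient(self, name: str) -> float:
        total = 0.0
        for coef, n in self.participants():
            if n == name:
                total += coef
        return total


_TERM = re.compile(r"^\s*(\d+(?:\.\d+)?|\d*/\d+)?\s*(\??)([^\s?]+)\s*$")


def parse_reaction(text: str) -> Reaction:
    """Parse ``"A + 2 B -> C + D + ?X"`` into a :class:`Reaction`.

    ``?X`` marks the unknown species (either side); coefficients default
    to 1 and may be integers, decimals, or simple fractions like 1/2.
    """
    if "->" not in text:
        raise ReactionError(f"no '->' in reaction {text!r}")
    lhs, rhs = text.split("->", 1)

    def parse_side(side: str):
        terms = []
        unknowns = []
        for raw in side.split("+"):
            m = _TERM.match(raw)
            if not m:
                raise ReactionError(f"unparseable term {raw.strip()!r}")
            coef_s, qmark, name = m.groups()
            if coef_s:
                coef = (
                    float(coef_s.split("/")[0]) / float(coef_s.split("/")[1])
                    if "/" in coef_s
                    else float(coef_s)
                )
            else:
                coef = 1.0
            terms.append((coef, name))
            if qmark:
                unknowns.append(name)
        return terms, unknowns

    r_terms, r_unknown = parse_side(lhs)
    p_terms, p_unknown = parse_side(rhs)
    unknowns = r_unknown + p_unknown
    if len(unknowns) != 1:
        raise ReactionError(
            f"reaction must mark exactly one unknown, found {len(unknowns)}"
        )
    return Reaction(tuple(r_terms), tuple(p_terms), unknowns[0])


def check_element_balance(
    rxn: Reaction,
    registry: Mapping[str, SpeciesRecord],
    tol: float = 1e-9,
) -> None:
    """Raise :class:`ReactionError` unless every element balances."""
    balance: Dict[str, float] = {}
    for coef, name in rxn.participants():
        if name not in registry:
            raise KeyError(f"species {name!r} not in registry")
        for el, n in registry[name].formula:
            balance[el] = balance.get(el, 0.0) + coef * n
    bad = {el: v for el, v in balance.items() if abs(v) > tol}
    if bad:
        raise ReactionError(f"reaction is not element-balanced: {bad}")


def reaction_enthalpy(
    rxn: Reaction,
    registry: Mapping[str, SpeciesRecord],
    constants: ConstantsTable = CONSTANTS,
) -> float:
    """Δr H°m(g) in kJ·mol⁻¹ from absolute (computed) enthalpies.

    ``Δr H = (Σν·H°_products − Σν·H°_reactants) · hartree→kJ·mol⁻¹``;
    the reaction must be element-balanced before any arithmetic.
    """
    check_element_balance(rxn, registry)
    total_hartree = 0.0
    for coef, name in rxn.participants():
        total_hartree += coef * registry[name].absolute_enthalpy(
            constants.T_ref, constants.R
        )
    return total_hartree * constants.hartree_to_kJ_per_mol


def solve_unknown_formation(
    rxn: Reaction,
    drH: float,
    registry: Mapping[str, SpeciesRecord],
) -> Quantity:
    """Solve Δf H°m(g) of the unknown from Δr H and the known participants.

    From ``Δr H = Σ ν_i·Δf H_i`` (signed stoichiometry, products
    positive), the unknown with signed coefficient ν_u satisfies

        Δf H(unknown) = (Δr H − Σ_{i≠u} ν_i·Δf H_i) / ν_u

    The uncertainty is the RSS of the known participants' uncertainties
    weighted by |ν_i/ν_u| (Δr H is treated as exact).
    """
    check_element_balance(rxn, registry)
    nu_u = rxn.signed_coefficient(rxn.unknown)
    if nu_u == 0:
        raise ReactionError("unknown species has zero net coefficient")
    known_sum = 0.0
    u_components: List[float] = []
    for coef, name in rxn.participants():
        if name == rxn.unknown:
            continue
        rec = registry[name]
        if rec.dfH_gas is None:
            raise ReactionError(
                f"species {name!r} lacks an experimental formation enthalpy"
            )
        known_sum += coef * rec.dfH_gas.value
        u_components.append(abs(coef / nu_u) * rec.dfH_gas.u)
    value = (drH - known_sum) / nu_u
    return Quantity(value, rss_combine(u_components), KJ_PER_MOL)


# --------------------------------------------------------------------------
# increments and the dimer cycle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Increment:
    """A transferable enthalpy increment (substitution or group change)."""

    name: str
    value: Quantity  # kJ·mol⁻¹


def increment_estimate(base: Quantity, inc: Increment) -> Quantity:
    """Apply an increment to a known formation enthalpy (RSS uncertainty)."""
    return base + inc.value


def dimer_cycle(
    dfH_gas_monomer: Quantity,
    dfH_liquid: Quantity,
    ddimH: Quantity,
) -> Tuple[Quantity, Quantity]:
    """Vaporization enthalpies of the monomer and hypothetical dimer.

    ``Δvap H(mon) = Δf H°(g) − Δf H°(l)`` and
    ``Δvap H(dim) = 2·Δf H°(g) − 2·Δf H°(l) + Δdim H°`` where Δdim H° is
    the dimerization enthalpy (2 monomers → dimer; negative =
    exothermic).  The identity ``dim − 2·mon = Δdim H°`` holds exactly.
    """
    monomer = dfH_gas_monomer - dfH_liquid
    dimer = (dfH_gas_monomer - dfH_liquid) * 2.0 + ddimH
    return monomer, dimer


def mean_of_estimates(estimates: Sequence[Quantity]) -> Quantity:
    """Mean ± sdom across reaction-based estimates (>= 2 required)."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates")
    vals = np.asarray([q.value for q in estimates])
    sdom = float(vals.std(ddof=1) / math.sqrt(len(vals)))
    unit = estimates[0].unit
    return Quantity(float(vals.mean()), sdom, unit)
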