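import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from enthalpics.constants import CONSTANTS, HARTREE_TO_KJ_PER_MOL
from enthalpics.formula import ChemicalFormula, parse_formula
from enthalpics.gasphase import (
    Conformer,
    Increment,
    Reaction,
    ReactionError,
    SpeciesRecord,
    boltzmann_populations,
    conformer_weighted_enthalpy,
    dimer_cycle,
    increment_estimate,
    mean_of_estimates,
    parse_reaction,
    reaction_enthalpy,
    solve_unknown_formation,
)
from enthalpics.quantities import Quantity

KJ = "kJ·mol⁻¹"


class TestBoltzmann:
    def test_degenerate_pair(self):
        p = boltzmann_populations([0.0, 0.0])
        assert p == pytest.approx([0.5, 0.5])

    def test_gauche_syn_split(self):
        """A free-energy gap of RT·ln(75.7/24.3) reproduces the
        75.7 % / 24.3 % two-conformer split."""
        dG = CONSTANTS.R * CONSTANTS.T_ref * math.log(75.7 / 24.3) / 1000.0
        assert dG == pytest.approx(2.82, abs=5e-3)
        p = boltzmann_populations([0.0, dG])
        assert p == pytest.approx([0.757, 0.243], abs=1e-9)

    def test_infinite_gap_limit(self):
        p = boltzmann_populations([0.0, 1e6])
        assert p == pytest.approx([1.0, 0.0])

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=8),
        st.floats(10, 2000),
    )
    def test_sums_to_one(self, dG, T):
        p = boltzmann_populations(dG, T=T)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()

    @given(st.lists(st.floats(0, 50, allow_nan=False), min_size=2, max_size=6),
           st.floats(-20, 20, allow_nan=False))
    def test_shift_invariance(self, dG, shift):
        assert boltzmann_populations(dG) == pytest.approx(
            boltzmann_populations([g + shift for g in dG])
        )


class TestConformerWeighting:
    def test_single_conformer(self):
        c = Conformer("only", 0.0, H_absolute=-400.123)
        assert conformer_weighted_enthalpy([c]) == -400.123

    def test_equal_populations_average(self):
        cs = [
            Conformer("a", 0.0, H_absolute=-400.0),
            Conformer("b", 0.0, H_absolute=-400.01),
        ]
        assert conformer_weighted_enthalpy(cs) == pytest.approx(-400.005)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 20, allow_nan=False),
                st.floats(-500, -100, allow_nan=False),
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_matches_direct_summation(self, data):
        cs = [
            Conformer(f"c{i}", g, H_absolute=h) for i, (g, h) in enumerate(data)
        ]
        p = boltzmann_populations([c.dG_rel for c in cs])
        oracle = float(np.dot(p, [c.H_absolute for c in cs]))
        assert conformer_weighted_enthalpy(cs) == pytest.approx(oracle)


def _species(name, formula, dfH=None, H=None):
    return SpeciesRecord(
        name=name,
        formula=parse_formula(formula),
        dfH_gas=Quantity(dfH[0], dfH[1], KJ) if dfH else None,
        H_absolute=H,
    )


class TestReactionEnthalpy:
    def test_identity_reaction_is_zero(self):
        reg = {"A": _species("A", "C5H7NO", H=-400.0)}
        rxn = Reaction(((1.0, "A"),), ((1.0, "A"),), unknown="A")
        assert reaction_enthalpy(rxn, reg) == pytest.approx(0.0)

    def test_hartree_conversion(self):
        reg = {
            "A": _species("A", "C5H7NO", H=-400.00),
            "B": _species("B", "C5H7NO", H=-399.99),
        }
        rxn = Reaction(((1.0, "A"),), ((1.0, "B"),), unknown="B")
        assert reaction_enthalpy(rxn, reg) == pytest.approx(
            0.01 * HARTREE_TO_KJ_PER_MOL
        )

    def test_reversal_negates(self):
        reg = {
            "A": _species("A", "C5H7NO", H=-400.00),
            "B": _species("B", "C5H7NO", H=-399.99),
        }
        fwd = Reaction(((1.0, "A"),), ((1.0, "B"),), unknown="B")
        rev = Reaction(((1.0, "B"),), ((1.0, "A"),), unknown="A")
        assert reaction_enthalpy(fwd, reg) == pytest.approx(
            -reaction_enthalpy(rev, reg)
        )

    def test_unbalanced_rejected_before_arithmetic(self):
        reg = {
            "A": _species("A", "C5H7NO", H=-400.0),
            "B": _species("B", "C6H9NO", H=-439.0),
        }
        rxn = Reaction(((1.0, "A"),), ((1.0, "B"),), unknown="B")
        with pytest.raises(ReactionError, match="balanced"):
            reaction_enthalpy(rxn, reg)


formula_counts = st.fixed_dictionaries(
    {"C": st.integers(1, 8), "H": st.integers(1, 16)},
    optional={"N": st.integers(0, 2), "O": st.integers(0, 3)},
)


class TestSolveUnknown:
    def test_isomerization_with_zero_enthalpy(self):
        reg = {
            "A": _species("A", "C5H7NO", dfH=(-50.0, 0.0)),
            "B": _species("B", "C5H7NO"),
        }
        rxn = Reaction(((1.0, "A"),), ((1.0, "B"),), unknown="B")
        q = solve_unknown_formation(rxn, 0.0, reg)
        assert q.value == pytest.approx(-50.0)

    def test_unknown_on_reactant_side(self):
        reg = {
            "A": _species("A", "C5H7NO"),
            "B": _species("B", "C5H7NO", dfH=(-50.0, 0.5)),
        }
        rxn = Reaction(((1.0, "A"),), ((1.0, "B"),), unknown="A")
        q = solve_unknown_formation(rxn, 10.0, reg)
        # drH = dfH(B) − dfH(A)  ->  dfH(A) = dfH(B) − drH
        assert q.value == pytest.approx(-60.0)
        assert q.u == pytest.approx(0.5)

    @given(
        formula_counts,
        formula_counts,
        st.floats(-300, 300, allow_nan=False),
        st.floats(-300, 300, allow_nan=False),
        st.floats(-100, 100, allow_nan=False),
    )
    def test_solve_then_recompute_round_trips(self, c1, c2, h1, h2, h3):
        """Solving the unknown and recomputing Σν·ΔfH reproduces Δr H
        exactly, for reactions balanced by construction (A + B -> AB)."""
        fA = ChemicalFormula.from_counts(c1)
        fB = ChemicalFormula.from_counts(c2)
        fAB = fA + fB
        reg = {
            "A": _species("A", fA.hill(), dfH=(h1, 1.0)),
            "B": _species("B", fB.hill(), dfH=(h2, 2.0)),
            "AB": SpeciesRecord("AB", fAB),
        }
        rxn = Reaction(((1.0, "A"), (1.0, "B")), ((1.0, "AB"),), unknown="AB")
        solved = solve_unknown_formation(rxn, h3, reg)
        recomputed = solved.value - h1 - h2
        assert recomputed == pytest.approx(h3, abs=1e-9)
        assert solved.u == pytest.approx(math.hypot(1.0, 2.0))

    def test_mutated_reaction_loses_balance(self):
        reg = {
            "A": _species("A", "C2H4", dfH=(10.0, 0.0)),
            "B": _species("B", "C3H6", dfH=(5.0, 0.0)),
            "AB": _species("AB", "C5H10"),
            "bad": _species("bad", "C5H12"),
        }
        ok = Reaction(((1.0, "A"), (1.0, "B")), ((1.0, "AB"),), unknown="AB")
        solve_unknown_formation(ok, 1.0, reg)  # balanced: no error
        mutated = Reaction(((1.0, "A"), (1.0, "B")), ((1.0, "bad"),), unknown="bad")
        with pytest.raises(ReactionError):
            solve_unknown_formation(mutated, 1.0, reg)


class TestReactionParsing:
    def test_marked_unknown_and_coefficients(self):
        rxn = parse_reaction("furan + 2 ethane -> ?target + 0.5 water")
        assert rxn.reactants == ((1.0, "furan"), (2.0, "ethane"))
        assert rxn.products == ((1.0, "target"), (0.5, "water"))
        assert rxn.unknown == "target"

    def test_exactly_one_unknown_required(self):
        with pytest.raises(ReactionError):
            parse_reaction("?A -> ?B")
        with pytest.raises(ReactionError):
            parse_reaction("A -> B")


class TestIncrements:
    def test_oxygen_to_sulfur_substitution(self):
        base = Quantity(-38.9, 0.6, KJ)
        inc = Increment("O->S", Quantity(147.3, 4.5, KJ))
        est = increment_estimate(base, inc)
        assert round(est.value, 1) == 108.4
        assert round(est.u, 1) == 4.5

    def test_methylated_analogue(self):
        est = increment_estimate(
            Quantity(-81.9, 0.9, KJ), Increment("O->S", Quantity(159.4, 5.0, KJ))
        )
        assert round(est.value, 1) == 77.5
        assert round(est.u, 1) == 5.1

    def test_zero_increment_identity(self):
        base = Quantity(-38.9, 0.6, KJ)
        est = increment_estimate(base, Increment("none", Quantity(0.0, 0.0, KJ)))
        assert (est.value, est.u) == (base.value, base.u)


class TestDimerCycle:
    @pytest.mark.parametrize(
        "liquid, mono, dim",
        [(-92.6, 53.7, 83.4), (-105.4, 66.5, 109.0)],
    )
    def test_known_cycles(self, liquid, mono, dim):
        m, d = dimer_cycle(
            Quantity(-38.9, 0.0, KJ),
            Quantity(liquid, 0.0, KJ),
            Quantity(-24.0, 0.0, KJ),
        )
        assert round(m.value, 1) == mono
        assert round(d.value, 1) == dim

    def test_zero_dimerization_doubles(self):
        m, d = dimer_cycle(
            Quantity(-40.0, 0.0, KJ), Quantity(-90.0, 0.0, KJ),
            Quantity(0.0, 0.0, KJ),
        )
        assert d.value == pytest.approx(2 * m.value)

    @given(
        st.floats(-200, 200, allow_nan=False),
        st.floats(-200, 200, allow_nan=False),
        st.floats(-50, 0, allow_nan=False),
    )
    def test_cycle_identity(self, g, l, ddim):
        m, d = dimer_cycle(
            Quantity(g, 0.0, KJ), Quantity(l, 0.0, KJ), Quantity(ddim, 0.0, KJ)
        )
        assert d.value - 2 * m.value == pytest.approx(ddim, abs=1e-9)


def test_mean_of_estimates_uses_sdom():
    qs = [Quantity(v, 0.0, KJ) for v in (-38.0, -39.0, -39.7)]
    m = mean_of_estimates(qs)
    vals = np.array([-38.0, -39.0, -39.7])
    assert m.value == pytest.approx(vals.mean())
    assert m.u == pytest.approx(vals.std(ddof=1) / math.sqrt(3))
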