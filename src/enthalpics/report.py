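"""Report tables for the bundled demo study.

``demo_report()`` runs the whole chain on the bundled printed inputs
(:mod:`enthalpics.datasets`) and returns the five tables of the study
as pandas DataFrames:

1. replicate massic combustion energies with mean ± sdom,
2. standard molar combustion energies/enthalpies and liquid-phase
   formation enthalpies,
3. Calvet vaporization enthalpies with the heat-capacity correction,
4. formation enthalpies in both phases (experimental and computed),
5. monomer/dimer vaporization enthalpies from the thermochemical cycle.

Presentation conventions: −Δ columns are printed as positive
magnitudes and everything is rounded to one decimal, with full
precision retained in companion ``*_unrounded`` columns.  Table 4
combines the rounded table entries (the way chained summary tables
are built); the unrounded chain is available from the results objects.
"""

from __future__ import annotations

from typing import Dict

import pandas as pd

from . import datasets as ds
from .formation import formation_gas
from .gasphase import dimer_cycle, increment_estimate
from .models import CombustionStudy, VaporizationStudy
from .quantities import Quantity

__all__ = ["demo_report", "demo_results"]


def _r1(x: float) -> float:
    return round(x, 1)


def demo_results():
    """Fitted results objects for both compounds of the bundled study."""
    out = {}
    for name, c in ds.COMPOUNDS.items():
        combustion = CombustionStudy(
            c.massic_energies, c.formula, eps_cal=c.eps_cal, name=name
        ).fit()
        vaporization = VaporizationStudy(
            cp=c.cp,
            observed=c.calvet_observed,
            T_oven=c.calvet_T_oven,
            name=name,
        ).fit()
        out[name] = (combustion, vaporization)
    return out


def demo_report() -> Dict[str, pd.DataFrame]:
    results = demo_results()

    t1_rows, t2_rows, t3_rows, t4_rows = [], [], [], []
    for name, (comb, vap) in results.items():
        t1_rows.append(
            {
                "compound": name,
                "n_runs": comb.replicates.n,
                "mean_massic_energy_J_per_g": _r1(comb.replicates.mean),
                "sdom_J_per_g": _r1(comb.replicates.sdom),
            }
        )
        t2_rows.append(
            {
                "compound": name,
                "minus_dcU_kJ_per_mol": _r1(-comb.dcU.value),
                "u_dcU": _r1(comb.dcU.u),
                "minus_dcH_kJ_per_mol": _r1(-comb.dcH.value),
                "u_dcH": _r1(comb.dcH.u),
                "minus_dfH_liquid_kJ_per_mol": _r1(-comb.dfH_liquid.value),
                "u_dfH_liquid": _r1(comb.dfH_liquid.u),
                "minus_dcU_unrounded": -comb.dcU.value,
                "minus_dcH_unrounded": -comb.dcH.value,
                "minus_dfH_liquid_unrounded": -comb.dfH_liquid.value,
            }
        )
        t3_rows.append(
            {
                "compound": name,
                "T_oven_K": vap.T_oven,
                "dH_observed_kJ_per_mol": _r1(vap.at_oven.value),
                "u_observed": _r1(vap.at_oven.u),
                "cp_integral_kJ_per_mol": _r1(vap.heating_correction),
                "dvapH_298_kJ_per_mol": _r1(vap.dvapH.value),
                "u_dvapH": _r1(vap.dvapH.u),
                "dvapH_298_unrounded": vap.dvapH.value,
            }
        )
        # chained summary table: combine the rounded entries of the
        # preceding tables, as the presentation layer does
        liquid = Quantity(
            _r1(comb.dfH_liquid.value), _r1(comb.dfH_liquid.u), comb.dfH_liquid.unit
        )
        dvap = Quantity(_r1(vap.dvapH.value), _r1(vap.dvapH.u), vap.dvapH.unit)
        gas = formation_gas(liquid, dvap)
        computed = ds.COMPOUNDS[name].dfH_gas_computed
        t4_rows.append(
            {
                "compound": name,
                "dfH_liquid_kJ_per_mol": liquid.value,
                "u_liquid": liquid.u,
                "dvapH_kJ_per_mol": dvap.value,
                "u_vap": dvap.u,
                "dfH_gas_exp_kJ_per_mol": _r1(gas.value),
                "u_gas_exp": _r1(gas.u),
                "dfH_gas_computed_kJ_per_mol": computed.value,
                "u_gas_computed": computed.u,
            }
        )

    # monomer/dimer cycle for furfurylamine, this work vs literature
    comb_f, _ = results[ds.FURFURYLAMINE.name]
    gas_computed = ds.FURFURYLAMINE.dfH_gas_computed
    t5_rows = []
    for source, liquid in (
        ("this work", comb_f.dfH_liquid),
        ("literature", ds.LITERATURE_DFH_LIQUID_FURFURYLAMINE),
    ):
        mono, dim = dimer_cycle(gas_computed, liquid, ds.DIMERIZATION_ENTHALPY)
        t5_rows.append(
            {
                "source": source,
                "monomer_dvapH_kJ_per_mol": _r1(mono.value),
                "dimer_dvapH_kJ_per_mol": _r1(dim.value),
                "monomer_unrounded": mono.value,
                "dimer_unrounded": dim.value,
            }
        )

    # O -> S substitution estimates for the thiophene analogues
    inc_rows = []
    for base, inc, target in (
        (ds.FURFURYLAMINE.dfH_gas_computed, ds.O_TO_S_FURAN,
         "2-thiophenemethylamine"),
        (ds.METHYLFURFURYLAMINE.dfH_gas_computed, ds.O_TO_S_METHYLFURAN,
         "5-methyl-2-thiophenemethylamine"),
    ):
        est = increment_estimate(base, inc)
        inc_rows.append(
            {
                "target": target,
                "base_kJ_per_mol": base.value,
                "increment_kJ_per_mol": inc.value.value,
                "estimate_kJ_per_mol": _r1(est.value),
                "u_estimate": _r1(est.u),
            }
        )

    return {
        "table1_replicates": pd.DataFrame(t1_rows),
        "table2_combustion": pd.DataFrame(t2_rows),
        "table3_vaporization": pd.DataFrame(t3_rows),
        "table4_formation": pd.DataFrame(t4_rows),
        "table5_dimer_cycle": pd.DataFrame(t5_rows),
        "increment_estimates": pd.DataFrame(inc_rows),
    }
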