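"""CSV/JSON readers and writers for the reduction chain.

Column schemas (all CSV, headers required):

* bomb experiments — ``m_sample, m_fuse, m_melinex, delta_m_h2o,
  dT_ad, du_ign, n_hno3, m_co2, eps_f`` (any column may be omitted or
  left blank; blanks become "absent").
* temperature traces — two columns ``t`` (s) and ``T`` (K); the fore
  and main period boundaries are passed separately.
* Calvet runs — ``m_sample`` (mg), ``T_oven`` (K), ``dH_observed``
  (kJ·mol⁻¹), optional ``blank_correction`` (J).
* Cp polynomials (JSON) — ``{"coefficients": [...], "scale_factor":
  0.965, "t_min": ..., "t_max": ...}`` with ascending powers of T.
* species registries (JSON) — a list of objects with ``name``,
  ``formula``, optional ``dfH_gas`` as ``[value, u]`` (kJ·mol⁻¹),
  optional ``H_absolute`` (hartree) and optional ``conformers`` as a
  list of ``{"label", "dG_rel", "dH_rel", "H_absolute"}``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd

from .bomb import BombExperiment, CalibrationResult, TemperatureTrace
from .calvet import CalvetRun, CpPolynomial
from .gasphase import Conformer, SpeciesRecord
from .formula import parse_formula
from .quantities import Quantity

__all__ = [
    "load_bomb_experiments",
    "load_trace",
    "load_calvet_runs",
    "load_cp_polynomial",
    "load_species_registry",
    "load_calibration",
    "save_calibration",
]

PathLike = Union[str, Path]

_BOMB_FLOAT_COLUMNS = (
    "m_sample", "m_fuse", "m_melinex", "delta_m_h2o", "dT_ad",
    "du_ign", "n_hno3", "m_co2", "eps_f",
)


def _opt(row, col) -> Optional[float]:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def load_bomb_experiments(path: PathLike) -> List[BombExperiment]:
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(_BOMB_FLOAT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            BombExperiment(
                m_sample=_opt(row, "m_sample"),
                m_fuse=_opt(row, "m_fuse") or 0.0,
                m_melinex=_opt(row, "m_melinex") or 0.0,
                delta_m_h2o=_opt(row, "delta_m_h2o") or 0.0,
                dT_ad=_opt(row, "dT_ad"),
                du_ign=_opt(row, "du_ign"),
                n_hno3=_opt(row, "n_hno3") or 0.0,
                m_co2=_opt(row, "m_co2"),
                eps_f=_opt(row, "eps_f") or 0.0,
            )
        )
    return out


def load_trace(
    path: PathLike, ignition_index: int, main_end_index: int
) -> TemperatureTrace:
    df = pd.read_csv(path)
    if not {"t", "T"} <= set(df.columns):
        raise ValueError(f"trace file {path} must have columns 't' and 'T'")
    return TemperatureTrace(
        time=df["t"].to_numpy(float),
        temperature=df["T"].to_numpy(float),
        ignition_index=ignition_index,
        main_end_index=main_end_index,
    )


def load_calvet_runs(path: PathLike) -> List[CalvetRun]:
    df = pd.read_csv(path)
    required = {"m_sample", "T_oven", "dH_observed"}
    if not required <= set(df.columns):
        raise ValueError(f"calvet file {path} must have columns {sorted(required)}")
    return [
        CalvetRun(
            m_sample=float(row["m_sample"]),
            T_oven=float(row["T_oven"]),
            dH_observed=float(row["dH_observed"]),
            blank_correction=_opt(row, "blank_correction") or 0.0,
        )
        for _, row in df.iterrows()
    ]


def load_cp_polynomial(path: PathLike) -> CpPolynomial:
    raw = json.loads(Path(path).read_text())
    kwargs = {"coefficients": tuple(float(c) for c in raw["coefficients"])}
    for key in ("scale_factor", "t_min", "t_max"):
        if key in raw:
            kwargs[key] = float(raw[key])
    return CpPolynomial(**kwargs)


def load_species_registry(path: PathLike) -> Dict[str, SpeciesRecord]:
    raw = json.loads(Path(path).read_text())
    registry: Dict[str, SpeciesRecord] = {}
    for entry in raw:
        dfh = entry.get("dfH_gas")
        conformers = tuple(
            Conformer(
                label=c.get("label", ""),
                dG_rel=float(c["dG_rel"]),
                dH_rel=float(c.get("dH_rel", 0.0)),
                H_absolute=(
                    float(c["H_absolute"]) if "H_absolute" in c else None
                ),
            )
            for c in entry.get("conformers", [])
        )
        registry[entry["name"]] = SpeciesRecord(
            name=entry["name"],
            formula=parse_formula(entry["formula"]),
            dfH_gas=(
                Quantity(float(dfh[0]), float(dfh[1]), "kJ·mol⁻¹")
                if dfh is not None
                else None
            ),
            H_absolute=(
                float(entry["H_absolute"]) if "H_absolute" in entry else None
            ),
            conformers=conformers,
        )
    return registry


def save_calibration(result: CalibrationResult, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "eps_cal": [result.eps_cal.value, result.eps_cal.u],
                "n_runs": result.n_runs,
                "certificate": [
                    result.certificate.value,
                    result.certificate.u,
                ],
            },
            indent=2,
        )
    )


def load_calibration(path: PathLike) -> CalibrationResult:
    raw = json.loads(Path(path).read_text())
    return CalibrationResult(
        eps_cal=Quantity(*map(float, raw["eps_cal"]), "J·K⁻¹"),
        n_runs=int(raw.get("n_runs", 0)),
        certificate=Quantity(*map(float, raw["certificate"]), "J·g⁻¹"),
    )
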