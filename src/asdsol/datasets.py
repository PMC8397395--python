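"""Published reference data for the nimesulide + Kollidon VA64 system.

The package ships the printed study tables for this drug-polymer pair:
pure-component constants, composition-Tg curves measured by DSC and by
broadband dielectric spectroscopy (BDS), and the solubility-limit points
obtained by annealing a supersaturated 40 wt%-polymer dispersion at a
ladder of temperatures, at ambient pressure and at 50 MPa.  They are the
worked example for the Gordon-Taylor inversion and the Flory-Huggins
fits, and the inputs of the reproduction script.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .flory import ComponentConstants, SolubilityPoint
from .io import read_table
from .mixing import CompositionTgPoint

__all__ = [
    "nimesulide_kollidon_constants",
    "load_solubility_table",
    "solubility_points",
    "load_tg_composition_table",
    "tg_composition_points",
]

_TABLES = {
    ("solubility", "dsc"): "solubility_ambient_dsc.tsv",
    ("solubility", "bds"): "solubility_ambient_bds.tsv",
    ("solubility", "50mpa"): "solubility_50mpa_bds.tsv",
    ("tg", "dsc"): "tg_composition_dsc.tsv",
    ("tg", "bds"): "tg_composition_bds.tsv",
    ("tg", "50mpa"): "tg_composition_50mpa_bds.tsv",
}


def _load(kind: str, source: str) -> tuple[pd.DataFrame, dict]:
    try:
        filename = _TABLES[(kind, source)]
    except KeyError:
        valid = sorted(s for k, s in _TABLES if k == kind)
        raise KeyError(f"unknown {kind} table {source!r}; choose from {valid}") from None
    path = resources.files("asdsol.data").joinpath(filename)
    with resources.as_file(path) as p:
        return read_table(p)


def nimesulide_kollidon_constants(pressure: str = "ambient") -> ComponentConstants:
    """Pure-component constants; ``pressure`` is 'ambient' or '50mpa'.

    Only the pure-drug melting point changes with pressure (421 K at
    0.1 MPa, 435 K at 50 MPa); fusion enthalpy and densities are treated
    as pressure-independent over this range.
    """
    path = resources.files("asdsol.data").joinpath("constants_nms_kva.json")
    raw = json.loads(path.read_text())
    tm0 = {"ambient": raw["tm0_K"], "50mpa": raw["tm0_50MPa_K"]}
    if pressure not in tm0:
        raise KeyError(f"pressure must be 'ambient' or '50mpa', got {pressure!r}")
    return ComponentConstants(
        tm0=tm0[pressure],
        dhfus=raw["dhfus_J_per_mol"],
        d_drug=raw["d_drug_g_per_cm3"],
        d_poly=raw["d_poly_g_per_cm3"],
        mw_drug=raw["mw_drug_g_per_mol"],
        mw_poly=raw["mw_poly_g_per_mol"],
    )


def load_solubility_table(source: str = "bds") -> pd.DataFrame:
    """Solubility-limit table ('dsc', 'bds' or '50mpa') as a DataFrame
    with columns temperature_K, tg_K, wtpct_drug and their errors."""
    df, meta = _load("solubility", source)
    df.attrs.update(meta)
    return df


def solubility_points(source: str = "bds") -> list[SolubilityPoint]:
    """The same table as :class:`SolubilityPoint` records."""
    df = load_solubility_table(source)
    pressure = float(df.attrs.get("pressure_MPa", 0.1))
    return [
        SolubilityPoint(
            temperature=float(r.temperature_K),
            wtpct_drug=float(r.wtpct_drug),
            pressure=pressure,
        )
        for r in df.itertuples()
    ]


def load_tg_composition_table(source: str = "dsc") -> pd.DataFrame:
    """Composition-Tg table ('dsc', 'bds' or '50mpa') as a DataFrame
    with columns wtpct_poly, tg_K."""
    df, meta = _load("tg", source)
    df.attrs.update(meta)
    return df


def tg_composition_points(source: str = "dsc") -> list[CompositionTgPoint]:
    """The same table as :class:`CompositionTgPoint` records."""
    df = load_tg_composition_table(source)
    pressure = float(df.attrs.get("pressure_MPa", 0.1))
    method = str(df.attrs.get("method", "DSC"))
    return [
        CompositionTgPoint(
            w_drug=1.0 - float(r.wtpct_poly) / 100.0,
            tg=float(r.tg_K),
            pressure=pressure,
            method=method,
        )
        for r in df.itertuples()
    ]
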