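"""CSV and configuration I/O.

Gas-exchange tables use the LI-6400 export dialect (Photo, Cond, Ci,
Trmmol, Tleaf, PARi, CO2R, CO2S); readers normalise them to the package's
internal names and units (transpiration mmol -> mol), writers emit the
same dialect so a write -> read round trip is the identity.  Column
matching is case-insensitive and remappable through a mapping config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aci import AciCurve

log = logging.getLogger("wheatphys")

__all__ = ["DEFAULT_COLUMN_MAP", "read_gas_exchange", "write_gas_exchange",
           "read_aci_curves", "write_aci_curves", "read_isotope",
           "write_isotope", "read_traits", "write_traits", "load_config"]

#: Instrument-name -> internal-name mapping (case-insensitive on read).
DEFAULT_COLUMN_MAP = {
    "Photo": "A",
    "Cond": "gs",
    "Ci": "Ci",
    "Trmmol": "E",      # mmol m-2 s-1 on the instrument; stored as mol
    "Tleaf": "Tleaf",
    "PARi": "PPFD",
    "CO2R": "CO2R",
    "CO2S": "CO2S",
}

#: Columns a gas-exchange file must provide (instrument names).
MANDATORY_GAS_COLUMNS = ("Photo", "Ci", "Tleaf")


def _normalise_columns(df: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    lower_map = {k.lower(): v for k, v in mapping.items()}
    renames = {c: lower_map[c.lower()] for c in df.columns
               if c.lower() in lower_map}
    return df.rename(columns=renames)


def read_gas_exchange(path, mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a LI-6400-style gas-exchange CSV into internal names and units.

    Malformed rows (non-numeric in a mapped numeric column) are dropped
    and counted in the log.  Raises a schema error naming the first
    missing mandatory column.
    """
    mapping = mapping or DEFAULT_COLUMN_MAP
    df = pd.read_csv(path)
    lower_cols = {c.lower() for c in df.columns}
    for col in MANDATORY_GAS_COLUMNS:
        if col.lower() not in lower_cols and \
                mapping.get(col, col).lower() not in lower_cols:
            raise ValueError(f"gas-exchange file {path} lacks mandatory "
                             f"column {col!r}")
    df = _normalise_columns(df, mapping)
    numeric = [v for v in mapping.values() if v in df.columns]
    n0 = len(df)
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=[c for c in ("A", "Ci", "Tleaf") if c in df.columns])
    skipped = n0 - len(df)
    if skipped:
        log.warning("%s: skipped %d malformed row(s)", path, skipped)
    if "E" in df.columns:
        df["E"] = df["E"] / 1000.0  # mmol -> mol m-2 s-1
    return df.reset_index(drop=True)


def write_gas_exchange(df: pd.DataFrame, path) -> None:
    """Write internal gas-exchange records in the instrument CSV dialect."""
    out = df.copy()
    if "E" in out.columns:
        out["E"] = out["E"] * 1000.0  # mol -> mmol
    inverse = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = out.rename(columns=inverse)
    out.to_csv(path, index=False)


def read_aci_curves(path, group_by: str = "plant_id",
                    mapping: dict[str, str] | None = None,
                    ) -> dict[str, AciCurve]:
    """Read an A-Ci CSV (one row per point) into curves keyed by plant.

    Expects internal or instrument column names; per-curve constants
    (Tleaf, PPFD, Rd, gm) are taken from the first row of each group.
    """
    df = pd.read_csv(path)
    df = _normalise_columns(df, mapping or DEFAULT_COLUMN_MAP)
    curves = {}
    for key, grp in df.groupby(group_by):
        grp = grp.sort_values("Ci")
        curves[key] = AciCurve(
            Ci=grp["Ci"].to_numpy(), A=grp["A"].to_numpy(),
            Tleaf=float(grp["Tleaf"].iloc[0]),
            PPFD=float(grp["PPFD"].iloc[0]) if "PPFD" in grp else 1500.0,
            Rd_measured=float(grp["Rd"].iloc[0]) if "Rd" in grp else 1.25,
            gm_measured=float(grp["gm"].iloc[0]) if "gm" in grp else np.inf)
    return curves


def write_aci_curves(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_isotope(path) -> pd.DataFrame:
    """Read an isotope-log CSV (Cref, Csam, delta_ref, delta_sam, A, E, ...)."""
    df = pd.read_csv(path)
    required = {"Cref", "Csam", "delta_ref", "delta_sam", "A", "E", "Ca", "Ci"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isotope file {path} lacks column(s) "
                         f"{sorted(missing)}")
    return df


def write_isotope(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_traits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
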