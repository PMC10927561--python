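"""Reading and writing the tabular formats the pipeline consumes.

Surveys arrive as long-format CSV tables (one row per site, date and
species, with an abundance value, its unit and the sampling protocol),
accompanied by a per-site covariate table and a species-origin table that
maps (species, basin) pairs to a native / non-native status.  Everything
is held in pandas DataFrames with a fixed column vocabulary; a *dialect*
maps foreign column headers and unit spellings onto that vocabulary so
that differently-headed deposits can be read without editing the files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical abundance units
UNITS = ("count", "density_100m2", "cpue", "leslie")

#: canonical species-origin labels
ORIGINS = ("native", "nonnative", "unknown")

SURVEY_COLUMNS = [
    "site_id", "basin_id", "date", "protocol", "species_id",
    "abundance", "unit",
]

COVARIATE_COLUMNS = [
    "site_id", "basin_id", "hfi_1993", "hfi_2009", "altitude_m",
    "slope_deg", "discharge_m3s", "dist_source_km", "strahler",
    "limed", "realm",
]

#: the five hydromorphological variables summarized into the stream axis
STREAM_VARIABLES = [
    "altitude_m", "slope_deg", "discharge_m3s", "dist_source_km", "strahler",
]


class FormatError(ValueError):
    """A table is structurally unusable (missing column, duplicate key)."""


class RecordError(ValueError):
    """Individual rows violate an invariant; carries their row indices."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {rows[:20]}{'...' if len(rows) > 20 else ''})")
        self.rows = rows


@dataclass
class Dialect:
    """Column-name and unit-label mapping for a survey CSV deposit.

    ``columns`` maps the file's headers to canonical names; headers not
    listed are assumed canonical already.  ``units`` maps the file's unit
    spellings (e.g. ``"ind/100m2"``) to the canonical unit enum.
    """

    columns: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def rename(self, df: pd.DataFrame) -> pd.DataFrame:
        return df.rename(columns=self.columns)

    def map_unit(self, unit: str) -> str:
        return self.units.get(unit, unit)


#: dialect for the RivFishTIME distribution headers
RIVFISHTIME_DIALECT = Dialect(
    columns={
        "TimeSeriesID": "site_id",
        "HydroBasin": "basin_id",
        "SamplingDate": "date",
        "Protocol": "protocol",
        "Species": "species_id",
        "Abundance": "abundance",
        "UnitAbundance": "unit",
    },
    units={
        "Count": "count",
        "Ind.100m2": "density_100m2",
        "ind/100m2": "density_100m2",
        "CPUE": "cpue",
        "Leslie": "leslie",
    },
)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_survey_table(
    path: str | Path,
    dialect: Dialect | None = None,
    origin_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read a long-format survey CSV into a typed record table.

    Returns a DataFrame with columns ``site_id, basin_id, date, protocol,
    species_id, abundance, unit`` (plus ``origin`` when an origin table is
    given), dates parsed to datetimes, exact duplicates dropped, and rows
    sorted canonically so the result is independent of input row order.

    Raises
    ------
    FormatError
        If a required column is absent.
    RecordError
        If any row has an unparseable date, a negative or unparseable
        abundance, or an unknown abundance unit.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, dtype=str)
    raw = dialect.rename(raw)
    _require_columns(raw, SURVEY_COLUMNS, "survey table")

    df = raw[SURVEY_COLUMNS].copy()
    dates = pd.to_datetime(df["date"], format="mixed", errors="coerce")
    bad = df.index[dates.isna()].tolist()
    if bad:
        raise RecordError("unparseable date", bad)
    df["date"] = dates

    abundance = pd.to_numeric(df["abundance"], errors="coerce")
    bad = df.index[abundance.isna() | (abundance < 0)].tolist()
    if bad:
        raise RecordError("abundance missing, non-numeric or negative", bad)
    df["abundance"] = abundance.astype(float)

    df["unit"] = df["unit"].map(dialect.map_unit)
    bad = df.index[~df["unit"].isin(UNITS)].tolist()
    if bad:
        raise RecordError(f"unit not one of {UNITS}", bad)

    df = df.drop_duplicates(subset=["site_id", "date", "species_id"])
    df = df.sort_values(["site_id", "date", "species_id"], kind="mergesort")
    df = df.reset_index(drop=True)

    if origin_table is not None:
        df["origin"] = lookup_origin(df, origin_table)
    return df


def read_site_covariates(path: str | Path) -> pd.DataFrame:
    """Read the per-site covariate table (one row per site).

    Raises ``FormatError`` on duplicated sites and ``RecordError`` when a
    human-footprint value falls outside the index's [0, 50] range.
    """
    df = pd.read_csv(path)
    _require_columns(df, COVARIATE_COLUMNS, "site covariates")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise FormatError(f"duplicated site_id(s): {dups}")
    for col in ("hfi_1993", "hfi_2009"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 50)].tolist()
        if bad:
            raise RecordError(f"{col} outside [0, 50]", bad)
        df[col] = vals.astype(float)
    df["limed"] = df["limed"].astype(bool)
    df = df.sort_values("site_id", kind="mergesort").reset_index(drop=True)
    return df


def read_origin_table(path: str | Path) -> pd.DataFrame:
    """Read a species-origin table.

    Columns: ``species_id``, ``basin_id`` (empty for country-scope rows),
    ``country`` (optional, empty for basin-scope rows) and ``origin``.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, ["species_id", "origin"], "origin table")
    if "basin_id" not in df.columns:
        df["basin_id"] = ""
    if "country" not in df.columns:
        df["country"] = ""
    bad = df.index[~df["origin"].isin(ORIGINS)].tolist()
    if bad:
        raise RecordError(f"origin not one of {ORIGINS}", bad)
    return df


def lookup_origin(
    records: pd.DataFrame,
    origin_table: pd.DataFrame,
    site_country: pd.Series | None = None,
) -> pd.Series:
    """Resolve species origin with the basin -> country -> unknown cascade.

    A (species, basin) row wins; failing that a (species, country) row is
    used when a ``site_id -> country`` mapping is supplied; anything still
    unresolved is ``unknown``.
    """
    basin_map = {
        (r.species_id, r.basin_id): r.origin
        for r in origin_table.itertuples()
        if r.basin_id
    }
    country_map = {
        (r.species_id, r.country): r.origin
        for r in origin_table.itertuples()
        if not r.basin_id and r.country
    }
    countries = None
    if site_country is not None:
        countries = records["site_id"].map(site_country)

    out = np.full(len(records), "unknown", dtype=object)
    species = records["species_id"].to_numpy()
    basins = records["basin_id"].to_numpy()
    for i in range(len(records)):
        o = basin_map.get((species[i], basins[i]))
        if o is None and countries is not None:
            o = country_map.get((species[i], countries.iloc[i]))
        if o is not None:
            out[i] = o
    return pd.Series(out, index=records.index, name="origin")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as UTF-8 CSV (RFC 4180), no index column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, parse_dates: list[str] | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, parse_dates=parse_dates or [])
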