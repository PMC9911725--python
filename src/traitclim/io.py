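"""Delimited-text I/O for the five input schemas and all result tables.

All tables are UTF-8 delimited text (comma by default, tab accepted) with a
"." decimal separator, matching common ecology-archive conventions.  Every
reader returns a validated :class:`pandas.DataFrame`; the validation report
(merged duplicates, flagged rows) is attached under ``df.attrs["validation"]``.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import BIOCLIM_VARS

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_results",
    "species_key",
]


class SchemaError(ValueError):
    """A file does not match its declared schema."""


#: schema name -> (required columns, optional columns, numeric columns)
SCHEMAS: Mapping[str, tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]] = {
    "vegetation": (("plot_id", "species", "cover"), ("genus",), ("cover",)),
    "plots": (
        ("plot_id", "latitude", "longitude"),
        ("survey_year", "abundance_type"),
        ("latitude", "longitude", "survey_year"),
    ),
    "traits": (
        ("taxon", "taxon_rank", "plant_height", "sla", "seed_mass", "srl"),
        (),
        ("plant_height", "sla", "seed_mass", "srl"),
    ),
    "habitats": (("plot_id", "level1"), ("level2", "level3"), ()),
    "climate": (("plot_id",) + BIOCLIM_VARS, (), BIOCLIM_VARS),
    "responses": (("plot_id",), tuple(), tuple()),  # direct-mode log-CWMs; wide
}


def species_key(name: str) -> str:
    """Collapse infraspecific taxa: the species key is the first two
    whitespace-separated name tokens (subspecies/varieties merge into their
    species)."""
    return " ".join(str(name).split()[:2])


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _check_columns(df: pd.DataFrame, schema_name: str) -> None:
    required, _, _ = SCHEMAS[schema_name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema_name} table is missing required column(s): {', '.join(missing)}"
        )


def _coerce_numeric(df: pd.DataFrame, cols, path: Path) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 0- vs 1-based numbering
            lines = (df.index[bad] + 2).tolist()[:5]
            raise SchemaError(
                f"unparseable numeric value(s) in column {col!r} of {path} "
                f"near line(s) {lines}"
            )
        df[col] = coerced


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate one of the known table schemas.

    Vegetation tables additionally get subspecies merged to the species
    level and duplicate (plot_id, species) cover records summed (capped at
    100%).  Climate tables flag (not drop) plots with missing variables.
    """
    path = Path(path)
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    _check_columns(df, schema_name)
    _, _, numeric = SCHEMAS[schema_name]
    _coerce_numeric(df, numeric, path)
    report: dict = {"schema": schema_name, "n_rows_read": int(len(df))}

    if schema_name == "vegetation":
        df["species"] = df["species"].map(species_key)
        if "genus" not in df.columns:
            df["genus"] = df["species"].str.split().str[0]
        if (df["cover"] <= 0).any():
            raise SchemaError(f"vegetation covers must be > 0 in {path}")
        before = len(df)
        df = (
            df.groupby(["plot_id", "species"], as_index=False, sort=False)
            .agg(genus=("genus", "first"), cover=("cover", "sum"))
        )
        df["cover"] = df["cover"].clip(upper=100.0)
        report["n_duplicates_merged"] = int(before - len(df))
    elif schema_name == "plots":
        if df["plot_id"].duplicated().any():
            raise SchemaError(f"duplicate plot_id in {path}")
        if "survey_year" not in df.columns:
            df["survey_year"] = np.nan
        if "abundance_type" not in df.columns:
            df["abundance_type"] = "cover"
        ok_lat = df["latitude"].isna() | df["latitude"].between(-90, 90)
        ok_lon = df["longitude"].isna() | df["longitude"].between(-180, 180)
        if not (ok_lat.all() and ok_lon.all()):
            raise SchemaError(f"coordinates out of WGS84 bounds in {path}")
    elif schema_name == "traits":
        df = df.copy()
        bad_rank = ~df["taxon_rank"].isin(["species", "genus"])
        if bad_rank.any():
            raise SchemaError(f"taxon_rank must be species|genus in {path}")
        if df.duplicated(["taxon", "taxon_rank"]).any():
            raise SchemaError(f"duplicate (taxon, rank) rows in {path}")
        vals = df[["plant_height", "sla", "seed_mass", "srl"]]
        if (vals <= 0).any().any():
            raise SchemaError(f"trait values must be > 0 in {path}")
    elif schema_name == "habitats":
        if df["plot_id"].duplicated().any():
            raise SchemaError(f"duplicate plot_id in habitat table {path}")
        for col in ("level2", "level3"):
            if col not in df.columns:
                df[col] = pd.NA
    elif schema_name == "climate":
        incomplete = df[list(BIOCLIM_VARS)].isna().any(axis=1)
        df["climate_missing"] = incomplete
        report["n_flagged_missing"] = int(incomplete.sum())
    elif schema_name == "responses":
        for col in df.columns:
            if col != "plot_id":
                df[col] = pd.to_numeric(df[col])

    report["n_rows"] = int(len(df))
    df.attrs["validation"] = report
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    return path


def write_results(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
    extra: Mapping | None = None,
) -> dict:
    """Write result tables plus a JSON run manifest; returns the manifest.

    The manifest records the config, seed, package versions and the row
    count of every written table.  Identical inputs produce identical
    tables; only the manifest timestamp differs between runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "versions": {
            "traitclim": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": dict(config) if config else None,
        "tables": {},
    }
    if extra:
        manifest.update(dict(extra))
    for name, df in results.items():
        path = out_dir / f"{name}.csv"
        write_table(df, path)
        manifest["tables"][name] = {"path": path.name, "n_rows": int(len(df))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
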