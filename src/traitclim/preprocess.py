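"""Plot-level exclusion rules, census deduplication and spatial stratification.

The six exclusion rules are applied in a fixed, auditable order:
presence/absence-only records; missing coordinates; an optional region
exclusion (off by default — on real data it removes, e.g., Greenland);
latitude outside the strict (34°, 82°) N window; trait coverage below 80%
of total plant cover; missing climate.  Boundary values (latitude exactly
34.0 or 82.0, coverage exactly 0.80) are retained: the thresholds are
strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, pi, radians
from typing import Optional

import numpy as np
import pandas as pd

from ._geo import EARTH_RADIUS_KM
from ._rng import rng_for

__all__ = ["FilterReport", "apply_filters", "stratify_spatial", "grid_cell_km",
           "DEFAULT_RULES"]

DEFAULT_RULES = dict(
    lat_min=34.0,
    lat_max=82.0,
    coverage_min=0.80,
    region_exclusion=None,  # optional dict(lat_min, lat_max, lon_min, lon_max)
)

_RULE_ORDER = (
    "presence_absence_only",
    "missing_coordinates",
    "region_exclusion",
    "latitude_bounds",
    "trait_coverage",
    "missing_climate",
)


@dataclass
class FilterReport:
    """Per-rule removal bookkeeping; removals sum to input − output."""

    n_input: int
    rules: list = field(default_factory=list)        # rule names in order
    removed: list = field(default_factory=list)      # plots removed per rule
    remaining: list = field(default_factory=list)    # plots left after each rule

    @property
    def n_final(self) -> int:
        return self.remaining[-1] if self.remaining else self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(rule=self.rules, n_removed=self.removed,
                                 n_remaining=self.remaining))


def apply_filters(
    veg: Optional[pd.DataFrame],
    meta: pd.DataFrame,
    climate: Optional[pd.DataFrame],
    cwm_coverage: Optional[pd.Series] = None,
    rules_config: Optional[dict] = None,
) -> tuple[np.ndarray, FilterReport]:
    """Apply the exclusion rules; returns (retained plot ids, report).

    ``cwm_coverage`` is the per-plot trait-coverage fraction precomputed by
    the CWM stage (indexed by plot_id); ``veg`` may be None in direct mode,
    in which case the presence/absence rule falls back to the metadata's
    ``abundance_type`` flag alone.
    """
    cfg = dict(DEFAULT_RULES)
    if rules_config:
        unknown = set(rules_config) - set(DEFAULT_RULES)
        if unknown:
            raise ValueError(f"unknown filter rule option(s): {sorted(unknown)}")
        cfg.update(rules_config)

    if veg is not None:
        missing_meta = set(veg["plot_id"]) - set(meta["plot_id"])
        if missing_meta:
            raise ValueError(
                f"{len(missing_meta)} plot(s) present in vegetation but absent "
                f"from metadata, e.g. {sorted(missing_meta)[:3]}")

    df = meta.set_index("plot_id")
    keep = pd.Series(True, index=df.index)
    report = FilterReport(n_input=len(df))

    def drop(rule: str, mask_bad: pd.Series):
        bad = keep & mask_bad
        keep[bad] = False
        report.rules.append(rule)
        report.removed.append(int(bad.sum()))
        report.remaining.append(int(keep.sum()))

    abund = df.get("abundance_type", pd.Series("cover", index=df.index))
    drop("presence_absence_only", abund.astype(str).eq("presence_absence"))
    drop("missing_coordinates", df["latitude"].isna() | df["longitude"].isna())

    region = cfg["region_exclusion"]
    if region:
        in_region = (
            df["latitude"].between(region["lat_min"], region["lat_max"])
            & df["longitude"].between(region["lon_min"], region["lon_max"])
        ).fillna(False)
        drop("region_exclusion", in_region)
    else:
        drop("region_exclusion", pd.Series(False, index=df.index))

    lat = df["latitude"]
    drop("latitude_bounds",
         (lat < cfg["lat_min"]) | (lat > cfg["lat_max"]))

    if cwm_coverage is not None:
        cov = pd.Series(cwm_coverage).reindex(df.index)
        drop("trait_coverage", cov.isna() | (cov < cfg["coverage_min"]))
    else:
        drop("trait_coverage", pd.Series(False, index=df.index))

    if climate is not None:
        if "climate_missing" in climate.columns:
            bad_ids = set(climate.loc[climate["climate_missing"].astype(bool),
                                      "plot_id"])
        else:
            vals = climate.drop(columns=["plot_id"])
            bad_ids = set(climate.loc[vals.isna().any(axis=1), "plot_id"])
        has_climate = pd.Series(df.index.isin(set(climate["plot_id"]) - bad_ids),
                                index=df.index)
        drop("missing_climate", ~has_climate)
    else:
        drop("missing_climate", pd.Series(False, index=df.index))

    retained = df.index[keep].to_numpy()
    return retained, report


def stratify_spatial(meta: pd.DataFrame, cell_deg: float = 0.01,
                     seed: int = 0) -> np.ndarray:
    """Most-recent census per exact location, then one plot per grid cell.

    Among plots sharing identical coordinates only the maximum survey year
    survives (year ties broken by a seeded uniform draw); survivors are
    binned into a floor(lat/cell) × floor(lon/cell) grid (half-open cells,
    lower-left inclusive) and one plot per non-empty cell is retained by a
    seeded uniform draw.  Deterministic given the seed.
    """
    if cell_deg <= 0:
        raise ValueError("cell_deg must be positive")
    df = meta.dropna(subset=["latitude", "longitude"]).copy()
    rng = rng_for(seed, "stratify")
    df = df.sort_values("plot_id").reset_index(drop=True)
    df["_tie"] = rng.uniform(size=len(df))

    year = df["survey_year"]
    df["_year"] = pd.to_numeric(year, errors="coerce").fillna(-np.inf)
    df = df.sort_values(["_year", "_tie"], ascending=[False, False])
    df = df.drop_duplicates(subset=["latitude", "longitude"], keep="first")

    df["_cell_lat"] = np.floor(df["latitude"] / cell_deg).astype(np.int64)
    df["_cell_lon"] = np.floor(df["longitude"] / cell_deg).astype(np.int64)
    df["_pick"] = rng.uniform(size=len(df))
    df = df.sort_values("_pick").drop_duplicates(
        subset=["_cell_lat", "_cell_lon"], keep="first")
    return np.sort(df["plot_id"].to_numpy())


def grid_cell_km(latitude: float, cell_deg: float = 0.01) -> tuple[float, float]:
    """North–south and east–west arc length (km) of one grid cell.

    Spherical Earth with mean radius 6371 km: ns = cell·(π/180)·R and
    ew = ns·cos(latitude).
    """
    if not abs(latitude) < 90:
        raise ValueError("|latitude| must be < 90")
    ns = cell_deg * (pi / 180.0) * EARTH_RADIUS_KM
    ew = ns * cos(radians(latitude))
    return ns, ew
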