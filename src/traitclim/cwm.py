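"""Trait assignment and community-weighted means.

Species receive species-level mean trait values when available, otherwise
the genus-level mean, otherwise nothing.  The CWM of trait t in a plot is
the cover-weighted arithmetic mean over the species that carry a value for
t (weights renormalized over trait-bearing species); the coverage fraction
is the share of total plant cover those species contribute.  CWMs are
natural-log transformed for modelling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import TRAITS

__all__ = ["assign_traits", "compute_cwm", "min_coverage"]


def assign_traits(species_list, trait_table: pd.DataFrame) -> pd.DataFrame:
    """Per-species trait values with provenance {species, genus, none}.

    ``species_list`` may be an iterable of binomial names or a vegetation
    table (its distinct species are used); genus is the first name token.
    """
    if isinstance(species_list, pd.DataFrame):
        species = species_list["species"].unique()
    else:
        species = pd.unique(pd.Series(list(species_list)))
    vals = trait_table[list(TRAITS)]
    if (vals <= 0).any().any() or vals.isna().any().any():
        raise ValueError("trait table must contain positive values only")

    sp_rows = trait_table[trait_table["taxon_rank"] == "species"].set_index("taxon")
    gen_rows = trait_table[trait_table["taxon_rank"] == "genus"].set_index("taxon")

    records = []
    for name in species:
        genus = str(name).split()[0]
        if name in sp_rows.index:
            row = sp_rows.loc[name, list(TRAITS)]
            prov = "species"
        elif genus in gen_rows.index:
            row = gen_rows.loc[genus, list(TRAITS)]
            prov = "genus"
        else:
            row = pd.Series({t: np.nan for t in TRAITS})
            prov = "none"
        records.append((name, prov, *row.tolist()))
    return pd.DataFrame(records, columns=["species", "provenance", *TRAITS])


def compute_cwm(veg: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Per-plot CWM, log-CWM and coverage fraction for each trait.

    Plots whose trait-bearing cover is zero for a trait get a missing CWM
    for that trait; plots with no species at all are excluded with a
    warning.  Output columns: cwm_<t>, log_cwm_<t>, coverage_<t>,
    coverage_min, total_cover.
    """
    if (veg["cover"] <= 0).any():
        raise ValueError("covers must be > 0")
    merged = veg.merge(assignment[["species", *TRAITS]], on="species", how="left")
    empty_plots = set(veg["plot_id"].unique()) ^ set(merged["plot_id"].unique())
    if empty_plots:
        warnings.warn(f"excluded {len(empty_plots)} plot(s) with no species")

    out = merged.groupby("plot_id").agg(total_cover=("cover", "sum"))
    for t in TRAITS:
        has = merged[t].notna()
        cw = merged.loc[has, ["plot_id", "cover", t]].copy()
        cw["wx"] = cw["cover"] * cw[t]
        g = cw.groupby("plot_id").agg(wx=("wx", "sum"), w=("cover", "sum"))
        cwm = g["wx"] / g["w"]
        out[f"cwm_{t}"] = cwm
        out[f"log_cwm_{t}"] = np.log(cwm)
        out[f"coverage_{t}"] = (g["w"] / out["total_cover"]).fillna(0.0)
        out[f"coverage_{t}"] = out[f"coverage_{t}"].fillna(0.0)
    cov_cols = [f"coverage_{t}" for t in TRAITS]
    out[cov_cols] = out[cov_cols].fillna(0.0)
    out["coverage_min"] = out[cov_cols].min(axis=1)
    return out.reset_index()


def min_coverage(cwm_table: pd.DataFrame) -> pd.Series:
    """Per-plot minimum trait coverage (the single filter criterion)."""
    return cwm_table.set_index("plot_id")["coverage_min"]
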