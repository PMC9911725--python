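"""End-to-end orchestration: generate/read -> filter -> stratify -> CWM ->
PCA -> mixed models -> slopes, tallies and R² decompositions -> write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._rng import derive_seed
from .climate import fit_climate_pca, project_climate
from .config import RunConfig, TRAITS
from .cwm import assign_traits, compute_cwm, min_coverage
from .inference import classify_and_tally, marginal_slopes, r2_partition
from .io import read_table, write_results
from .models import balanced_subsample, build_design, fit_mixed_reml
from .preprocess import apply_filters, stratify_spatial
from .synthetic import direct_mode_cwm_table, generate_dataset

logger = logging.getLogger("traitclim")

__all__ = ["RunArtifacts", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunArtifacts:
    manifest: dict
    fits: dict = field(default_factory=dict)          # (trait, model_id) -> FittedModel
    slopes: pd.DataFrame | None = None
    tallies: pd.DataFrame | None = None
    decompositions: pd.DataFrame | None = None
    filter_report: pd.DataFrame | None = None
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunArtifacts:
    config.validate()
    counts: dict[str, int] = {}
    stage = "setup"
    try:
        # ---- inputs --------------------------------------------------
        stage = "load"
        if config.mode == "synthetic":
            syn_cfg = config.synthetic
            if syn_cfg.seed != config.seed:
                syn_cfg = type(syn_cfg)(**{**vars(syn_cfg), "seed": config.seed})
            dataset = generate_dataset(syn_cfg)
            meta, climate, habitats = dataset.plots, dataset.climate, dataset.habitats
            veg = None
            cwm_table = direct_mode_cwm_table(dataset)
        else:
            paths = config.table_paths
            veg = read_table(paths["vegetation"], "vegetation")
            meta = read_table(paths["plots"], "plots")
            traits_tab = read_table(paths["traits"], "traits")
            climate = read_table(paths["climate"], "climate")
            habitats = read_table(paths["habitats"], "habitats")
            assignment = assign_traits(veg, traits_tab)
            cwm_table = compute_cwm(veg, assignment)
        counts["load_plots"] = len(meta)
        logger.info("load: %d plots", len(meta))

        # ---- filters -------------------------------------------------
        stage = "filter"
        retained, report = apply_filters(
            veg, meta, climate, cwm_coverage=min_coverage(cwm_table),
            rules_config={"lat_min": config.lat_bounds[0],
                          "lat_max": config.lat_bounds[1],
                          "coverage_min": config.coverage_threshold},
        )
        counts["after_filters"] = len(retained)
        logger.info("filter: %d -> %d plots", len(meta), len(retained))

        stage = "stratify"
        meta_f = meta[meta["plot_id"].isin(retained)]
        kept = stratify_spatial(meta_f, cell_deg=config.cell_deg,
                                seed=derive_seed(config.seed, "stratify"))
        counts["after_stratification"] = len(kept)
        logger.info("stratify: %d -> %d plots", len(meta_f), len(kept))

        keep = set(kept)
        meta_k = meta[meta["plot_id"].isin(keep)].reset_index(drop=True)
        climate_k = climate[climate["plot_id"].isin(keep)].reset_index(drop=True)
        cwm_k = cwm_table[cwm_table["plot_id"].isin(keep)].reset_index(drop=True)
        habitats_k = habitats[habitats["plot_id"].isin(keep)].reset_index(drop=True)

        # ---- climate PCA --------------------------------------------
        stage = "pca"
        clim_fit = climate_k.drop(columns=["climate_missing"], errors="ignore")
        pca = fit_climate_pca(clim_fit, n_components=config.n_pca_components)
        scores = project_climate(clim_fit, pca)
        counts["pca_plots"] = len(scores)
        logger.info("pca: top-%d components explain %.1f%%",
                    config.n_pca_components,
                    100 * pca.explained_variance_ratio_[:config.n_pca_components].sum())

        # ---- models --------------------------------------------------
        stage = "fit"
        fits, designs, decomp_rows, slope_frames, tally_frames = {}, {}, [], [], []
        opts = config.model_options
        for trait in config.traits:
            for mid in sorted(config.models):
                if mid == 1:
                    sub_ids = balanced_subsample(
                        habitats_k, level=1,
                        seed=derive_seed(config.seed, "balance"))
                    cwm_m = cwm_k[cwm_k["plot_id"].isin(set(sub_ids))]
                else:
                    cwm_m = cwm_k
                design = build_design(cwm_m, trait, scores, habitats_k,
                                      meta_k, mid, opts)
                fit = fit_mixed_reml(design, opts)
                fits[(trait, mid)] = fit
                designs[(trait, mid)] = design
                decomp_rows.append(r2_partition(fit, design).to_row())
                if mid >= 3:
                    sl = marginal_slopes(fit, design, min_n=opts.min_n_slope)
                    slope_frames.append(sl)
                    tally_frames.append(classify_and_tally(sl, habitats_k))
                logger.info("fit: trait=%s model=%d n=%d", trait, mid, fit.n_obs)
        counts["n_models_fit"] = len(fits)

        # ---- write ---------------------------------------------------
        stage = "write"
        decomp = pd.DataFrame(decomp_rows)
        slopes = (pd.concat(slope_frames, ignore_index=True)
                  if slope_frames else pd.DataFrame())
        tallies = (pd.concat(tally_frames, ignore_index=True)
                   if tally_frames else pd.DataFrame())
        results = {
            "filter_report": report.to_frame(),
            "r2_decomposition": decomp,
            "slopes": slopes,
            "slope_tallies": tallies,
            "cwm": cwm_k,
            "climate_scores": scores,
        }
        manifest = write_results(
            results, config.out_dir, config=config.to_dict(), seed=config.seed,
            extra={"stage_counts": counts},
        )
        return RunArtifacts(manifest=manifest, fits=fits, slopes=slopes,
                            tallies=tallies, decompositions=decomp,
                            filter_report=report.to_frame(), stage_counts=counts)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(stage, exc, {"stage_counts": counts}) from exc
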