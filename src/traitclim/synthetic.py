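"""Synthetic landscapes with known mixed-model structure.

The generator emulates the shape of a continental vegetation-plot archive:
plots scattered over a latitude/longitude window, a three-level nested
habitat hierarchy, 19 correlated bioclim-style variables driven by a few
latent gradients, and log community-weighted trait means (log-CWMs) that
follow a random-intercept/random-slope linear mixed model whose generating
parameters — and hence expected variance components and R² — are known
exactly.

Two fidelity modes are provided.  *Direct* mode emits the log-CWM response
table itself and is used for exact parameter-recovery experiments.
*Community* mode additionally inverts each plot's target CWMs into a small
species list with percent covers (softmax cover allocation over the
habitat's species pool, refined numerically), so the CWM and preprocessing
stages can be exercised end to end; inverting four traits at once is
over-constrained, which is why direct mode exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from ._geo import haversine_km
from ._rng import rng_for
from .climate import ClimatePCA, project_climate
from .config import (BIOCLIM_VARS, TRAIT_LOG_BASELINES, TRAITS,
                     ConfigurationError, PoolConfig, SyntheticConfig)

__all__ = [
    "SyntheticDataset",
    "TruthSummary",
    "generate_dataset",
    "expected_variance_components",
    "generate_communities",
    "direct_mode_cwm_table",
]


@dataclass
class TruthSummary:
    """Generating-side variance components and the R² they imply."""

    sigma2_fixed: float
    var_components: dict        # name -> expected variance contribution
    sigma2_residual: float
    r2_marginal: float
    r2_conditional: float


@dataclass
class SyntheticDataset:
    plots: pd.DataFrame         # plot_id, latitude, longitude, survey_year
    climate: pd.DataFrame       # plot_id + 19 variables
    habitats: pd.DataFrame      # plot_id, level1..level3
    responses: pd.DataFrame     # plot_id + log_cwm_<trait>
    scores: pd.DataFrame        # plot_id + pc1..pc4 (generation-side PCA)
    pca: ClimatePCA
    truth: dict
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> dict:
        """Write the vegdata_io table schemas plus a truth JSON sidecar."""
        from .io import write_table

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("plots", self.plots), ("climate", self.climate),
                         ("habitats", self.habitats), ("responses", self.responses),
                         ("scores", self.scores)):
            paths[name] = str(write_table(df, out_dir / f"{name}.csv"))
        sidecar = {
            "seed": self.config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "habitat_effects": {
                t: {"intercept": self.truth["intercept_dev"][t].tolist(),
                    "slopes": self.truth["slope_dev"][t].tolist()}
                for t in TRAITS
            },
            "effect_habitats": list(self.truth["effect_habitats"]),
        }
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        paths["truth"] = str(out_dir / "truth.json")
        return paths


def _habitat_codes(config: SyntheticConfig) -> pd.DataFrame:
    """Level-3 code table with its implied level-2 and level-1 parents."""
    l1, l2, l3 = config.n_habitats_per_level
    rows = []
    for t in range(l3):
        p2 = t // (l3 // l2)
        p1 = p2 // (l2 // l1)
        rows.append((f"H{p1 + 1}", f"H{p1 + 1}.{p2 % (l2 // l1) + 1}",
                     f"H{p1 + 1}.{p2 % (l2 // l1) + 1}.{t % (l3 // l2) + 1}"))
    return pd.DataFrame(rows, columns=["level1", "level2", "level3"])


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one fully reproducible synthetic dataset in direct mode."""
    config.validate()
    n = config.n_plots
    seed = config.seed

    rng = rng_for(seed, "coords")
    lat = rng.uniform(*config.lat_range, size=n)
    lon = rng.uniform(*config.lon_range, size=n)
    year = rng_for(seed, "years").integers(
        config.year_range[0], config.year_range[1] + 1, size=n)
    plot_ids = np.array([f"plot{i:06d}" for i in range(n)])
    plots = pd.DataFrame(dict(plot_id=plot_ids, latitude=lat, longitude=lon,
                              survey_year=year))
    plots["abundance_type"] = "cover"

    # habitat hierarchy ------------------------------------------------
    codes = _habitat_codes(config)
    h3 = rng_for(seed, "habitats").integers(len(codes), size=n)
    habitats = codes.iloc[h3].reset_index(drop=True)
    habitats.insert(0, "plot_id", plot_ids)

    # climate: latent gradients -> 19 correlated variables -------------
    rng_c = rng_for(seed, "climate")
    L = config.n_latent_gradients
    lat_z = (lat - lat.mean()) / lat.std()
    lon_z = (lon - lon.mean()) / lon.std()
    spatial_anchor = [-lat_z, lon_z, lat_z * lon_z / max(np.std(lat_z * lon_z), 1e-9), None]
    latents = np.empty((n, L))
    for k in range(L):
        noise = rng_c.standard_normal(n)
        anchor = spatial_anchor[k]
        latents[:, k] = noise if anchor is None else 0.8 * anchor + 0.6 * noise
        latents[:, k] = (latents[:, k] - latents[:, k].mean()) / latents[:, k].std()
    strengths = np.array([1.6, 1.2, 0.9, 0.7])[:L]
    mixing = rng_c.standard_normal((config.n_climate_vars, L)) * strengths
    raw = latents @ mixing.T + config.climate_noise_sd * rng_c.standard_normal(
        (n, config.n_climate_vars))
    var_scale = np.exp(rng_c.uniform(np.log(0.5), np.log(20.0),
                                     size=config.n_climate_vars))
    var_shift = rng_c.uniform(-5.0, 15.0, size=config.n_climate_vars)
    clim_vals = raw * var_scale + var_shift
    climate = pd.DataFrame(clim_vals, columns=list(BIOCLIM_VARS)[: config.n_climate_vars])
    climate.insert(0, "plot_id", plot_ids)

    pca = ClimatePCA(n_components=4).fit(climate)
    scores = project_climate(climate, pca)
    S = scores[["pc1", "pc2", "pc3", "pc4"]].to_numpy()

    # habitat random effects at the generating level -------------------
    level_col = f"level{config.effect_level}"
    effect_habitats = np.array(sorted(habitats[level_col].unique()))
    H = len(effect_habitats)
    h_idx = pd.Categorical(habitats[level_col],
                           categories=effect_habitats).codes
    rng_e = rng_for(seed, "effects")
    beta = np.asarray(config.beta, dtype=float)
    tau1 = np.asarray(config.tau1_sq, dtype=float)
    rho = config.intercept_slope_corr
    intercept_dev, slope_dev = {}, {}
    for t in TRAITS:
        z0 = rng_e.standard_normal(H)
        a = np.sqrt(config.tau0_sq) * z0
        b = np.empty((H, 4))
        for j in range(4):
            zj = rng_e.standard_normal(H)
            b[:, j] = np.sqrt(tau1[j]) * (rho * z0 + np.sqrt(1 - rho**2) * zj)
        intercept_dev[t], slope_dev[t] = a, b

    # shared spatial Gaussian-process field ----------------------------
    if config.spatial_sd > 0:
        rng_s = rng_for(seed, "spatial")
        k = min(config.spatial_n_knots, n)
        knot_idx = rng_s.choice(n, size=k, replace=False)
        D_kk = haversine_km(lat[knot_idx], lon[knot_idx],
                            lat[knot_idx], lon[knot_idx])
        K = np.exp(-D_kk / config.spatial_range_km)
        Lk = np.linalg.cholesky(K + 1e-8 * np.eye(k))
        C_nk = np.exp(-haversine_km(lat, lon, lat[knot_idx], lon[knot_idx])
                      / config.spatial_range_km)
        basis = solve_triangular(Lk, C_nk.T, lower=True).T
        field = config.spatial_sd * basis @ rng_s.standard_normal(k)
    else:
        field = np.zeros(n)

    # responses --------------------------------------------------------
    rng_r = rng_for(seed, "residuals")
    responses = pd.DataFrame(dict(plot_id=plot_ids))
    residuals = {}
    for t in TRAITS:
        e = np.sqrt(config.sigma_sq) * rng_r.standard_normal(n)
        residuals[t] = e
        y = (TRAIT_LOG_BASELINES[t] + S @ beta + intercept_dev[t][h_idx]
             + np.einsum("ij,ij->i", S, slope_dev[t][h_idx]) + field + e)
        responses[f"log_cwm_{t}"] = y

    truth = dict(
        effect_habitats=effect_habitats, effect_index=h_idx,
        intercept_dev=intercept_dev, slope_dev=slope_dev,
        spatial_field=field, residuals=residuals,
        fixed_part=S @ beta, seed=seed,
    )
    return SyntheticDataset(plots=plots, climate=climate, habitats=habitats,
                            responses=responses, scores=scores, pca=pca,
                            truth=truth, config=config)


def expected_variance_components(
    config: SyntheticConfig, climate_scores: np.ndarray | pd.DataFrame
) -> TruthSummary:
    """Analytic variance components implied by the generating parameters.

    The fixed component is the population variance of X·beta over the
    supplied plots; each random-slope component is the mean over plots of
    tau1²_j · score_j² and the intercept component is tau0² itself.
    """
    if isinstance(climate_scores, pd.DataFrame):
        cols = [c for c in ("pc1", "pc2", "pc3", "pc4") if c in climate_scores]
        S = climate_scores[cols].to_numpy(dtype=float)
    else:
        S = np.asarray(climate_scores, dtype=float)
    if S.size == 0:
        raise ConfigurationError("empty climate score matrix")
    beta = np.asarray(config.beta, dtype=float)
    tau1 = np.asarray(config.tau1_sq, dtype=float)
    sigma2_f = float(np.var(S @ beta))
    slope_comp = {
        f"habitat_slope_pc{j + 1}": float(tau1[j] * np.mean(S[:, j] ** 2))
        for j in range(S.shape[1])
    }
    comps = {"habitat_intercept": float(config.tau0_sq), **slope_comp,
             "spatial": float(config.spatial_sd**2)}
    total = sigma2_f + sum(comps.values()) + config.sigma_sq
    r2m = sigma2_f / total
    r2c = (sigma2_f + sum(comps.values())) / total
    return TruthSummary(sigma2_fixed=sigma2_f, var_components=comps,
                        sigma2_residual=float(config.sigma_sq),
                        r2_marginal=r2m, r2_conditional=r2c)


def direct_mode_cwm_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """CWM table equivalent of the direct-mode responses (coverage 1)."""
    out = pd.DataFrame(dict(plot_id=dataset.responses["plot_id"]))
    for t in TRAITS:
        logv = dataset.responses[f"log_cwm_{t}"].to_numpy()
        out[f"cwm_{t}"] = np.exp(logv)
        out[f"log_cwm_{t}"] = logv
        out[f"coverage_{t}"] = 1.0
    out["coverage_min"] = 1.0
    out["total_cover"] = 100.0
    return out


# ----------------------------------------------------------------------
# community mode
# ----------------------------------------------------------------------

def generate_communities(
    dataset: SyntheticDataset,
    pool_config: PoolConfig | None = None,
    seed: int | None = None,
):
    """Invert direct-mode log-CWM targets into species cover tables.

    Each level-1 habitat gets a pool of log-normally distributed species.
    For every plot, covers over a random pool subset start from a softmax
    of trait-space suitability and are refined so the log of the
    cover-weighted arithmetic trait mean — the exact quantity the CWM stage
    recomputes, under the same species/genus trait-assignment rules —
    falls within ``match_tol`` of the direct-mode target for all four
    traits.  Plots whose pool cannot reach their targets are flagged, not
    silently dropped.

    Returns ``(vegetation, trait_table, flagged_plot_ids)``.
    """
    pool_config = pool_config or PoolConfig()
    pool_config.validate()
    seed = dataset.config.seed if seed is None else seed
    rng = rng_for(seed, "communities")

    level1 = sorted(dataset.habitats["level1"].unique())
    n_sp = pool_config.species_per_habitat
    n_genera = max(n_sp // 4, 1)
    pools = {}
    trait_rows = []
    hab1_of_plot = dataset.habitats.set_index("plot_id")["level1"]
    resp_by_hab = dataset.responses.set_index("plot_id").groupby(hab1_of_plot)
    for h in level1:
        htag = h.replace(".", "")
        # pools are centred on the habitat's mean CWM target (species pools
        # track habitat conditions), jittered by the configured shift
        centre = resp_by_hab.mean().loc[h]
        shift = rng.normal(0.0, pool_config.habitat_shift_sd, size=len(TRAITS))
        log_traits = np.column_stack([
            centre[f"log_cwm_{t}"] + shift[j]
            + pool_config.trait_log_sd * rng.standard_normal(n_sp)
            for j, t in enumerate(TRAITS)
        ])
        genus_of = rng.integers(n_genera, size=n_sp)
        u = rng.uniform(size=n_sp)
        rank = np.where(u < pool_config.traitless_fraction, "none",
                        np.where(u < pool_config.traitless_fraction
                                 + pool_config.genus_only_fraction,
                                 "genus", "species"))
        # a species without any trait data anywhere must not inherit a genus
        # mean, so truly traitless species sit in their own (unmeasured) genus
        genus = np.array([
            f"Ignotus{htag}x{i + 1}" if rank[i] == "none"
            else f"Genus{htag}g{genus_of[i] + 1}"
            for i in range(n_sp)
        ])
        names = np.array([f"{genus[i]} sp{i + 1}" for i in range(n_sp)])
        # genus means only exist where at least one congener was measured
        measured = rank == "species"
        has_congener = np.isin(genus, np.unique(genus[measured]))
        rank = np.where((rank == "genus") & ~has_congener, "none", rank)
        pools[h] = dict(names=names, log_traits=log_traits, genus=genus,
                        rank=rank)
        for i in range(n_sp):
            if rank[i] == "species":
                trait_rows.append((names[i], "species",
                                   *np.exp(log_traits[i]).tolist()))

    # genus rows: mean over the species-rank (measured) congeners
    genus_acc: dict[str, list] = {}
    for h in level1:
        p = pools[h]
        for i in range(n_sp):
            if p["rank"][i] == "species":
                genus_acc.setdefault(p["genus"][i], []).append(
                    np.exp(p["log_traits"][i]))
    for g, vals in sorted(genus_acc.items()):
        trait_rows.append((g, "genus", *np.mean(vals, axis=0).tolist()))
    trait_table = pd.DataFrame(
        trait_rows, columns=["taxon", "taxon_rank", *TRAITS])

    # effective (as-assigned) trait values per pool species
    genus_means = {g: np.mean(vals, axis=0) for g, vals in genus_acc.items()}
    for h in level1:
        p = pools[h]
        eff = np.full((n_sp, len(TRAITS)), np.nan)
        for i in range(n_sp):
            if p["rank"][i] == "species":
                eff[i] = np.exp(p["log_traits"][i])
            elif p["rank"][i] == "genus":
                eff[i] = genus_means[p["genus"][i]]
        p["effective"] = eff
        p["traited_idx"] = np.flatnonzero(np.isfinite(eff).all(axis=1))
        p["traitless_idx"] = np.flatnonzero(p["rank"] == "none")

    veg_rows, flagged = [], []
    targets = dataset.responses.set_index("plot_id")
    hab1 = dataset.habitats.set_index("plot_id")["level1"]
    tol = pool_config.match_tol
    for pid in dataset.responses["plot_id"]:
        pool = pools[hab1[pid]]
        T = np.array([targets.loc[pid, f"log_cwm_{t}"] for t in TRAITS])
        idx = pool["traited_idx"]
        eff = pool["effective"][idx]
        has = np.isfinite(eff)
        if len(idx) <= 1:
            weights = np.ones(len(idx))
            err = _match_error(weights, eff, has, T) if len(idx) else np.inf
        else:
            logeff = np.where(has, np.log(np.where(has, eff, 1.0)), 0.0)
            d2 = np.where(has, (logeff - T) ** 2, 0.0).sum(axis=1)
            v0 = -d2 / 2.0
            res = minimize(_match_loss_grad, v0, args=(eff, has, T),
                           method="BFGS", jac=True,
                           options=dict(maxiter=400, gtol=1e-10))
            weights = _softmax(res.x)
            # prune near-zero covers if doing so keeps the match
            keep = weights > 1e-3
            if 2 <= keep.sum() < len(weights):
                pruned = np.where(keep, weights, 0.0)
                pruned = pruned / pruned.sum()
                if _match_error(pruned, eff, has, T) <= max(
                        tol, _match_error(weights, eff, has, T)):
                    weights, idx, eff, has = (pruned[keep], idx[keep],
                                              eff[keep], has[keep])
                    weights = weights / weights.sum()
            err = _match_error(weights, eff, has, T)
        if err > tol:
            flagged.append(pid)
        total = rng.uniform(*pool_config.total_cover_range)
        # traitless species dilute trait coverage but cannot move the CWM
        n_none = min(len(pool["traitless_idx"]),
                     rng.integers(0, 3) if len(idx) >= 2 else 0)
        none_pick = rng.choice(pool["traitless_idx"], size=n_none,
                               replace=False) if n_none else []
        none_share = rng.uniform(0.02, 0.10, size=n_none)
        trait_share = max(1.0 - none_share.sum(), 0.5)
        for i, w in zip(idx, weights):
            veg_rows.append((pid, pool["names"][i], pool["genus"][i],
                             max(w * trait_share * total, 1e-6)))
        for i, share in zip(none_pick, none_share):
            veg_rows.append((pid, pool["names"][i], pool["genus"][i],
                             share * total))

    vegetation = pd.DataFrame(veg_rows,
                              columns=["plot_id", "species", "genus", "cover"])
    return vegetation, trait_table, flagged


def _softmax(v):
    v = v - v.max()
    e = np.exp(v)
    return e / e.sum()


def _plot_log_cwm(weights, eff, has, j):
    wj = weights[has[:, j]]
    if wj.sum() <= 0:
        return np.nan
    return float(np.log(np.average(eff[has[:, j], j], weights=wj)))


def _match_error(weights, eff, has, T):
    errs = []
    for j in range(eff.shape[1]):
        v = _plot_log_cwm(weights, eff, has, j)
        if np.isfinite(v):
            errs.append(abs(v - T[j]))
    return max(errs) if errs else np.inf


def _match_loss(v, eff, has, T):
    return _match_loss_grad(v, eff, has, T)[0]


def _match_loss_grad(v, eff, has, T):
    """Loss and gradient of the softmax cover-matching objective."""
    w = _softmax(v)
    x = np.where(has, eff, 0.0)
    B = has.T @ w                      # trait-bearing weight per trait
    A = x.T @ w
    loss = 0.0
    dloss_dw = np.zeros_like(w)
    for j in range(eff.shape[1]):
        if B[j] <= 0 or A[j] <= 0:
            continue
        m = A[j] / B[j]
        r = np.log(m) - T[j]
        loss += r * r
        dloss_dw += 2.0 * r / m * has[:, j] * (x[:, j] - m) / B[j]
    grad = w * (dloss_dw - w @ dloss_dw)
    return loss, grad
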