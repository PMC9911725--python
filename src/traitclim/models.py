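"""The five-model hierarchy for one trait.

Model 1: fixed effects of the four climate PCs only (fitted on a balanced
subsample across the broad habitats).  Model 2 adds broad-habitat random
intercepts.  Models 3/4/5 add habitat random intercepts plus one random
habitat x PC slope block per climate PC, at the broad / intermediate /
narrow level respectively.  Every model may carry a low-rank
spline-on-the-sphere smooth of latitude and longitude as one extra
penalized component absorbing spatial dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._geo import haversine_km
from ._rng import rng_for
from .config import ModelOptions
from .lmm import RandomBlock, VarianceComponentsREML

__all__ = [
    "ModelDesign",
    "SpatialBasis",
    "FittedModel",
    "build_design",
    "spherical_smooth_basis",
    "fit_mixed_reml",
    "balanced_subsample",
    "MODEL_LEVEL",
]

N_PC = 4
#: habitat level whose random effects enter each model id (None = no random)
MODEL_LEVEL = {1: None, 2: 1, 3: 1, 4: 2, 5: 3}


@dataclass
class SpatialBasis:
    """Whitened low-rank radial basis on great-circle distance.

    ``basis`` is plots x k with one i.i.d. variance in the REML fit;
    ``penalty`` is the knot-kernel matrix the whitening was derived from.
    """

    knots: np.ndarray           # (k, 2) lat/lon
    basis: np.ndarray           # (n, k)
    penalty: np.ndarray         # (k, k) PSD kernel
    range_km: float
    k: int


@dataclass
class ModelDesign:
    model_id: int
    trait: str
    plot_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray               # n x 5: intercept + 4 PC scores
    blocks: list[RandomBlock]
    habitat_level: Optional[int]
    habitat_labels: Optional[np.ndarray]
    spatial: Optional[SpatialBasis] = None
    weights: Optional[np.ndarray] = None
    n_dropped: int = 0

    def all_blocks(self) -> list[RandomBlock]:
        out = list(self.blocks)
        if self.spatial is not None:
            out.append(RandomBlock(name="spatial", Z=self.spatial.basis,
                                   labels=[f"knot{i}" for i in range(self.spatial.k)]))
        return out


@dataclass
class FittedModel:
    """REML fit results in the vocabulary of the analysis."""

    model_id: int
    trait: str
    beta: pd.Series
    beta_se: pd.Series
    beta_cov: np.ndarray
    varcomp: dict
    sigma2: float
    blups: dict
    loglik_reml: float
    convergence: dict
    n_obs: int


def build_design(
    cwm: pd.DataFrame,
    trait_name: str,
    scores: pd.DataFrame,
    habitats: pd.DataFrame,
    meta: pd.DataFrame,
    model_id: int,
    options: ModelOptions | None = None,
) -> ModelDesign:
    """Assemble the complete-case design for one trait and model id."""
    options = options or ModelOptions()
    if model_id not in MODEL_LEVEL:
        raise ValueError(f"model_id must be in 1..5, got {model_id}")
    ycol = f"log_cwm_{trait_name}"
    if ycol not in cwm.columns:
        raise ValueError(f"trait column {ycol!r} absent from CWM table")

    df = cwm[["plot_id", ycol]].merge(
        scores[["plot_id", "pc1", "pc2", "pc3", "pc4"]], on="plot_id"
    )
    df = df.merge(habitats, on="plot_id", how="left")
    df = df.merge(meta[["plot_id", "latitude", "longitude"]], on="plot_id", how="left")
    if options.use_weights:
        wcol = f"coverage_{trait_name}"
        if wcol not in cwm.columns:
            raise ValueError(f"weight column {wcol!r} absent from CWM table")
        df = df.merge(cwm[["plot_id", wcol]], on="plot_id")

    level = MODEL_LEVEL[model_id]
    needed = [ycol, "pc1", "pc2", "pc3", "pc4"]
    if level is not None:
        needed.append(f"level{level}")
    if options.include_spatial:
        needed += ["latitude", "longitude"]
    n0 = len(df)
    df = df.dropna(subset=needed).reset_index(drop=True)
    n_dropped = n0 - len(df)

    y = df[ycol].to_numpy(dtype=float)
    S = df[["pc1", "pc2", "pc3", "pc4"]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), S])

    blocks: list[RandomBlock] = []
    habitat_labels = None
    if level is not None:
        habitat_labels = df[f"level{level}"].to_numpy()
        blocks.append(RandomBlock.from_groups(
            f"habitat_intercept_l{level}", habitat_labels))
        if model_id >= 3:
            for j in range(N_PC):
                blocks.append(RandomBlock.from_groups(
                    f"habitat_slope_pc{j + 1}_l{level}", habitat_labels,
                    covariate=S[:, j]))

    spatial = None
    if options.include_spatial:
        sub = df[["latitude", "longitude"]]
        spatial = spherical_smooth_basis(
            sub.rename(columns={"latitude": "latitude", "longitude": "longitude"}),
            k=min(options.spatial_k, sub.drop_duplicates().shape[0]),
            range_km=options.spatial_range_km,
            seed=options.subsample_seed,
        )

    weights = None
    if options.use_weights:
        weights = df[f"coverage_{trait_name}"].to_numpy(dtype=float)

    return ModelDesign(
        model_id=model_id, trait=trait_name,
        plot_ids=df["plot_id"].to_numpy(), y=y, X=X, blocks=blocks,
        habitat_level=level, habitat_labels=habitat_labels,
        spatial=spatial, weights=weights, n_dropped=n_dropped,
    )


def spherical_smooth_basis(
    meta: pd.DataFrame, k: int, range_km: float | None = None, seed: int = 0
) -> SpatialBasis:
    """Low-rank radial smooth of position on the sphere.

    Knots are a farthest-point (space-filling) subset of the observed plot
    locations under great-circle distance, started from a seeded draw.  The
    kernel is exponential, ``exp(-d / range_km)``, with the range defaulting
    to half the median plot-to-knot distance; the plot basis is whitened by
    the inverse Cholesky factor of the knot kernel so the smooth enters the
    REML fit as a single i.i.d.-variance component (a predictive-process /
    fixed-rank-kriging construction).
    """
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    pts = np.column_stack([lat, lon])
    uniq = np.unique(pts, axis=0)
    if k < 3:
        raise ValueError("k must be >= 3")
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds {len(uniq)} distinct locations")

    rng = rng_for(seed, "spatial-knots")
    start = int(rng.integers(len(uniq)))
    knot_idx = [start]
    d_min = haversine_km(uniq[:, 0], uniq[:, 1],
                         uniq[start:start + 1, 0], uniq[start:start + 1, 1]).ravel()
    for _ in range(k - 1):
        nxt = int(np.argmax(d_min))
        knot_idx.append(nxt)
        d_new = haversine_km(uniq[:, 0], uniq[:, 1],
                             uniq[nxt:nxt + 1, 0], uniq[nxt:nxt + 1, 1]).ravel()
        d_min = np.minimum(d_min, d_new)
    knots = uniq[knot_idx]

    D_nk = haversine_km(lat, lon, knots[:, 0], knots[:, 1])
    if range_km is None:
        range_km = max(float(np.median(D_nk)) / 2.0, 1.0)
    C_nk = np.exp(-D_nk / range_km)
    D_kk = haversine_km(knots[:, 0], knots[:, 1], knots[:, 0], knots[:, 1])
    K = np.exp(-D_kk / range_km)
    jitter = 1e-8 * np.trace(K) / k
    L = np.linalg.cholesky(K + jitter * np.eye(k))
    # whiten: with b ~ N(0, s2 I), basis @ b has covariance s2 * C K^-1 C'
    from scipy.linalg import solve_triangular

    basis = solve_triangular(L, C_nk.T, lower=True).T
    return SpatialBasis(knots=knots, basis=basis, penalty=K,
                        range_km=float(range_km), k=k)


def fit_mixed_reml(design: ModelDesign, options: ModelOptions | None = None) -> FittedModel:
    """Fit one assembled design by REML and package the results."""
    options = options or ModelOptions()
    est = VarianceComponentsREML(max_iter=options.max_iter, rel_tol=options.rel_tol)
    est.fit(design.X, design.y, blocks=design.all_blocks(), weights=design.weights)
    names = ["intercept", "pc1", "pc2", "pc3", "pc4"]
    return FittedModel(
        model_id=design.model_id, trait=design.trait,
        beta=pd.Series(est.beta_, index=names),
        beta_se=pd.Series(est.beta_se_, index=names),
        beta_cov=est.beta_cov_,
        varcomp=dict(est.varcomp_), sigma2=est.sigma2_,
        blups=est.blups_, loglik_reml=est.loglik_reml_,
        convergence=dict(est.convergence_), n_obs=est.n_obs_,
    )


def balanced_subsample(habitats: pd.DataFrame, level: int = 1, seed: int = 0) -> np.ndarray:
    """Equal-sized random subsample across habitats at one level.

    Draws ``n_min`` (the smallest group size) plots without replacement
    from every habitat group, so no habitat dominates the across-habitat
    fixed-effect fit.
    """
    col = f"level{level}"
    if col not in habitats.columns:
        raise ValueError(f"habitat table lacks {col}")
    grp = habitats.dropna(subset=[col]).groupby(col)["plot_id"]
    sizes = grp.size()
    if len(sizes) == 0 or (sizes == 0).any():
        raise ValueError("every habitat group must contain at least one plot")
    n_min = int(sizes.min())
    rng = rng_for(seed, f"balanced-subsample-l{level}")
    keep: list[np.ndarray] = []
    for _, ids in sorted(grp, key=lambda kv: str(kv[0])):
        arr = ids.to_numpy()
        keep.append(rng.choice(arr, size=n_min, replace=False))
    return np.concatenate(keep)
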