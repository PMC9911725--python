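"""Configuration objects for synthetic generation and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

#: The four community traits analysed throughout the package, with the
#: baseline (intercept) of each log-scale community-weighted mean.  Units:
#: plant height in m, SLA in mm^2/mg, seed mass in mg, SRL in m/g.
TRAITS = ("plant_height", "sla", "seed_mass", "srl")
TRAIT_LOG_BASELINES = {
    "plant_height": 0.0,   # ~1 m
    "sla": 3.0,            # ~20 mm^2/mg
    "seed_mass": 0.5,      # ~1.6 mg
    "srl": 4.6,            # ~100 m/g
}

N_BIOCLIM = 19
BIOCLIM_VARS = tuple(f"bio{i:02d}" for i in range(1, N_BIOCLIM + 1))


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Generating parameters of the synthetic landscape and response model.

    The response model for each trait is the linear mixed model

        y_i = b0 + sum_j beta_j * s_ij + a_{h(i)} + sum_j b_{h(i),j} * s_ij
              + f(lat_i, lon_i) + e_i

    with ``s_ij`` the plot's score on climate PC j, habitat random
    intercepts ``a_h ~ N(0, tau0_sq)`` and random slopes
    ``b_hj ~ N(0, tau1_sq[j])`` at ``effect_level`` of the habitat
    hierarchy, an optional Gaussian-process spatial field ``f`` and i.i.d.
    residuals ``e_i ~ N(0, sigma_sq)``.
    """

    n_plots: int = 6000
    n_habitats_per_level: tuple[int, int, int] = (8, 16, 48)
    lat_range: tuple[float, float] = (34.0, 71.0)
    lon_range: tuple[float, float] = (-10.0, 30.0)
    year_range: tuple[int, int] = (1960, 2020)
    n_climate_vars: int = N_BIOCLIM
    n_latent_gradients: int = 4
    climate_noise_sd: float = 0.45
    beta: tuple[float, ...] = (0.30, -0.20, 0.10, 0.0)
    tau0_sq: float = 0.50
    tau1_sq: tuple[float, ...] = (0.20, 0.0, 0.0, 0.0)
    sigma_sq: float = 1.0
    effect_level: int = 3
    intercept_slope_corr: float = 0.0
    spatial_sd: float = 0.0
    spatial_range_km: float = 300.0
    spatial_n_knots: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        l1, l2, l3 = self.n_habitats_per_level
        if not (1 <= l1 <= l2 <= l3):
            raise ConfigurationError(
                f"habitat counts must be non-decreasing, got {self.n_habitats_per_level}"
            )
        if l2 % l1 or l3 % l2:
            raise ConfigurationError(
                "nesting must be divisible: each child level a multiple of its "
                f"parent, got {self.n_habitats_per_level}"
            )
        if self.n_plots < 1:
            raise ConfigurationError("n_plots must be positive")
        if self.n_latent_gradients > self.n_climate_vars:
            raise ConfigurationError("n_latent_gradients must be <= n_climate_vars")
        if not 1 <= self.n_latent_gradients <= 4:
            raise ConfigurationError("n_latent_gradients must be in 1..4")
        if len(self.beta) != 4 or len(self.tau1_sq) != 4:
            raise ConfigurationError("beta and tau1_sq must have one entry per climate PC (4)")
        for name in ("tau0_sq", "sigma_sq", "spatial_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(t < 0 for t in self.tau1_sq):
            raise ConfigurationError("tau1_sq entries must be >= 0")
        if self.effect_level not in (1, 2, 3):
            raise ConfigurationError("effect_level must be 1, 2 or 3")
        if not -1.0 < self.intercept_slope_corr < 1.0:
            raise ConfigurationError("intercept_slope_corr must lie in (-1, 1)")


@dataclass
class PoolConfig:
    """Community-mode species pools: habitat-specific log-normal traits."""

    species_per_habitat: int = 40
    species_per_plot: int = 10
    trait_log_sd: float = 1.0
    habitat_shift_sd: float = 0.3
    #: fraction of pool species published without species-level traits
    #: (their genus still carries trait means)
    genus_only_fraction: float = 0.10
    #: fraction of pool species with no trait information at any rank
    traitless_fraction: float = 0.05
    match_tol: float = 0.05
    total_cover_range: tuple[float, float] = (60.0, 100.0)

    def validate(self) -> None:
        if self.species_per_habitat < 1 or self.species_per_plot < 2:
            raise ConfigurationError("pools need >=1 species and plots >=2")
        if not 0 <= self.genus_only_fraction + self.traitless_fraction <= 1:
            raise ConfigurationError("missing-trait fractions must sum within [0, 1]")
        if self.match_tol <= 0:
            raise ConfigurationError("match_tol must be positive")


@dataclass
class ModelOptions:
    """Fitting options shared by the five-model hierarchy."""

    include_spatial: bool = False
    spatial_k: int = 100
    spatial_range_km: Optional[float] = None
    use_weights: bool = False
    max_iter: int = 500
    rel_tol: float = 1e-8
    min_n_slope: int = 100
    subsample_seed: int = 0


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration."""

    mode: str = "synthetic"  # or "tables"
    out_dir: str = "traitclim_run"
    seed: int = 0
    traits: Sequence[str] = TRAITS
    models: Sequence[int] = (1, 2, 3, 4, 5)
    n_pca_components: int = 4
    coverage_threshold: float = 0.80
    lat_bounds: tuple[float, float] = (34.0, 82.0)
    cell_deg: float = 0.01
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    table_paths: dict = field(default_factory=dict)
    model_options: ModelOptions = field(default_factory=ModelOptions)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "tables"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ConfigurationError(f"unknown traits {sorted(unknown)}")
        bad = set(self.models) - {1, 2, 3, 4, 5}
        if bad:
            raise ConfigurationError(f"model ids must be in 1..5, got {sorted(bad)}")
        if self.mode == "tables":
            required = {"vegetation", "plots", "traits", "climate", "habitats"}
            missing = required - set(self.table_paths)
            if missing:
                raise ConfigurationError(f"tables mode needs paths for {sorted(missing)}")
        self.synthetic.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("synthetic", {}).items()
        })
        opts = ModelOptions(**raw.pop("model_options", {}))
        for key in ("traits", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("lat_bounds",):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(synthetic=syn, model_options=opts, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
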