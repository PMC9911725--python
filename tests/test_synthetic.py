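import numpy as np
import pandas as pd
import pytest

from traitclim import (PoolConfig, SyntheticConfig, assign_traits, compute_cwm,
                       expected_variance_components, generate_communities,
                       generate_dataset)
from traitclim.config import ConfigurationError, TRAITS
from traitclim.synthetic import direct_mode_cwm_table


class TestConfigValidation:
    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(sigma_sq=-1.0)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(tau1_sq=(0.1, -0.1, 0, 0))

    def test_non_divisible_nesting_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_habitats_per_level=(8, 40, 216))
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_habitats_per_level=(8, 4, 16))


class TestGenerateDataset:
    def test_zero_slope_variance_means_common_slope(self):
        cfg = SyntheticConfig(n_plots=200, tau1_sq=(0.0, 0.0, 0.0, 0.0), seed=1)
        ds = generate_dataset(cfg)
        for t in TRAITS:
            assert np.all(ds.truth["slope_dev"][t] == 0.0)

    def test_same_seed_byte_identical(self):
        cfg = SyntheticConfig(n_plots=300, seed=9)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        for name in ("plots", "climate", "habitats", "responses", "scores"):
            assert getattr(a, name).to_csv(index=False) == \
                getattr(b, name).to_csv(index=False)

    def test_truth_reconstructs_responses_exactly(self, small_dataset):
        ds = small_dataset
        tr = ds.truth
        S = ds.scores[["pc1", "pc2", "pc3", "pc4"]].to_numpy()
        from traitclim.config import TRAIT_LOG_BASELINES

        for t in TRAITS:
            y = (TRAIT_LOG_BASELINES[t] + tr["fixed_part"]
                 + tr["intercept_dev"][t][tr["effect_index"]]
                 + np.einsum("ij,ij->i", S, tr["slope_dev"][t][tr["effect_index"]])
                 + tr["spatial_field"] + tr["residuals"][t])
            np.testing.assert_allclose(
                y, ds.responses[f"log_cwm_{t}"].to_numpy(), rtol=0, atol=1e-12)

    def test_nested_labels_consistent(self, small_dataset):
        hab = small_dataset.habitats
        assert (hab.groupby("level3")["level2"].nunique() == 1).all()
        assert (hab.groupby("level2")["level1"].nunique() == 1).all()

    def test_fixed_variance_share_matches_formula(self):
        """Empirical variance decomposition of the generated response matches
        the analytic ratio built from the generating variances."""
        cfg = SyntheticConfig(
            n_plots=20_000, beta=(1.0, 0.0, 0.0, 0.0), tau0_sq=1.0,
            tau1_sq=(0.0, 0.0, 0.0, 0.0), sigma_sq=1.0, seed=77,
        )
        ds = generate_dataset(cfg)
        truth = expected_variance_components(cfg, ds.scores)
        y = ds.responses["log_cwm_sla"].to_numpy()
        fixed = ds.truth["fixed_part"]
        empirical_share = np.var(fixed) / np.var(y)
        assert empirical_share == pytest.approx(truth.r2_marginal, abs=0.02)

    def test_pca_recovers_latent_dimension(self, small_dataset):
        evr = small_dataset.pca.explained_variance_ratio_
        assert evr[:4].sum() > 0.80       # four latent gradients dominate
        assert evr[4] < evr[3]


class TestExpectedVarianceComponents:
    def test_no_signal_gives_zero_r2(self):
        cfg = SyntheticConfig(beta=(0, 0, 0, 0), tau0_sq=0.0,
                              tau1_sq=(0, 0, 0, 0), sigma_sq=1.0)
        scores = np.random.default_rng(0).standard_normal((100, 4))
        ts = expected_variance_components(cfg, scores)
        assert ts.r2_marginal == 0.0
        assert ts.r2_conditional == 0.0

    def test_closed_form_thirds(self):
        """Unit-variance PC1 with beta=1, tau0=1, sigma=1 splits variance
        into exactly 1/3 fixed and 2/3 fixed+random."""
        cfg = SyntheticConfig(beta=(1.0, 0, 0, 0), tau0_sq=1.0,
                              tau1_sq=(0, 0, 0, 0), sigma_sq=1.0)
        scores = np.zeros((10, 4))
        scores[:, 0] = np.tile([1.0, -1.0], 5)   # population variance exactly 1
        ts = expected_variance_components(cfg, scores)
        assert ts.r2_marginal == pytest.approx(1 / 3, abs=1e-12)
        assert ts.r2_conditional == pytest.approx(2 / 3, abs=1e-12)

    def test_more_noise_strictly_lowers_both_r2(self):
        scores = np.random.default_rng(1).standard_normal((50, 4))
        a = expected_variance_components(
            SyntheticConfig(sigma_sq=1.0), scores)
        b = expected_variance_components(
            SyntheticConfig(sigma_sq=2.0), scores)
        assert b.r2_marginal < a.r2_marginal
        assert b.r2_conditional < a.r2_conditional

    def test_r2_bounds_and_order(self, small_dataset):
        ts = expected_variance_components(small_dataset.config,
                                          small_dataset.scores)
        assert 0 <= ts.r2_marginal <= ts.r2_conditional <= 1

    def test_empty_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            expected_variance_components(SyntheticConfig(), np.empty((0, 4)))


class TestGenerateCommunities:
    def test_unflagged_plots_match_targets(self, community_fixture):
        """Recomputing the CWM from the emitted cover table reproduces each
        unflagged plot's direct-mode target within the match tolerance."""
        ds = community_fixture["dataset"]
        veg, traits = community_fixture["vegetation"], community_fixture["traits"]
        flagged = set(community_fixture["flagged"])
        cwm = compute_cwm(veg, assign_traits(veg, traits))
        merged = cwm.merge(ds.responses, on="plot_id", suffixes=("", "_target"))
        ok = ~merged["plot_id"].isin(flagged)
        assert ok.sum() > 0.5 * len(merged)
        for t in TRAITS:
            err = (merged[f"log_cwm_{t}"] - merged[f"log_cwm_{t}_target"]).abs()
            assert err[ok].max() <= PoolConfig().match_tol + 1e-9

    def test_every_plot_has_at_least_two_species(self, community_fixture):
        sizes = community_fixture["vegetation"].groupby("plot_id").size()
        assert sizes.min() >= 2

    def test_no_missing_traits_gives_full_coverage(self):
        cfg = SyntheticConfig(n_plots=25, n_habitats_per_level=(2, 4, 8),
                              beta=(0.05, 0, 0, 0), tau0_sq=0.02,
                              tau1_sq=(0, 0, 0, 0), sigma_sq=0.05, seed=8)
        ds = generate_dataset(cfg)
        veg, traits, _ = generate_communities(
            ds, PoolConfig(genus_only_fraction=0.0, traitless_fraction=0.0),
            seed=8)
        cwm = compute_cwm(veg, assign_traits(veg, traits))
        assert np.allclose(cwm["coverage_min"], 1.0)

    def test_single_species_pool_yields_that_species_cwm(self):
        cfg = SyntheticConfig(n_plots=6, n_habitats_per_level=(1, 1, 1),
                              beta=(0, 0, 0, 0), tau0_sq=0.0,
                              tau1_sq=(0, 0, 0, 0), sigma_sq=0.01, seed=3)
        ds = generate_dataset(cfg)
        veg, traits, flagged = generate_communities(
            ds, PoolConfig(species_per_habitat=1, species_per_plot=2,
                           genus_only_fraction=0.0, traitless_fraction=0.0),
            seed=3)
        cwm = compute_cwm(veg, assign_traits(veg, traits))
        sp = traits[traits.taxon_rank == "species"].iloc[0]
        for t in TRAITS:
            assert np.allclose(cwm[f"cwm_{t}"], sp[t])

    def test_direct_mode_table_round_trips_log(self, small_dataset):
        cwm = direct_mode_cwm_table(small_dataset)
        for t in TRAITS:
            np.testing.assert_allclose(np.log(cwm[f"cwm_{t}"]),
                                       cwm[f"log_cwm_{t}"], atol=1e-12)
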