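import numpy as np
import pandas as pd
import pytest

from traitclim.inference import classify_and_tally, marginal_slopes, r2_partition
from traitclim.models import (FittedModel, ModelDesign, build_design,
                              fit_mixed_reml)
from traitclim.config import ModelOptions
from traitclim.synthetic import direct_mode_cwm_table


def _fake_fit(blup, cond_se, n_per_habitat, beta_pc1=0.5, se_pc1=0.2):
    """Hand-built model-3 fit with one level-1 habitat per entry of blup."""
    habitats = [f"H{i+1}" for i in range(len(blup))]
    names = ["intercept", "pc1", "pc2", "pc3", "pc4"]
    beta = pd.Series([0.0, beta_pc1, 0.0, 0.0, 0.0], index=names)
    se = pd.Series([0.1, se_pc1, 0.1, 0.1, 0.1], index=names)
    blups = {"habitat_intercept_l1": dict(labels=habitats,
                                          estimate=np.zeros(len(blup)),
                                          cond_se=np.ones(len(blup)) * 0.1,
                                          cov_with_beta=np.zeros((len(blup), 5)))}
    for j in range(1, 5):
        est = np.array(blup) if j == 1 else np.zeros(len(blup))
        cse = np.array(cond_se) if j == 1 else np.full(len(blup), 0.05)
        blups[f"habitat_slope_pc{j}_l1"] = dict(
            labels=habitats, estimate=est, cond_se=cse,
            cov_with_beta=np.zeros((len(blup), 5)))
    labels = np.concatenate([np.full(n, h)
                             for h, n in zip(habitats, n_per_habitat)])
    n = len(labels)
    design = ModelDesign(model_id=3, trait="sla",
                         plot_ids=np.arange(n).astype(str),
                         y=np.zeros(n), X=np.column_stack([np.ones(n)] * 5),
                         blocks=[], habitat_level=1, habitat_labels=labels)
    fit = FittedModel(model_id=3, trait="sla", beta=beta, beta_se=se,
                      beta_cov=np.zeros((5, 5)), varcomp={}, sigma2=1.0,
                      blups=blups, loglik_reml=0.0, convergence={}, n_obs=n)
    return fit, design


class TestMarginalSlopes:
    def test_zero_blup_gives_fixed_slope(self):
        fit, design = _fake_fit([0.0], [0.1], [200])
        out = marginal_slopes(fit, design, min_n=100)
        row = out[(out.habitat == "H1") & (out.pc == 1)].iloc[0]
        assert row.slope == pytest.approx(0.5)

    def test_ci_arithmetic_and_significance(self):
        """slope 0.5, se 0.2 -> CI [0.108, 0.892], significant."""
        fit, design = _fake_fit([0.0], [0.0], [200], beta_pc1=0.5, se_pc1=0.2)
        out = marginal_slopes(fit, design, min_n=100, include_cov_term=False)
        row = out[(out.habitat == "(all)") & (out.pc == 1)].iloc[0]
        assert row.ci_low == pytest.approx(0.108)
        assert row.ci_high == pytest.approx(0.892)
        assert bool(row.significant)

    def test_fewer_than_min_n_plots_suppressed(self):
        fit, design = _fake_fit([0.3, 0.3], [0.01, 0.01], [99, 100])
        out = marginal_slopes(fit, design, min_n=100)
        by_hab = out[out.pc == 1].set_index("habitat")
        assert bool(by_hab.loc["H1", "suppressed"])
        assert not bool(by_hab.loc["H2", "suppressed"])
        # suppressed estimates carry no significance claim
        assert not bool(by_hab.loc["H1", "significant"])

    def test_se_combines_fixed_and_conditional_parts(self):
        fit, design = _fake_fit([0.1], [0.3], [500], se_pc1=0.4)
        out = marginal_slopes(fit, design, min_n=100, include_cov_term=False)
        row = out[(out.habitat == "H1") & (out.pc == 1)].iloc[0]
        assert row.se == pytest.approx(np.hypot(0.4, 0.3))
        assert row.se_formula == "fixed+blup"

    def test_models_without_random_slopes_rejected(self, small_dataset):
        cwm = direct_mode_cwm_table(small_dataset)
        design = build_design(cwm, "sla", small_dataset.scores,
                              small_dataset.habitats, small_dataset.plots, 2)
        fit = fit_mixed_reml(design)
        with pytest.raises(ValueError, match="models 3-5"):
            marginal_slopes(fit, design)


class TestClassifyAndTally:
    def _slopes(self):
        rows = [
            ("A.1", 0.5, 0.1, False),   # positive significant
            ("A.2", 0.4, 0.1, False),   # positive significant
            ("A.3", -0.5, 0.1, False),  # negative significant
            ("A.4", 0.05, 0.1, False),  # nonsignificant
            ("A.5", 0.9, 0.1, True),    # suppressed
        ]
        df = pd.DataFrame(rows, columns=["habitat", "slope", "se", "suppressed"])
        df["level"] = 2
        df["pc"] = 1
        df["trait"] = "sla"
        df["ci_low"] = df.slope - 1.96 * df.se
        df["ci_high"] = df.slope + 1.96 * df.se
        df["significant"] = ((df.ci_low > 0) | (df.ci_high < 0)) & ~df.suppressed
        return df

    def _habitats(self):
        return pd.DataFrame(dict(
            plot_id=[f"p{i}" for i in range(5)],
            level1=["A"] * 5,
            level2=[f"A.{i+1}" for i in range(5)],
            level3=[f"A.{i+1}.1" for i in range(5)],
        ))

    def test_fixture_counts(self):
        tally = classify_and_tally(self._slopes(), self._habitats())
        row = tally.iloc[0]
        assert (row.n_pos_sig, row.n_neg_sig, row.n_nonsig,
                row.n_suppressed) == (2, 1, 1, 1)

    def test_counts_partition_children(self):
        tally = classify_and_tally(self._slopes(), self._habitats())
        row = tally.iloc[0]
        assert row[["n_pos_sig", "n_neg_sig", "n_nonsig",
                    "n_suppressed"]].sum() == 5

    def test_ci_spanning_zero_is_nonsignificant(self):
        df = self._slopes().iloc[[3]]
        assert not df["significant"].iloc[0]
        tally = classify_and_tally(df, self._habitats())
        assert tally.iloc[0].n_nonsig == 1

    def test_input_order_invariance(self):
        slopes = self._slopes()
        a = classify_and_tally(slopes, self._habitats())
        b = classify_and_tally(slopes.sample(frac=1, random_state=3),
                               self._habitats())
        pd.testing.assert_frame_equal(a, b)

    def test_missing_parent_mapping_rejected(self):
        habitats = self._habitats().iloc[:3]  # A.4, A.5 unmapped
        with pytest.raises(ValueError, match="parent"):
            classify_and_tally(self._slopes(), habitats)


class TestR2Partition:
    def test_fixed_effects_only_identity(self, small_dataset):
        cwm = direct_mode_cwm_table(small_dataset)
        design = build_design(cwm, "plant_height", small_dataset.scores,
                              small_dataset.habitats, small_dataset.plots, 1)
        fit = fit_mixed_reml(design)
        vd = r2_partition(fit, design)
        expected = vd.sigma2_fixed / (vd.sigma2_fixed + fit.sigma2)
        assert vd.r2_marginal == pytest.approx(expected, rel=1e-10)
        assert vd.r2_conditional == pytest.approx(expected, rel=1e-10)

    def test_random_intercept_closed_form(self, small_dataset):
        cwm = direct_mode_cwm_table(small_dataset)
        design = build_design(cwm, "plant_height", small_dataset.scores,
                              small_dataset.habitats, small_dataset.plots, 2)
        fit = fit_mixed_reml(design)
        vd = r2_partition(fit, design)
        tau0 = fit.varcomp["habitat_intercept_l1"]
        total = vd.sigma2_fixed + tau0 + fit.sigma2
        assert vd.r2_conditional - vd.r2_marginal == pytest.approx(
            tau0 / total, rel=1e-8)
        # without slope blocks the climate share is the fixed share
        assert vd.r2_climate == pytest.approx(vd.r2_marginal, rel=1e-12)

    def test_shares_partition_unity(self, small_dataset):
        cwm = direct_mode_cwm_table(small_dataset)
        design = build_design(cwm, "srl", small_dataset.scores,
                              small_dataset.habitats, small_dataset.plots, 5)
        fit = fit_mixed_reml(design)
        vd = r2_partition(fit, design)
        total = (vd.sigma2_fixed + sum(vd.sigma2_random.values())
                 + vd.sigma2_residual)
        resid_share = vd.sigma2_residual / total
        spatial_share = vd.sigma2_random.get("spatial", 0.0) / total
        assert vd.r2_climate + vd.r2_habitat + spatial_share + resid_share \
            == pytest.approx(1.0, abs=1e-10)
        assert vd.r2_marginal <= vd.r2_conditional <= 1.0

    def test_spatial_counts_only_toward_conditional(self, small_dataset):
        cwm = direct_mode_cwm_table(small_dataset)
        opts = ModelOptions(include_spatial=True, spatial_k=25)
        design = build_design(cwm, "plant_height", small_dataset.scores,
                              small_dataset.habitats, small_dataset.plots, 2,
                              opts)
        fit = fit_mixed_reml(design, opts)
        vd = r2_partition(fit, design)
        assert "spatial" in vd.sigma2_random
        total = (vd.sigma2_fixed + sum(vd.sigma2_random.values())
                 + vd.sigma2_residual)
        # climate share excludes the smooth entirely
        assert vd.r2_climate == pytest.approx(vd.sigma2_fixed / total, rel=1e-10)
        # conditional includes it
        assert vd.r2_conditional == pytest.approx(
            (total - vd.sigma2_residual) / total, rel=1e-10)

    def test_fitted_r2_tracks_generating_r2(self, small_dataset):
        """The fitted marginal R² sits near the generating one."""
        from traitclim import expected_variance_components

        truth = expected_variance_components(small_dataset.config,
                                             small_dataset.scores)
        cwm = direct_mode_cwm_table(small_dataset)
        design = build_design(cwm, "seed_mass", small_dataset.scores,
                              small_dataset.habitats, small_dataset.plots, 5)
        vd = r2_partition(fit_mixed_reml(design), design)
        assert vd.r2_marginal == pytest.approx(truth.r2_marginal, abs=0.05)
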