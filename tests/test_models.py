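import numpy as np
import pandas as pd
import pytest

from traitclim.config import ModelOptions
from traitclim.models import (balanced_subsample, build_design, fit_mixed_reml,
                              spherical_smooth_basis)
from traitclim.synthetic import direct_mode_cwm_table


@pytest.fixture(scope="module")
def design_inputs(small_dataset):
    ds = small_dataset
    return dict(cwm=direct_mode_cwm_table(ds), scores=ds.scores,
                habitats=ds.habitats, meta=ds.plots)


class TestBuildDesign:
    def test_model1_has_no_random_blocks(self, design_inputs):
        d = build_design(design_inputs["cwm"], "sla", design_inputs["scores"],
                         design_inputs["habitats"], design_inputs["meta"], 1)
        assert d.blocks == []
        assert d.habitat_level is None

    def test_model3_block_structure(self, design_inputs):
        d = build_design(design_inputs["cwm"], "sla", design_inputs["scores"],
                         design_inputs["habitats"], design_inputs["meta"], 3)
        assert len(d.blocks) == 5  # 1 intercept + 4 slope blocks
        n_l1 = design_inputs["habitats"]["level1"].nunique()
        assert all(b.q == n_l1 for b in d.blocks)

    def test_fixed_design_always_five_columns(self, design_inputs):
        for mid in (1, 2, 3, 4, 5):
            d = build_design(design_inputs["cwm"], "srl",
                             design_inputs["scores"], design_inputs["habitats"],
                             design_inputs["meta"], mid)
            assert d.X.shape[1] == 5
            np.testing.assert_allclose(d.X[:, 0], 1.0)

    def test_invalid_model_or_trait_rejected(self, design_inputs):
        with pytest.raises(ValueError, match="model_id"):
            build_design(design_inputs["cwm"], "sla", design_inputs["scores"],
                         design_inputs["habitats"], design_inputs["meta"], 6)
        with pytest.raises(ValueError, match="absent"):
            build_design(design_inputs["cwm"], "leaf_noise",
                         design_inputs["scores"], design_inputs["habitats"],
                         design_inputs["meta"], 1)


class TestSphericalSmoothBasis:
    def test_basis_has_k_columns(self, small_dataset):
        basis = spherical_smooth_basis(small_dataset.plots, k=25, seed=1)
        assert basis.basis.shape == (len(small_dataset.plots), 25)
        assert basis.penalty.shape == (25, 25)
        # penalty symmetric PSD
        np.testing.assert_allclose(basis.penalty, basis.penalty.T)
        assert np.linalg.eigvalsh(basis.penalty).min() > -1e-10

    def test_longitude_shift_leaves_basis_unchanged(self, small_dataset):
        meta = small_dataset.plots.copy()
        shifted = meta.assign(longitude=meta.longitude + 15.0)
        a = spherical_smooth_basis(meta, k=20, range_km=300.0, seed=2)
        b = spherical_smooth_basis(shifted, k=20, range_km=300.0, seed=2)
        np.testing.assert_allclose(a.basis, b.basis, atol=1e-8)

    def test_plot_on_knot_attains_kernel_at_zero(self, small_dataset):
        basis = spherical_smooth_basis(small_dataset.plots, k=10,
                                       range_km=500.0, seed=3)
        lat0, lon0 = basis.knots[0]
        meta = pd.DataFrame(dict(latitude=[lat0], longitude=[lon0]))
        from traitclim._geo import haversine_km

        d = haversine_km([lat0], [lon0], basis.knots[:, 0],
                         basis.knots[:, 1]).ravel()
        assert d[0] == pytest.approx(0.0, abs=1e-9)  # kernel argument is 0

    def test_k_exceeding_locations_rejected(self):
        meta = pd.DataFrame(dict(latitude=[50.0, 51.0, 52.0],
                                 longitude=[5.0, 6.0, 7.0]))
        with pytest.raises(ValueError, match="exceeds"):
            spherical_smooth_basis(meta, k=4)


class TestSuperfluousSmooth:
    def test_spatial_basis_harmless_without_spatial_signal(self, design_inputs):
        """With no generated spatial field, adding the smooth moves the
        fixed slopes by less than one standard error."""
        args = (design_inputs["cwm"], "plant_height", design_inputs["scores"],
                design_inputs["habitats"], design_inputs["meta"], 3)
        plain = fit_mixed_reml(build_design(*args))
        opts = ModelOptions(include_spatial=True, spatial_k=30)
        smooth = fit_mixed_reml(build_design(*args, opts), opts)
        for pc in ("pc1", "pc2", "pc3", "pc4"):
            delta = abs(plain.beta[pc] - smooth.beta[pc])
            assert delta < plain.beta_se[pc]


class TestBalancedSubsample:
    def _habitats(self, sizes):
        rows = []
        for name, n in sizes.items():
            for i in range(n):
                rows.append((f"{name}_{i}", name))
        return pd.DataFrame(rows, columns=["plot_id", "level1"])

    def test_minimum_group_size_drawn_from_each(self):
        hab = self._habitats({"A": 50, "B": 30, "C": 29})
        ids = balanced_subsample(hab, level=1, seed=1)
        sub = hab[hab.plot_id.isin(ids)]
        assert sub.groupby("level1").size().tolist() == [29, 29, 29]

    def test_equal_groups_keep_everything(self):
        hab = self._habitats({"A": 10, "B": 10})
        ids = balanced_subsample(hab, level=1, seed=2)
        assert set(ids) == set(hab.plot_id)

    def test_same_seed_same_subsample(self):
        hab = self._habitats({"A": 40, "B": 25})
        assert set(balanced_subsample(hab, seed=5)) == \
            set(balanced_subsample(hab, seed=5))

    def test_missing_level_rejected(self):
        hab = self._habitats({"A": 5})
        with pytest.raises(ValueError, match="level3"):
            balanced_subsample(hab, level=3)
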