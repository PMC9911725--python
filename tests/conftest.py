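import numpy as np
import pandas as pd
import pytest

from traitclim import PoolConfig, SyntheticConfig, generate_communities, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Direct-mode landscape small enough for fast model fits."""
    cfg = SyntheticConfig(n_plots=800, n_habitats_per_level=(4, 8, 16), seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def community_fixture():
    """Community-mode tables under a modest-variance generating model.

    Low variances keep most plots' CWM targets inside the convex hull of
    their habitat's species pool, so the cover inversion succeeds for the
    bulk of plots.
    """
    cfg = SyntheticConfig(
        n_plots=80, n_habitats_per_level=(4, 8, 16), seed=5,
        beta=(0.08, -0.04, 0.02, 0.0), tau0_sq=0.04,
        tau1_sq=(0.004, 0.0, 0.0, 0.0), sigma_sq=0.09,
    )
    dataset = generate_dataset(cfg)
    veg, traits, flagged = generate_communities(dataset, PoolConfig(), seed=5)
    return dict(dataset=dataset, vegetation=veg, traits=traits, flagged=flagged)


@pytest.fixture()
def seven_plot_fixture():
    """Seven plots, six violating exactly one exclusion rule, one clean."""
    meta = pd.DataFrame(
        dict(
            plot_id=[f"p{i}" for i in range(1, 8)],
            latitude=[50.0, np.nan, 61.0, 30.0, 50.0, 50.0, 50.0],
            longitude=[5.0, 5.0, 11.0, 5.0, 5.0, 5.0, 5.0],
            survey_year=[2000] * 7,
            abundance_type=["presence_absence"] + ["cover"] * 6,
        )
    )
    coverage = pd.Series(
        [1.0, 1.0, 1.0, 1.0, 0.5, 1.0, 1.0], index=meta["plot_id"]
    )
    climate_ids = [p for p in meta["plot_id"] if p != "p6"]
    climate = pd.DataFrame({"plot_id": climate_ids})
    rules = dict(region_exclusion=dict(lat_min=60.0, lat_max=62.0,
                                       lon_min=10.0, lon_max=12.0))
    return meta, coverage, climate, rules
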