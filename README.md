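# traitclim

Habitat-hierarchical analysis of climate effects on the functional-trait
composition of plant communities.

Macroclimate is expected to shape which plant strategies dominate a site,
yet across broad data sets climate explains surprisingly little of the
variation in community-weighted trait means (CWMs).  One explanation is
that climate–trait relationships are *habitat-specific*: local factors
(soil, disturbance, land use, species pools) differ between habitats and
mask the climatic signal unless communities are compared within
increasingly narrow habitat definitions.  `traitclim` provides a tested
pipeline to quantify exactly that, for ecologists working with
vegetation-plot archives: from species cover tables to CWMs of four key
traits (plant height, specific leaf area, seed mass, specific root
length), climate principal components, random-slope mixed models at three
nesting levels of a habitat hierarchy, habitat-specific marginal slopes,
and marginal/conditional R² variance partitioning — plus a synthetic-data
generator with known ground truth that validates every statistical step by
parameter recovery.

## The model

For plot *i* with habitat *h(i)* and climate-PC scores *s_i1…s_i4*, the
log CWM of one trait follows

    y_i = β0 + Σ_j β_j s_ij + a_h(i) + Σ_j b_h(i),j s_ij + f(lat_i, lon_i) + ε_i

with habitat random intercepts `a_h ~ N(0, τ0²)`, habitat-specific random
slopes `b_hj ~ N(0, τ1j²)`, an optional low-rank spline-on-the-sphere
smooth *f* absorbing spatial dependence, and residuals
`ε_i ~ N(0, σ²/w_i)` (weights default to 1; optionally the plot's trait
coverage).  Five models per trait span the hierarchy: climate only
(model 1, on a balanced habitat subsample), + broad-habitat intercepts
(model 2), + habitat × PC random slopes at the broad / intermediate /
narrow level (models 3/4/5).  Estimation is restricted maximum likelihood
over the variance components; habitat-specific slopes are fixed slope +
BLUP with combined standard errors, 95% CIs are ±1.96 SE, and slopes from
habitats with fewer than 100 plots are suppressed.  The marginal R² is the
fixed-effect variance share; the conditional R² adds the random
components, with random slopes contributing `τ1j² · mean(s_j²)`; the
habitat-vs-climate split separates the intercept share from the fixed +
random-slope shares.  See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic landscape (6,000 plots, an 8 → 16 → 48 habitat
hierarchy, 19 correlated climate variables), fit the narrow-level
random-slope model for SLA and inspect habitat-specific slopes:

```python
from traitclim import (SyntheticConfig, generate_dataset, build_design,
                       fit_mixed_reml, marginal_slopes, r2_partition)
from traitclim.synthetic import direct_mode_cwm_table

ds = generate_dataset(SyntheticConfig(n_plots=6000, seed=1))
print(ds.pca.explained_variance_ratio_[:4].sum())   # 0.946

cwm = direct_mode_cwm_table(ds)
design = build_design(cwm, "sla", ds.scores, ds.habitats, ds.plots, model_id=5)
fit = fit_mixed_reml(design)
print(fit.beta.round(3).to_dict())
# {'intercept': 3.049, 'pc1': 0.286, 'pc2': -0.197, 'pc3': 0.107, 'pc4': 0.003}

vd = r2_partition(fit, design)
print(vd.r2_marginal, vd.r2_conditional)            # 0.221  0.740

slopes = marginal_slopes(fit, design, min_n=100)
print(slopes[slopes.pc == 1].head(6).round(3))
```

```
habitat  n_plots  slope    se  ci_low  ci_high  significant  suppressed
  (all)     6000  0.286 0.064   0.160    0.411         True       False
 H1.1.1      118  0.532 0.035   0.464    0.599         True       False
 H1.1.2      139 -0.056 0.030  -0.115    0.003        False       False
 H1.1.3      127 -0.202 0.032  -0.265   -0.139         True       False
 H1.2.1      136 -0.285 0.029  -0.342   -0.227         True       False
 H1.2.2      114  0.622 0.037   0.550    0.694         True       False
```

The generating slopes were β = (0.30, −0.20, 0.10, 0) with slope variance
τ1² = 0.20 on PC1 at the narrow level and σ² = 1: the fit recovers the
fixed slopes within one standard error (0.286 ± 0.064 for PC1), estimates
the variance components near truth (τ̂0² = 0.53, τ̂1,1² = 0.196,
σ̂² = 1.01), and the habitat-specific PC1 slopes scatter around the common
slope — some significantly reversed, the habitat-specificity the analysis
is designed to expose.  The fixed effects alone explain 22% of the SLA
variation; habitat structure raises the explained share to 74%.

The same analysis runs end to end from the command line:

```bash
traitclim run-all --seed 1 --out results/demo            # synthetic mode
traitclim simulate --seed 1 --n-plots 2000 --out data/   # tables only
traitclim pca --climate data/climate.csv --out results/pca
```

`run-all` writes `filter_report.csv`, `r2_decomposition.csv`,
`slopes.csv`, `slope_tallies.csv`, `climate_scores.csv` and a
`manifest.json` recording config, seed, versions and row counts.

## Input schemas

Delimited text (comma or tab), UTF-8, `.` decimal separator; headers are
order-insensitive.  One example row each:

| schema | columns | example |
|---|---|---|
| vegetation | plot_id, species, cover[, genus] | `p1,Poa annua,12.5` |
| plots | plot_id, latitude, longitude[, survey_year, abundance_type] | `p1,51.5,10.2,2004,cover` |
| traits | taxon, taxon_rank, plant_height, sla, seed_mass, srl | `Poa annua,species,0.25,21.1,0.3,180` |
| habitats | plot_id, level1[, level2, level3] | `p1,R,R1,R1A` |
| climate | plot_id, bio01 … bio19 | `p1,8.2,…,612` |

Duplicate (plot, species) covers are summed (capped at 100);
subspecies/varieties merge into their species.  A YAML run config mirrors
`traitclim.config.RunConfig`:

```yaml
mode: synthetic
seed: 1
models: [1, 2, 3, 4, 5]
coverage_threshold: 0.80
synthetic:
  n_plots: 6000
  n_habitats_per_level: [8, 16, 48]
model_options:
  include_spatial: false
  min_n_slope: 100
```

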