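# Methods

`traitclim` implements a habitat-hierarchical analysis of how macroclimate
shapes the functional-trait composition of plant communities, together with
a synthetic-data generator whose ground truth lets every statistical
component be validated by parameter recovery.  This note documents the
models, the generator, the numerical choices and the limits of what the
synthetic validation can show.

## The statistical model

The response for each of four traits (plant height, SLA, seed mass, SRL)
is the natural log of the plot-level community-weighted mean (CWM).  Climate
enters through the plot's scores on the first four principal components of
19 bioclim-style variables.  The model hierarchy per trait is:

* **Model 1** — fixed effects of the four climate PCs only, fitted on a
  balanced subsample (the minimum broad-habitat group size drawn from every
  broad habitat) so that no habitat dominates the across-habitat slopes.
* **Model 2** — model 1's fixed effects plus random intercepts of the broad
  (level-1) habitats, on all plots.
* **Models 3/4/5** — fixed effects plus habitat random intercepts plus one
  random habitat × PC slope block per climate PC, with the grouping at the
  broad / intermediate / narrow level respectively.

Every model can additionally carry a low-rank spline-on-the-sphere smooth
of latitude/longitude that absorbs residual spatial dependence.  Writing
`s_ij` for plot i's score on PC j and `h(i)` for its habitat,

    y_i = b0 + Σ_j beta_j s_ij + a_h(i) + Σ_j b_h(i),j s_ij + f(lat_i, lon_i) + e_i

with `a_h ~ N(0, tau0²)`, `b_hj ~ N(0, tau1²_j)` independent across blocks,
`e_i ~ N(0, sigma²)` (optionally `sigma²/w_i` with observation weights),
and `f` a penalized radial field.  Random intercepts and slopes are
modelled as independent i.i.d. Gaussian blocks, one variance each — the
random-effect-as-penalized-term construction of GAMM software — rather
than as a correlated intercept–slope pair.  The marginal structure is
identical; the REML problem is simpler; an intercept–slope correlation
parameter exists in the generator so the robustness of this choice can be
probed.

### REML estimation

Variance components are estimated by restricted maximum likelihood.  Fixed
effects and the residual variance are profiled out, leaving the profiled
deviance over log variance ratios `phi_k = log(sigma²_k / sigma²)`:

    d(phi) = log|L_Z|² + log|L_X|² + (n − p) [1 + log(2π r² / (n − p))]

with `L_Z` the Cholesky factor of `Λ'Z'ZΛ + I`, `L_X` from the profiled
fixed-effect block and `r²` the penalized residual sum of squares.  All
per-iteration work runs on cached cross-products (`Z'Z`, `Z'X`, `Z'y`,
`X'X`, `X'y`, `y'y`), so one deviance evaluation costs a single q × q
Cholesky factorization, with q the total number of random-effect columns
(a few hundred at the problem sizes used here).  The deviance is minimized
by bounded Powell search over `phi` (dimension ≤ ~10); convergence is
declared at relative deviance change below 1e−8, the reported gradient
norm is a central finite-difference estimate at the optimum, and the
deviance trace of accepted iterates is stored (and tested to be monotone).
Reported variance components are floored at 1e−10 × var(y).  Observation
weights rescale rows by √w, reducing the weighted problem to the
unweighted one.

BLUPs of the habitat deviations, their conditional standard errors, and
the joint covariance of (BLUP error, fixed estimate) come from the inverse
of the mixed-model-equations matrix at the optimum.  A habitat's marginal
slope for PC j is `beta_j + b_hj`; its variance is
`var(beta_j) + condvar(b_hj) + 2 cov`, with the covariance term taken from
the joint inverse (each slope row records which formula produced its SE).
Confidence intervals are ± 1.96 SE; an interval excluding zero is called
significant (separate two-sided tests; a Benjamini–Hochberg option exists
but defaults off, matching the analysis convention).  Slopes estimated
from fewer than 100 plots are reported but suppressed from significance
claims; the threshold is configurable.

### Variance decomposition

The marginal R² is the fixed-effect share of the total variance; the
conditional R² adds all random components.  For random-slope blocks the
component is `sigma²_slope × mean(s_j²)` — the mean diagonal of the
induced covariance — which is validated against a Monte-Carlo oracle
(empirical variance of freshly simulated `Z·b` contributions) to within
2%.  The habitat-vs-climate split reports the random-intercept share as
"habitat" and the fixed part plus all habitat × PC slope components as
"climate".  The spatial smooth's component counts toward the conditional
R² but neither the marginal R² nor the climate share: it models spatial
dependence, not climate.  This treatment is a reported convention and is
explicit in the output tables.

### Spline on the sphere

The spatial smooth is a low-rank radial basis under great-circle distance:
k knots (default 100) chosen by a farthest-point space-filling design over
the observed plots, an exponential kernel `exp(−d/ρ)` with ρ defaulting to
half the median plot-to-knot distance, and the plot basis whitened by the
inverse Cholesky factor of the knot kernel so the smooth enters REML as a
single i.i.d.-variance component (a predictive-process / fixed-rank
kriging construction).  This is deliberately not a full-rank sphere
spline: the contract is "absorb spatial dependence", and the test suite
verifies that adding the smooth to data generated *without* a spatial
field moves the fixed slopes by less than one standard error.

## Data preparation

* **Trait assignment** — species-level mean trait values when available,
  else the genus-level mean, else missing; provenance is recorded per
  species.  Subspecies and varieties merge into their species (the species
  key is the first two name tokens); duplicate (plot, species) covers are
  summed and capped at 100%.
* **CWM** — cover-weighted arithmetic mean over the species that carry a
  value for the trait, with weights renormalized over those species; the
  coverage fraction is their share of total plant cover.  CWMs are
  natural-log transformed (the log base only rescales slopes).
* **Exclusion rules**, applied in a fixed order with per-rule counts in an
  auditable report: presence/absence-only plots; missing coordinates; an
  optional region-exclusion box (off for synthetic landscapes); latitude
  outside (34°, 82°) N; minimum-across-traits coverage below 0.80; missing
  climate.  All thresholds are strict inequalities — latitude exactly 34.0
  or coverage exactly 0.80 is retained.  The coverage filter uses the
  minimum across the four traits so one per-plot criterion governs all
  trait models; with gap-filled trait tables the four coverages coincide
  anyway, and a per-trait mode is available.
* **Stratification** — among plots sharing identical coordinates only the
  most recent census survives (ties broken by a seeded draw); survivors
  are binned into a 0.01° grid (floor on signed coordinates, lower-left
  inclusive) and one plot per occupied cell is kept by a seeded draw.
  At 51.5° N a 0.01° cell measures 1.11 × 0.69 km (spherical Earth,
  R = 6371 km).
* **Climate PCA** — correlation-matrix PCA (the 19 variables mix °C, mm
  and dimensionless indices, so covariance PCA would be unit-dependent);
  loading signs are fixed so each column's largest-magnitude entry is
  positive, giving stable orientations across runs.

## The synthetic generator

Direct mode emits log-CWMs from the mixed model above with every
generating quantity recorded: realized habitat deviations, the spatial
field, the residuals, and the analytic variance components
(`expected_variance_components`).  Defaults, chosen once as desk-scale
study conditions: 6,000 plots on a European-extent window (34–71° N,
−10–30° E); a divisible (8, 16, 48) habitat hierarchy — equal branching is
required by the generator's nesting invariant, so the real-world habitat
counts (8/40/216, which do not branch evenly) are approximated by a
smaller even tree; 19 climate variables mixed from 4 latent gradients
(two anchored to latitude/longitude) with strengths giving roughly 90% of
standardized variance in the top four PCs; `beta = (0.30, −0.20, 0.10, 0)`
in log-trait units per PC unit; `tau0² = 0.50`; `tau1² = 0.20` on PC1 at
the narrow level; `sigma² = 1.0`; spatial field off unless a test enables
it (when on: an exponential-covariance Gaussian process simulated through
≤ 200 knots).  One master seed is split per stage by hashing stage names,
so every table is reproducible and stages are independent.

Community mode inverts each plot's four log-CWM targets into a species
cover list.  Each broad habitat holds a log-normal species pool centred on
the habitat's mean CWM target (species pools track habitat conditions);
covers start from a softmax of trait-space suitability and are refined by
BFGS (analytic gradient) on the squared mismatch of the log cover-weighted
arithmetic trait means — the exact quantity the CWM stage recomputes,
under the same species/genus assignment rules, so the round trip is
consistent by construction.  Configurable fractions of pool species are
published at genus rank only, or not at all (truly traitless species sit
in their own unmeasured genera so no genus fallback can reach them);
traitless species receive small covers that dilute coverage without
moving the CWM.  Plots whose pool cannot bracket their targets within the
tolerance (default 0.05 log units) are flagged, never silently dropped —
matching four trait targets at once is over-constrained, which is why the
statistical validation runs on direct mode.

## Validation experiments and problem sizes

The standing experiments (also run by `scripts/acceptance.py`):

* fixed-slope recovery: 200 replicates at n = 4,000 under the default
  effect sizes, model 5 refits; per-slope bias and 95%-CI coverage pooled
  over the four slopes (binomial noise at 200 replicates makes per-slope
  coverage too coarse to bound tightly);
* R² slope-component oracle: one 50-group, 5,000-plot fixture, 10,000
  redraws of the random effects;
* REML vs ANOVA: one balanced 25 × 16 one-way layout;
* climate-share trajectory: 50 replicates at n = 3,000 with a (6, 12, 24)
  hierarchy (≈125 plots per narrow habitat), models 3–5, with slope
  heterogeneity either at the narrow level or absent; "flat" means the
  mean model-5 minus model-3 difference in the climate share stays below
  0.01 — differences under one percentage point of explained variance.

These sizes are the package's chosen desk-scale study conditions; they are
stated here so results are interpretable, and they are deliberately left
alone across runs.

## What passing tests do and do not show

The generator draws habitats independently of climate and space by
default, uses Gaussian residuals, equal-probability habitat assignment,
and climate driven by exactly four latent gradients.  Real vegetation-plot
archives violate all of these: habitats are spatially and climatically
structured, sampling is biased, trait gaps are phylogenetically clustered,
and CWM errors are not homoskedastic.  Passing recovery and coverage tests
therefore show the estimator and its uncertainty quantification are
correct *under the stated model*, not that the model is adequate for any
particular archive.  Taxonomic harmonization, trait gap-filling and
climate raster extraction are upstream of this package and are not
emulated.

## Known limitations

* Only linear climate effects; no climate × climate interactions or smooth
  climate terms, and Gaussian responses only.
* The low-rank spatial smooth is not a full-rank sphere spline; with very
  strong, short-range spatial signal its variance component absorbs only
  part of the dependence.
* The REML optimizer is derivative-free; with many random blocks (>10)
  analytic gradients would be preferable.
* Community mode guarantees CWM fidelity only for unflagged plots and
  makes no attempt to mimic realistic species-abundance distributions.
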