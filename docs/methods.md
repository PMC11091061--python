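# Methods

`mycostats` quantifies arbuscular-mycorrhizal-fungus (AMF) colonization of
plant roots from instance-segmentation output and partitions its variance
across the levels of a hierarchical sampling design. This note documents
the models, the conventions chosen where several were defensible, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.

## Phenotypes

The unit of analysis is the *slide* (one root sample). Each segmented
object carries a class label — plant root or one of five AM fungal
structures: arbuscule (arb), extraradical hypha (exH), intraradical hypha
(inH), vesicle (ves), spore (sp) — a pixel area, and a classifier
confidence in [0, 1]. Records below the confidence threshold (default 0.7)
are discarded before anything is computed. Per slide and class `c`:

- count density: `n_c / root_pixels` (instances per root pixel),
- average size: `pixels_c / n_c` (undefined, propagated as missing, when
  `n_c = 0`),
- percent colonization: `pixels_c / root_pixels`.

Totals sum the five AMF classes; the catch-all "other" class never enters
totals. The proportion of nutrient-exchange structures is

    PNE = (n_arb + n_exH) / (n_arb + n_exH + n_inH + n_ves + n_sp),

a count-based ratio that is invariant to pixel areas. The root-pixel
denominator sums *all* root-class instances on the slide, so slides whose
images contain several root fragments are handled uniformly. Percent
colonization, count density and PNE are scale-invariant or 1/scale
covariant in the obvious ways, and these invariances are property-tested.

The logit transformation used for PNE is `ln((p + eps) / (1 - p + eps))`
with `eps = 0` by default: exact 0/1 values must be clipped explicitly by
the caller rather than smoothed silently.

## The mixed-model ladder

Slides are nested in plants (each plant sampled in three root regions —
TOP, MID, BOT — with three replicates per region). The models are
two-level Gaussian mixed models,

    y_ij = X_ij b + u_0i + u_1i x_1ij + e_ij,
    (u_0i, u_1i) ~ N(0, S_u),   e_ij ~ N(0, s2_e),

with plant-level random intercepts and at most one random slope. The
ladder runs from the null model (intercept + random intercept) through
region dummies and selected structure covariates to the random-slope
model. Diagnostics per model:

- ICC = `s2_u0 / (s2_u0 + s2_e)` — the between-plant share of variance;
- PCV = `(v_ref - v_new) / v_ref` for both components, against the null
  model; negative values (a component growing after adjustment) are
  legitimate and preserved;
- VPC(x) = `(s2_u0 + s2_u1 x^2 + 2 s_u01 x) / (... + s2_e)` for slope
  models — the quadratic-in-covariate generalization of the ICC. Ladder
  tables report it at the mean of the (standardized) slope covariate, so
  it is comparable to an ICC;
- marginal and conditional R²: the fixed-effect and fixed+random shares of
  `var_fixed + var_random + s2_e`, where `var_fixed` is the empirical
  variance (ddof = 1) of the fixed linear predictor and, for slope models,
  `var_random = s2_u0 + s2_u1 mean(x²) + 2 s_u01 mean(x)` averages the
  quadratic over the observed covariate;
- AIC = deviance + 2k and BIC = deviance + k ln(n), with k counting fixed
  effects plus distinct variance/covariance parameters (null model: 3;
  region model: 5; slope models add 2).

### Estimation conventions

- Region enters as TOP/BOT dummies against the MID reference, so the
  intercept is the MID-region mean.
- Covariates are z-scored once on the analysis dataset, before any model
  is fitted, and shared across the ladder.
- Variance components are reported from REML fits; deviance, AIC, BIC and
  likelihood-ratio tests use ML refits whenever the compared models differ
  in fixed effects (REML likelihoods are not comparable across
  fixed-effect structures).
- Fitting is delegated to `statsmodels` `MixedLM`. Its general-purpose
  optimizer stops around 1e-4 relative precision on variance components,
  so random-intercept-only fits are polished by a one-dimensional profiled
  (RE)ML optimization over the variance ratio `psi = s2_u0 / s2_e` (Brent
  around the interior optimum, a bounded global search at boundaries,
  tolerance 1e-10 on log psi). On balanced one-way layouts the polished
  estimates agree with the closed-form ANOVA estimators to better than
  1e-6 relative, which the acceptance suite checks on 50 seeded datasets.
  The polish evaluates the model's own likelihood, so log-likelihoods stay
  exactly comparable with unpolished fits.
- Variance estimates are constrained non-negative by construction; a fit
  at the zero-variance boundary is flagged, not rejected. An estimated
  intercept–slope covariance exceeding the positive-semidefinite bound by
  numerical error is clipped to the boundary and noted.
- The random-slope LRT uses 2 df (slope variance + covariance) against the
  plain chi-square reference, without a boundary-mixture correction; with
  the boundary correction the test would only be more conservative, so a
  retained slope is retained under either convention.

## Variable selection

1. **Lasso screen** on the pooled, standardized slide-level data (the
   mixed model is the inferential stage; the screen is deliberately
   non-hierarchical). The penalty grid is the coordinate-descent path; the
   penalty is chosen by seeded k-fold cross-validation (default 10-fold)
   with the 1-SE rule. The selected set is the support of the full-data
   fit at the chosen penalty. The full path and CV curves are retained in
   the result for reproducibility.
2. **Forward selection** by mixed-model ML likelihood-ratio tests: the
   candidate with the smallest p-value is added while p < 0.05.
3. **Random-slope search**: each selected covariate is tried as a random
   slope; the engine retains at most one slope, the candidate with the
   smallest LRT p-value below 0.05. A candidate whose slope fit fails to
   converge (or lands below the nested model's likelihood) is skipped with
   a warning rather than trusted.

## Region contrasts and rank comparisons

Tukey contrasts (MID−TOP, MID−BOT, TOP−BOT) are computed on the pooled
one-way region layout: pooled within-region mean square, studentized-range
reference with k = 3 groups. `adjust="none"` gives plain pairwise
pooled-variance t-tests (oracle-checked against `scipy.stats.ttest_ind`).
The pooled layout ignores the plant blocking; contrasts are descriptive
companions to the mixed models, which do model the hierarchy. Phenotype
rankings across plants are compared by Spearman correlation with midranks
for ties.

## Annotation geometry

Annotations arrive as VGG Image Annotator exports (JSON or CSV twin).
Cleaning rules: polygons pass through; polylines are closed; circles are
resampled as 64-gons; point/rect/ellipse shapes and empty segmentations
are dropped; class vocabulary is normalized to the seven canonical labels
with unknown labels merged into "other" (warned).

Conventions the source format leaves open, fixed here once:

- pixel coordinates are 0-based; a pixel counts when its center
  `(x+0.5, y+0.5)` lies strictly inside the polygon interior;
- self-intersecting rings are interpreted with the even-odd fill rule and
  dissected into simple polygons (the ring's edges are noded and
  polygonized; faces with odd crossing parity are kept), so a bowtie
  becomes its two triangles and total area is conserved;
- tiling clips polygons to 512-pixel squares with tile-local coordinates;
  boundary tiles are kept at reduced size, degenerate (point/segment)
  intersections are discarded, multi-part intersections become separate
  records, and empty tiles are dropped by default. Area is conserved to
  1e-6 relative, checked on random images.
- the images-below-100-pixels filter is applied at tiling time through
  `min_image_side`; whether small *boundary tiles* should also be dropped
  is left to the caller (they are kept by default).

An 8:1:1 seeded train/validation/test partition utility is provided for
completeness; nothing downstream consumes it (no model training here).

## Segmentation evaluation

Matching is class-wise and greedy in descending confidence (ties broken by
input order): a prediction takes the unmatched same-class truth with the
highest IoU at or above the threshold, one-to-one. AP is the 101-point
interpolated area under the precision–recall curve, on a 0–100 scale;
headline AP averages IoU thresholds 0.50:0.05:0.95; AP50 evaluates at 0.5;
mAP averages classes with at least one ground-truth instance. Cross-class
matches never count. A class with predictions but no truths scores 0; with
neither it is skipped.

Class-frequency agreement between two instance sources uses Fisher's exact
test on the 2×K table: full enumeration (multivariate hypergeometric, in
log space) when the bound on the table count permits, otherwise seeded
Monte Carlo via Patefield sampling of tables with fixed margins; the
method used is always reported. Confidence summaries report per-class
histograms above the threshold and plain moment-ratio sample skewness
(zero-variance inputs return 0 rather than NaN).

## Synthetic data

`simulate_mlm_dataset` draws directly from the two-level model above, with
defaults matching the study design (12 plants × 3 regions × 3 replicates)
and the final percent-colonization model's fixed effects (intercept
0.3410, region offsets 0.0226/−0.0087, covariate effects 0.0937/0.0304)
and variance components (intercept 0.0009, residual 0.0007). The slope
variance default, 0.0004, is a synthetic-only choice sized so the VPC
visibly rises with arbuscule count; no published value exists for it. The
latent random effects are returned so recovery tests can compare against
truth.

`simulate_instance_tables` emulates segmentation output at slide
granularity (fields of view within a slide are collapsed — every
phenotype is slide-level). Class counts come from a Gaussian copula over
Poisson margins, which lets the qualitative correlation structure be set
directly: arbuscule and extraradical-hypha counts positively correlated
(0.5), vesicle–spore counts positively (0.4), vesicle/spore counts versus
arbuscule size negatively (−0.3). Instance sizes are log-normal; one root
instance consumes the slide's root-pixel budget; region multipliers give
TOP > MID > BOT in arbuscule/extraradical-hypha counts and arbuscule
size; three log-normal per-plant multipliers (overall colonization 0.35,
nutrient-exchange allocation tilt 0.25, arbuscule size 0.15, on the log
scale) create the between-plant variance the mixed models partition. Mean
counts (40/25/15/10/6 per slide) and size medians are order-of-magnitude
choices that put total percent colonization near the observed population
mean of ~0.33; they are conventions of the generator, **not estimates of
any real dataset**. Root confidences are drawn in [0.75, 1] so the
denominator always survives the 0.7 filter.

What the generators do *not* emulate: image pixels (no rendering of
stained roots), spatial arrangement of structures within images,
classifier-specific confidence miscalibration, or between-image
heterogeneity within a slide. Tests passing on synthetic data therefore
validate the statistical machinery — estimators, selection, metrics —
not the upstream segmentation quality on real micrographs.

`simulate_mask_pairs` builds truth/prediction mask pairs on a coarse grid
whose cells are wide enough that a jittered prediction can only overlap
its own truth, making the generator's TP/FP/FN bookkeeping an independent
oracle for the greedy matcher.

## Validation scale

The acceptance computations run at: 50 datasets for the REML/ANOVA oracle
(12 plants × 9 samples); 30 replicates per size at 24/96/384 plants for
variance-component RMSE monotonicity plus 100 replicates at 96 plants for
fixed-effect coverage (coverage is per-coefficient: each fixed effect
within 2 SE of truth in ≥ 90% of replicates); 1000 null simulations for
LRT type-I calibration; 100 mask-pair cases at three IoU thresholds; 100
random images for tiling conservation and 20 polygons for the
rasterization oracle.

## Known limitations

- One random slope at most, no crossed random effects, Gaussian responses
  only (the PNE model is Gaussian-on-logit, not a true binomial GLMM).
- The Lasso screen ignores the grouping structure by design.
- Published per-class AP values, the study's region-contrast p-values and
  cross-phenotype correlations depend on the study's own images and
  morphometric data and are not recomputable from synthetic inputs; the
  machinery that produces such numbers is validated property-wise instead.
- Polygons with interior holes are not represented; inputs are VIA
  polygon annotations, which have none.
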