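# Methods

This note documents the models, the synthetic study design, the numerical
choices, and what the tests do and do not establish.

## The scientific setup

A two-census forest inventory observes, for every tree on a plot, its leaf
phenology (evergreen EV / deciduous DE), its stem diameter at the first
census (`dbh_prev`, cm), and its fate over the census interval (default
5 yr): survivor (with `dbh_curr`), death, or recruitment (new tree, enters
at the 12.7 cm measurement threshold). Plot composition is summarised by
the relative evergreen abundance, either basal-area based (Eq. relEV_area)
or stem-count based (relEV_density); the basal-area version is the default
predictor everywhere except the abundance null model, which works on stem
counts. Basal area uses the first-census diameter (state at the start of
the exposure interval); recruits contribute through their entry diameter.
Trees of unknown phenology never enter relEV; plots where they exceed 10 %
of basal area are excluded rather than imputed.

Plot inclusion mirrors standard inventory preprocessing: ≥ 10 trees,
≤ 50 % of first-census trees dead (pest/disturbance guard), ≥ 2 species
and no species above 90 % of basal area (monoculture guard), each rule
independently toggleable. Exclusions are audited under the first failing
rule in a fixed documented order (min_trees, unknown_ba, mortality,
min_species, single_species_ba) — the ordering is a reporting convention,
chosen for reproducibility.

## Vital-rate models

Per phenology, three generalized additive models:

* **survival** — tree level, binomial with logit link; predictors:
  smooth(dbh_prev), smooth(relEV), linear(stand basal area, stem density,
  10 environmental PCs, optionally MAT). Reported as survival
  (1 − mortality).
* **growth** — tree level, survivors only, Gaussian; response `dbh_curr`;
  same predictors. Growth is reported as (predicted `dbh_curr` −
  `dbh_prev`)/interval in cm yr⁻¹.
* **recruitment** — plot level, Poisson with log link; response recruit
  count of the focal phenology per interval; predictors: smooth(relEV),
  linear(basal area, density, con-phenological basal area, PCs). The
  con-phenological basal area stays in **both** the feedback and the null
  variant; relEV alone is the feedback term.

Smooths are penalized B-splines with basis dimension 5. The smoothing
weight is selected per fit by AIC (with effective degrees of freedom) over
the grid {10², 10⁴, 10⁶}; the grid deliberately starts at a moderate
penalty because the boundary regions of the feedback smooth are
data-sparse and an essentially unpenalized basis chases local noise there,
occasionally corrupting the boundary contrasts. relEV spline knots span
[0, 1] exactly so that predictions at pure compositions stay inside the
basis for both phenologies; other smooth covariates use constant
extrapolation beyond their training range (relevant when the simulator
grows trees past the largest fitted diameter). Spatial-cluster intercepts
are unnecessary for the synthetic studies (environments are iid by
construction) and are not fitted by default.

**Contrasts.** The feedback effects are summarised exactly as they are
estimated: predict both phenologies' rates with every predictor except
relEV held at the training mean (pooled across the two phenology models),
at relEV = 0 and 1 for survival and growth (relative % difference,
con − hetero over hetero) and relEV = 0.1 / 0.9 for recruitment
(con:hetero rate ratio). Uncertainty: 100 multivariate-normal draws from
the coefficient covariance; the 2.5–97.5 % quantiles of the per-draw
contrast form the interval. Contrasts are undefined (and refused) for
null-variant models.

## The synthetic study

The generator emulates a remeasured inventory at the scale the estimators
are designed for: 3000 plots of 0.1 ha, stand sizes 10 + Poisson with a
gamma-mixed mean (mean 25 trees; the gamma mixing gives realistic
between-plot density spread — and basal-area spread is precisely what
identifies stand-size effects separately from composition effects,
because con-phenological basal area is structurally relEV × total basal
area). Diameters are 12.7 cm + lognormal (median ≈ 23 cm). Environments
are 10 iid standard-normal PCs; MAT is an affine map of PC1 clipped to
the forest range [−2, 23] °C. Initial composition is a mixture: 10 %
pure-deciduous, 10 % pure-evergreen, 15 % near-pure each side
(Beta(30, 2) / Beta(2, 30)), and a uniform body. The near-pure components
matter: hetero-phenology trees must exist in strongly dominated stands
for the boundary contrasts at relEV = 0/1 to be identifiable.

True vital rates are logit-linear (survival), linear (growth) and
log-linear (recruitment) in the same predictors the fitted models use, so
recovery is a well-posed estimation problem rather than an approximation
contest. The feedback knobs are planted as relative contrasts at the
reference compositions and resolved in closed form; the defaults are the
study's headline effect sizes: DE survival advantage 14 % at relEV = 0,
EV advantage 17 % at relEV = 1, growth advantages 43 % (EV side) and 4 %
(DE side), con:hetero recruitment ratio 5 (via exp(0.8·c) = 5). Baseline
demography: 0.90 per-interval survival (~2 % yr⁻¹ mortality), 1.4 cm per
interval growth with σ = 0.6 cm, ~1.3 recruits per phenology per plot per
interval at mixed composition, with negative basal-area dependence on
survival, growth and recruitment so simulated stands equilibrate at
realistic structure (~300 stems ha⁻¹, ~15–20 m² ha⁻¹). An infeasible knob
combination (e.g. a survival advantage implying a probability outside
(0, 1) at the reference) raises a calibration error naming the knob.
Setting every knob to zero (ratio to one) makes the phenologies
exchangeable up to labels, which the tests verify.

Estimator characterisation (replicated synthetic studies, 12–24 seeds at
full scale): the five contrast estimators are unbiased — means
14.0 / 17.5 / 4.1 / 43.9 and 4.8 for the recruitment ratio — with
standard deviations ≈ 0.7 / 1.0 / 0.8 / 1.6 percentage points and 0.3 on
the ratio, and 88–96 % coverage of the planted value by the 95 %
intervals.

The abundance arm of the generator draws per-plot (EV, DE) counts from a
zero-adjusted Poisson whose zero probability and positive mean are
logistic/log-linear in the leading PCs, with opposite signs for the two
types (evergreen favoured cold). A coupling knob ρ ≤ 0 adds a shared
plot-level latent normal factor entering the two log-means with opposite
signs (strength √(−ρ)), producing negative EV–DE dependence beyond the
environment and enriching the outer relEV bins — the signature the null
model is built to detect. One caveat, documented because it shapes the
tests: the latent factor also overdisperses the marginals, which *dilutes*
the observed rank correlation; with strong environmental signal in the
means, a fitted null can show more env-driven anticorrelation than the
overdispersed data. The coupling test is therefore demonstrated on
env-free abundance means, while the histogram-envelope test keeps the
full environmental structure.

## The environmental null model

The hurdle factorises, and the implementation exploits it: the zero part
is a penalized logistic regression of the zero indicator, the positive
part a penalized zero-truncated-Poisson maximum likelihood (L-BFGS with
analytic gradients), both over B-spline bases (df 5) of the ten PCs with
a fixed modest smoothing weight. A generalized cross-validation search
was considered and rejected on cost grounds — acceptance is
recovery-based, and the fixed-penalty fits recover the generating
π₀(env) within 0.05 mean absolute error and μ(env) within 10 % relative
error at 2000 plots. Intercept-only fits use the closed forms (π₀ =
empirical zero fraction; μ solves μ/(1−e^{−μ}) = mean positive count) and
are tested against an independent root-finding oracle.

Null ensembles redraw both counts independently per plot from the fitted
plot-specific parameters, re-apply the ≥ 10-stem filter per replicate
(replicates with no qualifying plot are dropped with a warning), histogram
relEV_density at width 0.05, and report pointwise 2.5/97.5 % envelopes
over 1000 replicates plus outer-bin exceedance flags. The coupling test
compares the observed Spearman ρ to the same ensemble; p is the fraction
of null replicates at or below the observed ρ (one-sided, more negative
than the null).

## The succession simulator

Five-year steps in fixed order — disturbance, survival, growth,
recruitment — with plot covariates frozen at the start of the step. The
annual stand-replacing probability 0.0036 (the overall rate 0.009 minus
the management share 0.0054) compounds to 1 − (1 − 0.0036)⁵ ≈ 0.0179 per
step; a disturbed plot resets to 20 trees at 12.7 cm whose phenologies
are Bernoulli draws at the plot's relEV immediately before the
disturbance. Survivor growth adds the fitted residual σ as Gaussian noise
and floors the increment at zero (no shrinkage). An emptied plot keeps
its last defined relEV so recruitment (which does not require parents on
the plot) can restart it. The simulator accepts the generator's
closed-form truth or fitted model sets behind one adapter interface; the
null variant of the truth freezes every relEV term at 0.5, removing
frequency dependence while keeping all other structure.

Initializations: uniform relEV targets (generation experiment), 500/500
pure plots (maintenance), and 800/200 either way for hysteresis. The
hysteresis experiment splits the MAT range into 12 equal sections,
assigns every plot its section's MAT (uniform within the section, other
PCs iid), runs both initializations under both variants, and reports the
per-section EV-init minus DE-init mean final relEV gap with a normal 95 %
band. The MAT asymmetry in the truth enters recruitment (log-rates gain
∓1.8·MAT_std for EV/DE), making evergreens favoured cold and deciduous
warm; under feedbacks the interior of the gradient is bistable (gap > 0)
while the extremes are environmentally forced (gap ≈ 0), and without
feedbacks the gap vanishes everywhere. Because "no gap anywhere" is a
12-fold joint statement, the null check uses a simultaneous
(Bonferroni-adjusted) 95 % band; per-section 95 % bands are reported
as-is.

Scaled problem sizes are used throughout the regime tests — 200 plots and
500 years for bistability generation/maintenance, 100 plots per MAT
section for hysteresis — chosen as the smallest sizes at which the
qualitative outcomes (dip significance, band exclusion) are stable across
seeds.

## Dip, bimodality index, clustering, determinants

The dip statistic is the sup-distance between the sample ECDF and the
nearest unimodal CDF, computed by the classic modal-interval iteration on
the tie-collapsed sorted sample: greatest convex minorant of the lower
ECDF and least concave majorant of the upper ECDF over the current
candidate modal interval; the largest LCM−GCM gap tightens the interval,
the ECDF deviations outside it drive the running maximum, and twice the
dip is the final maximum. Degenerate vertical hull segments (heavy ties)
are skipped as gap candidates. Correctness is established against an
independent LP oracle that models a piecewise-linear unimodal CDF on a
dense knot grid with an enumerated mode knot — exact for tie-heavy
samples, grid-resolution accurate otherwise — plus the known closed-form
cases (balanced two-atom sample: 0.25; D ≥ 1/(2n) always).

Dip p-values are Monte-Carlo against the U(0,1) null at the observed n
(no table interpolation): p = fraction of null dips ≥ observed. The
published large-n threshold D′ > 0.546 for p < 0.05 is not asserted
anywhere; the Monte-Carlo calibration is n-exact and self-contained.

BI = −exp(−a·D′²)·sign(S) with a = 6, b = 2; sign(0) = 0 gives BI = 0,
classified bistable-evergreen per the [0, 0.22] bracket (boundary
conventions are documented and tested). The grouping of the exponent is
−exp(−a·(D′)^b): it is the only reading that reproduces the ±0.22 cutoff
at the dip threshold D′ = 0.5 (exp(−6·0.25) = e^{−1.5} ≈ 0.2231).
Skewness is the bias-adjusted Fisher–Pearson sample skewness; S < 0 means
mass at high relEV, i.e. evergreen dominance. A cluster whose plots all
share one composition has undefined skewness; its dominance sign is taken
from which side of 0.5 the composition sits on, with the minimum dip
1/(2n).

Fishing-net clustering bins plots into half-open 10-arc-minute lon/lat
cells (cell id = floor(lon/Δ), floor(lat/Δ), Δ = 1/6°); K-means clustering
uses the leading 3 environmental PCs, seeded. Clusters under 10 plots are
dropped and their plots leave the downstream analysis. Cluster BI uses
relEV_area. Determinant importance fits a random-forest regressor on 100
bootstrap subsamples (33 % each) of the seven key drivers (MAT, annual
precipitation, coldest-quarter temperature, driest-quarter precipitation,
soil pH, soil N density, soil C:N) and reports the mean ± sd increase in
out-of-bag squared error under single-feature permutation.

## What the synthetic studies do and do not show

The generator's environments are iid across plots — no spatial
autocorrelation, no multi-interval histories, no species identities beyond
a label pool, no measurement error on diameters beyond the growth noise,
and abundance counts without the full overdispersion of real inventories.
Passing tests therefore establish that the estimators and the simulation
machinery recover known truths under the stated statistical structure;
they do not validate the ecological conclusions on real FIA/GFBi data,
nor the spatial random-effect machinery real data would need (the
cluster-intercept option exists but is off by default). The documented
generic CSV schema plus converters, not the native FIA/GFBi formats, is
the ingestion contract.
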