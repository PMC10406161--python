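# Methods

This note records the modelling choices behind `agealign`, the defaults
and why, what the synthetic generators do and do not emulate, and the
numerical conventions that matter when reproducing results.

## Age frames and the log transform

All analysis runs in **natural-log days post conception**. Postnatal ages
add the species' gestation length (shipped defaults from standard
comparative life-history references, overridable in YAML); postnatal years
use 365.25 days. Organoid incubation days are placed on the same axis as
`incubation_day + organoid_offset_days`, with a default offset of 0 —
there is no principled anchor for in-vitro time, so the offset is a config
knob rather than a constant. Log base is irrelevant to translations (any
affine change of base cancels in the min–max scale and in the
inversion-then-prediction chain); natural log is used throughout and all
coefficients are reported on that scale.

When several time points (sexes, populations, replicates) feed one
species × event cell, the cell is the unweighted mean of *log* ages.
Averaging logs rather than days weights relative rather than absolute
error, which matches the log-scale regression the cell feeds; sex-split
tables are available separately for the variation analyses.

## Imputation

Time points are never observed in every species, so the table is completed
before the event scale is built. The scheme mirrors the model's own
structure — each species' log ages are approximately affine in the
cross-species event means:

1. initialize event means from observed cells;
2. regress each species' observed log ages on the current means (OLS,
   intercept + slope);
3. fill that species' missing cells with its regression predictions;
4. recompute means over all cells; repeat until the largest change in any
   filled cell is below `tol` (default 1e-6, `max_iter` 100).

Observed cells are never altered. On a noise-free table whose species are
exactly affine in the latent event order, the iteration's fixed point
reproduces the missing cells exactly (the 3 × 2 hand case in the tests
gives the fill in closed form). Every species must contribute at least two
observations — an affine fit needs two points. No multiple imputation or
imputation-uncertainty propagation is attempted; downstream standard
errors treat filled cells as data and are accordingly mildly optimistic
(see the heterochrony-test note below).

## Event scale and the identifiability of the quadratic

The event scale is the min–max normalization of per-event mean log ages:
earliest event 0, latest 1. Two consequences worth knowing:

- The scale is invariant to any common affine transform of all log ages,
  and it preserves the latent event *order* exactly (rank correlation 1 in
  noise-free recovery tests).
- Because the scale is built *from* the mean log ages, a curvature term
  shared by all species is partially absorbed into the scale itself: with
  identical species slopes a shared quadratic is absorbed completely, and
  the mapping from any latent event score to the computed scale is affine
  only when the latent model is quadratic-free. Exact-recovery tests
  (noise-free R² = 1, slopes equal to truth) therefore use the
  quadratic-free generator condition, with the latent slope mapped onto
  the score axis by the latent span; the quadratic generator condition is
  exercised by the tolerance-based tests and by the inversion round trip,
  which only needs the *fitted* curve, not the latent one.

## The translating-time fit

`log_age ~ score * C(species) * C(event_type) + I(score**2)`, OLS,
treatment coding. Human is the reference species because alignments are
conventionally expressed toward humans; the most frequent event type is
the reference type. The quadratic is shared across species (no
species × score² term). An event type observed in a single species leaves
aliased interaction columns; the fit proceeds by pseudoinverse and records
the aliasing in `rank_warnings` instead of failing.

**Translation** is defined at the individual level, not per organ: the
species curve used for inversion and prediction is the event-type-marginal
curve, i.e. the frequency-weighted average of the per-type predictions.
Because the design is quadratic in the score, three probe predictions
(E = 0, ½, 1) identify the marginal quadratic (c, b, g) exactly; these
per-species triples are what the YAML serialization stores, so a restored
fit can translate without the design matrix. Inversion takes the root of
g·E² + b·E + (c − ln age) on the increasing branch (the '+' root, whose
derivative is +√disc). Scores outside [0, 1] are returned but flagged:
late-life alignments for sparsely sampled species are extrapolations and
are labelled as such everywhere downstream (translation results, rescaled
survival grids).

**Heterochrony** is tested by the nested F test of the full model against
the model without event-type terms, plus the mean reduced-model residual
per type as an effect-direction summary. The test is exact for complete
tables; on imputed tables the filled cells make it anticonservative, so
calibration claims (type-I error ≈ α) are made — and tested — on complete
tables. At the default study scale (9 species, σ = 0.05 log-days) the
empirical type-I rate over 200 simulations is within two points of the
nominal 5%, and an injected 0.8× slope on one event type in one species is
detected essentially always at 60 events.

## Expression age transfer

Features are log(TPM + 1); targets are log ages. Six families are trained
on a ~70% split and scored by RMSE on the held-out ~30%: elastic-net and
lasso regularized linear models (counted as two families), support-vector
regression, k-nearest-neighbors, random forest, and Gaussian-process
regression. Hyperparameters come from 5-fold cross-validation inside the
training split (regularization paths for the linear models, small grids
for SVR/k-NN); the forest uses 200 trees; the GP uses an RBF + white
kernel with normalized targets. Families whose internal CV cannot run on a
tiny split are skipped with a warning and an infinite RMSE, never
silently. Selection is by minimum test RMSE.

Transfer reindexes the target matrix to the training genes; at least half
must be present, and absent genes are filled with their training-mean
feature value (with a warning) so the estimator sees a complete design.
Predictions for another species *are* translated ages by construction —
the model only knows the reference species' timeline. A hook exists to
merge pre-translated samples of a second species into the training pool
through any monotone age map.

RMSE-based selection is invariant to gene order; a common positive
rescaling of expression is only an *approximate* intercept shift after
log(x+1) (exact for log x), so the rescaling invariance is asserted within
tolerance for the linear families and not claimed for tree or kernel
families.

The correlation aligner filters genes on the target profile
(log10 expression > 0.5), Pearson-correlates log-transformed values
against every reference sample, and returns the full profile plus the
best-correlated sample's age; ties go to the youngest age with a flag, and
fewer than 100 surviving genes triggers a warning.

## Trajectory milestones

Growth series are fitted by least squares to logistic and Gompertz
sigmoids (starting values from the data: max as asymptote, median age as
inflection, 4/age-span as rate), with the lower AIC winning; if neither
converges, or the series decreases overall, an isotonic-regression +
PCHIP monotone spline takes over with a warning. The `pct = 100`
milestone is operationalized as reaching 99% of the asymptote — sigmoids
never attain their limit. Logistic and Gompertz milestones use closed-form
inversion; spline milestones use a bracketing root search. Peak ages come
from a smoothing spline whose penalty is chosen by generalized
cross-validation unless given; boundary maxima are flagged censored
rather than trusted.

Attainment ages for integer count series fit an isotonic step function
with threshold `adult − 0.5` (counts round to adult from there) and return
the first *observed* age whose fitted value clears it: a step between two
sampling ages is dated to the age where it is first seen, not interpolated
into the unobserved gap, so a clean 0 → adult step at age a returns
exactly a. Extrapolation beyond the observed range is refused.

## Variation statistics

Coefficients of variation are computed on linear-scale days (a CV of log
ages is not a standard dispersion measure), per event across population
means, with single-population events excluded and listed. The 5–95% band
is the empirical percentile band across events. Sex comparisons regress
male log age on female log age (the convention is arbitrary, so the
reverse slope is reported too); events with |externally studentized
residual| > 3 are flagged as deviating.

## Survival

The survivor convention is S(t) = P(T ≥ t), left-continuous: the grid
anchors at (0, 1) and records the fraction alive at each distinct death
age. No censoring machinery — the intended inputs are complete cohorts or
published life-table fractions (validated for monotonicity, offending
rows named). Quantile ages return the first grid age at which S has
dropped to p, exact to the grid resolution. Rescaling translates every
grid age through the fitted model and keeps fractions untouched;
monotonicity is preserved because translation is monotone, and quantiles
commute with rescaling exactly. Grid ages whose event score exceeds the
fitted range are kept and flagged.

## Synthetic generators and what passing tests mean

The generators are pure functions of their spec (seed included):

- **Event tables**: cell = αₛ + βₛ·E + γ·E² + N(0, σ²) with latent scores
  sorted-uniform on [0, 1], missing cells completely at random but
  repaired so every event keeps a species and every species two events.
  Defaults mirror the study scale: nine primate species with intercepts
  ≈ 4 (≈ 55 days post conception at E = 0) and slopes ordered by
  life-history pace (human 5.6 down to marmoset 4.4, shared γ = 0.5,
  σ = 0.05 log-days, 30% missing), sized so the flat export holds exactly
  573 time points. Heterochrony is injected as a slope multiplier on
  chosen (species, event-type) pairs.
- **Expression pairs**: informative genes follow aᵢ + bᵢ·ln t with
  positive slopes; the second species' samples are evaluated at the
  warped age (affine warp, default 1.3×); uninformative genes are
  age-independent noise; values clipped at 0.
- **Growth**: logistic or Gompertz with Gaussian noise.
- **Cohorts**: Gompertz mortality by inverse-transform sampling, with
  analytic survivor and quantile functions as oracles.

These emulate the *structure* the pipeline exploits — monotone signal,
affine species maps, MCAR missingness — not real data's features: no
phylogenetic correlation between species, no transcriptome covariance or
batch structure, no informative missingness, no measurement heterogeneity
across literature sources. Passing recovery tests therefore demonstrates
that the algorithms are correct and calibrated under their stated
assumptions, not that those assumptions hold in any particular empirical
compilation; on real tables the imputation and the heterochrony F test
inherit the caveats noted above.

## Problem sizes and determinism

Default test and acceptance problem sizes (64-event tables, 200-gene /
40-sample expression pairs, 200-replicate calibration runs, 10⁵-individual
cohorts) are chosen as the smallest sizes at which the recovery targets
are comfortably identified; everything regenerates from seeds at run time
and no data files ship with the package. All user-facing entry points
thread a single integer seed through every stochastic stage, so identical
configs produce byte-identical numeric outputs.

## Known limitations

- Fixed-effects OLS only: no mixed effects, no phylogenetic correction.
- Imputation uncertainty is not propagated.
- The event-type-marginal translation curve depends on the observed
  event-type mix; two fits with different type compositions translate
  slightly differently.
- Organoid time has no principled anchor on the post-conception axis
  beyond the configurable offset.
- Extrapolations beyond the fitted event scale are flagged, not
  uncertainty-quantified; the across-population CV band is the intended
  plausibility guide.
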