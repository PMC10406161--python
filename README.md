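# agealign

Tools for translating ages across primate species.

A one-year-old chimpanzee is not the developmental equal of a one-year-old
human, and the mismatch grows with age. `agealign` implements the
*translating-time* approach to cross-species age alignment for comparative
neuroscientists, developmental biologists and primate veterinarians: it
pools developmental and aging time points from many scales of study
(behavioral milestones, brain and body growth, life history, transcription,
skeletal maturation) into a common event scale, fits a regression of event
age on that scale, and inverts the fit to map any age in one species onto
its equivalent in another.

## The model

Each observed time point is an age at which some event occurs in some
species, expressed in days post conception (postnatal ages plus gestation)
and natural-log transformed. Events are ordered on a 0–1 **event scale**
`E`: the min–max normalization of each event's cross-species mean log age.
The core regression is

```
ln(age) = β₀ + β₁·E + β₂·E² + species + event_type
          + E × species × event_type (full factorial)
```

fitted by OLS with treatment coding (human as reference). Missing
species × event cells are first completed by an iterative scheme that
regresses each species' observed log ages on the current event means and
fills predictions until convergence. For a fixed species the fitted log age
is quadratic in `E`, so translation solves that quadratic in the source
species (on its increasing branch) and evaluates the target species' curve
at the same score. Event-type × species interactions are the model's notion
of **heterochrony** — a shift in the relative timing of one biological
program — and are tested by a nested-model F test.

Satellite modules mint additional time points and reuse the fitted model:

- `expression`: train six age-from-expression regressors (elastic net,
  lasso, SVR, k-NN, random forest, Gaussian process) on a reference
  species, pick the lowest held-out RMSE, and predict — i.e. translate —
  ages for another species' tissue or organoid samples; plus a
  correlation-profile aligner with the `log10(expr) > 0.5` filter.
- `milestones`: percent-of-adult milestone ages from logistic/Gompertz
  growth fits, smoothing-spline peak ages, and isotonic attainment ages
  for integer count series (e.g. ossified carpal numbers).
- `variation`: across-population coefficient-of-variation bands and
  male-on-female log-age slope regressions with outlier flagging.
- `survival`: empirical or life-table survival curves, quantile ages, and
  rescaling of a whole curve onto another species' timeline.
- `synthetic`: generators for every input class with known ground truth
  (latent event scales, expression time warps, sigmoid growth, Gompertz
  mortality) — the test bed for the whole pipeline.

## Worked example

`examples/01_event_scale_and_translation.py` builds the synthetic
study-scale bundle (573 time points over nine primate species), fits the
model and translates human ages:

```
573 time points across 9 species
imputed 3 missing cells in 7 iterations
fit: R^2 = 0.9993, F = 10148
human  1 y  ->  chimpanzee   1.0 y
human 10 y  ->  chimpanzee   8.7 y
human 35 y  ->  chimpanzee  29.2 y
human 68 y  ->  chimpanzee  55.4 y (extrapolated)
```

Humans and great apes are near-equivalent in infancy and diverge steadily
with age; late-life alignments beyond the last observed events are
reported but flagged as extrapolation. The other `examples/` scripts walk
through expression-based age transfer, milestone extraction, variation
bands and survival-curve rescaling the same way.

A thin CLI wraps the same calls:

```bash
agealign simulate --seed 0 --out run/
agealign fit --timepoints run/timepoints.csv --out run/fit.yaml
agealign translate --fit run/fit.yaml --from human --to gorilla --age 10000
agealign report --seed 0 --out run/report
```

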