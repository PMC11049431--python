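# Methods

## The generative model

Each simulated fruit carries a storage group, a multiplicative ripening
speed factor *m* (lognormal with median 1 and configurable log-sd σ,
default 0.2 — avocado ripening is notoriously heterogeneous), a starting
10-stage index in 1..3 (default mix 0.60/0.25/0.15: fruits arrive a few
days post-harvest, mostly unripe), and optionally a one-sided blemish
(wind-rub/sunburn texture; default prevalence 0.30).

The fruit advances through 10-stage windows with per-stage dwell times
drawn from a gamma distribution with mean δ·*m* days and coefficient of
variation *c* (default 0.15; deterministic at *c* = 0). Photography is
daily, two sides per day, from day 0 until the day stage 10 is reached
(or an optional observation cap, which censors fruits that have not
reached stage 9). *Days Left* for every record is
`max(0, first stage-9 day − record day)`; censored fruits have it
undefined and are excluded from regression.

### Dwell calibration

The defining property of a storage group is its slope preset α: the
cohort's emergent Days-Left-vs-stage law must satisfy
`Days Left = α (RI − E)` under the forced-endpoint estimator. Because a
fruit is photographed on *every* day of a multi-day stage dwell, records
within a stage sit below the stage-entry value of the line, and pooling
fruits whose dwell scales with *m* reweights the estimator toward faster
fruits. Setting δ = |α| therefore recovers a slope biased shallow by
5–13% for the preset magnitudes of interest. We instead invert the
estimator's expectation analytically. Writing x(s) for the regressor of
a record at 10-stage s (either `ceil(s/2) − 5` or `s − 9`), and averaging
over the start-stage mix,

    S1 = E[Σ_s x(s)·(8.5 − s)],  S2 = E[Σ_s x(s)],  W = E[Σ_s x(s)²]
    R  = (αW − S2/2) / (S1 + c²·S2/2),    δ = R · E[m]/E[m²] = R·e^{−3σ²/2}

which accounts for within-stage daily sampling (the 8.5 − s and S2/2
terms), gamma dwell dispersion (c²) and lognormal speed pooling. The
inversion is exact at α = −1 (unit dwell) and leaves a residual
day-rounding bias of ≲1.3% at the preset magnitudes — small against the
Monte-Carlo spread of a 200-fruit cohort (the acceptance suite checks
recovery within 3 Monte-Carlo standard deviations). Because the 5-stage
and 10-stage slope presets of a group are measured quantities that do not
scale exactly 2:1, either preset can drive the pace (`drive_index`);
recovery is then checked against the driving preset.

With defaults, the simulated study (192 + 143 + 143 fruits) yields
~14.6k labeled photographs, and the fitted regressions show uncentered
R² ≈ 0.96 — both emergent, not targeted.

### Rendering

Renders are schematic by intent: an ellipse on a near-white backdrop,
filled with the stage's CIELAB anchor (lightness nonincreasing over
stages 1..8), plus purple speckles whose density peaks in the
scattered-purple phase and falls in the homogeneous-purple phase, dark
mold spots only at stage ≥ 9, a one-sided blemish patch, and per-channel
gaussian noise (sd 0.012 sRGB). What passing tests show is that the
*color statistics* of the cohort behave like ripening skins (darkening,
stage separability, side asymmetry); they say nothing about texture,
gloss, shape variation or lighting of real photographs, so classifier
accuracies on synthetic cohorts do not transfer to real databases.

## Splitting and oversampling

Splits are by whole fruit (both sides, all days) to prevent leakage.
Exact stage stratification is impossible since each fruit traverses many
stages; a seeded greedy pass (largest fruits first, assign to the subset
with the least squared overshoot of its per-stage record targets) keeps
per-stage shares within a few points of 70/15/15. Random oversampling
duplicates randomly chosen training *records* per stage up to the
majority count; validation/test are never touched.

## Classifier

The training protocol: one random augmentation per image per epoch
(reflection, ±10° rotation, 0.95–1.05 rescale, ±10 px translations),
minibatch SGD with momentum 0.9, initial learning rate dropped by 0.1
every 10 epochs, validation every 10 iterations, early stop after 150
iterations without improvement, and restoration of the checkpoint with
the best validation accuracy (ties → lower loss, then earliest).

The default backbone is a deliberately small CNN (two 3×3 conv/ReLU/pool
blocks, 8 and 16 channels, linear head) on 32×32 inputs, implemented in
numpy so the whole pipeline runs on one CPU with no deep-learning
framework; heavier pretrained backbones can be plugged in behind
`build_backbone`. Defaults follow the two learning-rate presets (0.01
deep / 0.001 shallow); the scaled sanity configuration uses 0.003 for
the small CNN — an intermediate value suited to a shallow net without
normalization layers trained for few epochs. Optimizer, momentum and
input size are configuration, not measured quantities.

## Metrics and losses

Margin-of-error accuracy uses absolute integer stage difference; "within
half a stage" on the 5-stage scale corresponds to margin 1 on the
10-stage scale (two 10-stage steps per classical stage). Sample mode
counts a (fruit, day) as correct when at least one side meets the margin.
Per-stage accuracies for absent stages are reported as missing, never 0
or 1. Loss tables expose signed losses but report mean |loss|, per group
and overall with equal group weights; `by_sample` keeps the side with the
smaller |loss|. The loss KDE is Gaussian with an absolute 1-day
bandwidth.

## Numerical and design choices

* Dry matter is dehydrated/raw × 100 (the standard definition; the
  inverse ratio would exceed 100%).
* Through-origin R² is the uncentered definition (no-intercept models
  have no meaningful centered R²); confidence intervals use Student-t
  with n − 1 df. Cross-checked against statsmodels' no-constant OLS.
* Regressions fit records strictly before the endpoint stage; records at
  or beyond it have x = 0 (no leverage on a through-origin slope) or
  clipped Days Left.
* Both Days Left variants count down to the same physical day (first
  attainment of stage 9 of 10 ≡ stage 5 of 5); only the regressor
  differs.
* Palette aggregation is weight-aware k-means over all per-image palette
  entries — one defensible reading of "most predominant values"; ties in
  palette ordering are broken stably by weight.
* sRGB↔CIELAB conversions use the D65 2° observer. Planted-color tests
  use in-gamut Lab values (out-of-gamut colors shift on the sRGB round
  trip).
* Degenerate inputs: all-endpoint regressions raise; empty foreground
  segmentations return empty masks; fewer distinct colors than k returns
  the distinct colors with merged weights.
* Acceptance-scale problem sizes (220–240 fruits per preset, 30–36-fruit
  training cohorts, 48 px renders, ≤5 epochs) are chosen so the full
  suite runs in well under a minute of simulation and a few minutes of
  training on a single CPU while leaving the Monte-Carlo spreads small
  relative to the quantities checked.

## Known limitations

* The renderer does not model camera optics, lighting geometry, texture
  or fruit shape variation; real-data accuracies are out of reach of the
  synthetic cohort by construction.
* Stage semantics are encoded entirely in the palette/speckle/mold
  configuration; a palette with overlapping anchors makes stages
  genuinely ambiguous (useful for stress tests, not for sanity checks).
* The day-rounding residual in the dwell calibration grows as dwells
  approach one day; presets much faster than ~1 day/stage would need a
  finer correction.
* Censoring-aware survival modeling of shelf-life is out of scope;
  censored fruits simply drop out of the regression.
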