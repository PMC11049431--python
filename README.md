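# avoshelf

Image-based ripening assessment and shelf-life estimation for 'Hass'
avocado (*Persea americana*).

Avocados are climacteric: they ripen only after harvest, and their visual
trajectory — yellow-green skin, olive/brown darkening, scattered purple,
homogeneous purple, mold — tracks an ordinal **Ripening Index** (RI),
either 5 stages or a finer 10-stage variant in which each classical stage
is halved. End of shelf-life is the first attainment of stage 5 (of 5),
equivalently stage 9 (of 10). `avoshelf` implements the full analysis
pipeline around that index for cohorts of fruits stored under three
regimes (T10 = 10 °C, T20 = 20 °C, Tamb = fluctuating room temperature):

* **`synthetic_orchard`** — simulates labeled cohorts: per-fruit ripening
  trajectories with lognormal speed heterogeneity and gamma dwell noise,
  two photographed sides per fruit per day, and schematic renders whose
  CIELAB color statistics separate the stages (blemishes, purple
  speckling, mold spots included).
* **`fruitdb`** — the labeled-image database model: RI5/RI10 semantics,
  the *Days Left* annotation (days until the end-of-shelf-life stage,
  censoring-aware), CSV/PNG I/O, and the dry-matter maturity utility
  DM% = dehydrated/raw × 100.
* **`splitting`** — leakage-free 70/15/15 splits grouped by fruit, with
  random oversampling of minority stages in the training set only.
* **`colorlab`** — background segmentation, colorimeter-style Lab
  calibration, per-image 5-color k-means palettes, and cohort-level
  6-color predominance palettes.
* **`ripenet`** — the stage classifier: subtle geometric augmentation,
  minibatch SGD with momentum, step LR schedule, periodic validation
  with patience, best-checkpoint selection. The default backbone is a
  small numpy CNN that trains on one CPU in minutes.
* **`evalmetrics`** — margin-of-error accuracy per picture and per
  sample (best side), per-stage accuracy, confusion matrices, and
  two-model error-overlap analysis.
* **`shelflife`** — the forced-endpoint regression and loss analysis
  (below), plus Gaussian KDE of losses with a 1-day bandwidth.
* **`pipeline`** — one-command orchestration of all of the above with a
  JSON run manifest; `avoshelf` CLI included.

## The shelf-life model

For each storage group, *Days Left* is linear in the Ripening Index and
must vanish at the end-of-shelf-life stage *E*:

    Days Left = α · (RI − E),   E = 5 (5-stage) or E = 9 (10-stage),

with α (days/stage, negative) estimated by ordinary least squares through
the origin in x = RI − E: α̂ = Σxy / Σx², with Student-t 95% confidence
interval on n − 1 degrees of freedom and uncentered R². Prediction loss
is `loss = estimated − actual` shelf-life; summaries report mean |loss|
per group and overall (groups equally weighted), per picture and per
sample (best side of the two photographs).

## Worked example

Simulate the default cohort (192 T10 + 143 T20 + 143 Tamb fruits,
photographed on both sides daily until stage 10) and fit the 10-stage
shelf-life regressions:

```python
import pandas as pd
from avoshelf.synthetic_orchard import CohortConfig, simulate_cohort
from avoshelf.shelflife import fit_group_models

trajectories, records = simulate_cohort(CohortConfig(), rng_seed=42)
print(f"{len(trajectories)} fruits, {len(records)} labeled photographs")
models = fit_group_models(records, index_system=10)
print(pd.DataFrame([{"group": g, "alpha": round(m.alpha, 3),
                     "ci95": round(m.alpha_ci95, 3),
                     "r_squared": round(m.r_squared, 3), "n": m.n}
                    for g, m in models.items()]).to_string(index=False))
```

```
478 fruits, 14586 labeled photographs
group  alpha  ci95  r_squared    n
  T10 -2.455 0.012      0.959 7358
  T20 -1.132 0.008      0.967 2496
 Tamb -1.014 0.008      0.964 2202
```

Each α is the estimated days of shelf-life lost per 10-stage step: T10
fruits ripen roughly half as fast as T20/Tamb fruits (≈2.4 vs ≈1.1 days
per stage), and `estimate_days_left(model, ri)` converts any stage
classification into a days-left estimate (0 at stage 9 and beyond).

A full experiment — render images, split, train the classifier, evaluate,
regress, and analyse losses — is one call (or `avoshelf report`):

```python
from avoshelf.pipeline import ExperimentConfig, run_experiment
manifest = run_experiment(ExperimentConfig(seed=7), "runs/demo")
```

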