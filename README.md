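# moodcast

Forecasting self-reported mental states from passive smartphone sensing,
with evaluation that takes class imbalance seriously.

In digital-phenotyping studies of severe mental illness, participants rate
symptoms ("Have you been… depressed / hearing voices / feeling calm?") on
4-point ordinal scales while their phone passively records mobility,
activity, sleep, phone-usage and ambient-conversation features. Most
predictive work collapses these ratings to binary targets and reports
accuracy — which a majority-class predictor inflates badly, because labels
like "worried about people trying to harm you" put ~80% of mass on "Not at
all". `moodcast` implements a factorial forecasting benchmark over:

- **10 mental-state items** (5 positive, 5 negative valence),
- **3 forecast horizons** (same day, next day, next week — 3 days / 12
  six-hour periods of sensing input per example),
- **2 learning tasks** — ordinal regression on the original 0-3 scale
  vs. binary classification after the best-balanced recoding,
- **2 algorithms** — gradient-boosted trees (XGBoost) on the flattened
  block vs. an LSTM over the 12-period sequence with a rank-consistent
  CORN ordinal head,

for 120 model conditions and 60 Monte Carlo baseline conditions.

## The evaluation mathematics

For ordinal predictions the headline metric is the **macro-averaged mean
absolute error**

    MAMAE = (1/|C|) * sum_{c in C} mean_{i: y_i = c} |ŷ_i - c|,

which weights every class equally regardless of frequency; binary models
use **balanced accuracy** BAcc = (TPR + TNR)/2. Both are mapped to a
common **scale-normalized balanced error** in [0, 1] (binary: 1 - BAcc;
ordinal: per-class MAE divided by its worst achievable error max(c, 3-c),
then averaged) so the two task formulations can be compared directly.
Significance is assessed against a resampling baseline: prediction vectors
drawn with replacement from the condition's training labels and scored
against the test labels, with the model called significant only when it
beats the baseline's quantile at the Bonferroni-corrected level
0.05/120 ≈ 4.2e-4. Class imbalance is (majority − minority)/total.

Because the original cohort data cannot be redistributed, the package
ships a synthetic cohort generator (ordered-probit latent model with a
participant random intercept and AR(1) daily state) that reproduces the
study's structure: tri-weekly surveys, heavily skewed item marginals,
complete 4-period sensing days, and a controllable feature-label signal
with `signal_strength = 0` giving an exact null. See `docs/methods.md`.

## Worked example

```bash
python analysis/01_simulate_cohort.py --small        # 20 participants x 120 days
python analysis/02_run_benchmark.py                  # gbt grid, desk scale
python analysis/03_cross_condition_stats.py
python analysis/04_imbalance_figures.py              # needs matplotlib
```

A desk-scale run (20 participants, default signal, gradient-boosted
models over all 60 item x horizon x task conditions) prints, per
condition, the test metric against its baseline threshold and finishes
with a summary like:

```
completed 60 conditions in 1658s
significant vs baseline: 48/60
ordinal  mamae: median 0.779 range [0.606, 1.000]
binary   bacc: median 0.710 range [0.551, 0.815]
```

meaning 48 of the 60 models beat their Monte Carlo baseline at the
corrected threshold; ordinal models err by ~0.78 rating points per class
on average (0 = perfect, ~1.2-1.5 is baseline level depending on the item
skew), and binary models reach a median 71% balanced accuracy (50% =
chance). The statistics script then reports the cross-condition battery;
on this run:

```
ordinal vs binary mean residual (common 0-1 error scale): +0.0063 (sd 0.0639)
friedman_horizon_ordinal  Q=18.2  p=1.1e-04
spearman_ordinal_imbalance_vs_mamae  rho=+0.470  p=0.0088
spearman_ordinal_imbalance_vs_mae    rho=-0.211  p=0.26
```

— neither task formulation outperforms the other on the common error
scale, performance degrades slightly but systematically with the forecast
horizon, and imbalance correlates positively with the balanced error
metric but negatively with plain MAE: the metric-choice artifact the
benchmark is designed to expose.

Library use mirrors the scripts:

```python
from moodcast import BenchmarkConfig, CohortConfig, run_benchmark

cfg = BenchmarkConfig(
    cohort=CohortConfig(n_participants=16, days_per_participant=90, seed=0),
    algorithms=("gbt",), tuning_trials=3, seed=0,
)
result = run_benchmark(cfg, out_dir="results/benchmark")  # resumable
print(result.conditions[["item", "task", "mamae", "bacc", "significant"]])
```

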