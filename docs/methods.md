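# Methods

`moodcast` benchmarks two ways of forecasting ordinal mental-state
self-reports from passive smartphone sensing — ordinal regression on the
original 4-point scale versus binary classification after recoding — with
two learner families (gradient-boosted trees and a recurrent network) over
three forecast horizons, under evaluation metrics that are robust to heavy
class imbalance. Because the package must be testable without any data
download, it ships a synthetic cohort generator that emulates the
statistical structure such studies produce.

## Synthetic cohorts

**Latent model.** Each participant p carries a stable trait a_p ~ N(0, 1)
and a daily AR(1) state s_{p,d} with stationary unit variance and
autoregressive coefficient phi (default 0.8). The combined "distress"
latent is

    u_{p,d} = sqrt(tau) * a_p + sqrt(1 - tau) * s_{p,d},   tau = 0.5,

so half the latent variance is between-person. Ratings follow an ordered
probit: item j on survey day d has latent

    z = s_j * lambda * u_{p,d} + sqrt(1 - lambda^2) * eps,

with s_j = +1 for negative-valence items, -1 for positive ones, and
lambda = 0.8. z is marginally standard normal, so cutting it at the
inverse-CDF cutpoints of the configured class proportions reproduces
those proportions exactly in expectation, for any signal level. Item
marginals default to the skew the study population shows: the three rare
psychotic-symptom items put 76-81% of mass on "Not at all" and 3% on
"Extremely"; positive items skew high with 33-48% majorities; Social is
flat enough that its best-balanced binary cutoff is the 2-vs-2 split.
All items share the single latent driver; what makes rare-event items
harder downstream is not a generator dial but the arithmetic of their
marginals (few minority examples to learn from and score on).

**Features.** Eighteen sensing features (activity durations, distance,
distinct locations, phone unlocks, calls/SMS, ambient conversations) are
drawn per 6-hour period from right-skewed families — gamma with shape 1.6
for durations/distances, Poisson for counts — whose log-means carry
period-of-day offsets, a weekend effect, and a signal term
`signal_strength * beta_f * u_{p,d}` with fixed per-feature loadings
(mobility and social features load negatively on distress, phone-checking
and stillness positively). Sleep start/duration are truncated-normal per
day and repeated across that day's periods; calendar features complete the
24-column schema. At `signal_strength = 0` no feature depends on u, so
labels are independent of features by construction — the null generator
used for type-I-error checks.

**Cadence and determinism.** Surveys fall on Mondays, Wednesdays and
Fridays with a 3% chance of shifting to an adjacent day. One master seed
spawns per-participant substreams (`numpy` SeedSequence), so cohorts are
byte-identical across runs and unchanged by parallel generation order.

**What the generator does not emulate.** Inter-feature covariance beyond
the single latent driver, missing data (the emulated dataset has none),
raw sensor traces, device effects, and any real joint feature-label
geometry. Passing tests therefore show that the *pipeline and analyses*
behave correctly on data with the right marginal and direction-of-effect
structure, not that the models would achieve any particular accuracy on
real cohorts.

## Splitting and features

The split is participant-wise and chronological: the last 7 surveys per
participant are the test set, the previous 7 the validation set, all
earlier ones training; participants with fewer than 21 surveys are
excluded. Each survey is paired with 12 consecutive 6-hour periods (3
days) of sensing ending `horizon` days before it (0, 1 or 7); incomplete
windows are dropped and counted, never imputed. Features are made
Gaussian-like with a Yeo-Johnson power transform (maximum-likelihood
lambdas) plus z-scoring, fitted on training examples only — an explicit
no-leakage choice; final models refit the transform on train+validation,
mirroring final-fit practice. Tree models see the row-major flattened
12xF block with period-indexed column names; the recurrent models see the
(12, F) sequence.

## Models

**Gradient-boosted trees** (XGBoost, `hist`, single-thread). Ordinal:
squared-loss regression on the raw ratings, discretized by three strictly
increasing thresholds; the thresholds are searched jointly with the
hyperparameters — each of the 10 trials draws one gap-parameterized
proposal around the default midpoints (0.5, 1.5, 2.5), which always remain
in the candidate set — and the trial minimizing validation MAMAE wins. A
prediction exactly at a threshold goes to the upper class. Binary:
cross-entropy classifier whose decision threshold is chosen on validation
BAcc by default (`fixed_binary_threshold = 0.5` reproduces the naive
protocol). Hyperparameters are drawn by seeded random search over
max_depth 2-8, learning rate 1e-3-0.3 (log), 50-500 trees, subsample
0.5-1, min_child_weight 1-10.

**Recurrent models.** A single-layer LSTM (128 hidden units, 10% dropout
on the last hidden state, 150 epochs by default) implemented directly in
numpy with hand-written backpropagation through time and Adam; gradients
are verified against finite differences in the test suite. The ordinal
head is CORN: three conditional binary tasks (y>0; y>1 given y>0; y>2
given y>1), each trained with cross-entropy on its conditional subset;
unconditional exceedance probabilities are the running products of the
conditional sigmoids, which makes P(y>0) >= P(y>1) >= P(y>2) a structural
identity rather than a learned tendency. The predicted class is the
number of exceedance probabilities above 0.5. Learning rate and batch
size come from a short seeded range test (5-epoch probes over a small
grid); the best epoch is selected on the validation metric (MAMAE or
BAcc) every 10 epochs, and the final network is refit on
train+validation for that many epochs. Both behaviors can be disabled to
recover the literal fixed-150-epoch protocol.

## Evaluation and statistics

MAMAE averages the per-true-class MAE with equal class weights over the
classes present; BAcc is the mean of sensitivity and specificity. The
scale-normalized balanced error puts both tasks on one 0-1 scale: binary
error is 1 - BAcc; ordinal error divides each per-class MAE by the
largest error achievable for that class, max(c, 3 - c) on the 0-3 scale,
before averaging. This normalization is a reconstruction from the stated
properties (0-1 range, 0 at perfect, cross-task comparability); any
monotone variant would leave the rank-based downstream tests unchanged.
Class imbalance is (majority - minority) / total over the classes
present.

The Monte Carlo baseline draws test-length prediction vectors with
replacement from the condition's training labels — "best-guess"
predictions from past self-reports — and scores them against the true
test labels (12,000 draws by default; 1,000 reproduces the literal
protocol but cannot resolve the corrected quantile, in which case the
extreme order statistic is used and the call is flagged
resolution-limited). A model is significant when strictly better than the
inverse-ECDF quantile of that distribution at alpha = 0.05/120 ≈ 4.2e-4
(lower tail for MAMAE, upper for BAcc). Cross-condition comparisons:
two-sided Wilcoxon signed-rank between algorithms (zeros dropped; exact
null for small tie-free samples, normal approximation with continuity
correction otherwise), Friedman tests across horizons and items,
Spearman correlations between class imbalance and each metric, and the
identity-line residuals of ordinal vs binary normalized error.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced problem sizes chosen as this
package's own desk-scale study conditions: sign-pattern analyses use a
30-participant x 60-day cohort over the full 60-condition
(item x horizon x task) grid; signal-recovery and task-equivalence use
20-28-participant x 150-day strong-signal cohorts at the same-day
horizon;
type-I control uses five 10-participant null cohorts on a reduced grid.
Marginal-recovery checks need many participants (700) because the
participant random intercept, not the rating count, limits how fast
realized marginals converge. Degenerate cases are handled explicitly:
all-zero Wilcoxon differences give (statistic 0, p 1); Friedman with
identical treatments in every block gives (Q 0, p 1); near-constant
features degenerate to identity-plus-centering in the power transform;
single-class validation slices fall back to default thresholds with a
warning; single-class training labels are an error for binary fits.

## Known limitations

The generator's single-latent design caps how rich the reproduced
correlation structure can be; effect sizes are not calibrated to any real
cohort, only directions. Wilcoxon/Friedman/Spearman are delegated to
scipy and checked against small enumeration oracles. The recurrent
implementation is CPU-only and full-precision; at very large hidden sizes
or cohort scales a framework implementation would be preferable.
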