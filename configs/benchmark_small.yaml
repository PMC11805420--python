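# Desk-scale benchmark configuration.
#
# Schema (all keys optional; defaults reproduce the full-study protocol):
#   cohort:                  synthetic cohort parameters
#     n_participants         participants in the cohort (default 60)
#     days_per_participant   follow-up days, int or per-participant list (365)
#     survey_weekdays        weekday indices prompted for surveys ([0, 2, 4])
#     survey_shift_prob      chance a survey shifts to an adjacent day (0.03)
#     signal_strength        feature-label coupling; 0 = null generator (1.0)
#     ar_coefficient         AR(1) coefficient of the daily latent state (0.8)
#     item_marginals         per-item class proportions over ratings 0-3
#     seed                   cohort master seed
#   items / horizons / tasks / algorithms   the benchmark grid axes
#   tuning_trials            hyperparameter search budget per model (10)
#   rnn_hidden / rnn_epochs  recurrent architecture (128 / 150)
#   n_baseline_draws         Monte Carlo baseline draws (12000)
#   n_models_for_correction  Bonferroni family size (120)
#   fixed_binary_threshold   null = tune on validation BAcc; 0.5 = naive cut
#   seed                     master seed for per-condition substreams

cohort:
  n_participants: 16
  days_per_participant: 90
  signal_strength: 1.0
  seed: 0
items: [Calm, Social, Depressed, Harm]
horizons: [0, 7]
tasks: [ordinal, binary]
algorithms: [gbt, rnn]
tuning_trials: 3
rnn_hidden: 64
rnn_epochs: 40
n_baseline_draws: 12000
seed: 0
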