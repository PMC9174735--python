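# Synthetic end-to-end run. Swap the `synthetic` block for an `inputs` block
# (paths to interactions/coalitions/presence/focal/conceptions CSVs) to
# analyse real tables.
seed: 1
synthetic:
  population:
    n_groups: 1
    adult_males_per_group: 10
    study_days: 500
    seed: 1
  coalitions:
    event_rate: 0.1
  paternity:
    n_conceptions: 19
elo:
  start_value: 1000.0
  k: 100.0
  expected_score: logistic-400
windows:
  stability: 30
  aggression: 30
  conception: 11
  step: 10
  horizon: 120
model:
  include_autocorr: true
  bootstrap_B: 1000    # reduce for quick exploratory runs
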