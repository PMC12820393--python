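# Demonstration run: a small simulated campaign through the full pipeline.
# Cohort sizes are reduced relative to the emulated study design to keep the
# demo fast; the effect matrix is the packaged illustrative one.
simulation:
  cohorts:
    HC: 5
    CD: 5
    UC: 5
    IBS: 4
  effect_matrix: default
  cv_log: 0.6
  depletion_timescale_min: 40.0
  noise_sd_rfu: 15.0
  high_background_fraction: 0.2
  high_background_multiplier: 50.0
  replicates: 3
  seed: 20

qc:
  policy: adaptive
  k: 10

kinetics:
  t_min_window: 5
  t_max_window: 20
  min_points: 4
  linearity_tol: 0.02
  activity_floor_rfu_per_min: 1.0

profiling:
  level: class
  scope: per_ph

stats:
  comparisons:
    - [UC, CD]
    - [CD, HC]
    - [UC, HC]
  roc:
    - {positive: UC, negative: CD, substrate: Ac-RSVL-AMC, ph: 5.5}

seed: 20
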