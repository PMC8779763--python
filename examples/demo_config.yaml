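# End-to-end demo: generate a synthetic 20-week study from the
# moderate-expansion reference truth, run the soluble-phase workflow,
# fit base / linear / sigmoid models and derive consensus trajectories.
seed: 42
output_dir: demo_out

regimen:
  dose_mg_per_kg: 25.0
  weeks: 20
  pattern: [1, 2, 3, 4, 5]   # Monday-Friday, first dose on day 1

generate:
  truth:
    expansion: {kind: hill_exp, emax: 2.5, t50: 49.0, hill: 3.71}
    init: {v1: 2.43, v2: 0.00708, k: 0.229, k12: 0.183, k21: 3.36}
  sigma_serum: 0.1
  sigma_spleen: 0.1

soluble_phase:
  t_max: 28.0
  fix: [v1, k12]

models:
  - name: base
    expansion: {kind: constant}
    init: {v1: 2.43, v2: 0.00708, k: 0.1, k12: 0.183, k21: 1.0}
  - name: linear
    expansion: {kind: linear, x: 0.05}
    init: {v1: 2.43, v2: 0.00708, k: 0.1, k12: 0.183, k21: 1.0}
  - name: hill_exp
    expansion: {kind: hill_exp, emax: 1.8, t50: 60.0, hill: 3.71}
    fixed: [hill]
    init: {v1: 2.43, v2: 0.005, k: 0.15, k12: 0.183, k21: 2.0}

fitting:
  n_multistart: 3
  dt_max: 0.25

bootstrap:
  n_reps: 0      # set to e.g. 200 for CIs on the best model

derived:
  t_max: 140.0
  dt: 1.0

spleen_weight:
  w0_g: 0.1
  wmax_g: 0.5
  body_weight_kg: 0.02
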