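# Per-protocol defaults: training weights, scale knobs, environment settings.
# Values here override the protocol functions' signatures; CLI flags override
# both.  lambda_dev weights the policy-deviation KL, lambda_cx the
# variational-dropout complexity of the default pathway.
nav-ablation:
  lambda_dev: 0.1
  lambda_cx: 0.0003
  updates: 1500
nav-generalization:
  lambda_dev: 0.1
  lambda_cx: 0.00015
  updates: 1200
  adapt_updates: 60
stroop:
  lambda_dev: 0.5
  lambda_cx: 0.0001
  updates: 2500
demand-avoidance:
  lambda_dev: 0.5
  lambda_cx: 0.0001
  pretrain_updates: 2000
  updates: 2000
shape-naming:
  lambda_dev: 0.5
  lambda_cx: 0.0001
  pretrain_updates: 2000
  shape_trials: 44000
zero-shot-stroop:
  lambda_dev: 0.5
  lambda_cx: 0.0001
  updates: 2500
two-step:
  lambda_dev: 0.05
  lambda_cx: 0.0001
  updates: 2500
bandit-perseveration:
  lambda_dev: 0.2
  lambda_cx: 0.001
  updates: 1200
contingency-degradation:
  lambda_dev: 0.3
  lambda_cx: 0.0001
  durations: [500, 2000, 8000]
  post: 8000
heuristic-choice:
  lambda_dev: 2.0
  lambda_cx: 0.0003
  updates: 2500
heuristic-kl-sweep:
  lambda_dev_high: 2.0
  lambda_dev_low: 0.1
  lambda_cx_high: 0.0003
  lambda_cx_low: 0.0001
  updates: 2500
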