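# Methods

## Model

The agent is a dual-pathway recurrent policy. Both pathways are gated
recurrent (GRU) networks of the same shape over the same observation
vector; they differ only in regularization and role:

- **Default pathway (π₀)** — a *noisy, compressed* policy. Every weight
  matrix carries factorized Gaussian posteriors `w ~ N(θ, σ²)` whose KL
  against the scale-invariant log-uniform (Jeffreys) prior is penalized:
  sparse variational dropout (VDO). The per-connection dropout rate is
  `α = σ²/θ²`; the KL depends on α alone and vanishes as `α → ∞` (a pruned
  connection is free). A per-feature-group multiplicative input gate with
  its own variational noise sits in front of the network. During training
  the noise is sampled (local reparameterization: activations receive mean
  `xθ` plus Gaussian noise `√((x²)σ²)·ε`); evaluation uses the posterior
  means (`noise="mean"`).
- **Control pathway (π)** — a deterministic network of the same shape with
  a linear value head. It emits the overt action distribution; π₀ is its
  compressed understudy.

The training objective (minimization form) is

    L = −E[R] + λ_dev · KL(π ‖ π₀) + λ_cx · KL_VDO(q(w) ‖ p(w)),

i.e. expected return, a deviation cost pricing each step's divergence of
the control policy from the default policy (mean over timesteps, in nats),
and the complexity cost of the default pathway's weight posterior. The
deviation term backpropagates into *both* pathways by default: it pulls π
toward π₀ (a cost of control) and distills π into π₀ (habit formation).
Stop-gradient variants (`deviation_grad="pi_only" / "pi0_only"`) are
available for ablation studies.

Because the deviation term is an expectation over trajectories, its
gradient has two parts: the pathwise gradient through the two
distributions at visited states, and a score-function part through the
probability of *reaching* those states. The latter is implemented by
subtracting `λ_dev·KL_t/T̄` from the reward stream that enters the
advantage. Without it, the agent's *choices among futures* could never
respond to control demand (demand avoidance requires exactly this).

Optimization is advantage actor-critic over full episodes with Adam:
policy surrogate with value-baseline advantages, 0.5-weighted value
regression, and a small entropy bonus on π (default 0.01; the
reward-learning tasks use 0.05 to keep choice behavior stochastic). The
VDO KL uses the standard sigmoid closed-form approximation to the
Gaussian-vs-log-uniform KL, validated against a Monte-Carlo oracle in the
test suite (the improper prior fixes the KL only up to a constant; the
constant is chosen so KL → 0 as α → ∞). `complexity_warmup` optionally
anneals λ_cx linearly from 0 — standard KL warm-up, used where the default
pathway must first learn a behavior before compression carves it back.

"Overwrites" semantics: π is an independent head that replaces π₀ for
overt action; a config flag (`feed_default_to_control`) optionally feeds
π₀'s output distribution into π's input instead. All defaults use
independent heads.

## Architecture defaults and units

| Parameter | Default | Notes |
|---|---|---|
| hidden size | 48 per pathway | small recurrent nets suffice at this scale |
| init α | 0.05 | initial dropout rate of variational connections |
| λ_dev | per protocol (0.1–0.5) | nats of deviation KL per step |
| λ_cx | per protocol (1e-4–3e-4) | per-nat weight of the VDO complexity sum |
| γ | 0.9–0.95 | discount |
| lr | 2e-3–3e-3 | Adam |
| KL floor | 1e-8 | probability clip before log-ratios |
| RT threshold | 1.5 evidence units | accumulator; sensitivity {1.0, 1.5, 2.0} covered in tests |

Reaction time is modeled by per-action evidence accumulators that each
gain the action's probability per cycle; RT is the first cycle the leading
accumulator reaches threshold, `ceil(threshold / p_max)` for a static
distribution. Less concentrated policies — e.g. π pulled toward a
disagreeing π₀ on conflict trials — respond more slowly.

## Gate readout

The gating layer exists in the architecture (a per-group multiplicative
weight with variational noise), but the *reported* gate vector is
functional: for a probe batch of observations (and recurrent states cached
from recent rollouts), each feature group is zeroed in turn and the mean
KL shift `s_g` of π₀'s output distribution is measured under sustained
(5-step) presentation; the attention weight is `1 − exp(−s_g) ∈ [0, 1]`.
This measures what the pathway *processes* rather than a raw parameter,
which proved nearly unidentified (downstream weights can rescale a purely
parametric gate arbitrarily). At initialization all readouts are equal
(zero); a group the pathway ignores reads ≈ 0.

A caveat discovered at this scale: in the two-goal grid task the maximally
compressed habit ("drift toward the frequent corner goal") is almost
input-free, so *all* attention weights are near zero after training and
the goal-cue weight is minimal only up to probe resolution; the gate
signature for navigation therefore ranks gates above a small sensitivity
floor (0.05). The Stroop version of the signature (word gate strictly
maximal) is strict.

## Environments (synthetic data)

All environments are seeded, bit-reproducible generators with a uniform
`reset/step` contract; `info` carries every label the analyses use. They
emulate the *trial statistics* of the tasks, not stimulus surface form:

- **Grid navigation**: 5×5 grid, goals {(0,0), (4,4)}, cue frequencies
  80/20, reward 1 at the cued goal, step cost −0.01, horizon 20. The
  generalization variant cues goals by grid cell so held-out goals can be
  introduced.
- **Stroop**: one-hot word {RED, BLUE, none} ⊕ color {red, blue, none} ⊕
  task cue {WR, CN}; single-step trials; word-reading on 75% of training
  trials, 50% incongruent within each task. `neutral_only` omits the
  irrelevant dimension (zero-shot regime).
- **Demand choice**: a cued meta-choice between two 8-trial color-naming
  blocks with incongruent proportions 0.9 vs 0.1 (the cue marks which
  action leads to the low-incongruence block, counterbalanced).
- **Shape naming**: colored shapes with arbitrarily assigned color names;
  color-naming dominant in pretraining (80%), then a long shape-naming
  phase (90%); congruence = assigned name matches display color.
- **Two-step**: stage-1 binary choice; common transition 0.8; stage-2
  reward probabilities on reflecting Gaussian walks (sd 0.025 in
  [0.25, 0.75]); the stage-1→stage-2 mapping reverses with hazard 0.02 and
  is signalled by an observation feature. Sessions of 40 (training) to 150
  (evaluation) trials; observations carry the previous action and reward,
  so reward tracking is in-context (recurrent), not by weight updates.
- **Drifting bandit**: two arms on reflecting walks (sd 0.05 in
  [0.05, 0.95]); sessions as above.
- **Contingency degradation**: free-operant press/abstain; reward with
  p=0.5 contingent on pressing during training, action-independent after
  a cumulative-step onset; pressing carries a 0.2 effort cost (without an
  effort cost the phenomenon is undefined — there is never a reason to
  stop pressing); the step counter persists across episodes so a single
  agent traverses the phases in order while learning online.
- **Multi-attribute choice**: two binary 4-feature options under
  non-compensatory weights (8, 4, 2, 1) — each weight exceeds the sum of
  all smaller ones, the regime where one-reason decision making is
  adaptive; ties resampled; a payoff knob rescales the reward gap.

What the generators do *not* emulate: perceptual noise, continuous
response dynamics, motivational states, inter-subject variability.
Passing tests show the computational-level signatures under matched trial
statistics; they do not certify fits to any empirical dataset.

## Behavioral analyses

All logistic fits are maximum likelihood with a weak ridge (1e-4, recorded
in every result) via Newton/IRLS; standard errors come from the inverse
penalized Hessian (cross-checked against an unpenalized reference fit in
tests). Pattern calls use coefficient sign plus |z| ≥ 2 — a repo
convention. The stay regression uses intercept-free condition coding over
the four previous-trial conditions {common, uncommon} × {rewarded,
unrewarded}; the bandit regression uses, per lag k ≤ 20, the signed
choice×outcome product (reward seeking), signed choice (perseveration) and
signed outcome (main effect). Degradation half-decay smooths the press log
with a 50-step trailing window, evaluated only on windows wholly inside
the degradation phase (so the smallest measurable decay equals the window
length), and reports the first time the rate halves relative to its
pre-onset mean (∞ if never).

## Scale

All protocols run at reduced scale on one CPU: hidden size 48, 1–4k
gradient updates per protocol, evaluation sets of 10²–10³ episodes.
Episode counts are roughly 1–10% of what a full-scale replication would
use; the CLI runs three seeds by default, and the shipped test suite uses
between one and five seeds per protocol (more where training is cheap,
fewer where it is expensive) so that the whole suite fits a single-CPU
desk budget. Each protocol exposes a `scale` knob (and `--full` in the
CLI) to raise the budget. The 44,000-trial shape-naming schedule is run
at its stated length (single-step trials make it cheap).

## Per-protocol training settings

Executive-control tasks (navigation, Stroop family, shape naming,
zero-shot, demand choice) train with γ 0.95 (0.9–1.0 where episodic
structure differs), lr 3e-3, entropy 0.01, and the λ values in
`configs/defaults.yaml`. The reward-learning tasks are meta-learning
problems (the agent must adapt within a session from its recurrent state);
they use γ 0.8–0.9, entropy 0.03–0.05, and short training sessions with
longer evaluation sessions. Contingency degradation additionally slows the
default pathway's learning rate to 0.3× (the habit system as the slow
learner) — without this, π₀'s commitment saturates long before the longest
training duration and the duration effect vanishes. The demand-avoidance
protocol pretrains on standard Stroop (padded to the choice task's
observation layout) so that the word-reading habit, and hence the conflict
cost of incongruent color naming, is in place before block choices are
learned.

## Known limitations

- The two-step model-based/model-free split did not emerge at this scale:
  the best weighting yields a model-free π beside a perseverative π₀, and
  longer training collapses both toward repetition through the
  distillation loop. The sweep reports the observed patterns per cell
  honestly; the mapping-cue design also makes "model-based" behavior
  cue-conditional rather than inferential.
- In the drifting bandit, the regularized agent perseverates significantly
  while also seeking reward, but the unregularized baseline carries
  transient choice-autocorrelation that decays only with training lengths
  beyond this package's default budgets, so the baseline contrast is
  under-powered at desk scale.
- The generalization advantage of regularized pretraining (faster
  adaptation to held-out goals) does not reproduce at this scale: the
  small unregularized network already generalizes through the
  position-coded goal cue.
- Contingency half-decay times are high-variance summaries; orderings are
  evaluated on seed means with censoring at the observation window.
- Gate readouts are functional sensitivities, not synaptic quantities.
- Mean-mode evaluation removes weight noise but keeps policy
  stochasticity; reported RTs are accumulator cycles, not milliseconds.
- The λ ranges were tuned per protocol at this scale; they are not claimed
  to be scale-invariant.
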