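# mdlc — minimum description length control

Dual-process phenomena — automatic vs. controlled responding, habitual
vs. goal-directed learning, heuristic vs. deliberative judgment — recur
across cognitive domains. `mdlc` implements a single computational account
of all of them: an agent that maximizes reward while minimizing the
*description length of its own behavior*. The package is for computational
cognitive scientists who want to train the agent on the classic paradigms
and reproduce (or probe) its dual-process signatures.

## The model

The agent holds two identically shaped recurrent policies over the same
input. The control policy π emits overt actions; the default policy π₀ is
a compressed understudy. Training minimizes

```
L = −E[R]  +  λ_dev · E[ D_KL(π ‖ π₀) ]  +  λ_cx · D_KL( q(w₀) ‖ p(w₀) )
```

where the last term is a sparse variational-dropout penalty: every
default-pathway weight carries multiplicative Gaussian noise `w = θ(1+√α ε)`
whose KL against the scale-invariant log-uniform (Jeffreys) prior depends
only on the dropout rate α and vanishes as the connection is pruned.
The deviation term distills π into π₀ (habit formation) and pulls π toward
π₀ (a cost of control). From this one objective the simulations recover:
cue-neglecting habits under control ablation, Stroop interference and its
reaction-time profile, demand avoidance, side-by-side model-based (π) and
model-free (π₀) two-step profiles, choice perseveration, habit persistence
under contingency degradation, one-reason decision making, the reversal of
automaticity with practice, and zero-shot conflict robustness.

Everything — the autodiff engine, the recurrent pathways, the seven task
environments and the behavioral statistics — runs on numpy; there is no
deep-learning framework dependency.

## A worked example

Train the agent on the Stroop task and inspect the dissociation:

```python
from mdlc.protocols import stroop

res = stroop(seed=0)
print(res["accuracy"])        # control policy, per trial type
print(res["word_agreement"])  # default policy agreement with the word
print(res["mean_kl"])         # policy conflict per trial type
print(res["mean_rt"])         # accumulator reaction times
print(res["gates"])           # what pi0 attends to
```

Output from a run at the shipped defaults (seed 0):

```
{'WR_congruent': 1.0, 'WR_incongruent': 1.0, 'CN_congruent': 1.0, 'CN_incongruent': 1.0}
{'WR_congruent': 1.0, 'WR_incongruent': 1.0, 'CN_congruent': 1.0, 'CN_incongruent': 1.0}
{'WR_congruent': 0.010, 'WR_incongruent': 0.050, 'CN_congruent': 0.018, 'CN_incongruent': 0.710}
{'WR_congruent': 2.0, 'WR_incongruent': 2.0, 'CN_congruent': 2.0, 'CN_incongruent': 2.5}
{'word': 0.534, 'color': 0.019, 'task_cue': 0.001}
```

Read: the control policy answers every trial type correctly, while the
default policy always answers with the *word* — including on color-naming
incongruent trials, where that answer is wrong. Policy conflict (KL, nats)
and reaction time (accumulator cycles) are therefore maximal exactly on
color-naming incongruent trials — Stroop interference — and the default
pathway's attention weights show it processes the word while largely
ignoring ink color and task cue.

The same interface runs every simulation (`mdlc run two-step`,
`mdlc run contingency-degradation`, ... or `mdlc.protocols.run_protocol`);
each writes tidy CSV tables and a JSON report of its qualitative
signatures, and `mdlc sweep` repeats a protocol over a grid of
(λ_dev, λ_cx) weightings.

See `docs/methods.md` for the model, environment statistics, analysis
conventions, and known limitations.

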