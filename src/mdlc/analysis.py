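"""Behavioral statistics for the dual-process simulations.

Implements the analyses the simulations are scored with: the two-step
stay-probability regression (model-based vs model-free signatures), the
20-lag choice-history regression for the drifting bandit (reward seeking,
perseveration, outcome main effect), an evidence-accumulator reaction time,
Gini coefficients over fitted choice weights (one-reason vs compensatory
decision making), per-condition policy-conflict (KL) profiles,
masked-input divergence, and the half-decay summary for contingency
degradation.

All logistic fits use maximum likelihood with a weak ridge penalty
(default 1e-4) to guard against separation; standard errors come from the
inverse penalized Hessian and the penalty is recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agent import ActionDistribution, MDLCAgent, policy_kl

DEFAULT_RIDGE = 1e-4
STAY_CONDITIONS = ["common_rewarded", "common_unrewarded",
                   "uncommon_rewarded", "uncommon_unrewarded"]
LAG_FAMILIES = ["reward_seeking", "perseveration", "outcome_main"]


# ---------------------------------------------------------------------------
# penalized logistic fitting
# ---------------------------------------------------------------------------

def ridge_logistic(X: np.ndarray, y: np.ndarray, penalty: float = DEFAULT_RIDGE,
                   max_iter: int = 200, tol: float = 1e-10):
    """Newton/IRLS fit of logit P(y=1) = X beta with an L2 penalty.

    Returns ``(beta, bse, flags)``; ``bse`` from the inverse penalized
    Hessian.  Raises on rank deficiency that the ridge cannot absorb.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    flags = {"penalty": penalty, "converged": False, "separation": False}
    H = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + penalty * np.eye(p)
        g = X.T @ (y - mu) - penalty * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"rank-deficient design: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            flags["converged"] = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.any((mu > 1 - 1e-8) & (y == 1)) or np.any((mu < 1e-8) & (y == 0)):
        flags["separation"] = True
    bse = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, bse, flags


# ---------------------------------------------------------------------------
# two-step stay regression
# ---------------------------------------------------------------------------

@dataclass
class StayRegressionResult:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    z: dict[str, float]
    pattern: str
    flags: dict = field(default_factory=dict)


def classify_stay_pattern(coef: dict[str, float], z: dict[str, float],
                          z_thresh: float = 2.0) -> str:
    """Sign + |z| convention for calling the regression pattern."""
    sig_pos = {k: coef[k] > 0 and z[k] >= z_thresh for k in STAY_CONDITIONS}
    mb = sig_pos["common_rewarded"] and sig_pos["uncommon_unrewarded"]
    mf = sig_pos["common_rewarded"] and sig_pos["uncommon_rewarded"]
    if mb and mf:
        return "perseverative" if all(sig_pos.values()) else "mixed"
    if mb:
        return "model_based"
    if mf:
        return "model_free"
    if all(sig_pos.values()):
        return "perseverative"
    return "mixed"


def fit_stay_regression(trials, penalty: float = DEFAULT_RIDGE
                        ) -> StayRegressionResult:
    """Logistic regression of staying with the previous stage-1 choice.

    ``trials``: per-trial records (dicts with ``stage1_action``,
    ``transition``, ``reward`` and optionally ``session``), at least 200.
    The design is intercept-free condition coding: one indicator per
    previous-trial condition in {common, uncommon} x {rewarded, unrewarded}.
    """
    trials = list(trials)
    if len(trials) < 200:
        raise ValueError("need at least 200 trials")
    rows, ys = [], []
    prev = None
    prev_session = None
    for tr in trials:
        sess = tr.get("session", 0)
        if prev is not None and sess == prev_session:
            cond = ("common" if prev["transition"] == "common" else "uncommon") \
                + ("_rewarded" if prev["reward"] > 0 else "_unrewarded")
            x = np.zeros(4)
            x[STAY_CONDITIONS.index(cond)] = 1.0
            rows.append(x)
            ys.append(float(tr["stage1_action"] == prev["stage1_action"]))
        prev, prev_session = tr, sess
    X, y = np.asarray(rows), np.asarray(ys)
    counts = X.sum(axis=0)
    if np.any(counts == 0):
        missing = STAY_CONDITIONS[int(np.argmin(counts))]
        raise ValueError(f"no trials in condition {missing}")
    # stay is coded against the 50% baseline: y=1 -> stay, so a positive
    # coefficient means staying is favored after that condition
    beta, bse, flags = ridge_logistic(X, y, penalty)
    coef = dict(zip(STAY_CONDITIONS, beta))
    ses = dict(zip(STAY_CONDITIONS, bse))
    zs = {k: abs(coef[k] / ses[k]) for k in STAY_CONDITIONS}
    return StayRegressionResult(coef, ses, zs,
                                classify_stay_pattern(coef, zs), flags)


# ---------------------------------------------------------------------------
# lagged bandit regression
# ---------------------------------------------------------------------------

@dataclass
class LaggedRegressionResult:
    n_lags: int
    coefficients: np.ndarray     # (L, 3) by family order LAG_FAMILIES
    standard_errors: np.ndarray  # (L, 3)
    flags: dict = field(default_factory=dict)

    def z(self) -> np.ndarray:
        return np.abs(self.coefficients / self.standard_errors)

    def family(self, name: str) -> np.ndarray:
        return self.coefficients[:, LAG_FAMILIES.index(name)]


def fit_lagged_regression(sessions, n_lags: int = 20,
                          penalty: float = DEFAULT_RIDGE
                          ) -> LaggedRegressionResult:
    """Choice-history regression over the last ``n_lags`` trials.

    ``sessions``: iterable of (choices, rewards) arrays with choices in
    {0,1} and rewards in {0,1}.  For each lag k the regressors are the
    signed product choice*outcome (reward seeking), the signed choice
    (perseveration) and the signed outcome (main effect), predicting the
    current choice.
    """
    rows, ys = [], []
    for choices, rewards in sessions:
        c = 2.0 * np.asarray(choices, float) - 1.0
        r = 2.0 * np.asarray(rewards, float) - 1.0
        for t in range(n_lags, len(c)):
            feats = []
            for k in range(1, n_lags + 1):
                feats.extend([c[t - k] * r[t - k], c[t - k], r[t - k]])
            rows.append(feats)
            ys.append(float(c[t] > 0))
    if len(rows) < 20 * n_lags:
        raise ValueError("need at least 20 x n_lags usable trials")
    X, y = np.asarray(rows), np.asarray(ys)
    beta, bse, flags = ridge_logistic(X, y, penalty)
    return LaggedRegressionResult(
        n_lags, beta.reshape(n_lags, 3), bse.reshape(n_lags, 3), flags)


# ---------------------------------------------------------------------------
# reaction time, gini, choice weights
# ---------------------------------------------------------------------------

def reaction_time(dist, threshold: float = 1.5, max_cycles: int = 100000) -> int:
    """Cycles for the leading accumulator to reach ``threshold``.

    Each cycle adds the action's probability to its accumulator, so for a
    static distribution this equals ceil(threshold / p_max).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    p = dist.probs if isinstance(dist, ActionDistribution) else np.asarray(dist)
    evidence = np.zeros_like(p)
    for cycle in range(1, max_cycles + 1):
        evidence = evidence + p
        if evidence.max() >= threshold:
            return cycle
    raise RuntimeError("accumulator failed to reach threshold")


def gini(weights) -> float:
    """Concentration of absolute weights: 0 (even) .. 1 - 1/n (one cue)."""
    w = np.abs(np.asarray(weights, dtype=float))
    if w.size < 2:
        raise ValueError("need at least 2 weights")
    if np.all(w == 0):
        raise ValueError("all-zero weight vector")
    x = w / w.sum()
    n = x.size
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2.0 * n * x.sum()))


def fit_choice_weights(trials, penalty: float = DEFAULT_RIDGE):
    """Logistic weights of feature differences on multi-attribute choices.

    ``trials``: records with ``option_a``, ``option_b`` and ``choice``
    (0 = chose a).  Returns ``(weights, flags)``; on separation the ridge
    penalty is what keeps the fit finite, and the flag is set.
    """
    trials = list(trials)
    if len(trials) < 500:
        raise ValueError("need at least 500 trials")
    X = np.asarray([np.asarray(t["option_a"]) - np.asarray(t["option_b"])
                    for t in trials])
    y = np.asarray([1.0 - t["choice"] for t in trials])  # 1 = chose a
    beta, _bse, flags = ridge_logistic(X, y, penalty)
    return beta, flags


# ---------------------------------------------------------------------------
# conflict profiles and masked divergence
# ---------------------------------------------------------------------------

@dataclass
class ConflictProfile:
    mean_kl: dict[str, float]
    mean_rt: dict[str, float]
    n: dict[str, int]


def conflict_profile(agent: MDLCAgent, probes, threshold: float = 1.5
                     ) -> ConflictProfile:
    """Per-condition mean policy conflict and reaction time (mean mode).

    ``probes``: records with ``obs`` and ``condition``; each probe is
    evaluated as a single step from the zero recurrent state.
    """
    kls: dict[str, list] = {}
    rts: dict[str, list] = {}
    for probe in probes:
        if "condition" not in probe:
            raise ValueError("unlabeled probe trial")
        step, _ = agent.forward_step(probe["obs"], noise="mean")
        cond = probe["condition"]
        kls.setdefault(cond, []).append(step.step_kl)
        rts.setdefault(cond, []).append(
            reaction_time(agent.behavior_dist(step), threshold))
    return ConflictProfile(
        mean_kl={c: float(np.mean(v)) for c, v in kls.items()},
        mean_rt={c: float(np.mean(v)) for c, v in rts.items()},
        n={c: len(v) for c, v in kls.items()},
    )


def masked_divergence(agent: MDLCAgent, stimuli, group: str) -> float:
    """Mean KL between pi's response to full and group-masked stimuli."""
    names = [n for n, _ in agent.config.feature_groups]
    if group not in names:
        raise KeyError(f"unknown feature group {group!r}")
    off = 0
    for n, w in agent.config.feature_groups:
        if n == group:
            sl = slice(off, off + w)
            break
        off += w
    total = 0.0
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    for obs in stimuli:
        masked = obs.copy()
        masked[sl] = 0.0
        full_step, _ = agent.forward_step(obs, noise="mean")
        mask_step, _ = agent.forward_step(masked, noise="mean")
        total += policy_kl(full_step.control_dist, mask_step.control_dist)
    return total / len(stimuli)


def rt_interaction_pvalue(rows) -> float:
    """Two-way factorial test (task x trial type) on accumulator RTs.

    ``rows``: records with ``task``, ``congruence``, ``rt``.  Returns the
    interaction p-value from an ordinary two-way ANOVA; a perfectly
    separated design (zero residual variance) counts as p = 0 when the
    interaction carries variance and 1 otherwise.
    """
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(rows)[["task", "congruence", "rt"]]
    model = smf.ols("rt ~ C(task) * C(congruence)", data=df).fit()
    tab = anova_lm(model, typ=2)
    inter = "C(task):C(congruence)"
    p = float(tab.loc[inter, "PR(>F)"])
    if np.isnan(p):
        return 0.0 if tab.loc[inter, "sum_sq"] > 1e-12 else 1.0
    return p


# ---------------------------------------------------------------------------
# contingency degradation decay
# ---------------------------------------------------------------------------

def degradation_decay(presses, onset: int, window: int = 50) -> float:
    """Steps after ``onset`` until the smoothed press rate halves.

    The press log is smoothed with a trailing window; post-onset rates are
    only evaluated on windows wholly inside the degradation phase, so the
    earliest detectable decay time equals the window length.  Returns
    ``inf`` if the rate never falls below half its pre-onset mean.
    """
    presses = np.asarray(presses, dtype=float)
    if onset < window or onset >= len(presses):
        raise ValueError("log must span the degradation onset")
    pre = presses[max(0, onset - 10 * window):onset].mean()
    if pre == 0:
        raise ValueError("zero pre-onset press rate")
    half = pre / 2.0
    csum = np.concatenate([[0.0], np.cumsum(presses)])
    for t in range(onset + window, len(presses) + 1):
        rate = (csum[t] - csum[t - window]) / window
        if rate < half:
            return float(t - onset)
    return float("inf")
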