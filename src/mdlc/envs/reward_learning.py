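"""Reward-learning tasks: two-step, drifting bandit, contingency degradation.

These are session-structured: one episode is a run of trials whose payoff
statistics drift, and the observation carries the previous action and
outcome, so an agent must use its recurrent state to track them.
"""

from __future__ import annotations

import numpy as np

from .base import Environment, EnvSpec, StepResult


def _reflect(x: float, lo: float, hi: float) -> float:
    # reflecting boundaries for the Gaussian random walks
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


class TwoStepEnv(Environment):
    """Two-stage trials with drifting stage-2 rewards and cued reversals.

    Stage 1: binary choice; the current stage-1 -> stage-2 transition
    mapping is signalled by an observation feature and reverses with a small
    per-trial hazard.  Under mapping 0, action ``a`` commonly (prob
    ``common_prob``) leads to stage-2 state ``a``; mapping 1 swaps the
    states.  Stage 2 delivers a binary reward with a per-state probability
    following a bounded Gaussian random walk (the stage-2 "action" is
    inconsequential).
    """

    def __init__(self, common_prob: float = 0.8, drift_sd: float = 0.025,
                 drift_bounds: tuple[float, float] = (0.25, 0.75),
                 reversal_hazard: float = 0.02, n_trials: int = 100):
        if not 0.5 < common_prob < 1.0:
            raise ValueError("common_prob must lie in (0.5, 1)")
        if not (0.0 < drift_bounds[0] < drift_bounds[1] < 1.0):
            raise ValueError("drift bounds must lie within (0, 1)")
        self.common_prob = common_prob
        self.drift_sd = drift_sd
        self.bounds = drift_bounds
        self.hazard = reversal_hazard
        self.n_trials = n_trials
        self.spec = EnvSpec(
            feature_groups=[("stage", 2), ("mapping_cue", 2),
                            ("stage2_state", 2), ("prev_action", 2),
                            ("prev_reward", 1)],
            action_labels=["left", "right"],
            horizon=2 * n_trials,
        )

    def _obs(self, stage: int, s2: int | None) -> np.ndarray:
        o = np.zeros(self.spec.obs_dim)
        o[stage] = 1.0
        o[self.spec.group_slice("mapping_cue").start + self.mapping] = 1.0
        if s2 is not None:
            o[self.spec.group_slice("stage2_state").start + s2] = 1.0
        if self.prev_action is not None:
            o[self.spec.group_slice("prev_action").start + self.prev_action] = 1.0
            o[self.spec.group_slice("prev_reward").start] = self.prev_reward
        return self._check_obs(o)

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        self.p_reward = [float(self._rng.uniform(*self.bounds)) for _ in range(2)]
        self.mapping = int(self._rng.integers(2))
        self.trial = 0
        self.stage = 0
        self.prev_action = None
        self.prev_reward = 0.0
        return self._obs(0, None)

    def step(self, action: int) -> StepResult:
        if self.stage == 0:
            common = self._rng.random() < self.common_prob
            dest = action if self.mapping == 0 else 1 - action
            self.s2 = dest if common else 1 - dest
            self.stage1_action = action
            self.transition = "common" if common else "uncommon"
            self.stage = 1
            return StepResult(self._obs(1, self.s2), 0.0, False,
                              {"stage": 1, "trial": self.trial,
                               "mapping": self.mapping})
        # stage 2: reward regardless of action
        reward = float(self._rng.random() < self.p_reward[self.s2])
        info = {"stage": 2, "trial": self.trial,
                "stage1_action": self.stage1_action,
                "stage2_state": self.s2, "transition": self.transition,
                "reward": reward, "mapping": self.mapping,
                "p_reward": tuple(self.p_reward)}
        self.prev_action = self.stage1_action
        self.prev_reward = reward
        self.trial += 1
        self.stage = 0
        # drift and possible cued reversal between trials
        self.p_reward = [
            _reflect(p + self._rng.normal(0.0, self.drift_sd), *self.bounds)
            for p in self.p_reward]
        if self._rng.random() < self.hazard:
            self.mapping = 1 - self.mapping
        done = self.trial >= self.n_trials
        return StepResult(self._obs(0, None), reward, done, info)


class DriftingBanditEnv(Environment):
    """Two-armed bandit whose arm payoffs follow reflecting random walks."""

    def __init__(self, drift_sd: float = 0.05,
                 bounds: tuple[float, float] = (0.05, 0.95),
                 n_trials: int = 150):
        if drift_sd < 0:
            raise ValueError("drift sd must be >= 0")
        self.drift_sd = drift_sd
        self.bounds = bounds
        self.n_trials = n_trials
        self.spec = EnvSpec(
            feature_groups=[("go", 1), ("prev_action", 2), ("prev_reward", 1)],
            action_labels=["left", "right"],
            horizon=n_trials,
        )

    def _obs(self) -> np.ndarray:
        o = np.zeros(self.spec.obs_dim)
        o[0] = 1.0
        if self.prev_action is not None:
            o[self.spec.group_slice("prev_action").start + self.prev_action] = 1.0
            o[self.spec.group_slice("prev_reward").start] = self.prev_reward
        return self._check_obs(o)

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        self.p = [float(self._rng.uniform(*self.bounds)) for _ in range(2)]
        self.t = 0
        self.prev_action = None
        self.prev_reward = 0.0
        return self._obs()

    def step(self, action: int) -> StepResult:
        reward = float(self._rng.random() < self.p[action])
        info = {"trial": self.t, "choice": action, "reward": reward,
                "p_left": self.p[0], "p_right": self.p[1]}
        self.prev_action = action
        self.prev_reward = reward
        self.p = [_reflect(p + self._rng.normal(0.0, self.drift_sd),
                           *self.bounds) for p in self.p]
        self.t += 1
        return StepResult(self._obs(), reward, self.t >= self.n_trials, info)


class ContingencyEnv(Environment):
    """Free-operant lever pressing with later contingency degradation.

    During training, pressing is rewarded with probability ``p`` and
    abstaining never is; from ``degradation_onset`` cumulative steps onward,
    reward arrives with probability ``p`` regardless of the action.  The
    cumulative step counter persists across episode resets so that a single
    instance traverses the training and degradation phases in order.
    """

    def __init__(self, p: float = 0.5, degradation_onset: int = 2000,
                 session_length: int = 25, press_cost: float = 0.2):
        if degradation_onset <= 0 or session_length <= 0:
            raise ValueError("durations must be positive")
        self.p = p
        self.onset = degradation_onset
        self.session_length = session_length
        self.press_cost = press_cost
        self.global_step = 0
        self.spec = EnvSpec(
            feature_groups=[("go", 1), ("prev_action", 2), ("prev_reward", 1)],
            action_labels=["press", "abstain"],
            horizon=session_length,
            reward_range=(-press_cost, 1.0),
        )

    @property
    def phase(self) -> str:
        return "training" if self.global_step < self.onset else "degradation"

    def _obs(self) -> np.ndarray:
        o = np.zeros(self.spec.obs_dim)
        o[0] = 1.0
        if self.prev_action is not None:
            o[self.spec.group_slice("prev_action").start + self.prev_action] = 1.0
            o[self.spec.group_slice("prev_reward").start] = self.prev_reward
        return self._check_obs(o)

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        self.t = 0
        self.prev_action = None
        self.prev_reward = 0.0
        return self._obs()

    def step(self, action: int) -> StepResult:
        phase = self.phase
        if phase == "training":
            delivered = float(action == 0 and self._rng.random() < self.p)
        else:
            delivered = float(self._rng.random() < self.p)
        # pressing carries a small effort cost; info keeps the raw delivery
        reward = delivered - (self.press_cost if action == 0 else 0.0)
        info = {"phase": phase, "action": action, "press": action == 0,
                "reward": delivered, "global_step": self.global_step}
        self.prev_action = action
        self.prev_reward = delivered
        self.t += 1
        self.global_step += 1
        return StepResult(self._obs(), reward, self.t >= self.session_length,
                          info)
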