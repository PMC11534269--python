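"""Multi-attribute paired choice with a non-compensatory payoff structure.

Two options, each a binary feature vector, are compared under a weight
vector in which every weight exceeds the sum of all smaller ones (so the
most valid feature alone settles most comparisons — the regime where
one-reason decision making is adaptive).  Ties in weighted value are
resampled and never presented.
"""

from __future__ import annotations

import itertools

import numpy as np

from .base import Environment, EnvSpec, StepResult


def is_noncompensatory(weights) -> bool:
    w = sorted(np.abs(weights), reverse=True)
    return all(w[i] > sum(w[i + 1:]) for i in range(len(w) - 1))


class MultiAttributeEnv(Environment):
    def __init__(self, weights: tuple[float, ...] = (8.0, 4.0, 2.0, 1.0),
                 payoff_scale: float = 1.0):
        w = np.asarray(weights, dtype=float)
        if len(w) < 2 or np.any(np.diff(w) >= 0):
            raise ValueError("weights must be strictly decreasing")
        self.weights = w
        self.payoff_scale = payoff_scale
        n = len(w)
        self.spec = EnvSpec(
            feature_groups=[("option_a", n), ("option_b", n)],
            action_labels=["choose_a", "choose_b"],
            horizon=1,
            reward_range=(max(0.0, 1.0 - payoff_scale), 1.0),
        )

    def _sample_pair(self, rng):
        n = len(self.weights)
        while True:
            a = rng.integers(0, 2, size=n).astype(float)
            b = rng.integers(0, 2, size=n).astype(float)
            va, vb = float(a @ self.weights), float(b @ self.weights)
            if va != vb:
                return a, b, va, vb

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        a, b, va, vb = self._sample_pair(self._rng)
        top = int(np.argmax(self.weights))
        self.trial = {
            "option_a": a, "option_b": b, "value_a": va, "value_b": vb,
            "correct": 0 if va > vb else 1,
            "top_feature_differs": a[top] != b[top],
            "top_feature_choice": (0 if a[top] > b[top] else 1)
            if a[top] != b[top] else None,
        }
        return self._check_obs(np.concatenate([a, b]))

    def step(self, action: int) -> StepResult:
        correct = action == self.trial["correct"]
        # payoff_scale rescales the reward gap between correct and incorrect
        # choices (1 -> standard 0/1 payoff)
        reward = 1.0 if correct else 1.0 - self.payoff_scale
        info = dict(self.trial)
        info.update(choice=action, correct_choice=correct,
                    heuristic_consistent=(
                        action == self.trial["top_feature_choice"]
                        if self.trial["top_feature_choice"] is not None
                        else None))
        return StepResult(np.zeros(self.spec.obs_dim), reward, True, info)

    @classmethod
    def enumerate_pairs(cls, weights) -> list[tuple[np.ndarray, np.ndarray]]:
        """All admissible (untied) ordered option pairs — enumeration oracle."""
        w = np.asarray(weights, dtype=float)
        opts = [np.asarray(v, dtype=float)
                for v in itertools.product((0, 1), repeat=len(w))]
        return [(a, b) for a in opts for b in opts
                if float(a @ w) != float(b @ w)]
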