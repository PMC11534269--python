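"""Cued-goal grid navigation.

A square grid with a set of goal cells.  Each episode cues one goal (drawn
from configured frequencies — by default one goal is cued far more often
than the other); the agent starts at a random non-goal cell and earns 1 for
stepping onto the cued goal, paying a small step cost otherwise.  A
multi-goal variant (``cue_encoding="position"``) cues goals by their grid
cell so that held-out goals can be introduced for generalization probes.
"""

from __future__ import annotations

import numpy as np

from .base import Environment, EnvSpec, StepResult

ACTIONS = [(-1, 0), (1, 0), (0, -1), (0, 1)]  # up, down, left, right


class GoalNavEnv(Environment):
    def __init__(self, grid_size: int = 5,
                 goals: list[tuple[int, int]] | None = None,
                 goal_freqs: list[float] | None = None,
                 step_cost: float = -0.01,
                 horizon: int = 20,
                 cue_encoding: str = "identity",
                 fixed_goal: int | None = None):
        self.n = grid_size
        self.goals = goals if goals is not None else [(0, 0), (grid_size - 1,
                                                              grid_size - 1)]
        for g in self.goals:
            if not (0 <= g[0] < self.n and 0 <= g[1] < self.n):
                raise ValueError(f"goal {g} outside grid")
        if len(set(self.goals)) != len(self.goals):
            raise ValueError("goals must be distinct")
        freqs = goal_freqs if goal_freqs is not None \
            else [0.8, 0.2] if len(self.goals) == 2 \
            else [1.0 / len(self.goals)] * len(self.goals)
        if abs(sum(freqs) - 1.0) > 1e-9 or len(freqs) != len(self.goals):
            raise ValueError("goal frequencies must match goals and sum to 1")
        self.goal_freqs = np.asarray(freqs)
        self.step_cost = step_cost
        self.cue_encoding = cue_encoding
        self.fixed_goal = fixed_goal
        cue_w = self.n * self.n if cue_encoding == "position" else len(self.goals)
        self.spec = EnvSpec(
            feature_groups=[("position", self.n * self.n),
                            ("goal_cue", cue_w),
                            ("prev_action", 4)],
            action_labels=["up", "down", "left", "right"],
            horizon=horizon,
            reward_range=(step_cost, 1.0),
        )

    def _obs(self) -> np.ndarray:
        o = np.zeros(self.spec.obs_dim)
        o[self.pos[0] * self.n + self.pos[1]] = 1.0
        sl = self.spec.group_slice("goal_cue")
        if self.cue_encoding == "position":
            g = self.goals[self.goal_idx]
            o[sl.start + g[0] * self.n + g[1]] = 1.0
        else:
            o[sl.start + self.goal_idx] = 1.0
        if self.prev_action is not None:
            o[self.spec.group_slice("prev_action").start + self.prev_action] = 1.0
        return self._check_obs(o)

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        self.goal_idx = self.fixed_goal if self.fixed_goal is not None \
            else int(self._rng.choice(len(self.goals), p=self.goal_freqs))
        while True:
            self.pos = (int(self._rng.integers(self.n)),
                        int(self._rng.integers(self.n)))
            if self.pos != self.goals[self.goal_idx]:
                break
        self.prev_action = None
        self.t = 0
        return self._obs()

    def step(self, action: int) -> StepResult:
        dr, dc = ACTIONS[action]
        nr, nc = self.pos[0] + dr, self.pos[1] + dc
        if 0 <= nr < self.n and 0 <= nc < self.n:
            self.pos = (nr, nc)
        self.prev_action = action
        self.t += 1
        goal = self.goals[self.goal_idx]
        reached = self.pos == goal
        done = reached or self.t >= self.spec.horizon
        reward = 1.0 if reached else self.step_cost
        info = {"cued_goal": self.goal_idx, "goal_cell": goal,
                "position": self.pos, "reached": reached,
                "reached_goal_idx": self.goals.index(self.pos)
                if self.pos in self.goals else None}
        return StepResult(self._obs(), reward, done, info)

    def shortest_path_length(self, start, goal_idx: int) -> int:
        g = self.goals[goal_idx]
        return abs(start[0] - g[0]) + abs(start[1] - g[1])
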