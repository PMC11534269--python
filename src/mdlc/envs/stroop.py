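"""Stroop-family single-step tasks.

``StroopEnv``: color words shown in hues; a task cue selects word-reading
(the frequent, practiced mapping) or color-naming.  ``neutral_only`` mode
trains with the irrelevant dimension absent (word omitted during
color-naming, color omitted during word-reading) for zero-shot conflict
probes.  ``DemandChoiceEnv`` prepends a meta-choice between two
color-naming blocks differing in incongruent-trial proportion (demand
avoidance).  ``ShapeNamingEnv`` pairs color-naming with an arbitrary
shape-to-color-name mapping whose relative automaticity reverses with
extended shape-naming practice.
"""

from __future__ import annotations

import numpy as np

from .base import Environment, EnvSpec, StepResult

WORDS = ["RED", "BLUE", "none"]
COLORS = ["red", "blue", "none"]


class StroopEnv(Environment):
    """One trial per episode: respond 'red' or 'blue' per the task cue."""

    def __init__(self, p_word_reading: float = 0.75,
                 p_incongruent: float = 0.5,
                 neutral_only: bool = False):
        if not (0.0 <= p_word_reading <= 1.0 and 0.0 <= p_incongruent <= 1.0):
            raise ValueError("invalid trial mix")
        self.p_wr = p_word_reading
        self.p_inc = p_incongruent
        self.neutral_only = neutral_only
        self.spec = EnvSpec(
            feature_groups=[("word", 3), ("color", 3), ("task_cue", 2)],
            action_labels=["red", "blue"],
            horizon=1,
        )

    @staticmethod
    def make_obs(spec: EnvSpec, word: str, color: str, task: str) -> np.ndarray:
        o = np.zeros(spec.obs_dim)
        o[spec.group_slice("word").start + WORDS.index(word)] = 1.0
        o[spec.group_slice("color").start + COLORS.index(color)] = 1.0
        o[spec.group_slice("task_cue").start + ("WR", "CN").index(task)] = 1.0
        return o

    def _sample_trial(self, rng) -> dict:
        task = "WR" if rng.random() < self.p_wr else "CN"
        ident = int(rng.integers(2))  # identity of the relevant dimension
        if self.neutral_only:
            if task == "WR":
                word, color = WORDS[ident], "none"
            else:
                word, color = "none", COLORS[ident]
            congruence = "neutral"
        else:
            incong = rng.random() < self.p_inc
            if task == "WR":
                word = WORDS[ident]
                color = COLORS[1 - ident] if incong else COLORS[ident]
            else:
                color = COLORS[ident]
                word = WORDS[1 - ident] if incong else WORDS[ident]
            congruence = "incongruent" if incong else "congruent"
        correct = WORDS.index(word) if task == "WR" else COLORS.index(color)
        return {"task": task, "word": word, "color": color,
                "congruence": congruence, "correct": correct}

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        self.trial = self._sample_trial(self._rng)
        return self._check_obs(self.make_obs(
            self.spec, self.trial["word"], self.trial["color"],
            self.trial["task"]))

    def step(self, action: int) -> StepResult:
        reward = 1.0 if action == self.trial["correct"] else 0.0
        info = dict(self.trial)
        info["response"] = self.spec.action_labels[action]
        return StepResult(np.zeros(self.spec.obs_dim), reward, True, info)


class DemandChoiceEnv(Environment):
    """A meta-choice between two color-naming blocks, then the chosen block.

    At the choice step a cue indicates which action leads to the
    low-incongruence block (counterbalanced across episodes); the block then
    runs ``block_length`` color-naming trials at the chosen incongruence
    proportion.
    """

    def __init__(self, block_length: int = 8,
                 p_incongruent_high: float = 0.9,
                 p_incongruent_low: float = 0.1):
        if not p_incongruent_high > p_incongruent_low:
            raise ValueError("high proportion must exceed low")
        self.block_length = block_length
        self.p_high = p_incongruent_high
        self.p_low = p_incongruent_low
        self.spec = EnvSpec(
            feature_groups=[("word", 3), ("color", 3), ("task_cue", 2),
                            ("stage", 1), ("block_cue", 2)],
            action_labels=["red", "blue"],
            horizon=block_length + 1,
        )
        self._stroop = StroopEnv(p_word_reading=0.0, p_incongruent=0.5)

    def _choice_obs(self) -> np.ndarray:
        o = np.zeros(self.spec.obs_dim)
        o[self.spec.group_slice("stage").start] = 1.0
        o[self.spec.group_slice("block_cue").start + self.low_action] = 1.0
        return self._check_obs(o)

    def _trial_obs(self) -> np.ndarray:
        o = np.zeros(self.spec.obs_dim)
        o[self.spec.group_slice("word").start + WORDS.index(self.trial["word"])] = 1.0
        o[self.spec.group_slice("color").start + COLORS.index(self.trial["color"])] = 1.0
        o[self.spec.group_slice("task_cue").start + 1] = 1.0  # CN
        return self._check_obs(o)

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        self.low_action = int(self._rng.integers(2))
        self.t = 0
        self.chosen = None
        return self._choice_obs()

    def _sample_block_trial(self):
        self._stroop.p_inc = self.p_block
        self.trial = self._stroop._sample_trial(self._rng)

    def step(self, action: int) -> StepResult:
        if self.t == 0:
            self.chosen = "low" if action == self.low_action else "high"
            self.p_block = self.p_low if self.chosen == "low" else self.p_high
            self._sample_block_trial()
            self.t = 1
            return StepResult(self._trial_obs(), 0.0, False,
                              {"stage": "choice", "chosen_block": self.chosen,
                               "low_action": self.low_action})
        reward = 1.0 if action == self.trial["correct"] else 0.0
        info = dict(self.trial)
        info.update(stage="block", chosen_block=self.chosen, trial_index=self.t)
        self.t += 1
        done = self.t > self.block_length
        if not done:
            self._sample_block_trial()
            obs = self._trial_obs()
        else:
            obs = np.zeros(self.spec.obs_dim)
        return StepResult(obs, reward, done, info)


class ShapeNamingEnv(Environment):
    """Color-naming vs. arbitrary shape-naming over colored shapes.

    Shape ``i`` is arbitrarily assigned the color name ``i``; a trial is
    congruent when the shape's assigned name matches the displayed color.
    ``p_shape_naming`` sets the task mix of the current training phase.
    """

    def __init__(self, p_shape_naming: float = 0.2,
                 p_incongruent: float = 0.5):
        self.p_sn = p_shape_naming
        self.p_inc = p_incongruent
        self.spec = EnvSpec(
            feature_groups=[("shape", 2), ("color", 2), ("task_cue", 2)],
            action_labels=["red", "blue"],
            horizon=1,
        )

    @staticmethod
    def make_obs(spec: EnvSpec, shape: int, color: int, task: str) -> np.ndarray:
        o = np.zeros(spec.obs_dim)
        o[spec.group_slice("shape").start + shape] = 1.0
        o[spec.group_slice("color").start + color] = 1.0
        o[spec.group_slice("task_cue").start + ("CN", "SN").index(task)] = 1.0
        return o

    @classmethod
    def probe_set(cls, spec: EnvSpec) -> list[dict]:
        """All shape x color x task combinations, fixed composition."""
        probes = []
        for shape in (0, 1):
            for color in (0, 1):
                for task in ("CN", "SN"):
                    probes.append({
                        "shape": shape, "color": color, "task": task,
                        "congruence": "congruent" if shape == color
                        else "incongruent",
                        "correct": color if task == "CN" else shape,
                        "obs": cls.make_obs(spec, shape, color, task),
                    })
        return probes

    def reset(self, rng=None) -> np.ndarray:
        self._rng = self._coerce_rng(rng)
        task = "SN" if self._rng.random() < self.p_sn else "CN"
        shape = int(self._rng.integers(2))
        if self._rng.random() < self.p_inc:
            color = 1 - shape
        else:
            color = shape
        self.trial = {
            "task": task, "shape": shape, "color": color,
            "congruence": "congruent" if shape == color else "incongruent",
            "correct": color if task == "CN" else shape,
        }
        return self._check_obs(self.make_obs(self.spec, shape, color, task))

    def step(self, action: int) -> StepResult:
        reward = 1.0 if action == self.trial["correct"] else 0.0
        info = dict(self.trial)
        info["response"] = self.spec.action_labels[action]
        return StepResult(np.zeros(self.spec.obs_dim), reward, True, info)
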