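"""Shared environment contract.

Every task environment exposes an :class:`EnvSpec` (named observation
feature groups, action labels, horizon, reward range), a ``reset(rng)``
returning the first observation, and a ``step(action)`` returning a
:class:`StepResult`.  Observations are fixed-order one-hot concatenations of
the named groups; ``info`` carries every trial label the behavioral
analyses need, so no analysis ever re-derives trial types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EnvSpec:
    feature_groups: list[tuple[str, int]]
    action_labels: list[str]
    horizon: int
    reward_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if any(w <= 0 for _, w in self.feature_groups):
            raise ValueError("feature-group widths must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    @property
    def obs_dim(self) -> int:
        return sum(w for _, w in self.feature_groups)

    def group_slice(self, name: str) -> slice:
        off = 0
        for n, w in self.feature_groups:
            if n == name:
                return slice(off, off + w)
            off += w
        raise KeyError(f"unknown feature group {name!r}")


@dataclass
class StepResult:
    observation: np.ndarray
    reward: float
    done: bool
    info: dict = field(default_factory=dict)


class Environment:
    """Base class; subclasses set ``self.spec`` and implement the contract."""

    spec: EnvSpec

    def reset(self, rng: np.random.Generator | int | None = None) -> np.ndarray:
        raise NotImplementedError

    def step(self, action: int) -> StepResult:
        raise NotImplementedError

    def _coerce_rng(self, rng) -> np.random.Generator:
        if isinstance(rng, np.random.Generator):
            return rng
        return np.random.default_rng(rng)

    def _check_obs(self, obs: np.ndarray) -> np.ndarray:
        obs = np.asarray(obs, dtype=np.float64)
        assert obs.shape == (self.spec.obs_dim,)
        return obs
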