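"""Dual-pathway recurrent agent for minimum description length control.

The agent carries two identically shaped gated recurrent pathways over the
same perceptual input.  The *default* pathway (habit-like, ``pi0``) is
noise-regularized: every weight matrix and a per-feature-group input gate
carry multiplicative Gaussian noise whose KL penalty against a
scale-invariant (log-uniform / Jeffreys) prior induces sparsity — sparse
variational dropout.  The *control* pathway (``pi``) is deterministic,
carries a value head, and emits the overt action distribution.  The KL
divergence between the two action distributions is computed at every step;
it is both the deviation cost of the training objective and the conflict
signal used by the behavioral analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad

# Constants of the sigmoid approximation to the KL between a Gaussian
# posterior and the log-uniform prior (sparse variational dropout).
_K1, _K2, _K3 = 0.63576, 1.87320, 1.48695

#: floor applied to probabilities before log-ratios (see policy_kl)
KL_FLOOR = 1e-8

#: counts of clip events, keyed by call site; purely diagnostic
clip_log: dict[str, int] = {}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ActionDistribution:
    """Probability vector over a discrete action set."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1 or self.probs.shape[0] < 2:
            raise ValueError("ActionDistribution needs a 1-D vector with K >= 2")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


@dataclass
class AgentState:
    """Recurrent carriers for the two pathways; zeros at episode start."""

    default_hidden: np.ndarray
    control_hidden: np.ndarray


@dataclass
class VariationalParams:
    """Factorized Gaussian posterior over a set of connections.

    ``alpha = sigma^2 / mean^2`` is the per-connection dropout rate; a
    pruned connection (mean 0 with residual noise) reports ``alpha = inf``.
    """

    mean: np.ndarray
    log_sigma2: np.ndarray

    @property
    def sigma2(self) -> np.ndarray:
        return np.exp(self.log_sigma2)

    @property
    def log_var(self) -> np.ndarray:
        return np.asarray(self.log_sigma2)

    @property
    def dropout_rate(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(
                self.mean == 0.0, np.inf, self.sigma2 / np.square(self.mean)
            )


@dataclass
class GateVector:
    """Per-feature-group transmission weight of the default pathway, in [0,1]."""

    names: list[str]
    gates: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {n: float(g) for n, g in zip(self.names, self.gates)}


@dataclass
class PolicyStepOutput:
    default_dist: ActionDistribution
    control_dist: ActionDistribution
    value: float
    step_kl: float


@dataclass
class AgentConfig:
    feature_groups: list[tuple[str, int]]
    n_actions: int
    hidden_size: int = 64
    feed_default_to_control: bool = False
    init_alpha: float = 0.05
    seed: int = 0

    @property
    def obs_dim(self) -> int:
        return sum(w for _, w in self.feature_groups)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def policy_kl(p, q, floor: float | None = KL_FLOOR, tag: str = "policy_kl") -> float:
    """KL(p || q) in nats for two distributions over the same action set.

    Zero entries of ``p`` contribute nothing (0 log 0 = 0).  With
    ``floor=None``, ``p(a) > 0`` where ``q(a) = 0`` yields ``+inf``;
    otherwise both distributions are clipped at ``floor`` before the log
    ratio and the event is counted in :data:`clip_log`.
    """
    p = p.probs if isinstance(p, ActionDistribution) else np.asarray(p, float)
    q = q.probs if isinstance(q, ActionDistribution) else np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("mismatched action-set sizes")
    mask = p > 0
    if floor is None:
        if np.any(mask & (q == 0)):
            return float("inf")
        pq = np.where(mask, p / np.where(q == 0, 1.0, q), 1.0)
        return float(np.sum(np.where(mask, p * np.log(pq), 0.0)))
    if np.any((p < floor) | (q < floor)):
        clip_log[tag] = clip_log.get(tag, 0) + 1
    pc, qc = np.clip(p, floor, None), np.clip(q, floor, None)
    return float(np.sum(np.where(mask, p * np.log(pc / qc), 0.0)))


def vdo_kl_from_alpha(alpha: np.ndarray) -> np.ndarray:
    """Per-connection KL(posterior || log-uniform prior), sigmoid approximation.

    Strictly decreasing in alpha, tending to 0 as alpha -> inf; the additive
    constant of the improper prior is fixed by that limit.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    la = np.where(np.isinf(alpha), 700.0, np.log(np.clip(alpha, 1e-300, None)))
    neg_kl = _K1 / (1.0 + np.exp(-(_K2 + _K3 * la))) \
        - 0.5 * np.log1p(np.exp(-la)) - _K1
    return np.where(np.isinf(alpha), 0.0, -neg_kl)


def vdo_complexity(params) -> float:
    """Total complexity cost (nats) of one or more variational layers."""
    if isinstance(params, VariationalParams):
        params = [params]
    total = 0.0
    for vp in params:
        if np.any(np.asarray(vp.log_sigma2) != np.asarray(vp.log_sigma2)):
            raise ValueError("NaN variance in variational parameters")
        total += float(vdo_kl_from_alpha(vp.dropout_rate).sum())
    return total


def select_action(dist: ActionDistribution, rng_seed: int | np.random.Generator = 0,
                  mode: str = "sample") -> int:
    """Draw (seeded) or take the argmax (lowest index wins ties)."""
    p = dist.probs if isinstance(dist, ActionDistribution) else np.asarray(dist)
    if mode == "greedy":
        return int(np.argmax(p))
    if mode != "sample":
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    return int(rng.choice(len(p), p=p / p.sum()))


# ---------------------------------------------------------------------------
# the agent
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    s = np.sqrt(2.0 / (shape[0] + shape[1]))
    return rng.normal(0.0, s, size=shape)


class MDLCAgent:
    """Two recurrent policy pathways over shared input.

    Parameters are stored in a flat ``name -> Tensor`` dict.  Default-pathway
    weight matrices are pairs ``(<name>, <name>__ls2)`` holding the posterior
    mean and log-variance; the input gate is ``(gate_logit, gate_logalpha)``.
    """

    VD_MATS = ["d_Wz", "d_Uz", "d_Wr", "d_Ur", "d_Wn", "d_Un", "d_Wout"]

    def __init__(self, config: AgentConfig):
        self.config = config
        self.act_from = "control"        # flipped to "default" by ablate_control
        self.frozen_default = False      # set by ablate_default
        self.frozen_control = False      # distillation-only studies
        self._probe_cache: np.ndarray | None = None  # set by training
        rng = np.random.default_rng(config.seed)
        H, D, K = config.hidden_size, config.obs_dim, config.n_actions
        G = len(config.feature_groups)
        Dc = D + (K if config.feed_default_to_control else 0)
        p: dict[str, Tensor] = {}

        def par(name, arr):
            p[name] = Tensor(arr, requires_grad=True)

        # default pathway (variational)
        for nm, shape in [("d_Wz", (D, H)), ("d_Wr", (D, H)), ("d_Wn", (D, H)),
                          ("d_Uz", (H, H)), ("d_Ur", (H, H)), ("d_Un", (H, H)),
                          ("d_Wout", (H, K))]:
            theta = np.zeros(shape) if nm == "d_Wout" else _glorot(rng, shape)
            par(nm, theta)
            par(nm + "__ls2",
                np.log(config.init_alpha * np.square(theta) + 1e-12))
        for nm in ["d_bz", "d_br", "d_bn"]:
            par(nm, np.zeros(H))
        par("d_bout", np.zeros(K))
        # input gate: per-group multiplicative gate squashed to [0, 1] by a
        # sigmoid, with its own variational (dropout-rate) noise parameter
        par("gate_logit", np.full(G, 2.0))
        par("gate_logalpha", np.full(G, np.log(config.init_alpha)))
        # control pathway (deterministic) + value head
        for nm, shape in [("c_Wz", (Dc, H)), ("c_Wr", (Dc, H)), ("c_Wn", (Dc, H)),
                          ("c_Uz", (H, H)), ("c_Ur", (H, H)), ("c_Un", (H, H))]:
            par(nm, _glorot(rng, shape))
        for nm in ["c_bz", "c_br", "c_bn"]:
            par(nm, np.zeros(H))
        par("c_Wout", np.zeros((H, K)))
        par("c_bout", np.zeros(K))
        par("c_Wv", np.zeros((H, 1)))
        par("c_bv", np.zeros(1))
        self.params = p
        self._group_slices = []
        off = 0
        for _, w in config.feature_groups:
            self._group_slices.append(slice(off, off + w))
            off += w

    # -- parameter views ----------------------------------------------------
    def default_variational_params(self) -> list[VariationalParams]:
        out = [VariationalParams(self.params[n].data, self.params[n + "__ls2"].data)
               for n in self.VD_MATS]
        g = 1.0 / (1.0 + np.exp(-self.params["gate_logit"].data))
        alpha = np.exp(self.params["gate_logalpha"].data)
        out.append(VariationalParams(g, np.log(alpha * np.square(g) + 1e-300)))
        return out

    def trainable(self, include_default: bool = True) -> dict[str, Tensor]:
        items = {}
        for k, v in self.params.items():
            is_default = k.startswith("d_") or k.startswith("gate_")
            if is_default and (self.frozen_default or not include_default):
                continue
            if not is_default and self.frozen_control:
                continue
            items[k] = v
        return items

    # -- forward ------------------------------------------------------------
    def initial_state(self, batch: int = 1) -> AgentState:
        H = self.config.hidden_size
        return AgentState(np.zeros((batch, H)), np.zeros((batch, H)))

    def _vd_linear(self, x: Tensor, name: str, noise: str, rng,
                   cache: dict | None = None) -> Tensor:
        """Local reparameterization of a variational weight matrix."""
        theta = self.params[name]
        mean = x @ theta
        if noise == "mean":
            return mean
        if cache is not None:
            s2 = cache.get(name)
            if s2 is None:
                s2 = cache[name] = self.params[name + "__ls2"].exp()
        else:
            s2 = self.params[name + "__ls2"].exp()
        var = (x * x) @ s2
        eps = rng.standard_normal(mean.shape)
        return mean + (var + 1e-12).sqrt() * Tensor(eps)

    def _fused(self, prefix: str, which: str, cache: dict) -> Tensor:
        """Concatenated [Wz|Wr] (or [Uz|Ur]) weight view, cached per rollout."""
        key = f"{prefix}_{which}"
        t = cache.get(key)
        if t is None:
            t = cache[key] = concat([self.params[f"{prefix}_{which}z"],
                                     self.params[f"{prefix}_{which}r"]],
                                    axis=1)
        return t

    def _gru(self, x: Tensor, h: Tensor, prefix: str, noise: str, rng,
             cache: dict | None = None) -> Tensor:
        H = self.config.hidden_size
        if cache is None:
            cache = {}
        if prefix == "d":
            lin = lambda v, nm: self._vd_linear(v, nm, noise, rng, cache)
            # fused z|r pass through the local reparameterization
            def fused_zr(v, which):
                mats = self._fused("d", which, cache)
                key = f"d_{which}__s2cat"
                s2 = cache.get(key)
                if s2 is None and noise == "sampled":
                    s2 = cache[key] = concat(
                        [self.params[f"d_{which}z__ls2"].exp(),
                         self.params[f"d_{which}r__ls2"].exp()], axis=1)
                mean = v @ mats
                if noise == "mean":
                    return mean
                var = (v * v) @ s2
                eps = rng.standard_normal(mean.shape)
                return mean + (var + 1e-12).sqrt() * Tensor(eps)
            zr = (fused_zr(x, "W") + fused_zr(h, "U")
                  + cache.setdefault(
                      "d_bzr", concat([self.params["d_bz"],
                                       self.params["d_br"]], axis=0))
                  ).sigmoid()
        else:
            lin = lambda v, nm: v @ self.params[nm]
            zr = (x @ self._fused("c", "W", cache)
                  + h @ self._fused("c", "U", cache)
                  + cache.setdefault(
                      "c_bzr", concat([self.params["c_bz"],
                                       self.params["c_br"]], axis=0))
                  ).sigmoid()
        z, r = zr[:, :H], zr[:, H:]
        n = (lin(x, f"{prefix}_Wn") + lin(r * h, f"{prefix}_Un")
             + self.params[f"{prefix}_bn"]).tanh()
        return (1.0 - z) * h + z * n

    def _apply_gate(self, obs: Tensor, noise: str, rng,
                    gate_eps: np.ndarray | None = None) -> Tensor:
        gate = self.params["gate_logit"].sigmoid()
        parts = []
        for g, sl in enumerate(self._group_slices):
            gg = gate[g]
            if noise == "sampled":
                # multiplicative gate noise, one draw per group per episode;
                # the amplitude enters as data (the gate's dropout rate is
                # steered by the complexity prior, not by the pathwise term)
                a = float(np.exp(min(
                    self.params["gate_logalpha"].data[g], 8.0)))
                eps = gate_eps[:, g:g + 1] if gate_eps is not None \
                    else rng.standard_normal((obs.shape[0], 1))
                gg = gg * (1.0 + np.sqrt(a) * Tensor(eps))
            parts.append(obs[:, sl] * gg)
        return concat(parts, axis=1)

    def _forward(self, obs: Tensor, state: AgentState, noise: str, rng,
                 gate_eps: np.ndarray | None = None,
                 cache: dict | None = None):
        """Batched graph-building forward step; returns a dict of Tensors."""
        if obs.shape[1] != self.config.obs_dim:
            raise ValueError(
                f"obs dim {obs.shape[1]} != spec dim {self.config.obs_dim}")
        h0 = Tensor(state.default_hidden)
        hc = Tensor(state.control_hidden)
        x0 = self._apply_gate(obs, noise, rng, gate_eps)
        h0n = self._gru(x0, h0, "d", noise, rng, cache)
        logits0 = self._vd_linear(h0n, "d_Wout", noise, rng, cache) \
            + self.params["d_bout"]
        xc = obs
        logp0 = logits0.log_softmax()
        if self.config.feed_default_to_control:
            xc = concat([obs, logp0.exp().detach()], axis=1)
        hcn = self._gru(xc, hc, "c", noise, rng, cache)
        logits = hcn @ self.params["c_Wout"] + self.params["c_bout"]
        logp = logits.log_softmax()
        value = (hcn @ self.params["c_Wv"] + self.params["c_bv"])[:, 0]
        pi = logp.exp()
        step_kl = (pi * (logp - logp0)).sum(axis=1)
        for nm, t in (("default", logits0), ("control", logits)):
            if not np.all(np.isfinite(t.data)):
                raise FloatingPointError(f"non-finite activations in {nm} pathway")
        return {"logp0": logp0, "logp": logp, "value": value, "kl": step_kl,
                "state": AgentState(h0n.data.copy(), hcn.data.copy()),
                "h0": h0n, "hc": hcn}

    def forward_step(self, obs: np.ndarray, state: AgentState | None = None,
                     noise: str = "mean",
                     rng: np.random.Generator | None = None
                     ) -> tuple[PolicyStepOutput, AgentState]:
        """Evaluate both pathways on one observation (no graph retained)."""
        if noise not in ("mean", "sampled"):
            raise ValueError("noise must be 'mean' or 'sampled'")
        obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
        if state is None:
            state = self.initial_state(obs.shape[0])
        rng = rng or np.random.default_rng(0)
        with no_grad():
            out = self._forward(Tensor(obs), state, noise, rng)
        step = PolicyStepOutput(
            default_dist=ActionDistribution(np.exp(out["logp0"].data[0])),
            control_dist=ActionDistribution(np.exp(out["logp"].data[0])),
            value=float(out["value"].data[0]),
            step_kl=float(out["kl"].data[0]),
        )
        return step, out["state"]

    def behavior_dist(self, step: PolicyStepOutput) -> ActionDistribution:
        """The distribution overt actions are drawn from (ablation-aware)."""
        return step.default_dist if self.act_from == "default" else step.control_dist

    # -- ablations ----------------------------------------------------------
    def ablate_control(self) -> "MDLCAgent":
        """Agent forced to act from the default pathway (control removed)."""
        other = self.clone()
        other.act_from = "default"
        return other

    def ablate_default(self) -> "MDLCAgent":
        """Agent with the default pathway frozen and the deviation term off."""
        other = self.clone()
        other.frozen_default = True
        return other

    def gate_readout(self, probes: np.ndarray | None = None) -> GateVector:
        """Which information the default pathway processes, per feature group.

        For each group the probe observations are re-evaluated with that
        group zeroed; the mean KL shift of pi0's output distribution s_g is
        squashed to a [0, 1] attention weight 1 - exp(-s_g) (0 = the group
        is ignored, 1 = strongly processed).  ``probes`` defaults to a batch
        of observations cached from the most recent training rollout.
        """
        if probes is None:
            probes = self._probe_cache
        if probes is None:
            raise RuntimeError(
                "no probe batch: train the agent or pass probes explicitly")
        if isinstance(probes, tuple):
            probes, hidden = probes
        else:
            hidden = None
        probes = np.atleast_2d(np.asarray(probes, dtype=np.float64))
        base = self._default_dists(probes, hidden)
        sens = []
        for sl in self._group_slices:
            masked = probes.copy()
            masked[:, sl] = 0.0
            alt = self._default_dists(masked, hidden)
            kl = np.sum(base * (np.log(np.clip(base, KL_FLOOR, None))
                                - np.log(np.clip(alt, KL_FLOOR, None))),
                        axis=1)
            sens.append(float(np.mean(kl)))
        names = [n for n, _ in self.config.feature_groups]
        return GateVector(names, 1.0 - np.exp(-np.asarray(sens)))

    def _default_dists(self, obs: np.ndarray,
                       hidden: np.ndarray | None = None,
                       sustain: int = 5) -> np.ndarray:
        """pi0's response to a sustained stimulus: the observation is held
        for ``sustain`` recurrent steps (information enters the hidden state
        gradually, so a single step understates sensitivity)."""
        state = self.initial_state(obs.shape[0])
        if hidden is not None:
            state = AgentState(np.asarray(hidden), state.control_hidden)
        with no_grad():
            for _ in range(sustain):
                out = self._forward(Tensor(obs), state, "mean",
                                    np.random.default_rng(0))
                state = out["state"]
        return np.exp(out["logp0"].data)

    def clone(self) -> "MDLCAgent":
        other = MDLCAgent(self.config)
        for k, v in self.params.items():
            other.params[k].data = v.data.copy()
        other.act_from = self.act_from
        other.frozen_default = self.frozen_default
        other.frozen_control = self.frozen_control
        other._probe_cache = self._probe_cache
        return other

    # -- checkpoints: flat key -> array container (JSON) ---------------------
    def save(self, path: str) -> None:
        payload = {
            "config": {
                "feature_groups": self.config.feature_groups,
                "n_actions": self.config.n_actions,
                "hidden_size": self.config.hidden_size,
                "feed_default_to_control": self.config.feed_default_to_control,
                "init_alpha": self.config.init_alpha,
                "seed": self.config.seed,
            },
            "act_from": self.act_from,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "MDLCAgent":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["feature_groups"] = [tuple(fg) for fg in cfg["feature_groups"]]
        agent = cls(AgentConfig(**cfg))
        for k, v in payload["params"].items():
            agent.params[k].data = np.asarray(v, dtype=np.float64)
        agent.act_from = payload["act_from"]
        return agent
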