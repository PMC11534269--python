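"""Training objective and loop for minimum description length control.

The agent maximizes expected cumulative reward minus a weighted description
length of its own behavior, ``E[R] - [lambda_dev * KL(pi || pi0) +
lambda_cx * L(pi0)]``: the deviation cost prices overriding the default
policy, and the complexity cost is the variational-dropout KL of the default
pathway's weight posterior against the sparsity-inducing log-uniform prior.
Optimization is advantage actor-critic over full episodes (all tasks are
short-horizon), with the deviation cost entering both pathwise (gradients
through both policies' distributions — this is what distills ``pi`` into
``pi0``) and through the advantage (the score-function part of the gradient
of the expected trajectory-summed KL, which lets the *choice* of futures
respond to control demand).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .agent import MDLCAgent, vdo_complexity
from .autodiff import Tensor, no_grad

__all__ = [
    "Trajectory", "ObjectiveTerms", "TrainConfig", "discounted_returns",
    "mdlc_loss", "train", "Adam",
]


@dataclass
class Trajectory:
    """One episode's aligned records; the unit of training and analysis."""

    observations: np.ndarray   # (T, D)
    actions: np.ndarray        # (T,)
    rewards: np.ndarray        # (T,)
    default_dists: np.ndarray  # (T, K)
    control_dists: np.ndarray  # (T, K)
    values: np.ndarray         # (T,)
    step_kls: np.ndarray       # (T,)
    infos: list = field(default_factory=list)

    def __post_init__(self):
        T = len(self.actions)
        for name in ("observations", "rewards", "default_dists",
                     "control_dists", "values", "step_kls"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"{name} length != {T}")
        if not np.all(np.isfinite(self.rewards)):
            raise ValueError("non-finite rewards")
        if np.any(self.step_kls < -1e-9):
            raise ValueError("negative step KL")


@dataclass
class ObjectiveTerms:
    return_term: float
    deviation_term: float
    complexity_term: float
    lambda_dev: float
    lambda_cx: float

    @property
    def total(self) -> float:
        # minimization convention
        return (-self.return_term + self.lambda_dev * self.deviation_term
                + self.lambda_cx * self.complexity_term)


@dataclass
class TrainConfig:
    lambda_dev: float = 0.1
    lambda_cx: float = 1e-4
    gamma: float = 0.95
    lr: float = 3e-3
    entropy_bonus: float = 0.01
    # optional entropy bonus on the default policy: keeps habits "soft" and
    # bounds the distillation feedback loop in long closed-loop trainings
    entropy_pi0: float = 0.0
    value_coef: float = 0.5
    episodes_per_update: int = 16
    total_updates: int = 500
    seed: int = 0
    grad_clip: float = 5.0
    complexity_scale: float = 1.0
    # linear warm-up (in updates) of the complexity weight: the default
    # pathway first learns, then the sparsity prior carves it back
    complexity_warmup: int = 0
    # relative learning rate of the noise variances (log sigma^2 / log alpha)
    vdo_lr_scale: float = 1.0
    # relative learning rate of the whole default pathway (slow habit
    # learner); 1.0 = same speed as the control pathway
    default_lr_scale: float = 1.0
    # gradient routing through the deviation term: both | pi_only | pi0_only
    deviation_grad: str = "both"

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def discounted_returns(rewards, gamma: float) -> np.ndarray:
    """G_t = sum_k gamma^k r_{t+k}; length-preserving."""
    rewards = np.asarray(rewards, dtype=np.float64)
    if rewards.size == 0:
        raise ValueError("empty reward sequence")
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    out = np.empty_like(rewards)
    acc = 0.0
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


def mdlc_loss(batch: list[Trajectory], params, cfg: TrainConfig) -> ObjectiveTerms:
    """Decomposed objective evaluated on logged trajectories (reporting form).

    ``return_term`` is the advantage-weighted log-likelihood surrogate with
    the per-step deviation cost folded into the return (the score-function
    part of the deviation gradient); ``deviation_term`` the per-timestep mean
    KL(pi || pi0); ``complexity_term`` the variational-dropout KL of
    ``params``.
    """
    if not batch:
        raise ValueError("empty batch")
    mean_T = float(np.mean([len(tr.actions) for tr in batch]))
    surrogate, kl_sum, n_steps = 0.0, 0.0, 0
    for tr in batch:
        aug = tr.rewards - (cfg.lambda_dev / mean_T) * tr.step_kls
        G = discounted_returns(aug, cfg.gamma)
        adv = G - tr.values
        logp = np.log(np.clip(
            tr.control_dists[np.arange(len(tr.actions)), tr.actions], 1e-12, None))
        surrogate += float(np.sum(logp * adv))
        kl_sum += float(np.sum(tr.step_kls))
        n_steps += len(tr.actions)
    for name, val in (("return", surrogate), ("deviation", kl_sum)):
        if not np.isfinite(val):
            raise FloatingPointError(f"NaN in {name} term")
    cx = vdo_complexity(params) * cfg.complexity_scale
    return ObjectiveTerms(
        return_term=surrogate / len(batch),
        deviation_term=kl_sum / max(n_steps, 1),
        complexity_term=cx,
        lambda_dev=cfg.lambda_dev,
        lambda_cx=cfg.lambda_cx,
    )


class Adam:
    """Adam over a flat name -> Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 lr_scale=None):
        self.params, self.lr, self.betas, self.eps = params, lr, betas, eps
        self.lr_scale = lr_scale or (lambda name: 1.0)
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * self.lr_scale(k) * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _clip_grads(params: dict[str, Tensor], max_norm: float) -> None:
    sq = sum(float(np.sum(p.grad ** 2)) for p in params.values()
             if p.grad is not None)
    norm = np.sqrt(sq)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale


def _rollout(agent: MDLCAgent, envs: list, cfg: TrainConfig,
             rng: np.random.Generator, noise: str, build_graph: bool):
    """Run one batched episode per env; returns step records and trajectories."""
    B = len(envs)
    obs = np.stack([e.reset(rng) for e in envs])
    state = agent.initial_state(B)
    done = np.zeros(B, dtype=bool)
    steps = []  # per-step dict of tensors/arrays
    ep = [dict(obs=[], act=[], rew=[], d0=[], dc=[], val=[], kl=[], info=[])
          for _ in range(B)]
    horizon = max(e.spec.horizon for e in envs)
    gate_eps = rng.standard_normal((B, len(agent.config.feature_groups))) \
        if noise == "sampled" else None
    probe_obs, probe_hid = [], []
    cache: dict = {}
    for _t in range(horizon):
        out = agent._forward(Tensor(obs), state, noise, rng, gate_eps, cache)
        if _t % 3 == 0:
            live = ~done
            probe_obs.append(obs[live])
            probe_hid.append(state.default_hidden[live])
        state = out["state"]
        p_act = np.exp(out["logp0"].data) if agent.act_from == "default" \
            else np.exp(out["logp"].data)
        u = rng.random(B)
        acts = (p_act.cumsum(axis=1) < u[:, None]).sum(axis=1)
        acts = np.minimum(acts, p_act.shape[1] - 1)
        rewards = np.zeros(B)
        mask = (~done).astype(float)
        new_obs = obs.copy()
        for b, env in enumerate(envs):
            if done[b]:
                continue
            res = env.step(int(acts[b]))
            rewards[b] = res.reward
            ep[b]["obs"].append(obs[b])
            ep[b]["act"].append(int(acts[b]))
            ep[b]["rew"].append(res.reward)
            ep[b]["d0"].append(np.exp(out["logp0"].data[b]))
            ep[b]["dc"].append(np.exp(out["logp"].data[b]))
            ep[b]["val"].append(float(out["value"].data[b]))
            ep[b]["kl"].append(float(out["kl"].data[b]))
            ep[b]["info"].append(res.info)
            if res.done:
                done[b] = True
                new_obs[b] = 0.0
            else:
                new_obs[b] = res.observation
        steps.append({
            "out": out if build_graph else None,
            "acts": acts, "rewards": rewards, "mask": mask,
            "kl": out["kl"].data.copy(), "value": out["value"].data.copy(),
        })
        obs = new_obs
        if done.all():
            break
    probe_cache = (np.concatenate(probe_obs)[:96],
                   np.concatenate(probe_hid)[:96]) if probe_obs else None
    trajs = [Trajectory(
        observations=np.asarray(e["obs"]), actions=np.asarray(e["act"], int),
        rewards=np.asarray(e["rew"], float), default_dists=np.asarray(e["d0"]),
        control_dists=np.asarray(e["dc"]), values=np.asarray(e["val"], float),
        step_kls=np.asarray(e["kl"], float), infos=e["info"])
        for e in ep if e["act"]]
    return steps, trajs, probe_cache


def _loss_graph(agent: MDLCAgent, steps: list[dict], cfg: TrainConfig,
                update: int | None = None):
    """Assemble the differentiable loss from a batched rollout."""
    B = len(steps[0]["mask"])
    T = len(steps)
    mask = np.stack([s["mask"] for s in steps])          # (T, B)
    rewards = np.stack([s["rewards"] for s in steps])
    kls = np.stack([s["kl"] for s in steps]) * mask
    values = np.stack([s["value"] for s in steps])
    n_steps = mask.sum()
    mean_T = n_steps / B
    lam_d = 0.0 if agent.frozen_default else cfg.lambda_dev
    aug = rewards - (lam_d / mean_T) * kls
    # discounted returns per env over masked steps
    G = np.zeros_like(aug)
    acc = np.zeros(B)
    for t in range(T - 1, -1, -1):
        acc = aug[t] + cfg.gamma * acc * mask[t]
        G[t] = acc
    adv = (G - values) * mask

    pg = Tensor(0.0)
    vloss = Tensor(0.0)
    dev = Tensor(0.0)
    ent = Tensor(0.0)
    for t, s in enumerate(steps):
        out = s["out"]
        m = Tensor(mask[t])
        logp_a = out["logp"].take_along(s["acts"])
        pg = pg + (logp_a * Tensor(adv[t]) * m).sum()
        diff = out["value"] - Tensor(G[t])
        vloss = vloss + (diff * diff * m).sum()
        if cfg.deviation_grad == "pi_only":
            kl_t = (out["logp"].exp() * (out["logp"] - out["logp0"].detach())).sum(axis=1)
        elif cfg.deviation_grad == "pi0_only":
            lp = out["logp"].detach()
            kl_t = (lp.exp() * (lp - out["logp0"])).sum(axis=1)
        else:
            kl_t = out["kl"]
        dev = dev + (kl_t * m).sum()
        ent = ent + (-(out["logp"].exp() * out["logp"]).sum(axis=1) * m).sum()
        if cfg.entropy_pi0 > 0:
            ent0 = (-(out["logp0"].exp() * out["logp0"]).sum(axis=1) * m).sum()
            ent = ent + ent0 * (cfg.entropy_pi0 / max(cfg.entropy_bonus, 1e-12))
    return_term = pg * (1.0 / B)
    deviation_term = dev * (1.0 / n_steps)
    cx_params = agent.default_variational_params()
    cx_t = Tensor(0.0)
    from .agent import _K1, _K2, _K3  # sigmoid approximation constants
    for name in agent.VD_MATS:
        theta, ls2 = agent.params[name], agent.params[name + "__ls2"]
        log_alpha = ls2 - (theta * theta + 1e-12).log()
        neg = _K1 * (Tensor(_K2) + log_alpha * _K3).sigmoid() \
            - 0.5 * ((-log_alpha).exp() + 1.0).log() - _K1
        cx_t = cx_t + (neg * -1.0).sum()
    log_alpha_g = agent.params["gate_logalpha"]
    neg_g = _K1 * (Tensor(_K2) + log_alpha_g * _K3).sigmoid() \
        - 0.5 * ((-log_alpha_g).exp() + 1.0).log() - _K1
    cx_t = cx_t + (neg_g * -1.0).sum()
    complexity_term = cx_t * cfg.complexity_scale
    lam_cx = 0.0 if agent.frozen_default else cfg.lambda_cx
    if update is not None and cfg.complexity_warmup > 0:
        lam_cx *= min(1.0, (update + 1) / cfg.complexity_warmup)
    total = (return_term * -1.0) + deviation_term * lam_d \
        + complexity_term * lam_cx
    train_loss = total + vloss * (cfg.value_coef / n_steps) \
        + ent * (-cfg.entropy_bonus / n_steps)
    terms = ObjectiveTerms(
        return_term=float(return_term.data),
        deviation_term=float(deviation_term.data),
        complexity_term=float(complexity_term.data),
        lambda_dev=lam_d, lambda_cx=lam_cx)
    stats = {
        "mean_reward": float((rewards * mask).sum() / B),
        "mean_kl": float(kls.sum() / n_steps),
        "mean_length": float(mean_T),
    }
    return train_loss, terms, stats


def train(agent: MDLCAgent, env_factory, cfg: TrainConfig,
          callback=None) -> tuple[MDLCAgent, list[dict]]:
    """Advantage actor-critic training of the dual-pathway agent.

    ``env_factory(i, rng)`` builds the i-th of ``episodes_per_update``
    parallel environment instances (persistent across updates, reset every
    episode).  Returns the trained agent (in place) and a per-update metrics
    log.  Fully reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    envs = [env_factory(i, rng) for i in range(cfg.episodes_per_update)]
    def scale(name):
        s = 1.0
        if name.startswith("d_") or name.startswith("gate_"):
            s *= cfg.default_lr_scale
        if name.endswith("__ls2") or name == "gate_logalpha":
            s *= cfg.vdo_lr_scale
        return s
    opt = Adam(agent.trainable(), lr=cfg.lr, lr_scale=scale)
    log: list[dict] = []
    for upd in range(cfg.total_updates):
        steps, _trajs, probe_cache = _rollout(agent, envs, cfg, rng,
                                              "sampled", True)
        loss, terms, stats = _loss_graph(agent, steps, cfg, update=upd)
        if not np.isfinite(loss.data) or abs(float(loss.data)) > 1e8:
            raise FloatingPointError(
                f"training diverged at update {upd}: loss={float(loss.data)}; "
                f"last metrics {log[-1] if log else None}")
        opt.params = agent.trainable()
        opt.zero_grad()
        loss.backward()
        _clip_grads(opt.params, cfg.grad_clip)
        opt.step()
        if probe_cache is not None:
            agent._probe_cache = probe_cache
        row = {
            "update": upd, "total": terms.total,
            "return_term": terms.return_term,
            "deviation_term": terms.deviation_term,
            "complexity_term": terms.complexity_term,
            **stats,
        }
        for name, g in agent.gate_readout().as_dict().items():
            row[f"gate_{name}"] = g
        log.append(row)
        if callback is not None:
            callback(upd, agent, row, _trajs)
    return agent, log


def save_metrics(log: list[dict], csv_path, summary_path=None) -> None:
    """Write the per-update metrics log as CSV plus a JSON summary."""
    import json

    import pandas as pd

    df = pd.DataFrame(log)
    df.to_csv(csv_path, index=False)
    if summary_path is not None:
        tail = df.tail(max(1, len(df) // 10))
        summary = {
            "updates": len(df),
            "final_mean_reward": float(tail["mean_reward"].mean()),
            "final_mean_kl": float(tail["mean_kl"].mean()),
            "final_complexity": float(tail["complexity_term"].mean()),
        }
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)


def evaluate(agent: MDLCAgent, env_factory, n_episodes: int, seed: int,
             noise: str = "mean") -> list[Trajectory]:
    """Roll out episodes without learning (mean-mode by default)."""
    rng = np.random.default_rng(seed)
    out: list[Trajectory] = []
    envs = [env_factory(i, rng) for i in range(min(n_episodes, 16))]
    cfg = TrainConfig(seed=seed)
    while len(out) < n_episodes:
        with no_grad():
            _, trajs, _ = _rollout(agent, envs, cfg, rng, noise, False)
        out.extend(trajs)
    return out[:n_episodes]
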