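"""TD3 with fNIRS-gated IDM switching and behavior-cloning guidance.

Standard twin-delayed DDPG — twin critics regressing on the minimum of
the target critics (with target-policy smoothing), a delayed
deterministic actor, Polyak-averaged targets — plus the two study-
specific modifications:

* action switching: the executed action is
  a = (1 − k_fNIRS)·a_RL + k_fNIRS·a_IDM, i.e. exactly the IDM fallback
  whenever the risk gate is raised;
* guided actor update: an auxiliary behavior-cloning term
  k_fNIRS·‖a_IDM − π_θ(s)‖² is subtracted from the actor objective, so
  transitions executed by the fallback pull the policy toward it while
  ungated transitions leave the standard TD3 update untouched.

Training alternates human-in-loop episodes (gate live, exploration
noise, updates) with agent-only testing episodes (gate forced 0, no
noise, no updates), mirroring the odd/even experimental protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivesim import LongitudinalEnv
from .evalstats import jerk_stats
from .nets import MLP, Adam

STATE_DIM = 8
# fixed observation scaling: positions ~hundreds of m, speeds ~tens of m/s
OBS_SCALE = np.array([20.0, 20.0, 100.0, 10.0, 20.0, 20.0, 100.0, 10.0])


@dataclass
class TD3Config:
    hidden: tuple[int, ...] = (256, 256)
    critic_lr: float = 3e-4      # α
    actor_lr: float = 3e-4       # β
    gamma: float = 0.99
    rho: float = 0.995           # Polyak constant (fraction kept)
    batch_size: int = 256
    policy_delay: int = 2
    explore_noise: float = 0.1
    target_noise: float = 0.2
    target_noise_clip: float = 0.5
    target_smoothing: bool = True
    bc_weight: float = 1.0
    warmup_steps: int = 1000
    buffer_capacity: int = 100_000
    store_executed_action: bool = True


@dataclass
class Transition:
    s: np.ndarray
    a: float
    r: float
    s2: np.ndarray
    done: bool
    k_fnirs: int
    a_idm: float


class ReplayBuffer:
    """Uniform-sampling ring buffer of transitions."""

    def __init__(self, capacity: int, state_dim: int = STATE_DIM):
        self.capacity = capacity
        self.s = np.zeros((capacity, state_dim))
        self.a = np.zeros((capacity, 1))
        self.r = np.zeros((capacity, 1))
        self.s2 = np.zeros((capacity, state_dim))
        self.done = np.zeros((capacity, 1))
        self.k = np.zeros((capacity, 1))
        self.a_idm = np.zeros((capacity, 1))
        self.size = 0
        self._ptr = 0

    def add(self, tr: Transition) -> None:
        i = self._ptr
        self.s[i] = tr.s
        self.a[i] = tr.a
        self.r[i] = tr.r
        self.s2[i] = tr.s2
        self.done[i] = float(tr.done)
        self.k[i] = tr.k_fnirs
        self.a_idm[i] = tr.a_idm
        self._ptr = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator) -> dict:
        if self.size == 0:
            raise ValueError("cannot sample from an empty buffer")
        idx = rng.integers(0, self.size, batch_size)
        return {"s": self.s[idx], "a": self.a[idx], "r": self.r[idx],
                "s2": self.s2[idx], "done": self.done[idx],
                "k": self.k[idx], "a_idm": self.a_idm[idx]}


def switch_action(a_rl: float, a_idm: float, k_fnirs: int) -> float:
    """a = (1 − k)·a_RL + k·a_IDM with a strictly boolean gate."""
    if k_fnirs not in (0, 1):
        raise ValueError("k_fnirs must be 0 or 1")
    return (1 - k_fnirs) * a_rl + k_fnirs * a_idm


class TD3Agent:
    """Actor, twin critics, their targets, and the guided update rules."""

    def __init__(self, config: TD3Config | None = None, seed: int = 0):
        self.cfg = config if config is not None else TD3Config()
        rng = np.random.default_rng(seed)
        h = list(self.cfg.hidden)
        self.actor = MLP([STATE_DIM] + h + [1], tanh_head=True, rng=rng)
        self.critic1 = MLP([STATE_DIM + 1] + h + [1], rng=rng)
        self.critic2 = MLP([STATE_DIM + 1] + h + [1], rng=rng)
        self.actor_targ = self.actor.clone()
        self.critic1_targ = self.critic1.clone()
        self.critic2_targ = self.critic2.clone()
        self.actor_opt = Adam([self.actor], lr=self.cfg.actor_lr)
        self.critic_opt = Adam([self.critic1, self.critic2],
                               lr=self.cfg.critic_lr)
        self.rng = rng
        self.total_updates = 0

    # -- acting -------------------------------------------------------------

    def _obs(self, state: np.ndarray) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape[-1] != STATE_DIM:
            raise ValueError(f"state must be {STATE_DIM}-dimensional")
        return state / OBS_SCALE

    def select_action(self, state: np.ndarray, explore: bool = False) -> float:
        a = float(self.actor(self._obs(state))[0, 0])
        if explore and self.cfg.explore_noise > 0:
            a += self.rng.normal(0, self.cfg.explore_noise)
        return float(np.clip(a, -1.0, 1.0))

    # -- updates ------------------------------------------------------------

    def _target_actions(self, s2: np.ndarray) -> np.ndarray:
        a2 = self.actor_targ(s2)
        if self.cfg.target_smoothing and self.cfg.target_noise > 0:
            noise = np.clip(
                self.rng.normal(0, self.cfg.target_noise, a2.shape),
                -self.cfg.target_noise_clip, self.cfg.target_noise_clip)
            a2 = np.clip(a2 + noise, -1.0, 1.0)
        return a2

    def critic_update(self, batch: dict) -> tuple[float, float]:
        """Regress both critics toward r + γ·(1−done)·min_i Q_targ,i(s′,a′)."""
        if batch["s"].shape[0] == 0:
            raise ValueError("empty batch")
        s = self._obs(batch["s"])
        s2 = self._obs(batch["s2"])
        a2 = self._target_actions(s2)
        q1t = self.critic1_targ(np.hstack([s2, a2]))
        q2t = self.critic2_targ(np.hstack([s2, a2]))
        y = batch["r"] + self.cfg.gamma * (1.0 - batch["done"]) * np.minimum(q1t, q2t)
        n = s.shape[0]
        sa = np.hstack([s, batch["a"]])
        losses = []
        for critic in (self.critic1, self.critic2):
            q = critic(sa)
            err = q - y
            losses.append(float(np.mean(err ** 2)))
            critic.backward(2.0 * err / n)
        self.critic_opt.step()
        return losses[0], losses[1]

    def actor_update_guided(self, batch: dict) -> float:
        """Ascend Q_ϕ1(s, π(s)) − bc_weight·mean(k·(a_IDM − π(s))²)."""
        s = self._obs(batch["s"])
        n = s.shape[0]
        pi = self.actor(s)
        q = self.critic1(np.hstack([s, pi]))
        grad_sa = self.critic1.backward(np.ones_like(q) / n)
        self.critic1.zero_grad()  # the critic is frozen during the actor step
        grad_pi = grad_sa[:, STATE_DIM:]
        bc_grad = 2.0 * batch["k"] * (pi - batch["a_idm"]) / n
        # gradient of (−Q + bc term) with respect to the actor output
        self.actor.backward(-grad_pi + self.cfg.bc_weight * bc_grad)
        self.actor_opt.step()
        loss = float(-np.mean(q) + self.cfg.bc_weight
                     * np.mean(batch["k"] * (batch["a_idm"] - pi) ** 2))
        return loss

    def polyak_update(self, rho: float | None = None) -> None:
        rho = self.cfg.rho if rho is None else rho
        if not 0.0 <= rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        for src, targ in ((self.critic1, self.critic1_targ),
                          (self.critic2, self.critic2_targ),
                          (self.actor, self.actor_targ)):
            for p, q in zip(src.parameters(), targ.parameters()):
                q[...] = rho * q + (1.0 - rho) * p

    def train_step(self, buffer: ReplayBuffer) -> None:
        batch = buffer.sample(self.cfg.batch_size, self.rng)
        self.critic_update(batch)
        self.total_updates += 1
        if self.total_updates % self.cfg.policy_delay == 0:
            self.actor_update_guided(batch)
            self.polyak_update()


# ---------------------------------------------------------------------------
# training protocol


class OracleRiskSource:
    """Ground-truth gate: raised exactly while the hazard is active."""

    def attach(self, env: LongitudinalEnv) -> None:
        self.env = env

    def gate(self, info: dict | None) -> int:
        if info is None:
            return 0
        return int(info["risk_active"])


class NullRiskSource:
    """Control arm: the gate never rises (plain TD3)."""

    def attach(self, env: LongitudinalEnv) -> None:
        pass

    def gate(self, info: dict | None) -> int:
        return 0


def run_episode(env: LongitudinalEnv, agent: TD3Agent,
                buffer: ReplayBuffer | None, risk_source, seed: int,
                guided: bool, train: bool) -> dict:
    """One episode; guided means the gate may switch control to IDM."""
    state = env.reset(seed)
    risk_source.attach(env)
    info = None
    total = 0.0
    accels = []
    max_rf = 0.0
    min_ttc = float("inf")
    k_steps = 0
    steps = 0
    while True:
        k = risk_source.gate(info) if guided else 0
        a_rl = agent.select_action(state, explore=train)
        a_idm = env.idm_action()
        a = switch_action(a_rl, a_idm, k)
        next_state, r, done, info = env.step(a)
        if train and buffer is not None:
            stored = a if agent.cfg.store_executed_action else a_rl
            buffer.add(Transition(state, stored, r, next_state, done, k, a_idm))
            if buffer.size >= agent.cfg.warmup_steps:
                agent.train_step(buffer)
        total += r
        accels.append(info["accel"])
        max_rf = max(max_rf, info["risk_field"])
        min_ttc = min(min_ttc, info["ttc"])
        k_steps += k
        steps += 1
        state = next_state
        if done:
            break
    mpj, mnj = jerk_stats(np.array(accels), env.cfg.dt)
    return {"reward": total, "steps": steps, "collided": info["collided"],
            "near_miss": info["near_miss"], "max_risk_field": max_rf,
            "min_ttc": 0.0 if info["collided"] else min_ttc,
            "mean_pos_jerk": mpj, "mean_neg_jerk": mnj,
            "gated_steps": k_steps}


def run_protocol(env: LongitudinalEnv, agent: TD3Agent, risk_source,
                 n_pairs: int = 30, seed: int = 0,
                 buffer: ReplayBuffer | None = None) -> pd.DataFrame:
    """Alternating protocol: odd episodes guided training, even agent-only tests.

    Returns a per-episode log (one row per episode, ``guided`` flag set on
    the training episodes) with cumulative reward, max risk-field value,
    min TTC and mean jerk.
    """
    if buffer is None:
        buffer = ReplayBuffer(agent.cfg.buffer_capacity)
    ss = np.random.SeedSequence(seed)
    ep_seeds = ss.generate_state(2 * n_pairs) % (2**31 - 1)
    rows = []
    for pair in range(n_pairs):
        for guided, train in ((True, True), (False, False)):
            i = 2 * pair + (0 if guided else 1)
            out = run_episode(env, agent, buffer, risk_source,
                              int(ep_seeds[i]), guided=guided, train=train)
            out.update({"episode": i + 1, "pair": pair + 1,
                        "guided": guided, "train": train})
            rows.append(out)
    return pd.DataFrame(rows)
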