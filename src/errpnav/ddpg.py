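"""Discrete-action DDPG with HF-guided epsilon-greedy exploration.

Off-policy actor-critic adapted to the six-action navigation task: the
actor's output layer is replaced by a softmax over the discrete actions and
the critic scores (state, action-representation) pairs, taking the one-hot
action for stored transitions and the actor's soft output for the policy
gradient.  Exploration follows an epsilon schedule that decays linearly from
1 to 0 over a fixed global step count (125,000 at full scale); while epsilon
fires, the action comes from the HF policy's greedy choice (or uniformly at
random for the sparse baseline).  The replay buffer is reward-prioritized:
10% of every batch are the highest-reward transitions stored so far (ties
broken by recency), the rest uniform without replacement.

Per environment step the networks are updated ``updates_per_step`` times
(20 at full scale), each on a freshly sampled batch and followed by a
Polyak soft update of the target networks (tau = 0.005).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np

from .gridworld import GridWorld, N_ACTIONS, shortest_path_length
from .metrics import RunCurve
from .nn import MLP, Adam, soft_update_params, softmax

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DDPGConfig:
    """Hyperparameters; defaults are the full-scale study settings."""

    gamma: float = 0.9
    tau: float = 0.005
    actor_lr: float = 0.003
    critic_lr: float = 0.001
    updates_per_step: int = 20
    batch_size: int = 64
    buffer_capacity: int = 200_000
    epsilon_start: float = 1.0
    epsilon_end: float = 0.0
    epsilon_end_step: int = 125_000
    episodes: int = 8000
    max_steps: int = 160
    priority_fraction: float = 0.10
    hidden: tuple = (64, 64)
    warmup: int = 64          # env steps before updates start
    entropy_beta: float = 0.01  # actor entropy bonus; prevents premature
    #                             softmax saturation (vanishing gradients)

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")
        if self.epsilon_end > self.epsilon_start:
            raise ValueError("epsilon schedule must be non-increasing")


def desk_config(**overrides) -> DDPGConfig:
    """Reduced problem size for desk-scale experiments on one CPU core.

    Scales the full protocol down (fewer episodes, shorter episodes, fewer
    updates per step, epsilon budget matched to the reduced step budget)
    while keeping the learning dynamics (gamma, tau, learning rates,
    priority replay) identical.
    """
    base = dict(episodes=260, max_steps=28, updates_per_step=5,
                batch_size=32, epsilon_end_step=3_200, warmup=200,
                buffer_capacity=50_000)
    base.update(overrides)
    return DDPGConfig(**base)


def epsilon(step: int, cfg: DDPGConfig) -> float:
    """Piecewise-linear exploration schedule, exact at both endpoints."""
    if step >= cfg.epsilon_end_step:
        return cfg.epsilon_end
    frac = step / cfg.epsilon_end_step
    return cfg.epsilon_start + frac * (cfg.epsilon_end - cfg.epsilon_start)


class ReplayBuffer:
    """Flat transition store with reward-prioritized batch composition."""

    def __init__(self, capacity: int, obs_dim: int = 8):
        self.capacity = capacity
        self.obs = np.zeros((capacity, obs_dim))
        self.action = np.zeros(capacity, dtype=np.int64)
        self.reward = np.zeros(capacity)
        self.next_obs = np.zeros((capacity, obs_dim))
        self.done = np.zeros(capacity)
        self.insert_order = np.zeros(capacity, dtype=np.int64)
        self.size = 0
        self._next = 0
        self._counter = 0
        self._order = None   # cached reward/recency sort, invalidated on add

    def add(self, obs, action, reward, next_obs, done) -> None:
        i = self._next
        self.obs[i] = obs
        self.action[i] = action
        self.reward[i] = reward
        self.next_obs[i] = next_obs
        self.done[i] = float(done)
        self.insert_order[i] = self._counter
        self._counter += 1
        self._next = (self._next + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)
        self._order = None

    def sample_batch(self, batch_size: int, priority_fraction: float,
                     rng: np.random.Generator) -> dict:
        """ceil(priority_fraction * batch) highest-reward transitions (ties
        by recency), remainder uniform without replacement from the rest."""
        if self.size < batch_size:
            raise ValueError("buffer holds fewer transitions than one batch")
        n_prio = min(ceil(priority_fraction * batch_size), self.size)
        if self._order is None:
            self._order = np.lexsort((self.insert_order[:self.size],
                                      self.reward[:self.size]))
        order = self._order
        prio_idx = order[-n_prio:] if n_prio else np.array([], dtype=int)
        rest = order[:-n_prio] if n_prio else order
        n_rand = batch_size - n_prio
        rand_idx = rng.choice(rest, size=n_rand, replace=False) \
            if n_rand else np.array([], dtype=int)
        idx = np.concatenate([prio_idx, rand_idx]).astype(int)
        return {"obs": self.obs[idx], "action": self.action[idx],
                "reward": self.reward[idx], "next_obs": self.next_obs[idx],
                "done": self.done[idx]}


class DDPGAgent:
    """Softmax-actor / scalar-critic pair with target copies."""

    def __init__(self, cfg: DDPGConfig, seed: int = 0, obs_dim: int = 8):
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        s_actor, s_critic, s_sample = ss.spawn(3)
        rng_a = np.random.default_rng(s_actor)
        rng_c = np.random.default_rng(s_critic)
        h = list(cfg.hidden)
        self.actor = MLP([obs_dim] + h + [N_ACTIONS], rng_a, head="softmax")
        self.critic = MLP([obs_dim + N_ACTIONS] + h + [1], rng_c, head="linear")
        self.actor_target = self.actor.clone()
        self.critic_target = self.critic.clone()
        self.actor_opt = Adam(self.actor.params(), lr=cfg.actor_lr)
        self.critic_opt = Adam(self.critic.params(), lr=cfg.critic_lr)
        self.buffer = ReplayBuffer(cfg.buffer_capacity, obs_dim)
        self.rng = np.random.default_rng(s_sample)
        self.global_step = 0

    # ---- acting ----
    def greedy_action(self, obs) -> int:
        return int(np.argmax(self.actor.forward(obs, training=False)[0]))

    def sampled_action(self, obs) -> int:
        """Draw from the actor's softmax distribution (stochastic policy
        during training; it sharpens toward the greedy action as the actor
        converges)."""
        p = self.actor.forward(obs, training=False)[0]
        return int(self.rng.choice(N_ACTIONS, p=p))

    def select_action(self, obs, hf=None, step: int | None = None,
                      stochastic: bool = True) -> int:
        """Epsilon-greedy handover: with probability epsilon(step) take the
        HF policy's greedy action (uniform random when hf is None — the
        sparse baseline); otherwise act from the actor — sampling its
        softmax during training, argmax when ``stochastic`` is False."""
        step = self.global_step if step is None else step
        if self.rng.random() < epsilon(step, self.cfg):
            if hf is None:
                return int(self.rng.integers(N_ACTIONS))
            return int(hf.greedy(obs))
        return self.sampled_action(obs) if stochastic else self.greedy_action(obs)

    # ---- learning ----
    def soft_update(self, tau: float | None = None) -> None:
        tau = self.cfg.tau if tau is None else tau
        soft_update_params(self.actor_target, self.actor, tau)
        soft_update_params(self.critic_target, self.critic, tau)

    def update(self, batch: dict) -> dict:
        """One critic + actor gradient step on a batch; returns diagnostics."""
        cfg = self.cfg
        obs, action = batch["obs"], batch["action"]
        n = len(obs)
        onehot = np.eye(N_ACTIONS)[action]

        # --- critic: one-step bootstrapped TD target
        a_next = self.actor_target.forward(batch["next_obs"], training=False)
        q_next = self.critic_target.forward(
            np.hstack([batch["next_obs"], a_next]), training=False)[:, 0]
        target = batch["reward"] + cfg.gamma * (1.0 - batch["done"]) * q_next
        q = self.critic.forward(np.hstack([obs, onehot]), training=True)[:, 0]
        td = q - target
        critic_loss = float((td ** 2).mean())
        self.critic_opt.zero_grad()
        self.critic.backward((2.0 * td / n)[:, None])
        self.critic_opt.step()

        # --- actor: ascend the critic's value of the soft action output
        probs = self.actor.forward(obs, training=True)
        q_pi = self.critic.forward(np.hstack([obs, probs]), training=False)
        actor_loss = float(-q_pi.mean())
        dinput = self.critic.backward(-np.ones((n, 1)) / n)  # d(-Q)/d input
        dprobs = dinput[:, obs.shape[1]:]
        # route through the softmax jacobian
        dz = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
        if cfg.entropy_beta:
            # entropy bonus H(pi): d(-beta H)/dz = beta * p * (log p + H)
            logp = np.log(np.clip(probs, 1e-12, None))
            ent = -(probs * logp).sum(axis=1, keepdims=True)
            dz += cfg.entropy_beta / n * probs * (logp + ent)
        self.actor_opt.zero_grad()
        self.critic_opt.zero_grad()   # discard critic grads from this pass
        self.actor.backward(dz)
        self.actor_opt.step()

        if not np.isfinite(critic_loss) or not np.isfinite(actor_loss):
            raise FloatingPointError(
                f"non-finite losses: critic={critic_loss}, actor={actor_loss}")
        return {"critic_loss": critic_loss, "actor_loss": actor_loss,
                "td_abs": float(np.abs(td).mean())}


def train(world: GridWorld, hf=None, cfg: DDPGConfig | None = None,
          seed: int = 0, mode: str | None = None) -> RunCurve:
    """Full training loop; returns the per-episode SPL curve.

    ``hf=None`` is the sparse baseline (uniform random exploration).
    Updates start once the buffer holds ``cfg.warmup`` transitions; each
    environment step then triggers ``cfg.updates_per_step`` updates on
    freshly sampled prioritized batches, each followed by a soft target
    update.
    """
    cfg = cfg or DDPGConfig()
    mode = mode or ("sparse" if hf is None else "hf")
    ss = np.random.SeedSequence(seed)
    s_agent, s_env = ss.spawn(2)
    agent = DDPGAgent(cfg, seed=int(s_agent.generate_state(1)[0] % 2 ** 31))
    rng_env = np.random.default_rng(s_env)
    curve = RunCurve(mode=mode, seed=seed)
    for _ in range(cfg.episodes):
        world.max_steps = cfg.max_steps
        world.reset(rng=rng_env)
        shortest = shortest_path_length(world, world.agent, world.goal)
        taken = 0
        success = False
        done = False
        while not done:
            obs = world.observe().vector()
            action = agent.select_action(obs, hf=hf)
            tr = world.step(action)
            taken += 1
            agent.buffer.add(obs, action, tr.reward,
                             tr.next_state.vector(), tr.done)
            agent.global_step += 1
            if agent.buffer.size >= max(cfg.warmup, cfg.batch_size):
                for _ in range(cfg.updates_per_step):
                    batch = agent.buffer.sample_batch(
                        cfg.batch_size, cfg.priority_fraction, agent.rng)
                    agent.update(batch)
                    agent.soft_update()
            done = tr.done
            success = tr.success
        curve.append(success, shortest, taken)
    curve.agent_ = agent
    return curve
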