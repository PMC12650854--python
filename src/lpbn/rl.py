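"""Episodic policy-gradient training on LineWorld and CartPole.

LineWorld is a 1-D chain of 9 positions with terminals at both ends
(reward +1 at the right terminal, −1 at the left, 0 otherwise, horizon 40,
start at the center, one-hot states).  CartPole is the canonical inverted
pendulum (Euler integration at 0.02 s, 12° / 2.4 m termination thresholds,
+1 per surviving step, horizon 280), discretized into 8 equal-width bins
per state variable over fixed physical ranges.

LPBN policies sample a structure once per episode (so the action
log-probabilities along a trajectory are well defined under one concrete
wiring) and update selector logits with the episode's advantage; the
softmax action head and an optional linear critic on h train with ordinary
gradients.  MLP policies train with the same on-policy REINFORCE objective
for seed-paired comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from lpbn import core, estimators
from lpbn.binarize import discretize_rl_state
from lpbn.core import OperatorSet, SelectorPolicy

__all__ = [
    "LineWorldEnv",
    "CartPoleEnv",
    "Trajectory",
    "RLConfig",
    "lineworld_step",
    "cartpole_step",
    "run_episode",
    "returns_and_advantages",
    "train_policy",
    "moving_average",
    "LPBNPolicy",
    "MLPPolicy",
    "CARTPOLE_RANGES",
]


# ---------------------------------------------------------------------------
# Environments
# ---------------------------------------------------------------------------


@dataclass
class LineWorldEnv:
    """1-D chain: positions 0..L-1, terminals at both ends, start center."""

    L: int = 9
    horizon: int = 40

    @property
    def n_actions(self) -> int:
        return 2

    @property
    def substrate_width(self) -> int:
        return self.L

    def reset(self, rng: np.random.Generator) -> int:
        return self.L // 2

    def encode(self, position: int) -> np.ndarray:
        z = np.zeros(self.L, dtype=np.uint8)
        z[position] = 1
        return z

    def is_terminal(self, position: int) -> bool:
        return position == 0 or position == self.L - 1

    def step(self, position: int, action: int):
        return lineworld_step(position, action, L=self.L)


def lineworld_step(position: int, action, L: int = 9):
    """Deterministic unit move; reward on entering a terminal.

    ``action``: 0/'left' or 1/'right'.  Returns (position', reward, done).
    """
    if isinstance(action, str):
        action = {"left": 0, "right": 1}[action]
    if position <= 0 or position >= L - 1:
        raise ValueError("cannot step a finished episode (terminal position)")
    nxt = position + (1 if action == 1 else -1)
    if nxt == L - 1:
        return nxt, 1.0, True
    if nxt == 0:
        return nxt, -1.0, True
    return nxt, 0.0, False


# Canonical cart-pole constants (community-standard benchmark values).
_GRAVITY = 9.8
_CART_MASS = 1.0
_POLE_MASS = 0.1
_TOTAL_MASS = _CART_MASS + _POLE_MASS
_POLE_HALF_LENGTH = 0.5
_POLE_MASS_LENGTH = _POLE_MASS * _POLE_HALF_LENGTH
_FORCE = 10.0
_DT = 0.02
_THETA_THRESHOLD = 12.0 * math.pi / 180.0
_X_THRESHOLD = 2.4

# Fixed discretization ranges: positions/angles at their termination
# thresholds, velocities at ranges covering typical balanced trajectories.
CARTPOLE_RANGES = np.array(
    [[-2.4, 2.4], [-3.0, 3.0], [-_THETA_THRESHOLD, _THETA_THRESHOLD], [-3.5, 3.5]]
)


def cartpole_step(state: np.ndarray, action: int):
    """One Euler step of the canonical cart-pole equations of motion.

    Returns (state', reward, done) with reward +1 per surviving step; done
    on |x| > 2.4 m or |θ| > 12°.
    """
    x, x_dot, theta, theta_dot = state
    force = _FORCE if action == 1 else -_FORCE
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    temp = (force + _POLE_MASS_LENGTH * theta_dot**2 * sin_t) / _TOTAL_MASS
    theta_acc = (_GRAVITY * sin_t - cos_t * temp) / (
        _POLE_HALF_LENGTH * (4.0 / 3.0 - _POLE_MASS * cos_t**2 / _TOTAL_MASS)
    )
    x_acc = temp - _POLE_MASS_LENGTH * theta_acc * cos_t / _TOTAL_MASS
    new = np.array(
        [
            x + _DT * x_dot,
            x_dot + _DT * x_acc,
            theta + _DT * theta_dot,
            theta_dot + _DT * theta_acc,
        ]
    )
    done = abs(new[0]) > _X_THRESHOLD or abs(new[2]) > _THETA_THRESHOLD
    return new, 1.0, done


@dataclass
class CartPoleEnv:
    """Canonical cart-pole with 8-bin one-hot state discretization."""

    horizon: int = 280
    B: int = 8

    @property
    def n_actions(self) -> int:
        return 2

    @property
    def substrate_width(self) -> int:
        return 4 * self.B

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-0.05, 0.05, size=4)

    def encode(self, state: np.ndarray) -> np.ndarray:
        return discretize_rl_state(state, CARTPOLE_RANGES, B=self.B)

    def is_terminal(self, state) -> bool:
        return abs(state[0]) > _X_THRESHOLD or abs(state[2]) > _THETA_THRESHOLD

    def step(self, state, action):
        return cartpole_step(state, action)


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------


@dataclass
class LPBNPolicy:
    """Selector policy + softmax action head (+ linear critic on h)."""

    policy: SelectorPolicy
    operators: OperatorSet
    V: np.ndarray  # (n_actions, N) action head
    c: np.ndarray  # (n_actions,) action bias
    critic_w: np.ndarray = None
    critic_b: float = 0.0

    @classmethod
    def init(cls, m: int, N: int, n_actions: int = 2, critic: bool = False):
        pol = SelectorPolicy.uniform(N, m)
        return cls(
            pol,
            OperatorSet(),
            np.zeros((n_actions, N)),
            np.zeros(n_actions),
            critic_w=np.zeros(N) if critic else None,
        )

    @property
    def n_params(self) -> int:
        p = self.policy
        return p.N * (2 * p.m + p.n_ops) + self.V.size + self.c.size

    def action_probs(self, h: np.ndarray) -> np.ndarray:
        return core.selector_probs(h @ self.V.T + self.c)


@dataclass
class MLPPolicy:
    """Softmax MLP policy with one or more tanh hidden layers."""

    Ws: list
    bs: list

    @classmethod
    def init(cls, d_in: int, hidden, n_actions: int, rng):
        sizes = [d_in] + list(hidden) + [n_actions]
        Ws, bs = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            Ws.append(rng.uniform(-1, 1, size=(b, a)) / np.sqrt(a))
            bs.append(np.zeros(b))
        return cls(Ws, bs)

    @property
    def n_params(self) -> int:
        return sum(W.size for W in self.Ws) + sum(b.size for b in self.bs)

    def forward(self, x: np.ndarray):
        acts = [np.asarray(x, dtype=float)]
        for W, b in zip(self.Ws[:-1], self.bs[:-1]):
            acts.append(np.tanh(W @ acts[-1] + b))
        logits = self.Ws[-1] @ acts[-1] + self.bs[-1]
        return core.selector_probs(logits), acts

    def action_probs(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    states: list
    substrates: list
    actions: list
    rewards: list
    returns: np.ndarray = None
    advantages: np.ndarray = None
    structure: object = None  # the per-episode StructureSample (LPBN)
    structures: list = None  # per-step samples when resampling each step
    hs: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.actions)

    @property
    def total_reward(self) -> float:
        return float(np.sum(self.rewards))


def run_episode(
    policy, env, rng: np.random.Generator, resample_per_step: bool = False
) -> Trajectory:
    """Roll one episode, sampling actions from the policy head each step.

    By default an LPBN structure is sampled once per episode and held fixed
    along the trajectory (a concrete Boolean network acts as the controller
    for that episode); with ``resample_per_step`` a fresh structure is drawn
    at every step — the probabilistic-Boolean-network reading of the
    dynamics, which also feeds the selector estimator one sample per step.
    """
    is_lpbn = isinstance(policy, LPBNPolicy)
    struct = (
        core.sample_structure(policy.policy, rng)
        if is_lpbn and not resample_per_step
        else None
    )
    structures = [] if (is_lpbn and resample_per_step) else None
    s = env.reset(rng)
    states, subs, actions, rewards, hs = [], [], [], [], []
    for _ in range(env.horizon):
        z = env.encode(s)
        if is_lpbn:
            st = struct
            if resample_per_step:
                st = core.sample_structure(policy.policy, rng)
                structures.append(st)
            h = core.forward(st, z, policy.operators).astype(float)
            probs = policy.action_probs(h)
            hs.append(h)
        else:
            probs = policy.action_probs(z.astype(float))
        a = int(np.searchsorted(np.cumsum(probs), rng.random()))  # inverse CDF
        a = min(a, len(probs) - 1)
        states.append(s)
        subs.append(z)
        actions.append(a)
        s, r, done = env.step(s, a)
        rewards.append(r)
        if done:
            break
    return Trajectory(
        states, subs, actions, rewards, structure=struct,
        structures=structures, hs=hs,
    )


def returns_and_advantages(
    traj: Trajectory,
    discount: float = 1.0,
    baseline: float = 0.0,
    clip: tuple = (-5.0, 5.0),
) -> Trajectory:
    """Backward-recursion returns G_t and clipped advantages A_t = G_t − b."""
    T = traj.length
    G = np.zeros(T)
    acc = 0.0
    for t in range(T - 1, -1, -1):
        acc = traj.rewards[t] + discount * acc
        G[t] = acc
    traj.returns = G
    adv = G - np.asarray(baseline, dtype=float)
    traj.advantages = estimators.clip_values(adv, advantage_range=clip)
    return traj


def moving_average(values, window: int = 100) -> np.ndarray:
    """Trailing mean with truncated head windows (element 0 is itself)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(1, len(v) + 1)
    lo = np.maximum(0, idx - window)
    return (c[idx] - c[lo]) / (idx - lo)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class RLConfig:
    """Hyperparameters for episodic REINFORCE training.

    Defaults are the LineWorld recipe; :func:`cartpole_defaults` gives the
    CartPole one (lower rates, discounting, linear critic).
    """

    episodes: int = 500
    seed: int = 0
    lr_logits: float = 7e-2
    lr_head: float = 1.8e-1
    lr_critic: float = 0.05
    discount: float = 1.0
    ema_decay: float = 0.95
    lambda0: float = 5e-3
    anneal_over: int = None  # steps at which entropy hits 0 (default half)
    clip: tuple = (-5.0, 5.0)
    grad_norm_cap: float = 5.0
    N: int = 16
    use_critic: bool = False
    resample_per_step: bool = False
    structure_init: str = "uniform"  # or "identity" (pass-through wiring)
    init_bias: float = 8.0
    mlp_hidden: tuple = (16,)
    mlp_lr: float = 2e-2

    @classmethod
    def cartpole_defaults(cls, seed: int = 0) -> "RLConfig":
        """DRL recipe: low rates, discounting, linear critic, slow entropy
        annealing over the full budget, and identity-biased selector
        initialization (each unit starts wired as a pass-through of one
        substrate bit via OR(z, z) = z, so the action head sees a stable
        discretized state while the selectors remain trainable)."""
        return cls(
            episodes=300,
            seed=seed,
            lr_logits=1e-2,
            lr_head=2e-2,
            lr_critic=0.1,
            discount=0.99,
            lambda0=5e-3,
            anneal_over=300,
            N=32,
            use_critic=True,
            structure_init="identity",
            mlp_hidden=(40, 40),
            mlp_lr=5e-3,
        )


def _entropy_step(policy: SelectorPolicy, lam: float, lr: float):
    if lam <= 0:
        return
    policy.a_logits += lr * lam * estimators.entropy_grad(policy.a_logits)
    policy.b_logits += lr * lam * estimators.entropy_grad(policy.b_logits)
    policy.o_logits += lr * lam * estimators.entropy_grad(policy.o_logits)


def _update_lpbn(policy: LPBNPolicy, traj: Trajectory, cfg: RLConfig, baseline):
    """Per-episode update of head, critic and selector logits."""
    T = traj.length
    H = np.asarray(traj.hs, dtype=float)  # (T, N)
    A = np.asarray(traj.actions)
    G = traj.returns
    if cfg.use_critic and policy.critic_w is not None:
        values = H @ policy.critic_w + policy.critic_b
        adv = estimators.clip_values(G - values, advantage_range=cfg.clip)
        verr = values - G
        policy.critic_w = policy.critic_w - cfg.lr_critic * (verr @ H) / T
        policy.critic_b = policy.critic_b - cfg.lr_critic * float(verr.mean())
    else:
        adv = estimators.clip_values(G - baseline.b, advantage_range=cfg.clip)
    # softmax head: grad log pi(a|h) wrt logits = onehot(a) - probs
    probs = core.selector_probs(H @ policy.V.T + policy.c)
    onehot = np.zeros_like(probs)
    onehot[np.arange(T), A] = 1.0
    dlogits = (onehot - probs) * adv[:, None]
    gV = estimators.clip_values(dlogits.T @ H, None, cfg.grad_norm_cap)
    gc = estimators.clip_values(dlogits.sum(axis=0), None, cfg.grad_norm_cap)
    policy.V = policy.V + cfg.lr_head * gV
    policy.c = policy.c + cfg.lr_head * gc
    if cfg.resample_per_step and traj.structures is not None:
        # one selector sample per step: summed per-step advantage terms
        stacked = core.StructureSample(
            np.stack([s.A for s in traj.structures]),
            np.stack([s.B for s in traj.structures]),
            np.stack([s.O for s in traj.structures]),
        )
        grad = estimators.batch_score_function_grad(
            policy.policy, stacked, baseline.b + adv, baseline.b
        ).scaled(T)
    else:
        # per-episode structure: episode return with EMA baseline
        F = G[0]
        struct_adv = float(
            estimators.clip_values(np.array([F - baseline.b]), cfg.clip)[0]
        )
        grad = estimators.score_function_grad(
            policy.policy, traj.structure, baseline.b + struct_adv, baseline.b
        )
    for attr, g in (("a_logits", grad.a), ("b_logits", grad.b), ("o_logits", grad.o)):
        g = estimators.clip_values(g, None, cfg.grad_norm_cap)
        setattr(policy.policy, attr, getattr(policy.policy, attr) + cfg.lr_logits * g)


def _update_mlp(policy: MLPPolicy, traj: Trajectory, cfg: RLConfig, baseline):
    adv = estimators.clip_values(
        traj.returns - baseline.b, advantage_range=cfg.clip
    )
    grads_W = [np.zeros_like(W) for W in policy.Ws]
    grads_b = [np.zeros_like(b) for b in policy.bs]
    for t in range(traj.length):
        x = traj.substrates[t].astype(float)
        probs, acts = policy.forward(x)
        onehot = np.zeros_like(probs)
        onehot[traj.actions[t]] = 1.0
        delta = (onehot - probs) * adv[t]
        for layer in range(len(policy.Ws) - 1, -1, -1):
            grads_W[layer] += np.outer(delta, acts[layer])
            grads_b[layer] += delta
            if layer > 0:
                delta = (policy.Ws[layer].T @ delta) * (1 - acts[layer] ** 2)
    flat = np.concatenate([g.ravel() for g in grads_W + grads_b])
    norm = np.linalg.norm(flat)
    scale = cfg.grad_norm_cap / norm if norm > cfg.grad_norm_cap else 1.0
    for layer in range(len(policy.Ws)):
        policy.Ws[layer] += cfg.mlp_lr * scale * grads_W[layer]
        policy.bs[layer] += cfg.mlp_lr * scale * grads_b[layer]


def train_policy(env, policy_kind: str, cfg: RLConfig):
    """Train an LPBN or MLP policy with episodic REINFORCE.

    Returns (policy, returns array, moving_average array).  Entropy on the
    selector distributions is annealed linearly to zero over the first half
    of the episode budget (warm-up against premature structure collapse).
    """
    rng = np.random.default_rng(cfg.seed)
    if policy_kind == "lpbn":
        policy = LPBNPolicy.init(
            env.substrate_width, cfg.N, env.n_actions, critic=cfg.use_critic
        )
        if cfg.structure_init == "identity":
            m = env.substrate_width
            or_idx = policy.operators.index("OR")
            for n in range(cfg.N):
                policy.policy.a_logits[n, n % m] = cfg.init_bias
                policy.policy.b_logits[n, n % m] = cfg.init_bias
                policy.policy.o_logits[n, or_idx] = cfg.init_bias
        elif cfg.structure_init != "uniform":
            raise ValueError(f"unknown structure_init {cfg.structure_init!r}")
    elif policy_kind == "mlp":
        policy = MLPPolicy.init(
            env.substrate_width, cfg.mlp_hidden, env.n_actions, rng
        )
    else:
        raise ValueError(f"unknown policy kind {policy_kind!r}")
    baseline = estimators.BaselineState(ema_decay=cfg.ema_decay)
    total = cfg.anneal_over * 2 if cfg.anneal_over else cfg.episodes
    schedule = estimators.EntropySchedule(max(cfg.lambda0, 1e-30), total)
    returns = np.zeros(cfg.episodes)
    for ep in range(cfg.episodes):
        traj = run_episode(policy, env, rng, cfg.resample_per_step)
        traj = returns_and_advantages(traj, cfg.discount, 0.0, clip=(-np.inf, np.inf))
        returns[ep] = traj.total_reward
        F = traj.returns[0]
        if policy_kind == "lpbn":
            _update_lpbn(policy, traj, cfg, baseline)
            lam = estimators.anneal(schedule, ep) if cfg.lambda0 > 0 else 0.0
            _entropy_step(policy.policy, lam, cfg.lr_logits)
        else:
            _update_mlp(policy, traj, cfg, baseline)
        baseline = estimators.ema_update(baseline, F)
        if not np.isfinite(F):
            raise FloatingPointError(f"training diverged at episode {ep}")
    return policy, returns, moving_average(returns, 100)
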