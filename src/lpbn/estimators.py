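"""Score-function gradient machinery for discrete selector policies.

The structural logits of an LPBN cannot be trained by backpropagation, so
all structure learning runs through the log-derivative (REINFORCE) identity

    ∇_θ E[F] = E[(F − b) ∇_θ log π_θ(S)],

where F is the scalar feedback (negative loss for supervised training,
return for RL) and b any baseline independent of the sampled structure S.
This module provides the raw estimator, the EMA and variance-optimal
constant baselines, entropy regularization with linear annealing, an exact
Rao-Blackwellized per-unit estimator, the Gumbel-Softmax relaxed sampler,
a straight-through surrogate, and advantage/gradient clipping.

Sign convention: all gradients returned here are ascent directions on E[F].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lpbn.core import SelectorPolicy, StructureSample, selector_probs

__all__ = [
    "BaselineState",
    "EntropySchedule",
    "GradEstimate",
    "score_function_grad",
    "batch_score_function_grad",
    "ema_update",
    "optimal_constant_baseline",
    "entropy",
    "entropy_grad",
    "anneal",
    "gumbel_softmax_sample",
    "rao_blackwell_grad",
    "straight_through_grad",
    "clip_values",
    "clip_grad_norm",
]


@dataclass
class BaselineState:
    """Running EMA baseline b ← decay·b + (1−decay)·F.

    The first observed feedback initializes b directly, avoiding the
    transient bias of starting from zero.
    """

    b: float = 0.0
    ema_decay: float = 0.95
    initialized: bool = False

    def __post_init__(self):
        if not (0.9 <= self.ema_decay <= 0.99):
            raise ValueError("ema_decay must lie in [0.9, 0.99]")


def ema_update(state: BaselineState, F: float) -> BaselineState:
    """Return the updated baseline state after observing feedback F."""
    if not np.isfinite(F):
        raise ValueError("feedback must be finite")
    if not state.initialized:
        return BaselineState(float(F), state.ema_decay, True)
    b = state.ema_decay * state.b + (1.0 - state.ema_decay) * F
    return BaselineState(float(b), state.ema_decay, True)


@dataclass
class EntropySchedule:
    """Entropy-bonus weight λ(t), linearly annealed to 0 at half budget."""

    lambda0: float
    total_steps: int

    def __post_init__(self):
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be nonnegative")
        if self.total_steps <= 0:
            raise ValueError("total_steps must be positive")


def anneal(schedule: EntropySchedule, t: int) -> float:
    """λ_t = λ0 · max(0, 1 − 2t/total_steps)."""
    return schedule.lambda0 * max(0.0, 1.0 - 2.0 * t / schedule.total_steps)


@dataclass
class GradEstimate:
    """Per-logit gradients aligned with a SelectorPolicy, plus diagnostics."""

    a: np.ndarray
    b: np.ndarray
    o: np.ndarray
    advantage: float = 0.0

    def norm(self) -> float:
        return float(
            np.sqrt(
                (self.a**2).sum() + (self.b**2).sum() + (self.o**2).sum()
            )
        )

    def flat(self) -> np.ndarray:
        return np.concatenate([self.a.ravel(), self.b.ravel(), self.o.ravel()])

    def __add__(self, other: "GradEstimate") -> "GradEstimate":
        return GradEstimate(
            self.a + other.a, self.b + other.b, self.o + other.o, self.advantage
        )

    def scaled(self, c: float) -> "GradEstimate":
        return GradEstimate(self.a * c, self.b * c, self.o * c, self.advantage)


def _slot_grad(logits: np.ndarray, chosen: np.ndarray, weight) -> np.ndarray:
    """(F−b)·(1{chosen=i} − π(i)) for one slot; supports batched samples."""
    probs = selector_probs(logits)
    if chosen.ndim == 1:  # single sample: (N,)
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(chosen)), chosen] = 1.0
        return weight * (onehot - probs)
    # batched: chosen (batch, N), weight (batch,)
    batch, N = chosen.shape
    grad = np.zeros_like(probs)
    w = np.asarray(weight, dtype=float)
    units = np.tile(np.arange(N), batch)
    np.add.at(grad, (units, chosen.ravel()), np.repeat(w, N))
    grad -= w.sum() * probs
    return grad / batch


def score_function_grad(
    policy: SelectorPolicy,
    sample: StructureSample,
    F: float,
    baseline: float = 0.0,
) -> GradEstimate:
    """Single-sample REINFORCE gradient of E[F] w.r.t. selector logits.

    Each logit entry receives (F − b)·(1{chosen = i} − π(i)).
    """
    if not np.isfinite(F):
        raise ValueError("feedback must be finite")
    w = float(F) - float(baseline)
    return GradEstimate(
        _slot_grad(policy.a_logits, sample.A, w),
        _slot_grad(policy.b_logits, sample.B, w),
        _slot_grad(policy.o_logits, sample.O, w),
        advantage=w,
    )


def batch_score_function_grad(
    policy: SelectorPolicy,
    samples: StructureSample,
    F: np.ndarray,
    baseline: float = 0.0,
) -> GradEstimate:
    """Mini-batch REINFORCE: per-example samples and weights, averaged.

    ``samples`` carries (batch, N) index arrays; ``F`` is the per-example
    feedback vector.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("feedback must be finite")
    w = F - float(baseline)
    return GradEstimate(
        _slot_grad(policy.a_logits, samples.A, w),
        _slot_grad(policy.b_logits, samples.B, w),
        _slot_grad(policy.o_logits, samples.O, w),
        advantage=float(w.mean()),
    )


def optimal_constant_baseline(F_samples, score_norms_sq) -> float:
    """Variance-minimizing constant baseline b* = Σ F‖Z‖² / Σ ‖Z‖².

    ``score_norms_sq`` are the squared L2 norms of the score vectors
    ∇_θ log π_θ(S) paired with each feedback sample.
    """
    F = np.asarray(F_samples, dtype=float)
    s = np.asarray(score_norms_sq, dtype=float)
    if F.shape != s.shape or F.size == 0:
        raise ValueError("need nonempty paired lists of equal length")
    total = s.sum()
    if total <= 0:
        raise ValueError("all score norms are zero; b* undefined")
    return float((F * s).sum() / total)


def entropy(probs: np.ndarray) -> float:
    """Natural-log entropy of a probability vector, with 0·log 0 := 0."""
    p = np.asarray(probs, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def entropy_grad(logits: np.ndarray) -> np.ndarray:
    """Exact ∇_logits H(softmax(logits)).

    With p = softmax(θ) and H = −Σ p log p, the gradient is
    ∂H/∂θ_i = −p_i (log p_i + H)  (since Σ_j p_j log p_j = −H).
    Works on the last axis of any shape.
    """
    p = selector_probs(logits)
    logp = np.log(np.maximum(p, 1e-300))
    H = -(p * logp).sum(axis=-1, keepdims=True)
    return -p * (logp + H)


def gumbel_softmax_sample(
    logits: np.ndarray, tau: float, noise: np.ndarray
) -> np.ndarray:
    """Relaxed categorical sample softmax((logits + noise)/tau).

    ``noise`` is standard Gumbel; reusing the same noise across the hard
    (argmax) and relaxed paths gives common random numbers, maximizing the
    correlation between the surrogate and the true discrete objective.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    logits = np.asarray(logits, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != logits.shape:
        raise ValueError("noise shape must match logits")
    return selector_probs((logits + noise) / tau)


def rao_blackwell_grad(
    policy: SelectorPolicy,
    unit: int,
    conditional_F: dict,
    baseline: float = 0.0,
) -> GradEstimate:
    """Exact Rao-Blackwellized gradient slice for one unit.

    ``conditional_F`` maps slot names 'a', 'b', 'o' to tables of
    E[F | slot choice] over that unit's choices (lengths m, m, |O|).  The
    unit's own choice is integrated out analytically:

        grad_i = Σ_j π(j)(F̃_j − b)(1{j=i} − π(i))
               = π(i)·(F̃_i − Σ_j π(j) F̃_j),

    so the baseline cancels exactly and the estimate is the true per-slot
    gradient given the conditional tables — the Rao-Blackwell reduction of
    the raw estimator, with provably no larger variance (law of total
    variance).  Entries for other units are zero.
    """

    def slot(logits_row, table):
        table = np.asarray(table, dtype=float)
        if table.shape != logits_row.shape:
            raise ValueError("conditional table size mismatch")
        p = selector_probs(logits_row)
        centered = table - baseline
        return p * (centered - (p * centered).sum())

    ga = np.zeros_like(policy.a_logits)
    gb = np.zeros_like(policy.b_logits)
    go = np.zeros_like(policy.o_logits)
    ga[unit] = slot(policy.a_logits[unit], conditional_F["a"])
    gb[unit] = slot(policy.b_logits[unit], conditional_F["b"])
    go[unit] = slot(policy.o_logits[unit], conditional_F["o"])
    return GradEstimate(ga, gb, go)


def straight_through_grad(
    hard_output: int, soft_surrogate: float, upstream_grad: float
) -> float:
    """Straight-through backward rule: pass the upstream gradient through
    the hard threshold using the surrogate's (identity) derivative, clipped
    to [−1, 1]."""
    if not (0.0 < soft_surrogate < 1.0):
        raise ValueError("surrogate must lie strictly in (0, 1)")
    return float(np.clip(upstream_grad, -1.0, 1.0))


def clip_values(
    values: np.ndarray,
    advantage_range: tuple = (-5.0, 5.0),
    grad_norm_cap: float = None,
) -> np.ndarray:
    """Clip advantages elementwise and/or rescale a gradient's L2 norm.

    With ``advantage_range`` set, entries are clipped into the interval;
    with ``grad_norm_cap`` set, the whole vector is rescaled iff its L2 norm
    exceeds the cap.
    """
    out = np.asarray(values, dtype=float)
    if advantage_range is not None:
        out = np.clip(out, advantage_range[0], advantage_range[1])
    if grad_norm_cap is not None:
        out = clip_grad_norm(out, grad_norm_cap)
    return out


def clip_grad_norm(vec: np.ndarray, cap: float = 5.0) -> np.ndarray:
    """Rescale ``vec`` to L2 norm ``cap`` iff it exceeds the cap."""
    if cap <= 0:
        raise ValueError("norm cap must be positive")
    vec = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(vec)
    if norm > cap:
        return vec * (cap / norm)
    return vec
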