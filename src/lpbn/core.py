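"""Stochastic logical units: the core LPBN model objects.

An LPBN with ``N`` units operates on a Boolean substrate ``z ∈ {0,1}^m``.
Unit ``n`` holds three categorical distributions — over its first input
position, its second input position, and a 2-input Boolean operator — whose
logits are the trainable structural parameters.  A sampled structure turns
each unit into a concrete gate ``h_n = g_{O_n}(z_{A_n}, z_{B_n})``; the bit
vector ``h`` feeds a simple differentiable head (logistic, linear, softmax
or policy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OperatorSet",
    "SelectorPolicy",
    "StructureSample",
    "Head",
    "LPBNModel",
    "Circuit",
    "apply_operator",
    "selector_probs",
    "sample_structure",
    "sample_structures_batch",
    "map_structure",
    "structure_log_prob",
    "forward",
    "head_forward",
    "param_count",
    "match_mlp_width",
    "compile_indicator",
    "DEFAULT_OPERATORS",
]

_TRUTH = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
    "NAND": lambda a, b: 1 - (a & b),
}


@dataclass(frozen=True)
class OperatorSet:
    """Ordered set of 2-input Boolean operator labels."""

    labels: tuple = ("AND", "OR", "XOR", "NAND")

    def __post_init__(self):
        if len(self.labels) == 0:
            raise ValueError("operator set must be nonempty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("operator labels must be unique")
        for lab in self.labels:
            if lab not in _TRUTH:
                raise ValueError(f"unknown operator label {lab!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_OPERATORS = OperatorSet()


def apply_operator(op: str, a, b):
    """Evaluate a 2-input Boolean operator on bits (scalars or uint8 arrays)."""
    if op not in _TRUTH:
        raise ValueError(f"unknown operator label {op!r}")
    return _TRUTH[op](a, b)


@dataclass
class SelectorPolicy:
    """Per-unit logit triplets defining categorical structure distributions.

    ``a_logits`` and ``b_logits`` have shape (N, m) — one categorical over
    substrate positions per input slot per unit; ``o_logits`` has shape
    (N, |O|).
    """

    a_logits: np.ndarray
    b_logits: np.ndarray
    o_logits: np.ndarray

    def __post_init__(self):
        self.a_logits = np.asarray(self.a_logits, dtype=float)
        self.b_logits = np.asarray(self.b_logits, dtype=float)
        self.o_logits = np.asarray(self.o_logits, dtype=float)
        if not (
            np.all(np.isfinite(self.a_logits))
            and np.all(np.isfinite(self.b_logits))
            and np.all(np.isfinite(self.o_logits))
        ):
            raise ValueError("selector logits must be finite")
        if self.a_logits.shape != self.b_logits.shape:
            raise ValueError("a_logits and b_logits shapes differ")
        if self.a_logits.shape[0] != self.o_logits.shape[0]:
            raise ValueError("unit counts differ between input and operator logits")

    @property
    def N(self) -> int:
        return self.a_logits.shape[0]

    @property
    def m(self) -> int:
        return self.a_logits.shape[1]

    @property
    def n_ops(self) -> int:
        return self.o_logits.shape[1]

    @classmethod
    def uniform(cls, N: int, m: int, n_ops: int = 4) -> "SelectorPolicy":
        return cls(np.zeros((N, m)), np.zeros((N, m)), np.zeros((N, n_ops)))

    def copy(self) -> "SelectorPolicy":
        return SelectorPolicy(
            self.a_logits.copy(), self.b_logits.copy(), self.o_logits.copy()
        )


@dataclass
class StructureSample:
    """Concrete wiring: per-unit (A, B, O) index triples."""

    A: np.ndarray
    B: np.ndarray
    O: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.int64)
        self.B = np.asarray(self.B, dtype=np.int64)
        self.O = np.asarray(self.O, dtype=np.int64)

    @property
    def N(self) -> int:
        return self.A.shape[-1]


@dataclass
class Head:
    """Differentiable readout on the unit outputs h.

    variant: 'logistic' (binary classification), 'linear' (regression),
    'softmax' (multiclass) or 'policy' (action logits).  ``weights`` has
    shape (N,) for scalar heads, (C, N) otherwise; ``bias`` is a scalar or
    a (C,) vector accordingly.
    """

    variant: str
    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        if self.variant not in ("logistic", "linear", "softmax", "policy"):
            raise ValueError(f"unknown head variant {self.variant!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)

    @classmethod
    def zeros(cls, variant: str, N: int, n_out: int = 1) -> "Head":
        if variant in ("logistic", "linear"):
            return cls(variant, np.zeros(N), np.zeros(()))
        return cls(variant, np.zeros((n_out, N)), np.zeros(n_out))

    @property
    def n_params(self) -> int:
        return self.weights.size + self.bias.size


@dataclass
class LPBNModel:
    """A selector policy plus operator set, head and (optional) binarizer."""

    policy: SelectorPolicy
    operators: OperatorSet
    head: Head
    scheme: object = None  # BinarizationScheme or None for pre-binary inputs

    def __post_init__(self):
        if self.scheme is not None and self.policy.m != self.scheme.m:
            raise ValueError("policy logit length must equal substrate width")
        n_in = (
            self.head.weights.shape[0]
            if self.head.weights.ndim == 1
            else self.head.weights.shape[1]
        )
        if self.policy.N != n_in:
            raise ValueError("head input arity must equal unit count")

    def to_json(self) -> str:
        obj = {
            "a_logits": self.policy.a_logits.tolist(),
            "b_logits": self.policy.b_logits.tolist(),
            "o_logits": self.policy.o_logits.tolist(),
            "operators": list(self.operators.labels),
            "head_variant": self.head.variant,
            "head_weights": self.head.weights.tolist(),
            "head_bias": np.asarray(self.head.bias).tolist(),
            "scheme": json.loads(self.scheme.to_json()) if self.scheme else None,
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "LPBNModel":
        from lpbn.binarize import BinarizationScheme

        obj = json.loads(text)
        policy = SelectorPolicy(
            np.asarray(obj["a_logits"]),
            np.asarray(obj["b_logits"]),
            np.asarray(obj["o_logits"]),
        )
        head = Head(
            obj["head_variant"],
            np.asarray(obj["head_weights"]),
            np.asarray(obj["head_bias"]),
        )
        scheme = (
            BinarizationScheme.from_json(json.dumps(obj["scheme"]))
            if obj["scheme"]
            else None
        )
        return cls(policy, OperatorSet(tuple(obj["operators"])), head, scheme)


def selector_probs(logits: np.ndarray) -> np.ndarray:
    """Softmax with max-subtraction; works on the last axis of any shape."""
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _categorical(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draws via the Gumbel-Max trick (exact)."""
    g = rng.gumbel(size=logits.shape)
    return np.argmax(logits + g, axis=-1)


def sample_structure(
    policy: SelectorPolicy, rng: np.random.Generator
) -> StructureSample:
    """Draw one structure: independent categorical draws per unit and slot."""
    return StructureSample(
        _categorical(policy.a_logits, rng),
        _categorical(policy.b_logits, rng),
        _categorical(policy.o_logits, rng),
    )


def sample_structures_batch(
    policy: SelectorPolicy, batch: int, rng: np.random.Generator
) -> StructureSample:
    """Draw ``batch`` i.i.d. structures; index arrays get shape (batch, N)."""
    shape_a = (batch,) + policy.a_logits.shape
    A = np.argmax(policy.a_logits[None] + rng.gumbel(size=shape_a), axis=-1)
    B = np.argmax(policy.b_logits[None] + rng.gumbel(size=shape_a), axis=-1)
    O = np.argmax(
        policy.o_logits[None] + rng.gumbel(size=(batch,) + policy.o_logits.shape),
        axis=-1,
    )
    return StructureSample(A, B, O)


def map_structure(policy: SelectorPolicy) -> StructureSample:
    """Per-slot argmax of logits (ties broken toward the lowest index)."""
    return StructureSample(
        np.argmax(policy.a_logits, axis=-1),
        np.argmax(policy.b_logits, axis=-1),
        np.argmax(policy.o_logits, axis=-1),
    )


def structure_log_prob(policy: SelectorPolicy, sample: StructureSample) -> float:
    """log π_θ(S) = Σ_n log π_n^A(A_n) + log π_n^B(B_n) + log π_n^O(O_n)."""
    with np.errstate(divide="ignore"):  # unchosen zero-prob entries may be -inf
        la = np.log(selector_probs(policy.a_logits))
        lb = np.log(selector_probs(policy.b_logits))
        lo = np.log(selector_probs(policy.o_logits))
    idx = np.arange(policy.N)
    return float(
        la[idx, sample.A].sum() + lb[idx, sample.B].sum() + lo[idx, sample.O].sum()
    )


def forward(
    structure: StructureSample,
    z: np.ndarray,
    operators: OperatorSet = DEFAULT_OPERATORS,
) -> np.ndarray:
    """Deterministic Boolean pass: h_n = g_{O_n}(z_{A_n}, z_{B_n}).

    ``z`` may be a single substrate vector (m,) or a batch (n, m).  When the
    structure carries per-example indices of shape (n, N), each row of ``z``
    is evaluated under its own wiring.
    """
    z = np.asarray(z, dtype=np.uint8)
    single = z.ndim == 1
    Z = z[None, :] if single else z
    A, B, O = structure.A, structure.B, structure.O
    if A.ndim == 1:
        za = Z[:, A]
        zb = Z[:, B]
        ops = O[None, :]
    else:
        rows = np.arange(Z.shape[0])[:, None]
        za = Z[rows, A]
        zb = Z[rows, B]
        ops = O
    h = np.empty(za.shape, dtype=np.uint8)
    for k, lab in enumerate(operators.labels):
        mask = ops == k
        if np.any(mask):
            vals = _TRUTH[lab](za, zb)
            h = np.where(mask, vals, h)
    return h[0] if single else h


def head_forward(head: Head, h: np.ndarray) -> np.ndarray:
    """Map unit outputs to predictions.

    logistic -> probability in (0,1); linear -> real; softmax/policy ->
    probability vector.  ``h`` may be (N,) or (n, N).
    """
    h = np.asarray(h, dtype=float)
    if head.variant in ("logistic", "linear"):
        score = h @ head.weights + head.bias
        if head.variant == "linear":
            return score
        return 1.0 / (1.0 + np.exp(-score))
    logits = h @ head.weights.T + head.bias
    return selector_probs(logits)


def param_count(model: LPBNModel) -> int:
    """Trainable parameters: N·(2m + |O|) selector logits + head weights."""
    p = model.policy
    return p.N * (2 * p.m + p.n_ops) + model.head.n_params


def _mlp_param_count(H: int, d_in: int, d_out: int) -> int:
    return (d_in + 1) * H + (H + 1) * d_out


def match_mlp_width(lpbn_params: int, d_in: int, d_out: int) -> int:
    """Hidden width H of a 1-hidden-layer MLP parameter-matched within ±10%.

    Returns the H whose parameter count (d_in+1)·H + (H+1)·d_out is closest
    to ``lpbn_params`` (ties toward the smaller H); raises if no width lands
    within the ±10% band.
    """
    per_unit = d_in + 1 + d_out
    h_star = max(1, round((lpbn_params - d_out) / per_unit))
    best, best_gap = None, None
    for H in range(max(1, h_star - 3), h_star + 4):
        gap = abs(_mlp_param_count(H, d_in, d_out) - lpbn_params)
        if best_gap is None or gap < best_gap:
            best, best_gap = H, gap
    if best_gap / lpbn_params > 0.10:
        raise ValueError(
            f"no MLP width within 10% of {lpbn_params} params "
            f"(closest H={best}, gap {best_gap})"
        )
    return best


@dataclass
class Circuit:
    """A feed-forward gate list over an input space of width d.

    Gate ``k`` reads wire indices ``(a, b)`` — wires ``0..d-1`` are the
    inputs, wire ``d+j`` is the output of gate ``j`` — and applies ``op``.
    The circuit's output is the last gate's output.  Used by the NAND
    compilation constructions; trained LPBNs remain single-layer.
    """

    d: int
    gates: list = field(default_factory=list)  # (a, b, op_label)

    def add(self, a: int, b: int, op: str) -> int:
        """Append a gate; returns its wire index."""
        self.gates.append((a, b, op))
        return self.d + len(self.gates) - 1

    def evaluate(self, z: np.ndarray) -> int:
        """Output bit for input z (length d)."""
        wires = list(np.asarray(z, dtype=np.uint8))
        for a, b, op in self.gates:
            wires.append(apply_operator(op, wires[a], wires[b]))
        return int(wires[-1])


def compile_indicator(pattern: Sequence[int]) -> Circuit:
    """Build a NAND circuit computing 1{z == pattern}.

    Literals are formed as the input bit itself (pattern bit 1) or its
    negation NAND(x, x) (pattern bit 0); the conjunction of the d literals is
    a binary tree of NAND pairs, since AND(a, b) = NAND(NAND(a,b), NAND(a,b)).
    Together with a linear readout this realizes any map on a finite subset
    of {0,1}^d — the universal-approximation construction over discretized
    inputs.
    """
    pattern = list(pattern)
    d = len(pattern)
    if d < 1:
        raise ValueError("pattern must have at least one bit")
    circ = Circuit(d)
    literals = []
    for j, bit in enumerate(pattern):
        if bit:
            literals.append(j)
        else:
            literals.append(circ.add(j, j, "NAND"))
    # Reduce literals pairwise with NAND-built ANDs.
    while len(literals) > 1:
        nxt = []
        for i in range(0, len(literals) - 1, 2):
            nand = circ.add(literals[i], literals[i + 1], "NAND")
            nxt.append(circ.add(nand, nand, "NAND"))
        if len(literals) % 2:
            nxt.append(literals[-1])
        literals = nxt
    if literals[0] < d:
        # Single positive literal: pass through an AND built from NANDs so
        # the circuit always has at least one gate.
        nand = circ.add(literals[0], literals[0], "NAND")
        circ.add(nand, nand, "NAND")
    elif literals[0] != d + len(circ.gates) - 1:
        # Last literal of an odd reduction may not be the final gate; buffer.
        nand = circ.add(literals[0], literals[0], "NAND")
        circ.add(nand, nand, "NAND")
    return circ
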