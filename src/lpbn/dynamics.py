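"""Boolean networks as Markov chains: attractors and stationary behavior.

A deterministic synchronous Boolean network over n genes defines a map on
the 2^n state space.  Flipping each bit independently with probability p
after every update turns it into an ergodic finite Markov chain (a PBN in
the perturbation sense) with a closed-form transition kernel

    P(x -> y) = p^H (1-p)^(n-H),   H = Hamming(f(x), y),

a unique stationary distribution, and stationary mass concentrating on
attractor basins as p -> 0.  This module parses plain-text rule files,
enumerates attractors exhaustively, builds and solves the perturbed chain,
simulates trajectories, and fits a per-gene LPBN to observed one-step
transitions (cross-entropy against empirical frequencies).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from lpbn import core
from lpbn.core import LPBNModel

__all__ = [
    "BooleanNetwork",
    "PerturbedChain",
    "AttractorSet",
    "Attractor",
    "ChainSummary",
    "parse_network",
    "synchronous_step",
    "successor_table",
    "enumerate_attractors",
    "transition_matrix",
    "stationary_distribution",
    "kl_divergence",
    "simulate_trajectory",
    "fit_transition_lpbn",
    "lpbn_to_network",
]


# ---------------------------------------------------------------------------
# Rule-file parsing: NAME = <expr> with AND/OR/NOT/XOR/NAND and parentheses;
# NAME := 0|1 freezes a gene.  Precedence: NOT > AND = NAND > XOR > OR.
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_]*|[01])")
_KEYWORDS = {"AND", "OR", "NOT", "XOR", "NAND"}


def _tokenize(expr: str, lineno: int):
    out, pos = [], 0
    while pos < len(expr):
        mobj = _TOKEN_RE.match(expr, pos)
        if not mobj:
            raise ValueError(f"line {lineno}: cannot parse near {expr[pos:]!r}")
        out.append(mobj.group(1))
        pos = mobj.end()
    return out


class _Parser:
    def __init__(self, tokens, lineno):
        self.toks = tokens
        self.i = 0
        self.lineno = lineno

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else None

    def pop(self):
        tok = self.peek()
        if tok is None:
            raise ValueError(f"line {self.lineno}: unexpected end of expression")
        self.i += 1
        return tok

    def parse(self):
        node = self.expr_or()
        if self.peek() is not None:
            raise ValueError(
                f"line {self.lineno}: trailing tokens {self.toks[self.i:]!r}"
            )
        return node

    def expr_or(self):
        node = self.expr_xor()
        while self.peek() == "OR":
            self.pop()
            node = ("or", node, self.expr_xor())
        return node

    def expr_xor(self):
        node = self.expr_and()
        while self.peek() == "XOR":
            self.pop()
            node = ("xor", node, self.expr_and())
        return node

    def expr_and(self):
        node = self.expr_not()
        while self.peek() in ("AND", "NAND"):
            op = self.pop()
            node = (op.lower(), node, self.expr_not())
        return node

    def expr_not(self):
        if self.peek() == "NOT":
            self.pop()
            return ("not", self.expr_not())
        return self.atom()

    def atom(self):
        tok = self.pop()
        if tok == "(":
            node = self.expr_or()
            if self.pop() != ")":
                raise ValueError(f"line {self.lineno}: unbalanced parentheses")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in _KEYWORDS or tok == ")":
            raise ValueError(f"line {self.lineno}: unexpected token {tok!r}")
        return ("var", tok)


def _ast_vars(node, acc):
    kind = node[0]
    if kind == "var":
        acc.add(node[1])
    elif kind == "not":
        _ast_vars(node[1], acc)
    elif kind in ("and", "or", "xor", "nand"):
        _ast_vars(node[1], acc)
        _ast_vars(node[2], acc)
    return acc


def _eval_ast(node, states, index):
    """Evaluate an AST on a (k, n) uint8 state matrix -> (k,) uint8."""
    kind = node[0]
    if kind == "var":
        return states[:, index[node[1]]]
    if kind == "const":
        return np.full(states.shape[0], node[1], dtype=np.uint8)
    if kind == "not":
        return 1 - _eval_ast(node[1], states, index)
    a = _eval_ast(node[1], states, index)
    b = _eval_ast(node[2], states, index)
    if kind == "and":
        return a & b
    if kind == "or":
        return a | b
    if kind == "xor":
        return a ^ b
    return 1 - (a & b)  # nand


@dataclass
class BooleanNetwork:
    """Ordered genes with synchronous per-gene update functions.

    ``asts`` maps gene name to an expression AST, or to ("const", v) for
    frozen genes.  Updates are simultaneous: every gene reads the current
    full state.
    """

    genes: list
    asts: dict
    frozen: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.genes)

    def step_batch(self, states: np.ndarray) -> np.ndarray:
        """Synchronous update of a (k, n) batch of states."""
        states = np.asarray(states, dtype=np.uint8)
        index = {g: i for i, g in enumerate(self.genes)}
        return np.column_stack(
            [_eval_ast(self.asts[g], states, index) for g in self.genes]
        )


def parse_network(rule_text: str) -> BooleanNetwork:
    """Parse a rule file: one `NAME = expr` (or `NAME := 0|1`) per line.

    Comment lines start with '#'; blank lines are skipped.  Every variable
    referenced must itself be a declared gene (cyclic references are fine —
    they resolve through the synchronous state).
    """
    genes, asts, frozen = [], {}, {}
    for lineno, raw in enumerate(str(rule_text).splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":=" in line:
            name, _, val = line.partition(":=")
            name, val = name.strip(), val.strip()
            if val not in ("0", "1"):
                raise ValueError(f"line {lineno}: frozen value must be 0 or 1")
            if name in asts:
                raise ValueError(f"line {lineno}: duplicate gene {name!r}")
            genes.append(name)
            asts[name] = ("const", int(val))
            frozen[name] = int(val)
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected NAME = <expr>")
        name, _, expr = line.partition("=")
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
            raise ValueError(f"line {lineno}: bad gene name {name!r}")
        if name in asts:
            raise ValueError(f"line {lineno}: duplicate gene {name!r}")
        ast = _Parser(_tokenize(expr, lineno), lineno).parse()
        genes.append(name)
        asts[name] = ast
    known = set(genes)
    for g in genes:
        unknown = _ast_vars(asts[g], set()) - known
        if unknown:
            raise ValueError(f"rule for {g!r} references unknown genes {unknown}")
    if not genes:
        raise ValueError("empty rule file")
    return BooleanNetwork(genes, asts, frozen)


def synchronous_step(net: BooleanNetwork, state: np.ndarray) -> np.ndarray:
    """One synchronous update of a single state vector (length n)."""
    state = np.asarray(state, dtype=np.uint8)
    if state.shape != (net.n,):
        raise ValueError(f"state must have length {net.n}")
    return net.step_batch(state[None, :])[0]


def _all_states(n: int) -> np.ndarray:
    """(2^n, n) matrix of all states; gene i is bit i of the state index."""
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(np.uint8)


def _pack(bits: np.ndarray) -> np.ndarray:
    n = bits.shape[-1]
    return (bits.astype(np.int64) << np.arange(n)).sum(axis=-1)


def successor_table(net: BooleanNetwork) -> np.ndarray:
    """succ[x] = packed index of the synchronous successor of state x."""
    if net.n > 20:
        raise ValueError(
            "exhaustive state-space construction is limited to n <= 20 genes; "
            "use simulate_trajectory for larger networks"
        )
    return _pack(net.step_batch(_all_states(net.n)))


@dataclass
class Attractor:
    """An ordered cycle of packed states (length 1 = fixed point)."""

    states: tuple
    basin: int = 0

    def __len__(self):
        return len(self.states)


@dataclass
class AttractorSet:
    n: int
    attractors: list

    def fixed_points(self):
        return [a for a in self.attractors if len(a) == 1]

    def cycles(self):
        return [a for a in self.attractors if len(a) > 1]

    def state_bits(self, packed: int) -> np.ndarray:
        return ((packed >> np.arange(self.n)) & 1).astype(np.uint8)


def enumerate_attractors(net: BooleanNetwork) -> AttractorSet:
    """Exhaustively iterate every state to its cycle (n <= 20).

    Cycles are canonicalized to start at their minimal state; basins count
    every state (including the attractor states themselves) that flows into
    each attractor.
    """
    succ = successor_table(net)
    n_states = len(succ)
    # color: 0 unvisited, 1 in progress, 2 done; attr_of[x] = attractor id
    attr_of = np.full(n_states, -1, dtype=np.int64)
    attractors = []
    for start in range(n_states):
        if attr_of[start] >= 0:
            continue
        path = []
        on_path = {}
        x = start
        while attr_of[x] < 0 and x not in on_path:
            on_path[x] = len(path)
            path.append(x)
            x = succ[x]
        if attr_of[x] >= 0:
            aid = attr_of[x]
        else:
            # new cycle discovered on this path
            cyc = path[on_path[x] :]
            k = int(np.argmin(cyc))
            cyc = tuple(cyc[k:] + cyc[:k])
            aid = len(attractors)
            attractors.append(Attractor(states=cyc))
        for s in path:
            attr_of[s] = aid
    for aid, att in enumerate(attractors):
        att.basin = int((attr_of == aid).sum())
    return AttractorSet(net.n, attractors)


@dataclass
class PerturbedChain:
    """A Boolean network with independent per-bit flips after each update."""

    network: BooleanNetwork
    p: float

    def __post_init__(self):
        if not (0.0 <= self.p < 0.5):
            raise ValueError("flip probability must lie in [0, 0.5)")


@dataclass
class ChainSummary:
    P: np.ndarray
    mu: np.ndarray = None
    attractor_mass: list = None


def transition_matrix(chain: PerturbedChain) -> ChainSummary:
    """Dense 2^n x 2^n kernel P(x->y) = p^H (1-p)^(n-H) (n <= 12)."""
    n = chain.network.n
    if n > 12:
        raise ValueError("dense transition matrices are limited to n <= 12")
    succ = successor_table(chain.network)
    idx = np.arange(2**n, dtype=np.int64)
    ham = np.bitwise_count(np.bitwise_xor(succ[:, None], idx[None, :]))
    if chain.p == 0.0:
        P = (ham == 0).astype(float)
    else:
        P = (chain.p**ham) * ((1.0 - chain.p) ** (n - ham))
    return ChainSummary(P=P)


def stationary_distribution(
    P: np.ndarray, tol: float = 1e-12, max_doublings: int = 60
) -> np.ndarray:
    """Stationary distribution by squaring-accelerated power iteration.

    Repeatedly squares the (row-stochastic) kernel — equivalent to power
    iteration over 2^k steps — until all rows agree to l1 tolerance, then
    returns the common row.  Raises for chains that do not mix (reducible
    or periodic, e.g. p = 0), which is reported rather than silently
    returning one of many stationary vectors.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P rows must sum to 1")
    Q = P.copy()
    for _ in range(max_doublings):
        spread = np.abs(Q - Q[0]).sum(axis=1).max()
        if spread < tol:
            mu = Q.mean(axis=0)
            mu = np.maximum(mu, 0.0)
            mu /= mu.sum()
            if np.abs(mu @ P - mu).sum() > 1e-10:
                break
            return mu
        Q = Q @ Q
        Q /= Q.sum(axis=1, keepdims=True)
    raise ValueError(
        "power iteration did not converge to a unique stationary distribution "
        "(chain may be reducible or periodic; need p > 0)"
    )


def kl_divergence(mu: np.ndarray, nu: np.ndarray, floor: float = 1e-12) -> float:
    """KL(mu || nu) in nats, with nu floored at 1e-12 and renormalized."""
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if mu.shape != nu.shape:
        raise ValueError("distributions must share a support size")
    mu = mu / mu.sum()
    nu = np.maximum(nu, floor)
    nu = nu / nu.sum()
    nz = mu > 0
    return float((mu[nz] * np.log(mu[nz] / nu[nz])).sum())


def simulate_trajectory(
    chain: PerturbedChain, T: int, rng: np.random.Generator, start: np.ndarray = None
) -> np.ndarray:
    """Simulate T steps: synchronous update, then independent bit flips.

    Returns a (T+1, n) bit matrix including the initial state (random if
    ``start`` is not given).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    n = chain.network.n
    out = np.empty((T + 1, n), dtype=np.uint8)
    if start is None:
        out[0] = rng.integers(0, 2, size=n, dtype=np.uint8)
    else:
        out[0] = np.asarray(start, dtype=np.uint8)
    flips = (
        (rng.random((T, n)) < chain.p).astype(np.uint8)
        if chain.p > 0
        else np.zeros((T, n), dtype=np.uint8)
    )
    if n <= 12:
        succ = successor_table(chain.network)
        fl = _pack(flips)
        x = int(_pack(out[0]))
        states = np.empty(T + 1, dtype=np.int64)
        states[0] = x
        for t in range(T):
            x = succ[x] ^ fl[t]
            states[t + 1] = x
        out = ((states[:, None] >> np.arange(n)[None, :]) & 1).astype(np.uint8)
    else:
        for t in range(T):
            out[t + 1] = chain.network.step_batch(out[t][None, :])[0] ^ flips[t]
    return out


def fit_transition_lpbn(
    trajectory: np.ndarray, config=None, gene_names: list = None
) -> list:
    """Fit one logistic-head LPBN per gene to observed one-step transitions.

    The substrate is the current state plus CONST0/CONST1.  Observed
    (state, next state) pairs are collapsed to unique states with empirical
    next-bit frequencies and visit counts; each gene's LPBN minimizes the
    count-weighted cross-entropy between its predicted transition
    probability and those frequencies — the same objective as per-sample
    cross-entropy over the raw trajectory, computed far faster.
    """
    from lpbn.supervised import TrainConfig, _fit_lpbn

    traj = np.asarray(trajectory, dtype=np.uint8)
    if traj.ndim != 2 or traj.shape[0] < 2:
        raise ValueError("trajectory must contain at least one transition")
    n = traj.shape[1]
    cur, nxt = traj[:-1], traj[1:]
    uniq, inv, counts = np.unique(
        cur, axis=0, return_inverse=True, return_counts=True
    )
    k = uniq.shape[0]
    freqs = np.zeros((k, n))
    np.add.at(freqs, inv, nxt.astype(float))
    freqs /= counts[:, None]

    Z = np.concatenate(
        [uniq, np.zeros((k, 1), np.uint8), np.ones((k, 1), np.uint8)], axis=1
    )
    if config is not None:
        cfg = config
    else:
        # default budget targets ~2400 selector updates regardless of how
        # few unique states the trajectory visited (count-weighted batches
        # carry less per-update signal than raw replicated samples would)
        n_batches = max(1, int(np.ceil(k / 64)))
        cfg = TrainConfig(
            N=16,
            epochs=max(300, int(np.ceil(2400 / n_batches))),
            batch_size=64,
            lambda0=1e-3,
        )
    models = []
    for g in range(n):
        rng = np.random.default_rng(cfg.seed + 7919 * (g + 1))
        policy, head, ops, _ = _fit_lpbn(
            Z, freqs[:, g], "logistic", cfg, rng, sample_weight=counts.astype(float)
        )
        models.append(LPBNModel(policy, ops, head, None))
    return models


def lpbn_to_network(models: list, gene_names: list = None) -> BooleanNetwork:
    """Freeze per-gene LPBNs into a deterministic Boolean network.

    Each gene's update is its model's MAP-structure Boolean function
    thresholded through the logistic head at 0.5, enabling attractor and
    stationary-distribution comparison against the source network.
    """
    n = len(models)
    genes = list(gene_names) if gene_names else [f"g{i}" for i in range(n)]

    fns = []
    for model in models:
        struct = core.map_structure(model.policy)
        fns.append((struct, model))

    class _LearnedNetwork(BooleanNetwork):
        def step_batch(self, states: np.ndarray) -> np.ndarray:
            states = np.asarray(states, dtype=np.uint8)
            k = states.shape[0]
            Z = np.concatenate(
                [states, np.zeros((k, 1), np.uint8), np.ones((k, 1), np.uint8)],
                axis=1,
            )
            cols = []
            for struct, model in fns:
                h = core.forward(struct, Z, model.operators)
                p = core.head_forward(model.head, h)
                cols.append((p >= 0.5).astype(np.uint8))
            return np.column_stack(cols)

    return _LearnedNetwork(genes, {g: ("learned",) for g in genes})
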