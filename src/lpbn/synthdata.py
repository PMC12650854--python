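"""Seeded synthetic benchmark generators.

Six task families cover the supervised, representation and control settings
used throughout the package: linear-score binary classification and
regression over standard-normal covariates, three 120-degree-separated
Gaussian blobs for clustering, templated negation sentences for text, the
LineWorld and CartPole environments (in :mod:`lpbn.rl`), and the 10-gene
mammalian cell-cycle Boolean network shipped as a plain-text rule file.

Every generator is a pure function of its spec: identical seeds give
bitwise-identical datasets, which is what makes seed-paired model
comparisons meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticSpec",
    "Dataset",
    "gen_classification",
    "gen_regression",
    "gen_blobs",
    "gen_text",
    "cellcycle_fixture",
    "text_vocabulary",
    "POSITIVE_WORDS",
    "NEGATIVE_WORDS",
    "INTENSIFIERS",
    "WEIGHT_SEED",
]

# The task-defining weight vector is drawn once from this documented seed so
# "the same synthetic task" is shareable across runs and models.
WEIGHT_SEED = 1150

POSITIVE_WORDS = (
    "good", "great", "excellent", "superb", "reliable", "fast", "sturdy", "elegant",
)
NEGATIVE_WORDS = (
    "bad", "awful", "terrible", "poor", "flimsy", "slow", "fragile", "clunky",
)
INTENSIFIERS = ("very", "really", "quite", "extremely")
_TEMPLATE = ("the", "product", "is")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic task draw.

    ``noise`` is the Gaussian noise scale sigma of the linear-score tasks
    (default 0.1) or the isotropic cluster spread for blobs; ``weight_seed``
    fixes the task (the weight vector / cluster means), ``seed`` the data.
    """

    task: str = "classification"
    n: int = 2000
    d: int = 8
    noise: float = 0.1
    weight_seed: int = WEIGHT_SEED
    seed: int = 0
    splits: tuple = (0.7, 0.1, 0.2)


@dataclass
class Dataset:
    """Features, targets, and disjoint-exhaustive split indices."""

    X: np.ndarray
    y: np.ndarray
    idx_train: np.ndarray
    idx_val: np.ndarray
    idx_test: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def X_train(self):
        return self.X[self.idx_train]

    @property
    def y_train(self):
        return self.y[self.idx_train]

    @property
    def X_val(self):
        return self.X[self.idx_val]

    @property
    def y_val(self):
        return self.y[self.idx_val]

    @property
    def X_test(self):
        return self.X[self.idx_test]

    @property
    def y_test(self):
        return self.y[self.idx_test]


def _split_indices(n: int, rng: np.random.Generator) -> tuple:
    """70/10/20 split: floor(0.7n) / floor(0.1n) / remainder, shuffled."""
    perm = rng.permutation(n)
    n_tr = int(np.floor(0.7 * n))
    n_va = int(np.floor(0.1 * n))
    return perm[:n_tr], perm[n_tr : n_tr + n_va], perm[n_tr + n_va :]


def _task_weights(d: int, weight_seed: int) -> np.ndarray:
    return np.random.default_rng(weight_seed).standard_normal(d)


def gen_classification(spec: SyntheticSpec) -> Dataset:
    """Linear-score labels: x ~ N(0, I_d), y = 1{w'x + eps >= 0}."""
    rng = np.random.default_rng(spec.seed)
    w = _task_weights(spec.d, spec.weight_seed)
    X = rng.standard_normal((spec.n, spec.d))
    eps = rng.normal(0.0, spec.noise, size=spec.n)
    y = (X @ w + eps >= 0).astype(np.int64)
    tr, va, te = _split_indices(spec.n, rng)
    return Dataset(X, y, tr, va, te, meta={"w": w, "sigma": spec.noise})


def gen_regression(spec: SyntheticSpec) -> Dataset:
    """Linear-Gaussian targets: t = w'x + eps, eps ~ N(0, sigma^2)."""
    rng = np.random.default_rng(spec.seed)
    w = _task_weights(spec.d, spec.weight_seed)
    X = rng.standard_normal((spec.n, spec.d))
    t = X @ w + rng.normal(0.0, spec.noise, size=spec.n)
    tr, va, te = _split_indices(spec.n, rng)
    return Dataset(X, t, tr, va, te, meta={"w": w, "sigma": spec.noise})


def gen_blobs(spec: SyntheticSpec = None) -> Dataset:
    """Three isotropic Gaussian clusters in R^4 with 120-degree means.

    The cluster means are unit vectors in a fixed 2-plane of R^4 at pairwise
    angles of exactly 120 degrees (pairwise cosine −1/2); ``spec.noise`` is
    the isotropic standard deviation (default 0.25, well-separated regime).
    True labels ride along in ``y`` for external evaluation only.
    """
    spec = spec or SyntheticSpec(task="blobs", d=4, noise=0.25)
    if spec.d != 4:
        raise ValueError("blobs task is defined in R^4")
    rng = np.random.default_rng(spec.seed)
    angles = 2.0 * np.pi * np.arange(3) / 3.0
    means = np.zeros((3, 4))
    means[:, 0] = np.cos(angles)
    means[:, 1] = np.sin(angles)
    labels = rng.integers(0, 3, size=spec.n)
    X = means[labels] + rng.normal(0.0, spec.noise, size=(spec.n, 4))
    tr, va, te = _split_indices(spec.n, rng)
    return Dataset(X, labels, tr, va, te, meta={"means": means})


def gen_text(spec: SyntheticSpec = None) -> tuple:
    """Templated negation sentences with XOR label structure.

    Sentences follow "the product is [not] [intensifier] word."; the label
    is the polarity of the final word XOR the presence of "not", so any
    model without interaction features is at chance.  Returns
    ``(sentences, labels, splits)`` where sentences are token tuples.
    """
    spec = spec or SyntheticSpec(task="text")
    rng = np.random.default_rng(spec.seed)
    sentences, labels = [], []
    for _ in range(spec.n):
        negated = rng.random() < 0.5
        positive = rng.random() < 0.5
        word = (
            POSITIVE_WORDS[rng.integers(len(POSITIVE_WORDS))]
            if positive
            else NEGATIVE_WORDS[rng.integers(len(NEGATIVE_WORDS))]
        )
        toks = list(_TEMPLATE)
        if negated:
            toks.append("not")
        if rng.random() < 0.5:
            toks.append(INTENSIFIERS[rng.integers(len(INTENSIFIERS))])
        toks.append(word)
        sentences.append(tuple(toks))
        labels.append(int(positive) ^ int(negated))
    splits = _split_indices(spec.n, rng)
    return sentences, np.asarray(labels, dtype=np.int64), splits


def text_vocabulary() -> tuple:
    """The closed vocabulary of the negation task, in a fixed order."""
    return tuple(_TEMPLATE) + ("not",) + INTENSIFIERS + POSITIVE_WORDS + NEGATIVE_WORDS


def cellcycle_fixture():
    """The 10-gene mammalian cell-cycle Boolean network.

    Loaded from the packaged plain-text rule file (see the file's header for
    provenance).  Synchronous update; CycD is a self-sustaining input.  The
    network has exactly one quiescent fixed point (Rb, p27, Cdh1 active) and
    one 7-state oscillatory cycle.
    """
    from lpbn.dynamics import parse_network

    path = Path(__file__).parent / "data" / "cellcycle.rules"
    if not path.exists():
        raise FileNotFoundError(f"cell-cycle rule fixture missing: {path}")
    return parse_network(path.read_text())
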