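"""Supervised training loops for LPBNs and parameter-matched MLP baselines.

One shared trainer drives classification (logistic head, cross-entropy),
regression (linear head, squared error) and reconstruction (linear decoder).
Continuous head parameters follow ordinary stochastic gradients; selector
logits follow the mini-batch REINFORCE estimator with an EMA baseline and
an annealed entropy bonus, using per-example structure samples and
per-example advantages.

Evaluation uses the MAP structure (deterministic wiring) by default, so the
reported test metrics are those of the decoded rule system rather than a
stochastic ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lpbn import binarize as _bin
from lpbn import core, estimators
from lpbn.core import Head, LPBNModel, OperatorSet, SelectorPolicy
from lpbn.synthdata import Dataset, text_vocabulary

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "MLPBaseline",
    "EmbeddingModel",
    "train_classifier",
    "train_regressor",
    "train_embedding",
    "train_mlp",
    "text_featurize",
    "evaluate_classifier",
    "evaluate_regressor",
]


@dataclass
class TrainConfig:
    """Hyperparameters for supervised LPBN training.

    Defaults follow the package's standard recipe: 50 epochs, batch 64,
    selector learning rate 7e-2, head learning rate 0.3 (midpoint of the
    [0.25, 0.35] range), EMA decay 0.95, entropy weight 1e-3 annealed to
    zero over the first half of training, B = 5 bins, N = 20 units.
    """

    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    lr_logits: float = 7e-2
    lr_head: float = 0.3
    estimator: str = "reinforce"  # or "gumbel" (relaxed surrogate ablation)
    ema_decay: float = 0.95
    lambda0: float = 1e-3
    B: int = 5
    N: int = 20
    const_bits: bool = False
    operators: tuple = ("AND", "OR", "XOR", "NAND")
    eval_structure: str = "map"  # or "sample"
    tau_start: float = 1.0
    tau_end: float = 0.3

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("budgets must be positive")


@dataclass
class TrainHistory:
    """Per-epoch traces; lengths equal the epoch budget (no early stop)."""

    loss: list = field(default_factory=list)
    selector_entropy: list = field(default_factory=list)
    baseline: list = field(default_factory=list)
    metric: list = field(default_factory=list)


@dataclass
class MLPBaseline:
    """1-hidden-layer tanh MLP trained with mini-batch SGD."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    task: str  # 'logistic' | 'linear' | 'decoder'

    @classmethod
    def init(cls, d_in: int, H: int, d_out: int, task: str, rng) -> "MLPBaseline":
        if H <= 0:
            raise ValueError("hidden width must be positive")
        s1 = 1.0 / np.sqrt(d_in)
        s2 = 1.0 / np.sqrt(H)
        return cls(
            rng.uniform(-s1, s1, size=(H, d_in)),
            np.zeros(H),
            rng.uniform(-s2, s2, size=(d_out, H)),
            np.zeros(d_out),
            task,
        )

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1.T + self.b1)

    def forward(self, X: np.ndarray) -> np.ndarray:
        out = self.hidden(X) @ self.W2.T + self.b2
        if self.task == "logistic":
            return 1.0 / (1.0 + np.exp(-out[:, 0]))
        if self.task == "linear":
            return out[:, 0]
        return out


@dataclass
class EmbeddingModel:
    """LPBN feature extractor plus the shallow linear decoder it was
    trained against (reconstruction objective)."""

    model: LPBNModel
    decoder_W: np.ndarray
    decoder_b: np.ndarray

    def embed(self, X: np.ndarray) -> np.ndarray:
        Z = _bin.transform(self.model.scheme, X)
        struct = core.map_structure(self.model.policy)
        return core.forward(struct, Z, self.model.operators).astype(float)


def _substrate(dataset: Dataset, cfg: TrainConfig):
    """Binarize a dataset, or pass binary features straight through."""
    if dataset.meta.get("binary"):
        Z = np.asarray(dataset.X, dtype=np.uint8)
        return None, Z
    scheme = _bin.fit_binarizer(dataset.X_train, B=cfg.B, const_bits=cfg.const_bits)
    return scheme, _bin.transform(scheme, dataset.X)


def _per_example_loss(head: Head, h: np.ndarray, y: np.ndarray) -> tuple:
    """Loss and d(loss)/d(score) per example for scalar heads."""
    score = h @ head.weights + head.bias
    if head.variant == "logistic":
        p = 1.0 / (1.0 + np.exp(-score))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        loss = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
        return loss, p - y
    # half-squared-error convention: gradient is the plain residual, which
    # keeps the stated head learning rate inside the stability region of
    # the 0/1 unit-feature Gram matrix
    loss = 0.5 * (score - y) ** 2
    return loss, score - y


def _fit_lpbn(
    Z: np.ndarray,
    y: np.ndarray,
    head_variant: str,
    cfg: TrainConfig,
    rng: np.random.Generator,
    sample_weight: np.ndarray = None,
    val: tuple = None,
    operators: OperatorSet = None,
):
    """Shared LPBN trainer for scalar heads (logistic / linear).

    ``y`` may be soft targets in [0,1] for the logistic head (cross-entropy
    against empirical transition frequencies).  ``sample_weight`` weights
    examples in both the head and the selector gradients.
    """
    n, m = Z.shape
    ops = operators or OperatorSet(tuple(cfg.operators))
    policy = SelectorPolicy.uniform(cfg.N, m, len(ops))
    head = Head.zeros(head_variant, cfg.N)
    baseline = estimators.BaselineState(ema_decay=cfg.ema_decay)
    w_all = (
        np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    )

    n_batches = max(1, int(np.ceil(n / cfg.batch_size)))
    schedule = estimators.EntropySchedule(cfg.lambda0, cfg.epochs * n_batches)
    history = TrainHistory()
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for bi in range(n_batches):
            idx = order[bi * cfg.batch_size : (bi + 1) * cfg.batch_size]
            Zb, yb, wb = Z[idx], y[idx], w_all[idx]
            bsz = len(idx)
            structs = core.sample_structures_batch(policy, bsz, rng)
            h = core.forward(structs, Zb, ops).astype(float)
            loss_i, dscore = _per_example_loss(head, h, yb)
            wmean = wb / wb.sum()
            epoch_loss += float((loss_i * wmean).sum()) * bsz / n

            F = -loss_i
            baseline = estimators.ema_update(baseline, float((F * wmean).sum()))
            # Fold sample weights (normalized to mean 1) into the advantage;
            # the structural update applies the SUMMED per-example terms of
            # the mini-batch, mirroring the per-trajectory sum of the RL
            # estimator — this is what gives the stated selector learning
            # rate a workable signal scale.
            adv = (F - baseline.b) * wb * bsz / wb.sum()
            grad = estimators.batch_score_function_grad(
                policy, structs, baseline.b + adv, baseline.b
            ).scaled(bsz)
            lam = estimators.anneal(schedule, step)
            policy.a_logits += cfg.lr_logits * (
                grad.a + lam * estimators.entropy_grad(policy.a_logits)
            )
            policy.b_logits += cfg.lr_logits * (
                grad.b + lam * estimators.entropy_grad(policy.b_logits)
            )
            policy.o_logits += cfg.lr_logits * (
                grad.o + lam * estimators.entropy_grad(policy.o_logits)
            )

            head.weights = head.weights - cfg.lr_head * (dscore * wmean) @ h
            head.bias = head.bias - cfg.lr_head * float((dscore * wmean).sum())
            step += 1

        history.loss.append(epoch_loss)
        history.selector_entropy.append(_mean_selector_entropy(policy))
        history.baseline.append(baseline.b)
        if val is not None:
            Zv, yv = val
            hv = core.forward(core.map_structure(policy), Zv, ops).astype(float)
            lv, _ = _per_example_loss(head, hv, yv)
            history.metric.append(float(lv.mean()))
    return policy, head, ops, history


def _mean_selector_entropy(policy: SelectorPolicy) -> float:
    ents = [
        estimators.entropy(p)
        for logits in (policy.a_logits, policy.b_logits, policy.o_logits)
        for p in core.selector_probs(logits)
    ]
    return float(np.mean(ents))


def train_classifier(dataset: Dataset, cfg: TrainConfig = None):
    """Train a logistic-head LPBN classifier; F = −cross-entropy."""
    cfg = cfg or TrainConfig()
    y_tr = np.asarray(dataset.y_train, dtype=float)
    uniq = np.unique(y_tr)
    if uniq.size < 2 and not ((uniq > 0) & (uniq < 1)).any():
        raise ValueError("degenerate single-class training split")
    scheme, Z = _substrate(dataset, cfg)
    rng = np.random.default_rng(cfg.seed)
    val = (Z[dataset.idx_val], np.asarray(dataset.y_val, float)) if len(
        dataset.idx_val
    ) else None
    policy, head, ops, hist = _fit_lpbn(
        Z[dataset.idx_train], y_tr, "logistic", cfg, rng, val=val
    )
    return LPBNModel(policy, ops, head, scheme), hist


def train_regressor(dataset: Dataset, cfg: TrainConfig = None):
    """Train a linear-head LPBN regressor; F = −squared error.

    Targets are standardized on the training split for the optimization
    (which also normalizes the selector feedback scale) and the head is
    rescaled back afterwards, so the returned model predicts on the
    original target scale.
    """
    cfg = cfg or TrainConfig()
    scheme, Z = _substrate(dataset, cfg)
    rng = np.random.default_rng(cfg.seed)
    y_tr = np.asarray(dataset.y_train, dtype=float)
    mu_y = y_tr.mean()
    sd_y = y_tr.std() or 1.0
    val = (
        (Z[dataset.idx_val], (np.asarray(dataset.y_val, float) - mu_y) / sd_y)
        if len(dataset.idx_val)
        else None
    )
    policy, head, ops, hist = _fit_lpbn(
        Z[dataset.idx_train], (y_tr - mu_y) / sd_y, "linear", cfg, rng, val=val
    )
    head.weights = head.weights * sd_y
    head.bias = head.bias * sd_y + mu_y
    return LPBNModel(policy, ops, head, scheme), hist


def train_embedding(dataset: Dataset, cfg: TrainConfig = None):
    """Train an LPBN feature extractor to reconstruct its (standardized)
    inputs through a shallow linear decoder; embeddings are the unit
    outputs h at the last epoch."""
    cfg = cfg or TrainConfig()
    scheme, Z = _substrate(dataset, cfg)
    rng = np.random.default_rng(cfg.seed)
    Ztr = Z[dataset.idx_train]
    Xtr = np.asarray(dataset.X_train, dtype=float)
    if scheme is not None:
        Xtr = (Xtr - scheme.means) / scheme.sds
    n, m = Ztr.shape
    d = Xtr.shape[1]
    ops = OperatorSet(tuple(cfg.operators))
    policy = SelectorPolicy.uniform(cfg.N, m, len(ops))
    W = np.zeros((d, cfg.N))
    b = Xtr.mean(axis=0).copy()  # decoder bias starts at the feature means
    baseline = estimators.BaselineState(ema_decay=cfg.ema_decay)
    n_batches = max(1, int(np.ceil(n / cfg.batch_size)))
    schedule = estimators.EntropySchedule(cfg.lambda0, cfg.epochs * n_batches)
    history = TrainHistory()
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for bi in range(n_batches):
            idx = order[bi * cfg.batch_size : (bi + 1) * cfg.batch_size]
            Zb, Xb = Ztr[idx], Xtr[idx]
            bsz = len(idx)
            structs = core.sample_structures_batch(policy, bsz, rng)
            h = core.forward(structs, Zb, ops).astype(float)
            recon = h @ W.T + b
            err = recon - Xb
            loss_i = (err**2).mean(axis=1)
            epoch_loss += float(loss_i.sum()) / n
            F = -loss_i
            baseline = estimators.ema_update(baseline, float(F.mean()))
            grad = estimators.batch_score_function_grad(
                policy, structs, F, baseline.b
            ).scaled(bsz)  # summed per-example terms, as in the classifier
            lam = estimators.anneal(schedule, step)
            policy.a_logits += cfg.lr_logits * (
                grad.a + lam * estimators.entropy_grad(policy.a_logits)
            )
            policy.b_logits += cfg.lr_logits * (
                grad.b + lam * estimators.entropy_grad(policy.b_logits)
            )
            policy.o_logits += cfg.lr_logits * (
                grad.o + lam * estimators.entropy_grad(policy.o_logits)
            )
            gW = (2.0 / (bsz * d)) * err.T @ h
            gb = (2.0 / (bsz * d)) * err.sum(axis=0)
            W -= cfg.lr_head * gW
            b -= cfg.lr_head * gb
            step += 1
        history.loss.append(epoch_loss)
        history.selector_entropy.append(_mean_selector_entropy(policy))
        history.baseline.append(baseline.b)
    model = LPBNModel(policy, ops, Head.zeros("linear", cfg.N), scheme)
    return EmbeddingModel(model, W, b), history


def train_mlp(
    dataset: Dataset,
    task: str,
    cfg: TrainConfig,
    hidden: int = None,
    lr: float = 0.05,
    lpbn_params: int = None,
):
    """Train the parameter-matched 1-hidden-layer tanh MLP baseline.

    ``hidden`` may be given directly; otherwise it is derived from
    ``lpbn_params`` through the ±10% matching rule.  The same seed set and
    splits as the paired LPBN run keep the comparison seed-paired.
    """
    if dataset.meta.get("binary"):
        X = np.asarray(dataset.X, dtype=float)
        mu, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    else:
        X = np.asarray(dataset.X, dtype=float)
        mu = X[dataset.idx_train].mean(axis=0)
        sd = X[dataset.idx_train].std(axis=0)
        sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    d_in = Xs.shape[1]
    d_out = d_in if task == "decoder" else 1
    if hidden is None:
        if lpbn_params is None:
            raise ValueError("give either hidden width or lpbn_params to match")
        hidden = core.match_mlp_width(lpbn_params, d_in, d_out)
    rng = np.random.default_rng(cfg.seed)
    mlp = MLPBaseline.init(d_in, hidden, d_out, task, rng)
    y = np.asarray(dataset.y, dtype=float)
    idx_tr = dataset.idx_train
    history = TrainHistory()
    n = len(idx_tr)
    n_batches = max(1, int(np.ceil(n / cfg.batch_size)))
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for bi in range(n_batches):
            idx = idx_tr[order[bi * cfg.batch_size : (bi + 1) * cfg.batch_size]]
            Xb = Xs[idx]
            hid = mlp.hidden(Xb)
            out = hid @ mlp.W2.T + mlp.b2
            if task == "logistic":
                p = 1.0 / (1.0 + np.exp(-out[:, 0]))
                p = np.clip(p, 1e-12, 1 - 1e-12)
                yb = y[idx]
                loss = -(yb * np.log(p) + (1 - yb) * np.log(1 - p)).mean()
                dout = ((p - yb) / len(idx))[:, None]
            elif task == "linear":
                yb = y[idx]
                err = out[:, 0] - yb
                loss = float((err**2).mean())
                dout = (2 * err / len(idx))[:, None]
            else:  # decoder: reconstruct standardized inputs
                err = out - Xb
                loss = float((err**2).mean())
                dout = 2 * err / err.size
            epoch_loss += loss * len(idx) / n
            dW2 = dout.T @ hid
            db2 = dout.sum(axis=0)
            dhid = dout @ mlp.W2 * (1 - hid**2)
            dW1 = dhid.T @ Xb
            db1 = dhid.sum(axis=0)
            mlp.W2 -= lr * dW2
            mlp.b2 -= lr * db2
            mlp.W1 -= lr * dW1
            mlp.b1 -= lr * db1
        history.loss.append(epoch_loss)
    mlp_meta = {"mu": mu, "sd": sd}
    history.metric.append(epoch_loss)
    mlp.norm = mlp_meta  # standardization carried with the model
    return mlp, history


def text_featurize(sentences, vocabulary=None) -> np.ndarray:
    """Binary bag-of-words presence features plus CONST0/CONST1 bits.

    Feature width is ``len(vocabulary) + 2``; the two trailing positions are
    the constant-0 and constant-1 bits that allow unary gates (identity and
    NOT via AND/XOR with CONST1).  Out-of-vocabulary tokens are rejected.
    """
    vocab = tuple(vocabulary) if vocabulary is not None else text_vocabulary()
    index = {tok: i for i, tok in enumerate(vocab)}
    V = len(vocab)
    Z = np.zeros((len(sentences), V + 2), dtype=np.uint8)
    for r, sent in enumerate(sentences):
        for tok in sent:
            if tok not in index:
                raise ValueError(f"out-of-vocabulary token {tok!r}")
            Z[r, index[tok]] = 1
    Z[:, V + 1] = 1  # CONST1; CONST0 stays zero
    return Z


def evaluate_classifier(model: LPBNModel, X: np.ndarray, y: np.ndarray) -> float:
    """Test accuracy under the MAP structure."""
    Z = _bin.transform(model.scheme, X) if model.scheme else np.asarray(X, np.uint8)
    h = core.forward(core.map_structure(model.policy), Z, model.operators)
    p = core.head_forward(model.head, h)
    return float(((p >= 0.5).astype(int) == np.asarray(y)).mean())


def evaluate_regressor(model: LPBNModel, X: np.ndarray, y: np.ndarray) -> float:
    """Test RMSE under the MAP structure."""
    Z = _bin.transform(model.scheme, X) if model.scheme else np.asarray(X, np.uint8)
    h = core.forward(core.map_structure(model.policy), Z, model.operators)
    pred = core.head_forward(model.head, h)
    return float(np.sqrt(((pred - np.asarray(y, float)) ** 2).mean()))
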