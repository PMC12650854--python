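"""Metrics and the seed-paired statistical comparison harness.

Model comparisons are built on per-seed score differences
Δ_s = score_ANN(s) − score_LPBN(s) on a uniformly higher-is-better scale
(regression uses −RMSE).  For each task the harness reports the mean Δ, a
bootstrap 95% CI (10,000 resamples), an exact two-sided sign test with
ties dropped, Holm adjustment across tasks, Cliff's δ, and a TOST
equivalence verdict against a pre-registered margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import (
    accuracy_score,
    adjusted_rand_score,
    calinski_harabasz_score,
    mean_squared_error,
    roc_auc_score,
    silhouette_score,
)

__all__ = [
    "PairedResult",
    "metric",
    "bootstrap_ci",
    "sign_test",
    "holm_adjust",
    "tost_equivalence",
    "cliffs_delta",
    "compare_models",
    "render_table",
]


def metric(name: str, predictions, truth, embeddings=None, k: int = 3) -> float:
    """Standard evaluation metrics behind one switch.

    accuracy / auroc / rmse compare ``predictions`` with ``truth``;
    ari / silhouette / calinski_harabasz run k-means (K = ``k``) on
    ``embeddings`` (or on ``predictions`` if no embeddings given) and score
    the partition — ARI against ``truth``, the internal indices without it.
    """
    if name == "accuracy":
        return float(accuracy_score(truth, np.round(predictions)))
    if name == "auroc":
        truth = np.asarray(truth)
        if len(np.unique(truth)) < 2:
            raise ValueError("AUROC undefined for single-class truth")
        return float(roc_auc_score(truth, predictions))
    if name == "rmse":
        return float(np.sqrt(mean_squared_error(truth, predictions)))
    E = np.asarray(embeddings if embeddings is not None else predictions, float)
    labels = KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(E)
    if name == "ari":
        return float(adjusted_rand_score(truth, labels))
    if name == "silhouette":
        return float(silhouette_score(E, labels))
    if name == "calinski_harabasz":
        return float(calinski_harabasz_score(E, labels))
    raise ValueError(f"unknown metric {name!r}")


def bootstrap_ci(
    deltas,
    resamples: int = 10_000,
    rng: np.random.Generator = None,
    alpha: float = 0.05,
    method: str = "percentile",
) -> tuple:
    """Bootstrap CI for the mean of ``deltas`` (percentile by default).

    ``method='bca'`` applies the bias-corrected (BC) percentile adjustment.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta list")
    rng = rng or np.random.default_rng(0)
    means = rng.choice(d, size=(resamples, d.size), replace=True).mean(axis=1)
    if method == "percentile":
        lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    if method == "bca":
        prop = np.mean(means < d.mean())
        z0 = sps.norm.ppf(np.clip(prop, 1e-9, 1 - 1e-9))
        za = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
        qs = sps.norm.cdf(2 * z0 + za)
        lo, hi = np.quantile(means, qs)
        return float(lo), float(hi)
    raise ValueError(f"unknown bootstrap method {method!r}")


def sign_test(deltas) -> tuple:
    """Exact two-sided sign test on paired differences; ties dropped.

    p = min(1, 2·P(X >= max(n+, n−))) with X ~ Binomial(n+ + n−, 1/2);
    all-ties gives p = 1 with counts 0/0.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta list")
    n_plus = int((d > 0).sum())
    n_minus = int((d < 0).sum())
    n = n_plus + n_minus
    if n == 0:
        return 1.0, 0, 0
    k = max(n_plus, n_minus)
    p = min(1.0, 2.0 * float(sps.binom.sf(k - 1, n, 0.5)))
    return p, n_plus, n_minus


def holm_adjust(pvalues) -> list:
    """Holm–Bonferroni step-down adjustment with monotonicity, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def tost_equivalence(deltas, epsilon: float, alpha: float = 0.05) -> dict:
    """Two one-sided t-tests of the mean difference against ±epsilon.

    Verdict 'Yes' requires both one-sided tests to reject at ``alpha`` and —
    because t-based TOST degenerates at very small n — the percentile
    bootstrap CI of the mean to lie strictly inside (−ε, ε).  Zero-variance
    samples fall back to exact containment of the common value.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise ValueError("TOST needs at least 2 paired differences")
    if epsilon <= 0:
        raise ValueError("equivalence margin must be positive")
    mean = d.mean()
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        inside = abs(mean) < epsilon
        return {
            "equivalent": bool(inside),
            "p_lower": 0.0 if inside else 1.0,
            "p_upper": 0.0 if inside else 1.0,
            "mean": float(mean),
        }
    se = sd / np.sqrt(n)
    t_lower = (mean + epsilon) / se  # H0: mean <= -eps
    t_upper = (mean - epsilon) / se  # H0: mean >= +eps
    p_lower = float(sps.t.sf(t_lower, n - 1))
    p_upper = float(sps.t.cdf(t_upper, n - 1))
    lo, hi = bootstrap_ci(d, rng=np.random.default_rng(0))
    verdict = (
        p_lower < alpha and p_upper < alpha and -epsilon < lo and hi < epsilon
    )
    return {
        "equivalent": bool(verdict),
        "p_lower": p_lower,
        "p_upper": p_upper,
        "mean": float(mean),
    }


def cliffs_delta(a, b) -> float:
    """Cliff's δ = (#{a_i > b_j} − #{a_i < b_j}) / (|a|·|b|) ∈ [−1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


@dataclass
class PairedResult:
    """One task row of the paired ANN-vs-LPBN comparison table."""

    task: str
    deltas: np.ndarray
    mean_delta: float
    ci: tuple
    sign_p: float
    holm_p: float = None
    n_plus: int = 0
    n_minus: int = 0
    cliffs: float = 0.0
    tost_epsilon: float = None
    equivalent: str = ""
    winner: str = "No clear winner"
    extras: dict = field(default_factory=dict)


def compare_models(
    results: dict,
    epsilons: dict = None,
    rng: np.random.Generator = None,
    alpha: float = 0.05,
) -> list:
    """Build the paired comparison table across tasks.

    ``results`` maps task name to a dict with per-seed score arrays
    ``{"ann": [...], "lpbn": [...]}`` on a higher-is-better scale (use
    −RMSE for regression); the seed ordering must pair the two lists.
    The sign convention is Δ = ANN − LPBN, so positive Δ favors the ANN.
    A winner is declared when the bootstrap CI of the mean difference
    excludes zero; otherwise the verdict is "No clear winner".
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for task, scores in results.items():
        ann = np.asarray(scores["ann"], dtype=float)
        lpbn = np.asarray(scores["lpbn"], dtype=float)
        if ann.shape != lpbn.shape:
            raise ValueError(f"unpaired seed sets for task {task!r}")
        deltas = ann - lpbn
        p, n_plus, n_minus = sign_test(deltas)
        ci = bootstrap_ci(deltas, rng=rng)
        row = PairedResult(
            task=task,
            deltas=deltas,
            mean_delta=float(deltas.mean()),
            ci=ci,
            sign_p=p,
            n_plus=n_plus,
            n_minus=n_minus,
            cliffs=cliffs_delta(ann, lpbn),
        )
        if epsilons and task in epsilons:
            row.tost_epsilon = epsilons[task]
            row.equivalent = (
                "Yes"
                if tost_equivalence(deltas, epsilons[task], alpha)["equivalent"]
                else "No"
            )
        rows.append(row)
    adj = holm_adjust([r.sign_p for r in rows])
    for row, ap in zip(rows, adj):
        row.holm_p = ap
        if row.ci[0] > 0 or row.ci[1] < 0:
            row.winner = "ANN" if row.mean_delta > 0 else "LPBN"
    return rows


def render_table(rows: list) -> str:
    """Plain-text comparison table (one row per task)."""
    header = (
        f"{'Task':<22}{'Mean d':>9}{'95% CI':>20}{'Sign p':>9}"
        f"{'n+/n-':>8}{'Cliff d':>9}  Winner"
    )
    lines = [header, "-" * len(header)]
    for r in rows:
        ci = f"[{r.ci[0]:.3f}, {r.ci[1]:.3f}]"
        lines.append(
            f"{r.task:<22}{r.mean_delta:>9.3f}{ci:>20}{r.sign_p:>9.3f}"
            f"{f'{r.n_plus}/{r.n_minus}':>8}{r.cliffs:>9.3f}  {r.winner}"
        )
    return "\n".join(lines)
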