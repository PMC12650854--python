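"""One-hot binarization of real features onto a Boolean substrate.

Real vectors ``x ∈ R^d`` are standardized (train-split statistics only) and
each feature is cut into ``B`` equal-width bins spanning the standardized
training min-max.  Concatenating the one-hot bin indicators yields the
substrate ``z ∈ {0,1}^m`` with ``m = d·B`` (plus two optional constant bits
CONST0/CONST1 that let single-input behaviours such as identity and NOT be
expressed with 2-input gates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinarizationScheme",
    "fit_binarizer",
    "transform",
    "discretize_rl_state",
]


@dataclass
class BinarizationScheme:
    """Per-feature standardization statistics and bin edges.

    Attributes
    ----------
    d : int
        Number of real-valued input features.
    B : int
        Bins per feature (>= 2).
    means, sds : ndarray of shape (d,)
        Standardization parameters estimated on the training split only.
    edges : ndarray of shape (d, B + 1)
        Ascending bin boundaries per feature, in standardized units.
    const_bits : bool
        If set, two extra substrate positions are appended that are always
        0 and always 1 respectively.
    """

    d: int
    B: int
    means: np.ndarray
    sds: np.ndarray
    edges: np.ndarray
    const_bits: bool = False
    zero_variance: np.ndarray = field(default=None)  # bool flags per feature

    @property
    def m(self) -> int:
        """Substrate width: d*B plus two constant bits when enabled."""
        return self.d * self.B + (2 if self.const_bits else 0)

    @property
    def const0_index(self) -> int:
        if not self.const_bits:
            raise ValueError("scheme has no constant bits")
        return self.d * self.B

    @property
    def const1_index(self) -> int:
        if not self.const_bits:
            raise ValueError("scheme has no constant bits")
        return self.d * self.B + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "d": self.d,
                "B": self.B,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "edges": self.edges.tolist(),
                "const_bits": self.const_bits,
                "zero_variance": np.asarray(self.zero_variance).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BinarizationScheme":
        obj = json.loads(text)
        return cls(
            d=obj["d"],
            B=obj["B"],
            means=np.asarray(obj["means"], dtype=float),
            sds=np.asarray(obj["sds"], dtype=float),
            edges=np.asarray(obj["edges"], dtype=float),
            const_bits=obj["const_bits"],
            zero_variance=np.asarray(obj["zero_variance"], dtype=bool),
        )


def fit_binarizer(
    train_features: np.ndarray, B: int = 5, const_bits: bool = False
) -> BinarizationScheme:
    """Fit a binarization scheme on training data.

    Standardizes each feature to zero mean / unit variance using the training
    split only, then lays out ``B`` equal-width bins over the standardized
    train min-max.  The same affine map is reused downstream; validation and
    test data never refit.

    Parameters
    ----------
    train_features : array of shape (n, d)
    B : int
        Bins per feature; must be >= 2 (a single bin carries no information).
    const_bits : bool
        Append always-0 / always-1 substrate positions.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("train_features must be a 2-D array")
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 training rows to fit a binarizer")
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    zero_var = sds == 0.0
    sds_safe = np.where(zero_var, 1.0, sds)

    Xs = (X - means) / sds_safe
    lo = Xs.min(axis=0)
    hi = Xs.max(axis=0)
    # Degenerate (constant) features get a symbolic unit-width range so the
    # bin edges remain strictly increasing; the feature is flagged.
    width = np.where(hi > lo, hi - lo, 1.0)
    edges = lo[:, None] + np.linspace(0.0, 1.0, B + 1)[None, :] * width[:, None]
    return BinarizationScheme(
        d=d,
        B=B,
        means=means,
        sds=sds_safe,
        edges=edges,
        const_bits=const_bits,
        zero_variance=zero_var,
    )


def _bin_indices(values: np.ndarray, edges: np.ndarray, B: int) -> np.ndarray:
    """Map standardized values to bin indices with clamping.

    Bins are half-open ``[e_k, e_{k+1})`` except the last, which is closed;
    out-of-range values clamp to the boundary bins.
    """
    # edges: (d, B+1); values: (..., d)
    idx = np.empty(values.shape, dtype=np.int64)
    for j in range(edges.shape[0]):
        idx[..., j] = np.searchsorted(edges[j, 1:-1], values[..., j], side="right")
    return np.clip(idx, 0, B - 1)


def transform(scheme: BinarizationScheme, x: np.ndarray) -> np.ndarray:
    """Binarize a vector (d,) or matrix (n, d) into substrate bits.

    Exactly one bit is hot per feature block; values outside the training
    range clamp to the boundary bin.  Constant bits, when present, are fixed
    to 0 and 1.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[-1] != scheme.d:
        raise ValueError(f"expected {scheme.d} features, got {X.shape[-1]}")
    Xs = (X - scheme.means) / scheme.sds
    idx = _bin_indices(Xs, scheme.edges, scheme.B)
    n = X.shape[0]
    Z = np.zeros((n, scheme.m), dtype=np.uint8)
    cols = idx + np.arange(scheme.d)[None, :] * scheme.B
    Z[np.arange(n)[:, None], cols] = 1
    if scheme.const_bits:
        Z[:, scheme.const1_index] = 1
    return Z[0] if single else Z


def discretize_rl_state(
    state: np.ndarray, ranges: np.ndarray, B: int = 8
) -> np.ndarray:
    """One-hot code an RL state over fixed physical ranges.

    Each state variable is cut into ``B`` equal-width bins over its fixed
    interval ``[lo_i, hi_i]``; values outside the interval clamp to the
    boundary bins.  Returns a bit vector of length ``len(state) * B``.
    """
    s = np.asarray(state, dtype=float)
    r = np.asarray(ranges, dtype=float)
    if r.shape != (s.shape[-1], 2):
        raise ValueError("ranges must have shape (n_vars, 2)")
    if not np.all(np.isfinite(r)):
        raise ValueError("ranges must be finite")
    lo, hi = r[:, 0], r[:, 1]
    frac = (s - lo) / (hi - lo)
    idx = np.clip(np.floor(frac * B).astype(np.int64), 0, B - 1)
    z = np.zeros(s.shape[-1] * B, dtype=np.uint8)
    z[idx + np.arange(s.shape[-1]) * B] = 1
    return z
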