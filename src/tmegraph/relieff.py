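"""ReliefF importance weighting for patient-level spatial features.

For every instance, the k nearest same-class neighbors (hits) and the k
nearest other-class neighbors (misses) are found under Manhattan distance on
min-max normalized features.  A feature's weight accumulates the mean
per-feature absolute difference to misses minus the mean difference to hits,
averaged over instances, so weights live in [-1, 1]: discriminative features
differ across classes but not within.  With a binary outcome the
prior-weighted multi-class miss term reduces to the plain miss mean.

All instances are used (no subsampling), so the default is deterministic;
``seed`` is kept in the result for provenance.  Neighbor ties at equal
distance resolve by instance index order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class WeightVector:
    weights: np.ndarray
    k_neighbors: int
    n_iterations: int
    seed: int | None = None
    feature_names: tuple[str, ...] | None = None


def _minmax_normalize(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng_safe = np.where(rng > 0, rng, 1.0)
    return (X - lo) / rng_safe


def relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
    seed: int | None = None,
    feature_names=None,
) -> WeightVector:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.isnan(X).any():
        raise ValueError("NA values are not allowed")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 instances")
    m, d = X.shape
    Xn = _minmax_normalize(X)
    D = cdist(Xn, Xn, metric="cityblock")
    W = np.zeros(d)
    for i in range(m):
        hit_mask = (y == y[i])
        hit_idx = np.flatnonzero(hit_mask)
        hit_idx = hit_idx[hit_idx != i]
        k_h = min(k_neighbors, hit_idx.size)
        order = hit_idx[np.lexsort((hit_idx, D[i, hit_idx]))][:k_h]
        hit_diff = np.abs(Xn[order] - Xn[i]).mean(axis=0) if k_h else 0.0
        miss_diff = np.zeros(d)
        others = classes[classes != y[i]]
        for c in others:
            miss_idx = np.flatnonzero(y == c)
            k_m = min(k_neighbors, miss_idx.size)
            order_m = miss_idx[np.lexsort((miss_idx, D[i, miss_idx]))][:k_m]
            # binary outcome: the class-prior weighting degenerates to the mean
            miss_diff += np.abs(Xn[order_m] - Xn[i]).mean(axis=0) / len(others)
        W += miss_diff - hit_diff
    W /= m
    names = tuple(feature_names) if feature_names is not None else None
    return WeightVector(
        weights=W, k_neighbors=k_neighbors, n_iterations=m, seed=seed,
        feature_names=names,
    )


def rank_and_select(weights: WeightVector | np.ndarray, n_top: int = 8) -> list[int]:
    """Indices of the n_top largest weights, descending; ties by lower index."""
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > w.size:
        raise ValueError("n_top exceeds the feature count")
    order = np.argsort(-w, kind="stable")
    return [int(i) for i in order[:n_top]]


def weight_table(wv: WeightVector) -> pd.DataFrame:
    """Ranked weight table; includes the per-class-pair maximum weight when
    feature names follow the ``pair<a>-<b>|<feature>`` convention."""
    names = wv.feature_names or tuple(f"f{i}" for i in range(wv.weights.size))
    df = pd.DataFrame({"feature": names, "weight": wv.weights})
    df["pair"] = [n.split("|")[0] if "|" in n else "" for n in names]
    df = df.sort_values("weight", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def pair_weight_table(wv: WeightVector) -> pd.DataFrame:
    """Per-pair maximum weight (the class-pair granularity of the ranking)."""
    df = weight_table(wv)
    agg = (
        df[df["pair"] != ""]
        .groupby("pair", as_index=False)["weight"]
        .max()
        .sort_values("weight", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg
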