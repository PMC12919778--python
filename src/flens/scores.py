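"""Structure-preservation and label-separation scores for 2-D projections.

A projection that visually separates a sensitive variable (site) is only
evidence of a batch effect if the projection is trustworthy; conversely a
high silhouette by site in a faithful projection is a red flag. Four
complementary scores are therefore bundled:

* **silhouette** — how well the given labels separate in the projected
  space (mean of (b - a)/max(a, b) per point);
* **ARI vs. labels** — agreement between an unsupervised k-means partition
  of the projection (k = number of label levels) and the labels, corrected
  for chance by pair counting;
* **KNN preservation** — mean fraction of each point's k nearest neighbors
  shared between the high- and low-dimensional spaces (local fidelity);
* **CPD** — Spearman rank correlation of pairwise distances between the two
  spaces (global fidelity).

Caveat: when a label's items form several well-separated local clusters,
silhouette and ARI are pulled toward zero even though the label is clearly
visible; the scores are reported as-is and should be read alongside the
plots.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import spearmanr

from .projector import ProjectionResult
from .store import EmbeddingSet, VariableSpec, subset

__all__ = [
    "StructureScores",
    "silhouette_score",
    "adjusted_rand_index",
    "kmeans_ari",
    "knn_preservation",
    "cpd",
    "score_projection",
]

_SILHOUETTE_CAP = 5000  # O(n^2) distances; larger inputs are subsampled


@dataclass
class StructureScores:
    silhouette: float
    ari: float
    knn_preservation: float
    cpd: float
    k_used: int
    n_scored: int
    subsample_seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_labels(labels) -> np.ndarray:
    return np.array([str(v) for v in labels], dtype=object)


def silhouette_score(points: np.ndarray, labels, seed: int = 0) -> float:
    """Mean silhouette over points (Euclidean).

    s(i) = (b(i) - a(i)) / max(a(i), b(i)), where a(i) is the mean distance
    to same-label points (excluding self) and b(i) the smallest mean
    distance to any other label. Points whose label is a singleton score 0.
    Inputs above the internal cap are scored on a seeded subsample.
    """
    X = np.asarray(points, dtype=np.float64)
    y = _as_labels(labels)
    if len(X) != len(y):
        raise ValueError("points and labels must align")
    if len(X) < 2:
        raise ValueError("need at least 2 points")
    if len(set(y)) < 2:
        raise ValueError("need at least 2 distinct labels")
    if len(X) > _SILHOUETTE_CAP:
        idx = np.sort(
            np.random.default_rng(seed).choice(len(X), _SILHOUETTE_CAP, replace=False)
        )
        X, y = X[idx], y[idx]
        if len(set(y)) < 2:
            raise ValueError("subsample lost all but one label")
    D = cdist(X, X)
    classes = sorted(set(y))
    masks = {c: y == c for c in classes}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    s = np.zeros(len(X))
    for i in range(len(X)):
        ci = y[i]
        if sizes[ci] == 1:
            continue  # singleton convention: s(i) = 0
        a = D[i, masks[ci]].sum() / (sizes[ci] - 1)
        b = min(D[i, masks[c]].mean() for c in classes if c != ci)
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if len(a) != len(b):
        raise ValueError("partitions must have equal length")
    n = len(a)
    ca = sorted(set(a))
    cb = sorted(set(b))
    cont = np.zeros((len(ca), len(cb)), dtype=np.int64)
    ia = {c: k for k, c in enumerate(ca)}
    ib = {c: k for k, c in enumerate(cb)}
    for x, y in zip(a, b):
        cont[ia[x], ib[y]] += 1

    def comb2(v):
        v = np.asarray(v, dtype=np.float64)
        return v * (v - 1) / 2

    index = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((index - expected) / (max_index - expected))


def _farthest_first_centers(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy farthest-first center selection from a seeded start point."""
    start = int(rng.integers(0, len(X)))
    centers = [start]
    d2 = np.sum((X - X[start]) ** 2, axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d2))  # argmax: ties -> lowest index
        centers.append(nxt)
        d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
    return X[centers].copy()


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int = 300, tol: float = 1e-4
) -> tuple[np.ndarray, float]:
    k = len(centers)
    assign = np.zeros(len(X), dtype=np.int64)
    for _ in range(max_iter):
        D = cdist(X, centers)
        assign = np.argmin(D, axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = X[assign == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
        shift = float(np.linalg.norm(new_centers - centers, axis=1).max())
        centers = new_centers
        if shift < tol:
            break
    inertia = float(np.sum((X - centers[assign]) ** 2))
    return assign, inertia


def kmeans_ari(
    points: np.ndarray, labels, seed: int = 0, n_restarts: int = 10
) -> float:
    """ARI between a k-means partition of ``points`` and the given labels.

    Lloyd's algorithm with k = number of distinct labels, greedy
    farthest-first initialization from a seeded start, best inertia over
    ``n_restarts`` restarts. Measures whether the labels correspond to the
    dominant unsupervised cluster structure of the projection.
    """
    X = np.asarray(points, dtype=np.float64)
    y = _as_labels(labels)
    k = len(set(y))
    if k < 2:
        raise ValueError("need at least 2 distinct labels")
    if k > len(X):
        raise ValueError("more labels than points")
    rng = np.random.default_rng(seed)
    best_assign, best_inertia = None, np.inf
    for _ in range(n_restarts):
        centers = _farthest_first_centers(X, k, rng)
        assign, inertia = _lloyd(X, centers)
        if inertia < best_inertia:
            best_assign, best_inertia = assign, inertia
    return adjusted_rand_index(y, best_assign)


def _knn_sets(X: np.ndarray, k: int) -> list[set[int]]:
    D = cdist(X, X)
    out = []
    for i in range(len(X)):
        d = D[i].copy()
        d[i] = np.inf  # exclude self
        # stable sort on distance -> ties broken by lower index
        order = np.argsort(d, kind="stable")
        out.append(set(order[:k].tolist()))
    return out


def knn_preservation(high: np.ndarray, low: np.ndarray, k: int) -> float:
    """Mean fraction of shared k-nearest-neighbor sets across the two spaces."""
    H = np.asarray(high, dtype=np.float64)
    L = np.asarray(low, dtype=np.float64)
    if len(H) != len(L):
        raise ValueError("high and low row counts differ")
    n = len(H)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, n-1], got {k} for n={n}")
    nn_h = _knn_sets(H, k)
    nn_l = _knn_sets(L, k)
    return float(np.mean([len(a & b) / k for a, b in zip(nn_h, nn_l)]))


def cpd(
    high: np.ndarray,
    low: np.ndarray,
    max_points: int = 1000,
    seed: int = 0,
) -> float:
    """Spearman correlation of pairwise distances (global structure).

    For n > ``max_points`` a seeded uniform subsample bounds the quadratic
    pair count; ties receive average ranks.
    """
    H = np.asarray(high, dtype=np.float64)
    L = np.asarray(low, dtype=np.float64)
    if len(H) != len(L):
        raise ValueError("high and low row counts differ")
    if len(H) < 3:
        raise ValueError("need at least 3 points")
    if len(H) > max_points:
        idx = np.sort(
            np.random.default_rng(seed).choice(len(H), max_points, replace=False)
        )
        H, L = H[idx], L[idx]
    rho = spearmanr(pdist(H), pdist(L)).statistic
    return float(rho)


def score_projection(
    es: EmbeddingSet,
    projection: ProjectionResult,
    variable: VariableSpec,
    k: int = 15,
    seed: int = 0,
) -> StructureScores:
    """Bundle all four scores for one projection of (a subset of) ``es``.

    Default k matches the projector's n_neighbors default, tying the local
    fidelity metric to the neighborhood size the projection optimized.
    """
    aligned = subset(es, projection.ids)  # raises on unknown ids
    X = aligned.features
    coords = projection.coords
    y = aligned.variable(variable.name)
    k_eff = min(k, len(coords) - 1)
    return StructureScores(
        silhouette=silhouette_score(coords, y, seed=seed),
        ari=kmeans_ari(coords, y, seed=seed),
        knn_preservation=knn_preservation(X, coords, k_eff),
        cpd=cpd(X, coords, seed=seed),
        k_used=k_eff,
        n_scored=len(coords),
        subsample_seed=seed,
    )
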