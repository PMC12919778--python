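"""2-D projection of embeddings for visual bias inspection.

Two backends share one contract:

* ``neighbor_embedding`` — UMAP (via umap-learn, imported lazily), honoring
  ``n_neighbors``, ``min_dist`` and the seed. Defaults follow the standard
  general-purpose starting point (n_neighbors=15, min_dist=0.1); because no
  single setting is known to be optimal for bias detection, a parameter
  grid sweep is provided instead of a tuned default.
* ``linear_fallback`` — a built-in deterministic PCA onto the top-2
  principal directions via iterated power method with deflation. It ignores
  the neighbor parameters and exists so scoring and reporting are exactly
  reproducible and testable without the stochastic neighbor-embedding
  optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .store import EmbeddingSet, subset

__all__ = [
    "ProjectorParams",
    "ProjectionResult",
    "PCAProjector",
    "project",
    "project_grid",
    "draw_projection_sample",
]


@dataclass(frozen=True)
class ProjectorParams:
    method: str = "neighbor_embedding"  # or "linear_fallback"
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 0
    sample_sizes: tuple[int, ...] = (10_000, 70_000)

    def __post_init__(self) -> None:
        if self.method not in ("neighbor_embedding", "linear_fallback"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")


@dataclass
class ProjectionResult:
    ids: list[str]
    coords: np.ndarray  # n x 2
    params: ProjectorParams
    source_hash: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be n x 2, aligned with ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def to_dict(self) -> dict:
        return {
            "ids": self.ids,
            "coords": self.coords.tolist(),
            "params": asdict(self.params),
            "source_hash": self.source_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionResult":
        params = dict(d["params"])
        params["sample_sizes"] = tuple(params.get("sample_sizes", (10_000, 70_000)))
        return cls(
            ids=list(d["ids"]),
            coords=np.asarray(d["coords"], dtype=np.float64),
            params=ProjectorParams(**params),
            source_hash=d["source_hash"],
        )


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for u in basis:
        v = v - (v @ u) * u
    return v


def _power_iteration(
    S: np.ndarray,
    ortho: list[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 50_000,
) -> tuple[float, np.ndarray]:
    """Dominant eigenpair of symmetric PSD ``S`` within span(ortho)^perp.

    Iterates are re-orthogonalized against ``ortho`` every step, so
    deflation stays exact even when the residual spectrum is (numerically)
    zero — e.g. rank-deficient data, where any orthogonal direction is a
    valid component and the projection onto it must vanish.
    """
    d = S.shape[0]
    # fixed internal start (independent of user seeds): deterministic output
    v = _orthogonalize(np.random.default_rng(0).normal(size=d), ortho)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("no direction left orthogonal to previous components")
    v /= norm
    lam = 0.0
    for _ in range(max_iter):
        w = _orthogonalize(S @ v, ortho)
        norm = np.linalg.norm(w)
        if norm < 1e-300:  # residual spectrum is zero: v is a valid component
            return 0.0, v
        w /= norm
        lam_new = float(w @ S @ w)
        # vector criterion far below tol: the eigenvector error is the
        # iterate change divided by the (unknown) eigengap
        if abs(lam_new - lam) < tol and np.linalg.norm(w - v) < 1e-12:
            return lam_new, w
        v, lam = w, lam_new
    return lam, v


class PCAProjector(BaseEstimator, TransformerMixin):
    """Deterministic 2-component PCA via power iteration with deflation.

    The sign of each principal direction is fixed so that its
    largest-magnitude loading is positive, making the output unique.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 50_000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "PCAProjector":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need at least 3 points")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        S = Xc.T @ Xc / len(X)
        comps: list[np.ndarray] = []
        for _ in range(2):
            lam, v = _power_iteration(S, comps, self.tol, self.max_iter)
            j = int(np.argmax(np.abs(v)))
            if v[j] < 0:
                v = -v
            comps.append(v)
            S = S - lam * np.outer(v, v)
        self.components_ = np.stack(comps)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) @ self.components_.T


def project(es: EmbeddingSet, params: ProjectorParams) -> ProjectionResult:
    """Project an embedding set to 2-D under ``params``."""
    X = es.features
    if params.method == "linear_fallback":
        coords = PCAProjector().fit(X).transform(X)
    else:
        if es.n < params.n_neighbors + 1:
            raise ValueError(
                f"need at least n_neighbors+1={params.n_neighbors + 1} points, "
                f"got {es.n}"
            )
        import umap  # heavy import, deferred

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            random_state=params.seed,
        )
        coords = np.asarray(reducer.fit_transform(X), dtype=np.float64)
    return ProjectionResult(
        ids=list(es.ids),
        coords=coords,
        params=params,
        source_hash=es.source_hash(),
    )


def project_grid(
    es: EmbeddingSet,
    neighbor_values: list[int],
    min_dist_values: list[float],
    seed: int = 0,
    method: str = "neighbor_embedding",
) -> list[ProjectionResult]:
    """One projection per (n_neighbors, min_dist) pair, same input sample.

    Sweeping the two key parameters replaces a tuned default: local structure
    at small n_neighbors, global groupings (e.g. by site) at large.
    """
    if not neighbor_values or not min_dist_values:
        raise ValueError("parameter value lists must be non-empty")
    results = []
    for nn in neighbor_values:
        for md in min_dist_values:
            params = ProjectorParams(
                method=method, n_neighbors=nn, min_dist=md, seed=seed
            )
            results.append(project(es, params))
    return results


def draw_projection_sample(
    es: EmbeddingSet,
    size: int,
    stratify_by: str | None = None,
    seed: int = 0,
) -> EmbeddingSet:
    """Seeded random subsample of ``size`` items, without replacement.

    With ``stratify_by``, per-class counts are proportional to class
    frequencies using largest-remainder rounding (ties broken by class
    name ascending), so small classes keep fair representation.
    """
    if size > es.n:
        raise ValueError(f"sample size {size} exceeds set size {es.n}")
    rng = np.random.default_rng(seed)
    if size == es.n:
        return subset(es, list(es.ids))
    if stratify_by is None:
        idx = np.sort(rng.choice(es.n, size=size, replace=False))
    else:
        y = np.array([str(v) for v in es.variable(stratify_by)], dtype=object)
        classes = sorted(set(y))
        quotas = {c: size * int((y == c).sum()) / es.n for c in classes}
        counts = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = size - sum(counts.values())
        by_remainder = sorted(classes, key=lambda c: (-(quotas[c] - counts[c]), c))
        for c in by_remainder[:short]:
            counts[c] += 1
        parts = []
        for c in classes:
            pool = np.flatnonzero(y == c)
            parts.append(rng.choice(pool, size=counts[c], replace=False))
        idx = np.sort(np.concatenate(parts))
    return subset(es, [es.ids[i] for i in idx])
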