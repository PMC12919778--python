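"""Data-curation computations for whole-slide-image tile studies.

Covers the pipeline from slide geometry to leak-free evaluation sets:
tessellating a slide into fixed-size overlapping tiles, removing
near-empty (whitespace) tiles, ranking sites by tile count, balancing a
clinical covariate across sites so that site comparisons are not
confounded by it, and patient-disjoint train/validation/test splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .store import EmbeddingSet, subset

__all__ = [
    "TileGrid",
    "SplitAssignment",
    "tile_grid",
    "whitespace_fraction",
    "filter_whitespace",
    "top_n_groups",
    "balance_by_covariate",
    "patient_disjoint_split",
]

WHITE_LEVEL = 220  # a pixel is "whitespace" when all three channels are >= this


@dataclass
class TileGrid:
    """Tile origins for one slide, 0-based top-left pixel coordinates."""

    slide_id: str
    tile_side: int
    overlap: float
    origins: list[tuple[int, int]]

    @property
    def stride(self) -> int:
        return max(1, int(round(self.tile_side * (1.0 - self.overlap))))


@dataclass
class SplitAssignment:
    """Item id -> split name, with all items of one unit in one split."""

    mapping: dict[str, str]
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    unit: str = "patient"
    unit_of: dict[str, str] = field(default_factory=dict)

    def ids_in(self, split: str) -> list[str]:
        return [i for i, s in self.mapping.items() if s == split]


def tile_grid(
    width: int,
    height: int,
    tile_side: int = 1024,
    overlap: float = 0.25,
    slide_id: str = "",
) -> TileGrid:
    """Regular tessellation with overlapping tiles; partial edge tiles dropped.

    stride = round(tile_side * (1 - overlap)); a slide smaller than one
    tile yields an empty grid rather than an error.
    """
    if tile_side < 1:
        raise ValueError("tile_side must be >= 1")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    stride = max(1, int(round(tile_side * (1.0 - overlap))))
    origins = [
        (x, y)
        for y in range(0, height - tile_side + 1, stride)
        for x in range(0, width - tile_side + 1, stride)
    ]
    return TileGrid(slide_id=slide_id, tile_side=tile_side, overlap=overlap,
                    origins=origins)


def whitespace_fraction(tile: np.ndarray) -> float:
    """Fraction of pixels whose R, G and B are all >= 220 (near-white).

    Accepts an H x W x 3 uint8 array (or anything castable to it).
    """
    arr = np.asarray(tile)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    white = np.all(arr >= WHITE_LEVEL, axis=2)
    return float(white.mean())


def filter_whitespace(
    tiles: list[np.ndarray], threshold: float = 0.85
) -> list[int]:
    """Indices of tiles kept: whitespace fraction <= threshold.

    Removal is strict ("more than" the threshold), so a tile at exactly
    the threshold is kept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return [i for i, t in enumerate(tiles) if whitespace_fraction(t) <= threshold]


def top_n_groups(counts: dict, n: int) -> list:
    """Groups ranked by item count descending, ties by group id ascending.

    Used to restrict analysis to the largest sites so every class has
    enough samples for reliable probing and projection.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not counts:
        raise ValueError("empty counts")
    ranked = sorted(counts, key=lambda g: (-counts[g], str(g)))
    return ranked[: min(n, len(ranked))]


def balance_by_covariate(
    es: EmbeddingSet, group_var: str, covariate_var: str, seed: int = 0
) -> EmbeddingSet:
    """Equalize the (group x covariate) contingency table by subsampling.

    First drops covariate levels absent from any group (e.g. a tumor stage
    that only one site has), then subsamples every remaining cell down to
    the global minimum cell count. After balancing, group comparisons
    cannot be confounded by the covariate: every group has an identical
    covariate composition by construction.
    """
    g = np.array([str(v) for v in es.variable(group_var)], dtype=object)
    c = np.array([str(v) for v in es.variable(covariate_var)], dtype=object)
    groups = sorted(set(g))
    levels_by_group = {grp: set(c[g == grp]) for grp in groups}
    common = set.intersection(*levels_by_group.values()) if groups else set()
    if not common:
        # blame the group(s) that disagree with what the rest share
        offenders = []
        for grp in groups:
            others = [levels_by_group[o] for o in groups if o != grp]
            shared_by_others = set.intersection(*others) if others else set()
            if not (levels_by_group[grp] & shared_by_others):
                offenders.append(grp)
        raise ValueError(
            "no covariate level common to all groups; offending group(s): "
            f"{offenders or groups}"
        )
    keep_level = np.isin(c, sorted(common))
    cells: dict[tuple[str, str], np.ndarray] = {}
    for grp in groups:
        for lev in sorted(common):
            cells[(grp, lev)] = np.flatnonzero((g == grp) & (c == lev) & keep_level)
    min_count = min(len(v) for v in cells.values())
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for key in sorted(cells):  # fixed iteration order for reproducibility
        pool = cells[key]
        chosen.extend(rng.choice(pool, size=min_count, replace=False).tolist())
    chosen = sorted(chosen)  # preserve original row order
    return subset(es, [es.ids[i] for i in chosen])


def patient_disjoint_split(
    es: EmbeddingSet,
    unit_var: str = "patient",
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratify_by: str | None = None,
) -> SplitAssignment:
    """Assign whole units (patients) to train/validation/test.

    Units are shuffled by seed, then greedily assigned to the split whose
    current item-count shortfall relative to its target is largest; all of
    a unit's items follow it, so no patient leaks across splits. Per-split
    proportions deviate from targets by at most the largest unit's share.
    Zero fractions are allowed (that split stays empty).

    With ``stratify_by`` (e.g. "site"), the greedy assignment runs
    independently within each stratum, so every split reproduces the
    stratum proportions of the whole set. This matters when probing a
    class-valued variable at chance level: an unstratified split can leave
    train and test class proportions anti-correlated, which biases
    held-out accuracy *below* chance even for pure-noise features.
    """
    if stratify_by is not None:
        strata = np.array([str(v) for v in es.variable(stratify_by)], dtype=object)
        mapping: dict[str, str] = {}
        unit_of: dict[str, str] = {}
        for j, stratum in enumerate(sorted(set(strata))):
            ids = [es.ids[i] for i in np.flatnonzero(strata == stratum)]
            part = patient_disjoint_split(
                subset(es, ids), unit_var, fractions, seed + j, stratify_by=None
            )
            mapping.update(part.mapping)
            unit_of.update(part.unit_of)
        mapping = {i: mapping[i] for i in es.ids}  # restore original order
        return SplitAssignment(
            mapping=mapping, fractions=tuple(float(f) for f in fractions),
            unit=unit_var, unit_of=unit_of,
        )
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be 3 non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    units = np.array([str(v) for v in es.variable(unit_var)], dtype=object)
    unit_names = sorted(set(units))
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(unit_names) < n_nonzero:
        raise ValueError(
            f"{len(unit_names)} units cannot fill {n_nonzero} non-empty splits"
        )
    sizes = {u: int((units == u).sum()) for u in unit_names}
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unit_names))
    split_names = ("train", "validation", "test")
    targets = [f * es.n for f in fractions]
    filled = [0.0, 0.0, 0.0]
    unit_of: dict[str, str] = {}
    for u in order:
        shortfalls = [
            (targets[k] - filled[k]) if fractions[k] > 0 else -np.inf
            for k in range(3)
        ]
        k = int(np.argmax(shortfalls))
        unit_of[u] = split_names[k]
        filled[k] += sizes[u]
    mapping = {es.ids[i]: unit_of[units[i]] for i in range(es.n)}
    return SplitAssignment(
        mapping=mapping, fractions=fractions, unit=unit_var, unit_of=unit_of
    )
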