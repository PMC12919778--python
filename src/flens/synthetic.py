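"""Synthetic embeddings and toy tiles with controllable batch-effect structure.

The generator emulates the setting in which batch effects are studied in
histopathology: a handful of tissue source sites, a few tumor-stage
classes, and a patient/slide/tile hierarchy (every tile inherits its
patient's site and stage). Each tile's feature vector is

    x = class_sep * mu_c + delta * v_s + sigma * eps,

where ``mu_c`` are fixed orthonormal class directions, ``v_s`` fixed
orthonormal site directions orthogonal to all class directions, and eps is
i.i.d. standard normal noise. Because the two signals live in orthogonal
subspaces, the site batch effect has an analytically known geometry
(site-centroid distances delta * sqrt(2)) and is independent of the class
signal by construction — balancing classes cannot change site
separability. ``delta`` is the single dial for how much batch effect an
encoder "leaked" into its embedding space; delta = 0 is a clean encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import EmbeddingSet

__all__ = ["SyntheticConfig", "gen_embeddings", "gen_tiles"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters.

    Defaults mirror the five-site, three-stage study layout with a
    patient/slide hierarchy (5 sites x 10 patients x 2 slides x 50 tiles
    = 5000 items) at unit noise. ``d`` defaults to 64 for desk-scale work;
    1536 is the encoder-realistic width.
    """

    n_sites: int = 5
    n_classes: int = 3
    d: int = 64
    patients_per_site: int = 10
    slides_per_patient: int = 2
    tiles_per_slide: int = 50
    delta: float = 1.0
    sigma: float = 1.0
    class_sep: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < self.n_classes + self.n_sites:
            raise ValueError(
                f"d={self.d} must be >= n_classes + n_sites "
                f"= {self.n_classes + self.n_sites}"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.delta < 0 or self.class_sep < 0:
            raise ValueError("delta and class_sep must be >= 0")

    @property
    def n_items(self) -> int:
        return (
            self.n_sites
            * self.patients_per_site
            * self.slides_per_patient
            * self.tiles_per_slide
        )


def gen_embeddings(config: SyntheticConfig) -> EmbeddingSet:
    """Draw a fully seeded embedding set from ``config``.

    Class directions are the first ``n_classes`` standard basis vectors and
    site directions the next ``n_sites`` (orthonormal, mutually orthogonal).
    Stage classes are assigned uniformly at the *patient* level, so all of
    a patient's tiles share one stage, mirroring the clinical hierarchy
    that patient-disjoint splitting must respect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_items
    d = config.d
    feats = rng.normal(0.0, config.sigma, size=(n, d))

    ids, sites, stages, patients, slides = [], [], [], [], []
    row = 0
    for s in range(config.n_sites):
        site = f"site{s:02d}"
        for p in range(config.patients_per_site):
            patient = f"{site}_p{p:03d}"
            stage = int(rng.integers(0, config.n_classes))
            for sl in range(config.slides_per_patient):
                slide = f"{patient}_s{sl}"
                for t in range(config.tiles_per_slide):
                    ids.append(f"{slide}_t{t:04d}")
                    sites.append(site)
                    stages.append(f"stage{stage}")
                    patients.append(patient)
                    slides.append(slide)
                    feats[row, stage] += config.class_sep
                    feats[row, config.n_classes + s] += config.delta
                    row += 1

    meta = pd.DataFrame(
        {"site": sites, "stage": stages, "patient": patients, "slide": slides}
    )
    return EmbeddingSet(ids=ids, features=feats, metadata=meta)


def gen_tiles(
    n: int, side: int, white_fractions: list[float], seed: int = 0
) -> tuple[list[np.ndarray], list[float]]:
    """Toy RGB tiles with exact, known whitespace content.

    Tile i gets exactly ``round(white_fractions[i % len] * side**2)`` white
    pixels (255 on all channels) at seeded-random positions; all other
    pixels are dark (50 on all channels). Returns the tiles and the true
    realized whitespace fractions.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    for f in white_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} not in [0, 1]")
    rng = np.random.default_rng(seed)
    tiles, fractions = [], []
    for i in range(n):
        frac = white_fractions[i % len(white_fractions)]
        n_white = int(round(frac * side * side))
        tile = np.full((side, side, 3), 50, dtype=np.uint8)
        pos = rng.choice(side * side, size=n_white, replace=False)
        tile.reshape(-1, 3)[pos] = 255
        tiles.append(tile)
        fractions.append(n_white / (side * side))
    return tiles, fractions
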