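import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flens import (
    EmbeddingSet,
    balance_by_covariate,
    filter_whitespace,
    gen_tiles,
    patient_disjoint_split,
    tile_grid,
    top_n_groups,
    whitespace_fraction,
)


class TestTileGrid:
    def test_single_exact_tile(self):
        g = tile_grid(1024, 1024, 1024, 0.25)
        assert g.origins == [(0, 0)]

    def test_quarter_overlap_stride(self):
        # stride = round(1024 * 0.75) = 768 -> two columns fit in 1792
        g = tile_grid(1792, 1024, 1024, 0.25)
        assert g.origins == [(0, 0), (768, 0)]
        assert g.stride == 768

    def test_slide_smaller_than_tile_gives_empty_grid(self):
        assert tile_grid(1000, 1000, 1024, 0.25).origins == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        w=st.integers(1, 5000),
        h=st.integers(1, 5000),
        side=st.integers(1, 1200),
        overlap=st.floats(0.0, 0.9),
    )
    def test_origin_count_formula(self, w, h, side, overlap):
        g = tile_grid(w, h, side, overlap)
        stride = max(1, round(side * (1 - overlap)))
        if w < side or h < side:
            assert g.origins == []
        else:
            nx = (w - side) // stride + 1
            ny = (h - side) // stride + 1
            assert len(g.origins) == nx * ny
        for x, y in g.origins:
            assert x + side <= w and y + side <= h


class TestWhitespace:
    def test_extremes(self):
        white = np.full((8, 8, 3), 255, dtype=np.uint8)
        black = np.zeros((8, 8, 3), dtype=np.uint8)
        assert whitespace_fraction(white) == 1.0
        assert whitespace_fraction(black) == 0.0

    def test_constructed_fraction_exact(self):
        tiles, fracs = gen_tiles(1, 10, [0.84], seed=0)
        assert fracs == [0.84]
        assert whitespace_fraction(tiles[0]) == pytest.approx(0.84)

    def test_threshold_is_strictly_greater(self):
        tiles, _ = gen_tiles(3, 10, [0.0, 0.85, 1.0], seed=1)
        assert filter_whitespace(tiles, threshold=0.85) == [0, 1]

    def test_near_white_pixels_count(self):
        # all channels exactly at the 220 cutoff counts as whitespace
        tile = np.full((4, 4, 3), 220, dtype=np.uint8)
        assert whitespace_fraction(tile) == 1.0
        tile[:, :, 0] = 219  # one channel below -> not whitespace
        assert whitespace_fraction(tile) == 0.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            whitespace_fraction(np.empty((0, 0, 3), dtype=np.uint8))


class TestTopNGroups:
    def test_site_ranking_by_tile_count(self):
        counts = {22: 19499, 39: 32686, 60: 19300, 66: 25694, 85: 49355}
        assert top_n_groups(counts, 5) == [85, 39, 66, 22, 60]

    def test_n_larger_than_group_count(self):
        assert top_n_groups({"a": 1, "b": 2}, 10) == ["b", "a"]

    def test_tie_broken_lexicographically(self):
        assert top_n_groups({"B": 10, "A": 10}, 1) == ["A"]

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            top_n_groups({}, 1)


def _hier_set(cells: dict[tuple[str, str], int], seed=0) -> EmbeddingSet:
    """Build a set with given (group, stage) cell counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for (g, s), count in cells.items():
        for k in range(count):
            rows.append((f"{g}_{s}_{k}", g, s))
    ids, groups, stages = zip(*rows)
    return EmbeddingSet(
        list(ids),
        rng.normal(size=(len(ids), 3)),
        pd.DataFrame({"site": groups, "stage": stages,
                      "patient": [i.rsplit("_", 1)[0] for i in ids]}),
    )


class TestBalanceByCovariate:
    def test_already_balanced_unchanged_counts(self):
        es = _hier_set({("g1", "s1"): 10, ("g1", "s2"): 10,
                        ("g2", "s1"): 10, ("g2", "s2"): 10})
        out = balance_by_covariate(es, "site", "stage", seed=0)
        table = pd.crosstab(out.metadata["site"], out.metadata["stage"])
        assert (table.to_numpy() == 10).all()

    def test_min_cell_equalization(self):
        es = _hier_set({("g1", "s1"): 5, ("g1", "s2"): 9,
                        ("g2", "s1"): 7, ("g2", "s2"): 5})
        out = balance_by_covariate(es, "site", "stage", seed=0)
        table = pd.crosstab(out.metadata["site"], out.metadata["stage"])
        assert (table.to_numpy() == 5).all()

    def test_level_missing_from_one_group_dropped(self):
        # stage IV exists only in g2: dropped before balancing
        es = _hier_set({("g1", "I"): 6, ("g1", "II"): 6,
                        ("g2", "I"): 6, ("g2", "II"): 6, ("g2", "IV"): 4})
        out = balance_by_covariate(es, "site", "stage", seed=0)
        assert "IV" not in set(out.metadata["stage"])
        table = pd.crosstab(out.metadata["site"], out.metadata["stage"])
        assert sorted(table.columns) == ["I", "II"]
        assert (table.to_numpy() == 6).all()

    def test_group_sharing_no_level_is_named(self):
        es = _hier_set({("g1", "s1"): 3, ("g2", "s2"): 3})
        with pytest.raises(ValueError, match="g"):
            balance_by_covariate(es, "site", "stage")

    def test_identical_contingency_rows_invariant(self):
        rng = np.random.default_rng(5)
        cells = {
            (f"g{i}", f"s{j}"): int(rng.integers(3, 12))
            for i in range(4) for j in range(3)
        }
        out = balance_by_covariate(_hier_set(cells), "site", "stage", seed=2)
        table = pd.crosstab(out.metadata["site"], out.metadata["stage"])
        assert (table.nunique(axis=0) == 1).all()

    def test_seeded_reproducibility(self):
        es = _hier_set({("g1", "s1"): 5, ("g1", "s2"): 9,
                        ("g2", "s1"): 7, ("g2", "s2"): 5})
        a = balance_by_covariate(es, "site", "stage", seed=3)
        b = balance_by_covariate(es, "site", "stage", seed=3)
        assert a.ids == b.ids


def _patient_set(n_patients=10, tiles_per_patient=10, seed=0):
    rng = np.random.default_rng(seed)
    ids, patients = [], []
    for p in range(n_patients):
        for t in range(tiles_per_patient):
            ids.append(f"p{p}_t{t}")
            patients.append(f"p{p}")
    return EmbeddingSet(ids, rng.normal(size=(len(ids), 2)),
                        pd.DataFrame({"patient": patients}))


class TestPatientDisjointSplit:
    def test_single_unit_goes_to_train(self):
        es = _patient_set(n_patients=1)
        sp = patient_disjoint_split(es, fractions=(1.0, 0.0, 0.0))
        assert set(sp.mapping.values()) == {"train"}

    def test_equal_units_match_targets_within_one_unit(self):
        es = _patient_set(n_patients=10, tiles_per_patient=10)
        sp = patient_disjoint_split(es, seed=4)
        counts = pd.Series(sp.mapping).value_counts()
        assert counts["train"] == 70
        assert {counts.get("validation", 0), counts.get("test", 0)} <= {10, 20}
        assert counts.sum() == 100

    def test_patients_never_straddle_splits(self):
        for seed in range(10):
            es = _patient_set(n_patients=13, tiles_per_patient=7, seed=seed)
            sp = patient_disjoint_split(es, seed=seed)
            df = pd.DataFrame(
                {"patient": [i.split("_")[0] for i in sp.mapping],
                 "split": list(sp.mapping.values())}
            )
            assert (df.groupby("patient")["split"].nunique() == 1).all()

    def test_proportion_deviation_bounded_by_largest_unit(self):
        rng = np.random.default_rng(9)
        ids, patients = [], []
        sizes = rng.integers(1, 30, size=12)
        for p, size in enumerate(sizes):
            for t in range(size):
                ids.append(f"p{p}_t{t}")
                patients.append(f"p{p}")
        es = EmbeddingSet(ids, rng.normal(size=(len(ids), 2)),
                          pd.DataFrame({"patient": patients}))
        sp = patient_disjoint_split(es, seed=1)
        counts = pd.Series(sp.mapping).value_counts()
        n = len(ids)
        for split, frac in zip(("train", "validation", "test"),
                               sp.fractions):
            dev = abs(counts.get(split, 0) - frac * n)
            assert dev <= sizes.max()

    def test_stratified_split_preserves_stratum_shares(self):
        rng = np.random.default_rng(2)
        ids, patients, sites = [], [], []
        for s in range(4):
            for p in range(8):
                for t in range(5):
                    ids.append(f"s{s}p{p}t{t}")
                    patients.append(f"s{s}p{p}")
                    sites.append(f"s{s}")
        es = EmbeddingSet(ids, rng.normal(size=(len(ids), 2)),
                          pd.DataFrame({"patient": patients, "site": sites}))
        sp = patient_disjoint_split(es, fractions=(0.5, 0.0, 0.5), seed=0,
                                    stratify_by="site")
        df = pd.DataFrame({"site": sites,
                           "split": [sp.mapping[i] for i in ids]})
        table = pd.crosstab(df["site"], df["split"])
        assert (table["train"] == 20).all()
        assert (table["test"] == 20).all()

    def test_too_few_units_rejected(self):
        es = _patient_set(n_patients=2)
        with pytest.raises(ValueError):
            patient_disjoint_split(es, fractions=(0.4, 0.3, 0.3))

    def test_bad_fractions_rejected(self):
        es = _patient_set()
        with pytest.raises(ValueError):
            patient_disjoint_split(es, fractions=(0.5, 0.2, 0.2))

    def test_seeded_reproducibility(self):
        es = _patient_set(n_patients=9, tiles_per_patient=4)
        a = patient_disjoint_split(es, seed=6)
        b = patient_disjoint_split(es, seed=6)
        assert a.mapping == b.mapping
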