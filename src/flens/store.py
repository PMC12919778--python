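"""Embedding tables with aligned categorical metadata.

The universal currency of the toolkit is the :class:`EmbeddingSet`: one row
per item (e.g. a whole-slide-image tile), a numeric feature vector produced
by some frozen encoder, and categorical metadata such as tissue source site,
tumor stage, patient and slide identifiers.

Two on-disk dialects are supported:

* delimited text (TSV/CSV) with a header of one ``id`` column, zero or more
  ``meta_*`` columns and feature columns ``f0 … f{d-1}`` — self-describing
  and greppable;
* a columnar binary container (Parquet) storing the feature matrix as
  float32, which round-trips exactly.

Features are canonicalized to float32 in memory, so both dialects are
lossless round-trips (text is written with 9 significant digits, enough to
reproduce any float32 exactly).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmbeddingSet",
    "VariableSpec",
    "load_embeddings",
    "save_embeddings",
    "pixels_as_embeddings",
    "subset",
]

_META_PREFIX = "meta_"
_NA_LEVEL = "NA"


@dataclass(frozen=True)
class VariableSpec:
    """A metadata variable to analyze.

    ``role`` distinguishes sensitive/bias variables (e.g. tissue source
    site), which a model *should not* encode, from prognostic variables
    (e.g. tumor stage), which it legitimately may.
    """

    name: str
    role: str = "bias"

    def __post_init__(self) -> None:
        if self.role not in ("bias", "prognostic"):
            raise ValueError(f"role must be 'bias' or 'prognostic', got {self.role!r}")


@dataclass
class EmbeddingSet:
    """n items x d features with ids and per-item categorical metadata.

    Invariants enforced at construction: ids are unique and align with the
    feature rows and metadata rows; every feature value is finite; every
    metadata cell is a string (missing values are materialized as the
    explicit level ``"NA"`` so row alignment stays trivially checkable).
    """

    ids: list[str]
    features: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        feats = np.asarray(self.features)
        if feats.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {feats.shape}")
        self.features = np.ascontiguousarray(feats, dtype=np.float32)
        if len(self.ids) != self.features.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.features.shape[0]} feature rows"
            )
        seen: set[str] = set()
        for i in self.ids:
            if i in seen:
                raise ValueError(f"duplicate id: {i!r}")
            seen.add(i)
        if not np.all(np.isfinite(self.features)):
            r, c = np.argwhere(~np.isfinite(self.features))[0]
            raise ValueError(f"non-finite feature value at row {r}, column {c}")
        if self.metadata is None or len(self.metadata.columns) == 0:
            self.metadata = pd.DataFrame(index=range(len(self.ids)))
        if len(self.metadata) != len(self.ids):
            raise ValueError(
                f"{len(self.metadata)} metadata rows but {len(self.ids)} ids"
            )
        self.metadata = self.metadata.reset_index(drop=True)
        for col in self.metadata.columns:
            vals = self.metadata[col]
            self.metadata[col] = (
                vals.astype(object).where(vals.notna(), _NA_LEVEL).astype(str)
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def feature_dim(self) -> int:
        return int(self.features.shape[1])

    def variable(self, name: str) -> np.ndarray:
        """Metadata column ``name`` as an array of strings."""
        if name not in self.metadata.columns:
            raise KeyError(
                f"variable {name!r} not in metadata "
                f"(have: {sorted(self.metadata.columns)})"
            )
        return self.metadata[name].to_numpy(dtype=object)

    def source_hash(self) -> str:
        """SHA-256 digest of the feature matrix bytes (provenance tag)."""
        return hashlib.sha256(self.features.tobytes()).hexdigest()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmbeddingSet):
            return NotImplemented
        return (
            self.ids == other.ids
            and np.array_equal(self.features, other.features)
            and list(self.metadata.columns) == list(other.metadata.columns)
            and self.metadata.equals(other.metadata)
        )


def _to_frame(es: EmbeddingSet) -> pd.DataFrame:
    cols: dict[str, object] = {"id": es.ids}
    for c in es.metadata.columns:
        cols[_META_PREFIX + str(c)] = es.metadata[c].to_numpy()
    for j in range(es.feature_dim):
        cols[f"f{j}"] = es.features[:, j]
    return pd.DataFrame(cols)


def _from_frame(df: pd.DataFrame, source: str) -> EmbeddingSet:
    if "id" not in df.columns:
        raise ValueError(f"{source}: header must declare an 'id' column")
    meta_cols = [c for c in df.columns if c.startswith(_META_PREFIX)]
    feat_cols = [c for c in df.columns if c != "id" and c not in meta_cols]
    ids = df["id"].astype(str).tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if len(dup):
        raise ValueError(f"{source}: duplicate id: {dup.iloc[0]!r}")
    feats = np.empty((len(df), len(feat_cols)), dtype=np.float32)
    for j, c in enumerate(feat_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            r = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{source}: non-numeric feature value {df[c].iloc[r]!r} "
                f"at row {r}, column {c!r}"
            )
        feats[:, j] = col.to_numpy()
    meta = df[meta_cols].rename(columns=lambda c: c[len(_META_PREFIX):])
    return EmbeddingSet(ids=ids, features=feats, metadata=meta)


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "csv", "binary"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    p = str(path).lower()
    if p.endswith(".csv"):
        return "csv"
    if p.endswith((".parquet", ".bin", ".pq")):
        return "binary"
    return "tsv"


def load_embeddings(path: str, format: str | None = None) -> EmbeddingSet:
    """Read an embedding table from ``path`` and validate it.

    Format is inferred from the extension unless given explicitly
    (``tsv``, ``csv`` or ``binary``). Row order is preserved.
    """
    fmt = _infer_format(path, format)
    if fmt == "binary":
        df = pd.read_parquet(path)
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
    return _from_frame(df, source=str(path))


def save_embeddings(es: EmbeddingSet, path: str, format: str | None = None) -> str:
    """Write ``es`` to ``path``; the file round-trips through ``load_embeddings``."""
    fmt = _infer_format(path, format)
    df = _to_frame(es)
    if fmt == "binary":
        df.to_parquet(path, index=False)
    else:
        sep = "\t" if fmt == "tsv" else ","
        # 9 significant digits reproduce any float32 exactly on re-parse
        df.to_csv(path, sep=sep, index=False, float_format="%.9g")
    return str(path)


def pixels_as_embeddings(image_paths: list[str], target_side: int) -> EmbeddingSet:
    """Flatten raw tile pixels into feature vectors for side-by-side views.

    Each image is resized to ``target_side x target_side`` by area averaging
    (box filter), converted to RGB, flattened row-major channel-last, and
    scaled to [0, 1]; the resulting vectors have length ``3 * target_side**2``.
    This gives a projection input that uses *only the raw pixels*, the
    control against which encoder embeddings are compared.
    """
    from PIL import Image

    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    ids, rows = [], []
    for p in image_paths:
        try:
            with Image.open(p) as im:
                im = im.convert("RGB").resize(
                    (target_side, target_side), resample=Image.Resampling.BOX
                )
                arr = np.asarray(im, dtype=np.float32) / 255.0
        except Exception as exc:  # noqa: BLE001 - re-raise with the file name
            raise ValueError(f"cannot decode image {p!r}: {exc}") from exc
        ids.append(str(p))
        rows.append(arr.reshape(-1))
    feats = (
        np.stack(rows) if rows else np.empty((0, 3 * target_side**2), np.float32)
    )
    return EmbeddingSet(ids=ids, features=feats)


def subset(es: EmbeddingSet, ids: list[str]) -> EmbeddingSet:
    """Rows of ``es`` for ``ids``, in the requested order, metadata aligned."""
    index = {i: k for k, i in enumerate(es.ids)}
    rows = []
    for i in ids:
        if i not in index:
            raise KeyError(f"unknown id: {i!r}")
        rows.append(index[i])
    return EmbeddingSet(
        ids=[es.ids[r] for r in rows],
        features=es.features[rows],
        metadata=es.metadata.iloc[rows].reset_index(drop=True),
    )
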