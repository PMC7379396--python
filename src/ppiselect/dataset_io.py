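"""Labeled protein-pair feature tables and the dataset-identity diagnostic.

A :class:`FeatureTable` is the currency of the whole pipeline: one row per
protein pair, one column per real-valued feature, and a binary label
(``positive`` = interacting, ``negative`` = non-interacting).

The identity diagnostic measures dataset redundancy: the identity of two
pairs is the direction cosine (cosine similarity) of their feature vectors,
and its distribution over all (or sampled) row pairs is histogrammed with a
fixed 0.1 step over [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableParseError, UndefinedIdentityError, ValidationError

POSITIVE = "positive"
NEGATIVE = "negative"
LABEL_COLUMN = "label"
_LABEL_CODES = {NEGATIVE: 0, POSITIVE: 1}
_SEPARATORS = {"csv": ",", "tsv": "\t"}


@dataclass
class FeatureTable:
    """Labeled matrix of protein-pair feature vectors.

    Parameters
    ----------
    row_ids
        Pair identifiers, e.g. ``"P12345-Q67890"``.
    feature_names
        Unique column names.
    X
        Float matrix of shape ``(len(row_ids), len(feature_names))``.
    y
        Integer labels, 1 for the positive (interacting) class, 0 otherwise.
    """

    row_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.ndim != 2:
            raise ValidationError("values matrix must be 2-dimensional")
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValidationError("duplicate feature names")
        if self.X.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValidationError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.row_ids)} row ids x {len(self.feature_names)} features"
            )
        if self.y.shape != (len(self.row_ids),):
            raise ValidationError("every row must have a label")
        if not np.isin(self.y, (0, 1)).all():
            raise ValidationError("labels must be 0 (negative) or 1 (positive)")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(self.n_rows - self.y.sum())

    def subset_rows(self, indices: np.ndarray) -> "FeatureTable":
        indices = np.asarray(indices)
        return FeatureTable(
            [self.row_ids[i] for i in indices],
            list(self.feature_names),
            self.X[indices],
            self.y[indices],
        )

    def subset_features(self, indices: "list[int] | np.ndarray") -> "FeatureTable":
        indices = list(indices)
        return FeatureTable(
            list(self.row_ids),
            [self.feature_names[i] for i in indices],
            self.X[:, indices],
            self.y.copy(),
        )

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "pair_id", self.row_ids)
        df[LABEL_COLUMN] = [POSITIVE if v else NEGATIVE for v in self.y]
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.y, other.y)
        )


@dataclass(frozen=True)
class IdentityHistogram:
    """Histogram of pairwise direction-cosine identities, 0.1-wide bins on [-1, 1]."""

    bin_edges: np.ndarray  # 21 edges, -1.0 .. 1.0
    counts: np.ndarray  # 20 nonnegative integers
    n_pairs: int

    def __post_init__(self) -> None:
        if len(self.bin_edges) != 21 or len(self.counts) != 20:
            raise ValidationError("expected 21 edges and 20 counts")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValidationError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_pairs:
            raise ValidationError("counts must sum to the number of compared pairs")

    def to_frame(self) -> pd.DataFrame:
        mids = (np.asarray(self.bin_edges[:-1]) + np.asarray(self.bin_edges[1:])) / 2
        return pd.DataFrame({"bin_midpoint": mids, "count": self.counts})


def read_table(path: str | Path, dialect: str = "csv") -> FeatureTable:
    """Read a labeled feature table from a delimited text file.

    Layout: header row; first column is the pair id, a column named
    ``label`` holds ``positive``/``negative``, every other column is a
    numeric feature.  Missing or non-numeric cells are rejected with
    row/column coordinates.
    """
    sep = _separator(dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TableParseError(f"malformed file: {exc}") from exc
    if df.shape[1] < 2:
        raise TableParseError("header must contain a pair-id column and a 'label' column")
    if LABEL_COLUMN not in df.columns:
        raise TableParseError(f"missing required column {LABEL_COLUMN!r}", column=LABEL_COLUMN)
    id_col = df.columns[0]
    feature_cols = [c for c in df.columns if c not in (id_col, LABEL_COLUMN)]

    labels = np.empty(len(df), dtype=np.int8)
    for i, raw in enumerate(df[LABEL_COLUMN]):
        code = _LABEL_CODES.get(str(raw).strip().lower())
        if code is None:
            raise TableParseError(
                f"label must be '{POSITIVE}' or '{NEGATIVE}', got {raw!r}",
                row=i + 2,
                column=LABEL_COLUMN,
            )
        labels[i] = code

    X = np.empty((len(df), len(feature_cols)), dtype=np.float64)
    for j, col in enumerate(feature_cols):
        values = df[col].to_numpy()
        try:
            X[:, j] = values.astype(np.float64)
        except ValueError:
            for i, cell in enumerate(values):
                try:
                    float(cell)
                except ValueError:
                    raise TableParseError(
                        f"non-numeric or missing cell {cell!r}", row=i + 2, column=col
                    ) from None
            raise
    return FeatureTable(list(df[id_col].astype(str)), feature_cols, X, labels)


def write_table(table: FeatureTable, path: str | Path, dialect: str = "csv") -> None:
    """Write a feature table so that :func:`read_table` recovers an equal table."""
    if table.n_rows == 0:
        raise ValidationError("refusing to write an empty table")
    table.to_dataframe().to_csv(path, sep=_separator(dialect), index=False)


def pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Direction cosine a.b / (|a||b|) of two feature vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedIdentityError("direction cosine undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def identity_histogram(
    table: FeatureTable,
    pairs: str = "all_vs_all",
    n_sampled: int = 100_000,
    seed: int = 0,
) -> IdentityHistogram:
    """Histogram of pairwise identities over row pairs of ``table``.

    ``pairs="all_vs_all"`` compares every unordered row pair (O(n^2));
    ``pairs="sampled"`` draws ``n_sampled`` uniform random row pairs
    (i != j), for tables where all-vs-all is impractical.

    Bins are half-open ``[lo, hi)`` with the final bin closed at 1.0.
    """
    if table.n_rows < 2:
        raise ValidationError("identity histogram needs at least 2 rows")
    norms = np.linalg.norm(table.X, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise UndefinedIdentityError(
            f"row {table.row_ids[bad]!r} is a zero vector; identity undefined"
        )
    Xn = table.X / norms[:, None]

    if pairs == "all_vs_all":
        gram = Xn @ Xn.T
        iu = np.triu_indices(table.n_rows, k=1)
        values = gram[iu]
    elif pairs == "sampled":
        rng = np.random.default_rng(seed)
        i = rng.integers(0, table.n_rows, n_sampled)
        j = rng.integers(0, table.n_rows - 1, n_sampled)
        j = np.where(j >= i, j + 1, j)  # uniform over j != i
        values = np.einsum("ij,ij->i", Xn[i], Xn[j])
    else:
        raise ValidationError(f"pairs must be 'all_vs_all' or 'sampled', got {pairs!r}")

    values = np.clip(values, -1.0, 1.0)
    edges = np.round(np.linspace(-1.0, 1.0, 21), 10)
    counts, _ = np.histogram(values, bins=edges)  # final bin closed at 1.0
    return IdentityHistogram(edges, counts.astype(np.int64), int(values.size))


def _separator(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValidationError(f"dialect must be one of {sorted(_SEPARATORS)}, got {dialect!r}") from None
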