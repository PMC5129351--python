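"""Descriptor tables, correlation screening, and the train/test splitter.

A descriptor table is one row per compound: an identifier, a block of
named numeric molecular descriptors, and a binary carcinogenicity label
(1 = carcinogen, 0 = non-carcinogen).  The module covers delimited-text
I/O, pairwise Pearson correlation, the two descriptor pre-screening rules
(coverage and variability), the pairwise-collinearity filter at |r| < 0.8,
and the encoding-based random allocation of compounds to training and
test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "DescriptorTable",
    "CorrelationMatrix",
    "read_table",
    "write_table",
    "correlation_matrix",
    "collinearity_filter",
    "prefilter",
    "random_split",
]

ID_COLUMN = "compound"
LABEL_COLUMN = "label"


class TableFormatError(ValueError):
    """Malformed descriptor-table file (bad header, cell, or label)."""


@dataclass
class DescriptorTable:
    """Compounds x descriptors with an optional binary label vector."""

    ids: np.ndarray                 # compound identifiers (object dtype ok)
    X: pd.DataFrame                 # numeric descriptor block
    y: np.ndarray | None = None     # 0/1 labels, None for unlabeled tables

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        if len(self.ids) != len(self.X):
            raise TableFormatError("id / descriptor row count mismatch")
        if self.X.columns.duplicated().any():
            raise TableFormatError("duplicate descriptor column names")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if len(self.y) != len(self.X):
                raise TableFormatError("label / descriptor row count mismatch")
            bad = ~np.isin(self.y, (0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise TableFormatError(f"non-binary label in row {row}")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def descriptors(self) -> list[str]:
        return list(self.X.columns)

    @property
    def is_labeled(self) -> bool:
        return self.y is not None

    def class_counts(self) -> tuple[int, int]:
        """(positives, negatives); requires labels."""
        if self.y is None:
            raise TableFormatError("table has no labels")
        pos = int((self.y == 1).sum())
        return pos, len(self.y) - pos

    def env(self) -> dict[str, np.ndarray]:
        """Column arrays keyed by lowercase descriptor name (for rule evaluation)."""
        return {c.lower(): self.X[c].to_numpy(dtype=float) for c in self.X.columns}

    def subset(self, index: Sequence[int]) -> "DescriptorTable":
        idx = np.asarray(index)
        return DescriptorTable(
            self.ids[idx],
            self.X.iloc[idx].reset_index(drop=True),
            None if self.y is None else self.y[idx],
        )

    def select(self, columns: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(self.ids, self.X[list(columns)].copy(), self.y)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({ID_COLUMN: self.ids})
        frame = pd.concat([frame, self.X.reset_index(drop=True)], axis=1)
        if self.y is not None:
            frame[LABEL_COLUMN] = self.y
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, id_col: str = ID_COLUMN,
                   label_col: str | None = LABEL_COLUMN) -> "DescriptorTable":
        cols = list(frame.columns)
        if id_col in cols:
            ids = frame[id_col].to_numpy()
            cols.remove(id_col)
        else:
            ids = np.arange(1, len(frame) + 1)
        y = None
        if label_col is not None and label_col in cols:
            raw = frame[label_col]
            try:
                y = raw.astype(int).to_numpy()
            except (TypeError, ValueError) as exc:
                raise TableFormatError(f"non-numeric label column {label_col!r}") from exc
            if not np.isin(y, (0, 1)).all() or not (raw.astype(float) == y).all():
                row = int(np.flatnonzero(~np.isin(raw.astype(float), (0.0, 1.0)))[0])
                raise TableFormatError(f"non-binary label in row {row}")
            cols.remove(label_col)
        Xblock = frame[cols].copy()
        for c in cols:
            try:
                Xblock[c] = pd.to_numeric(Xblock[c])
            except (TypeError, ValueError) as exc:
                bad = pd.to_numeric(frame[c], errors="coerce")
                row = int(bad[bad.isna() & frame[c].notna()].index[0])
                raise TableFormatError(
                    f"non-numeric descriptor cell at row {row}, column {c!r}"
                ) from exc
        return cls(ids, Xblock.reset_index(drop=True), y)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","


def read_table(path: str | Path) -> DescriptorTable:
    """Read a delimited descriptor table (separator chosen by extension).

    Expects a header row ``compound, <descriptors...>[, label]``.  Lines
    starting with '#' are metadata comments and are skipped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), comment="#",
                            float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty or header-less file") from exc
    if frame.shape[1] < 2:
        raise TableFormatError(f"{path}: need an id column plus descriptors")
    try:
        return DescriptorTable.from_frame(frame)
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_table(table: DescriptorTable, path: str | Path,
                header_comments: Iterable[str] = ()) -> None:
    """Write a table as delimited text; optional '#' comment lines first."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        # repr gives the shortest exact representation: write/read round-trips
        table.to_frame().to_csv(fh, sep=sep, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# correlation screening

@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with named columns."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix must be square")
        if not self.names:
            self.names = [f"x{i + 1}" for i in range(k)]
        if len(self.names) != k:
            raise ValueError("name count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be 1")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def max_offdiag(self) -> float:
        off = np.abs(self.values - np.eye(self.k))
        return float(off.max()) if self.k > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def correlation_matrix(table: DescriptorTable) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the descriptor columns."""
    if table.n < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    X = table.X.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        col = table.descriptors[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"constant descriptor column {col!r}")
    return CorrelationMatrix(np.corrcoef(X, rowvar=False), table.descriptors)


def collinearity_filter(m: CorrelationMatrix, threshold: float = 0.8) -> list[str]:
    """Drop descriptors until every pairwise |r| is below the threshold.

    Greedy and deterministic: at each step take the worst offending pair
    (largest |r|, first in column order on ties) and drop the member with
    the larger mean absolute correlation to the other remaining columns
    (the later column on ties).  Returns the retained column names in
    their original order.
    """
    keep = list(range(m.k))
    vals = np.abs(m.values)
    while len(keep) > 1:
        sub = vals[np.ix_(keep, keep)]
        np.fill_diagonal(sub, 0.0)
        worst = float(sub.max())
        if worst < threshold:
            break
        i_loc, j_loc = np.unravel_index(int(sub.argmax()), sub.shape)
        if i_loc > j_loc:        # use the upper-triangle representative
            i_loc, j_loc = j_loc, i_loc
        others = [k for k in range(len(keep)) if k not in (i_loc, j_loc)]
        if others:
            mean_i = sub[i_loc, others].mean()
            mean_j = sub[j_loc, others].mean()
        else:
            mean_i = mean_j = 0.0
        # drop the more globally collinear member; tie -> the later column
        drop_loc = j_loc if mean_j >= mean_i else i_loc
        del keep[drop_loc]
    return [m.names[i] for i in keep]


def prefilter(table: DescriptorTable, min_coverage: float = 0.9,
              min_distinct: int = 2) -> DescriptorTable:
    """Descriptor pre-screening: keep columns defined for at least
    ``min_coverage`` of compounds and taking at least ``min_distinct``
    distinct values (constant columns carry no signal)."""
    kept = []
    for c in table.descriptors:
        col = table.X[c]
        if col.notna().mean() < min_coverage:
            continue
        if col.dropna().nunique() < min_distinct:
            continue
        kept.append(c)
    return table.select(kept)


# ---------------------------------------------------------------------------
# train/test allocation

def random_split(n_total: int, n_test: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random allocation by compound encoding.

    Compounds are encoded 1..n_total; ``n_test`` distinct random encodings
    form the test set, the remainder the training set.  Returns sorted
    1-based encoding arrays ``(train_ids, test_ids)``.
    """
    if n_total < 2 or not (1 <= n_test < n_total):
        raise ValueError(f"need 1 <= n_test < n_total, got {n_test}/{n_total}")
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(np.arange(1, n_total + 1), size=n_test, replace=False))
    train = np.setdiff1d(np.arange(1, n_total + 1), test)
    return train, test
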