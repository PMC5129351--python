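"""Synthetic descriptor tables with the benchmark's statistical structure.

The original descriptor values for the 128 benchmark compounds were never
published, so every pipeline stage is exercised on generated data that
emulates what the study assumed: eight descriptors whose pairwise Pearson
correlations follow the published 8x8 matrix, and binary labels produced
by a plantable ground-truth decision rule (value > 0 -> carcinogen) with
controllable independent label noise.

Descriptors are drawn as correlated standard Gaussians via a Cholesky
factor of the target correlation matrix; if rounding has pushed the
printed target off the positive-semidefinite cone it is repaired by
eigenvalue clipping and re-normalization to unit diagonal (the repair is
reported on the spec).  Gaussian marginals are a deliberate
simplification -- real atom-count descriptors are small non-negative
integers -- and an optional post-step rounds the two count columns for
workflows that care.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CorrelationMatrix, DescriptorTable, random_split
from .karva import ExpressionTree, Node
from .reference import DESCRIPTOR_NAMES, reference_correlations

__all__ = [
    "SyntheticSpec",
    "default_planted_rule",
    "gen_descriptors",
    "plant_labels",
    "make_study",
]

STUDY_SIZE = 128
STUDY_TEST_SIZE = 35
COUNT_COLUMNS = ("NCOS", "NNOS")


def default_planted_rule() -> ExpressionTree:
    """Planted ground truth: ncos + nnos > 0 (balanced for centered data)."""
    left = Node("ncos", None)
    right = Node("nnos", None)
    from .karva import _PRIMITIVES
    root = Node("+", _PRIMITIVES["+"])
    root.children = [left, right]
    return ExpressionTree(root)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic descriptor study."""

    n_compounds: int = STUDY_SIZE
    correlation: CorrelationMatrix | None = None    # None -> published matrix
    rule: ExpressionTree | None = None              # None -> ncos + nnos
    flip: float = 0.0                               # label-noise probability
    seed: int = 0
    discretize_counts: bool = False
    repaired: bool = field(default=False, init=False)  # set by gen_descriptors

    def __post_init__(self):
        if not 0.0 <= self.flip < 0.5:
            raise ValueError("flip probability must be in [0, 0.5)")

    def target(self) -> CorrelationMatrix:
        return self.correlation if self.correlation is not None else reference_correlations()

    def planted(self) -> ExpressionTree:
        return self.rule if self.rule is not None else default_planted_rule()


def _psd_factor(m: CorrelationMatrix) -> tuple[np.ndarray, bool]:
    """Cholesky-like factor of the target; eigenvalue-clip repair if needed."""
    vals = m.values
    try:
        return np.linalg.cholesky(vals), False
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(vals)
        w = np.clip(w, 1e-10, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        np.fill_diagonal(fixed, 1.0)
        return np.linalg.cholesky(fixed + 1e-12 * np.eye(m.k)), True


def gen_descriptors(spec: SyntheticSpec) -> DescriptorTable:
    """Unlabeled table of correlated Gaussian descriptors."""
    if spec.n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    target = spec.target()
    L, repaired = _psd_factor(target)
    spec.repaired = repaired
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n_compounds, target.k))
    X = Z @ L.T
    names = target.names if target.names else DESCRIPTOR_NAMES[:target.k]
    frame = pd.DataFrame(X, columns=names)
    if spec.discretize_counts:
        for c in COUNT_COLUMNS:
            if c in frame.columns:
                frame[c] = np.round(frame[c]).astype(float)
    ids = np.arange(1, spec.n_compounds + 1)
    return DescriptorTable(ids, frame, None)


def plant_labels(table: DescriptorTable, rule: ExpressionTree, flip: float,
                 rng: np.random.Generator) -> DescriptorTable:
    """Label by the planted rule (value > 0 -> 1), then flip with prob ``flip``."""
    if not 0.0 <= flip < 0.5:
        raise ValueError("flip probability must be in [0, 0.5)")
    missing = sorted(set(rule.variables()) - set(table.env()))
    if missing:
        raise ValueError(f"rule uses unknown descriptor(s) {missing}")
    vals = np.atleast_1d(rule.evaluate(table.env()))
    y = (vals > 0).astype(int)
    if flip > 0:
        flips = rng.random(len(y)) < flip
        y = np.where(flips, 1 - y, y)
    return DescriptorTable(table.ids, table.X.copy(), y)


def make_study(spec: SyntheticSpec) -> tuple[DescriptorTable, DescriptorTable]:
    """One full synthetic study: 128 labeled compounds allocated 93/35.

    Uses the encoding-based random splitter so the partition is exact,
    disjoint, and reproducible from the spec seed.
    """
    if spec.n_compounds != STUDY_SIZE:
        raise ValueError(f"a study uses exactly {STUDY_SIZE} compounds")
    table = gen_descriptors(spec)
    rng = np.random.default_rng(spec.seed + 1)   # label noise independent of draws
    labeled = plant_labels(table, spec.planted(), spec.flip, rng)
    train_ids, test_ids = random_split(STUDY_SIZE, STUDY_TEST_SIZE, spec.seed)
    train = labeled.subset(train_ids - 1)
    test = labeled.subset(test_ids - 1)
    return train, test
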