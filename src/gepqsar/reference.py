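"""Packaged reference data from the published aromatic-amine benchmark.

The study this package re-implements reports, for 128 fused-ring aromatic
amines (35 rat-liver carcinogens, 93 non-carcinogens): the pairwise
correlation matrix of the eight retained molecular descriptors, the
per-compound observed and predicted labels for its 93-compound training
and 35-compound test allocations, the four-row screening-metric summary,
and one evolved classification rule over the descriptors

    x1=NCOS  x2=NNOS  x3=KFBI  x4=BBI  x5=SICI  x6=TEIA  x7=PLPT  x8=LUMO

(number of C atoms, number of N atoms, Kier flexibility index, Balaban
index, structural information content index order 0, topographic
electronic index over all bonds, polarity parameter, LUMO energy).  The
descriptor values themselves were computed with a commercial toolchain
and are not published, so the rule cannot be re-evaluated on the original
compounds; it ships here as a frozen expression tree for study and for
exercising the evaluator.

Two typographic ambiguities in the printed rule are resolved by explicit,
named interpretations (see :func:`reference_rule`); neither is a claim
about the original software's internal model.

Known internal inconsistency, preserved verbatim: recomputing accuracy
from the per-compound GEP prediction columns gives ~0.656 (training) and
~0.686 (test), not the summary table's 0.914 / 0.829, while the MLP
columns reproduce their summary accuracies to within printed rounding
(0.839 recomputed vs 0.838 training; 0.743 test exactly) -- though not
the summary sensitivity/specificity pairs.
The summary table is treated as the metric ground truth; the prediction
columns are shipped unrepaired for transparency.  Likewise the summary
text states 24 training carcinogens where the training table contains 25
rows labeled 1.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .data import CorrelationMatrix
from .karva import ExpressionTree, Node, _PRIMITIVES

__all__ = [
    "DESCRIPTOR_NAMES",
    "VARIABLE_ALIASES",
    "REPORTED_METRICS",
    "reference_correlations",
    "reference_predictions",
    "reference_rule",
    "RULE_INTERPRETATIONS",
]

DESCRIPTOR_NAMES = ["NCOS", "NNOS", "KFBI", "BBI", "SICI", "TEIA", "PLPT", "LUMO"]

#: positional aliases x1..x8 for the descriptor schema
VARIABLE_ALIASES = {f"x{i + 1}": n for i, n in enumerate(DESCRIPTOR_NAMES)}

#: published screening-metric summary (Accuracy, Sensitivity, Specificity,
#: Youden's index) per method and split
REPORTED_METRICS = {
    "gep_train": {"accuracy": 0.914, "sensitivity": 0.947, "specificity": 0.905, "youden": 0.852},
    "gep_test": {"accuracy": 0.829, "sensitivity": 0.667, "specificity": 0.885, "youden": 0.552},
    "mlp_train": {"accuracy": 0.838, "sensitivity": 0.844, "specificity": 0.813, "youden": 0.657},
    "mlp_test": {"accuracy": 0.743, "sensitivity": 0.793, "specificity": 0.500, "youden": 0.293},
}

#: reported overall accuracies (abstract-level) for reference
REPORTED_ACCURACY = {"gep": (0.92, 0.82), "mlp": (0.84, 0.74)}


def _data_text(name: str) -> str:
    return resources.files("gepqsar").joinpath("data").joinpath(name).read_text()


def reference_correlations() -> CorrelationMatrix:
    """The published 8x8 descriptor Pearson-correlation matrix.

    The raw fixture preserves the source verbatim (upper triangle,
    Unicode minus signs, one entry printed as -0.18); values are
    normalized and symmetrized here.
    """
    lines = _data_text("descriptor_correlations.tsv").strip().splitlines()
    names = lines[0].split("\t")[1:]
    k = len(names)
    m = np.zeros((k, k))
    for i, line in enumerate(lines[1:]):
        cells = line.split("\t")[1:]
        # row i starts at the diagonal; leading cells are blank
        vals = [float(c.replace("−", "-")) for c in cells if c != ""]
        m[i, i:] = vals
    m = m + m.T - np.eye(k)
    return CorrelationMatrix(m, names)


def reference_predictions(split: str) -> pd.DataFrame:
    """Per-compound observed and predicted labels for a benchmark split.

    ``split`` is 'train' (93 compounds) or 'test' (35).  Columns:
    ``no, compound, label_observed, label_gep, label_mlp``.
    """
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    txt = _data_text(f"benchmark_{split}_predictions.tsv")
    from io import StringIO
    return pd.read_csv(StringIO(txt), sep="\t")


# ---------------------------------------------------------------------------
# the published evolved rule

def _n(tok: str, *children: Node) -> Node:
    sym = _PRIMITIVES.get(tok)
    if sym is None:
        return Node(tok, None)
    node = Node(tok, sym)
    node.children = list(children)
    return node


def _v(name: str) -> Node:
    return Node(name.lower(), None)


def _build_rule(juxtaposition: str) -> ExpressionTree:
    """Assemble the published rule under one juxtaposition reading.

    The printed formula contains two typographically ambiguous fragments:
    a tangent term written directly against a binary-mod bracket, and an
    'x5 mod(x3, x1)' grouping inside a log.  ``juxtaposition='product'``
    (default) reads both adjacencies as multiplication; ``'modulo'``
    reads them as an outer binary mod.  All operators are the package's
    protected primitives, so either reading is finite everywhere.
    """
    x = {i: _v(f"x{i}") for i in range(1, 9)}

    term1 = x[1]
    # tan( log(x8 + x5) - x1*x6 / (x3 + x2) )
    term2 = _n("tan", _n("-", _n("log", _n("+", x[8], x[5])),
                         _n("/", _n("*", x[1], x[6]), _n("+", x[3], x[2]))))
    # tan(x5 + x3) <juxt> mod(log(x6*x2), log(x8))
    tan_a = _n("tan", _n("+", x[5], x[3]))
    mod_a = _n("mod", _n("log", _n("*", x[6], x[2])), _n("log", x[8]))
    if juxtaposition == "product":
        term3 = _n("*", tan_a, mod_a)
    else:
        term3 = _n("mod", tan_a, mod_a)
    term4 = x[5]
    term5 = _n("tan", _n("-", _n("+", _n("+", x[2], x[3]), x[7]), x[1]))
    term6 = _n("tan", _n("-", _n("+", x[4], x[8]), x[1]))
    # tan( exp( log( x5 <juxt> mod(x3, x1) ) + x5 ) )
    mod_b = _n("mod", x[3], x[1])
    inner = _n("*", x[5], mod_b) if juxtaposition == "product" else _n("mod", x[5], mod_b)
    term7 = _n("tan", _n("exp", _n("+", _n("log", inner), x[5])))

    total = term1
    for t in (term2, term3, term4, term5, term6, term7):
        total = _n("+", total, t)
    return ExpressionTree(total)


RULE_INTERPRETATIONS = ("product", "modulo")


def reference_rule(interpretation: str = "product") -> ExpressionTree:
    """The published evolved classification rule as a frozen expression tree.

    A compound is predicted carcinogenic when the rule value exceeds 0.
    Variables are x1..x8 (see :data:`VARIABLE_ALIASES`).  The
    ``interpretation`` names how the two ambiguous printed fragments are
    parsed; see :func:`_build_rule`.
    """
    if interpretation not in RULE_INTERPRETATIONS:
        raise ValueError(f"interpretation must be one of {RULE_INTERPRETATIONS}")
    return _build_rule(interpretation)
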