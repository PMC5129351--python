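"""Screening-test evaluation: confusion counts, sensitivity/specificity,
Youden's index, predictive values, and the prediction-margin statistic.

The 2x2 screening table follows the epidemiological layout with the
carcinogen class as positive:

    A = true positives     B = false positives
    C = false negatives    D = true negatives

sensitivity = A/(A+C), specificity = D/(B+D), Youden's index =
sensitivity + specificity - 1.  The margin of a prediction is the
probability assigned to the actual class minus the largest probability
assigned to any wrong class; for a binary classifier with complementary
probabilities it equals 2*p(actual) - 1 and lies in [-1, 1], with values
near 1 indicating confident correct classification.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ScreeningMetrics",
    "confusion",
    "screening_metrics",
    "margin",
    "margins_from_proba",
    "metrics_report",
    "plot_margins",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Screening-table cells: tp=A, fp=B, fn=C, tn=D."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ScreeningMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    youden: float
    ppv: float
    npv: float

    def round3(self) -> "ScreeningMetrics":
        """Report rounding: 3 decimals, round-half-even."""
        return ScreeningMetrics(**{k: float(np.round(v, 3)) for k, v in asdict(self).items()})

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the 2x2 table with label 1 (carcinogen) as positive."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1 or len(yt) < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-d arrays")
    for name, arr in (("y_true", yt), ("y_pred", yp)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary values")
    yt = yt.astype(int)
    yp = yp.astype(int)
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
    )


def screening_metrics(c: ConfusionCounts) -> ScreeningMetrics:
    """All screening indices from one confusion table.

    Requires at least one actual positive and one actual negative, since
    sensitivity and specificity are otherwise undefined.
    """
    if c.tp + c.fn == 0:
        raise ValueError("no actual positives: sensitivity undefined")
    if c.fp + c.tn == 0:
        raise ValueError("no actual negatives: specificity undefined")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.fp + c.tn)
    return ScreeningMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        ppv=c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0,
        npv=c.tn / (c.fn + c.tn) if c.fn + c.tn else 0.0,
    )


def margin(p_actual: float, p_wrong_max: float) -> float:
    """Prediction margin: p(actual class) - max over wrong classes."""
    if not (0.0 <= p_actual <= 1.0 and 0.0 <= p_wrong_max <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p_actual - p_wrong_max)


def margins_from_proba(proba, y_true) -> pd.DataFrame:
    """Per-compound margins from an (n, 2) class-probability matrix.

    Column 0 holds p(class 0), column 1 p(class 1).  Returns a frame with
    1-based compound index and margin, mirroring a margin-curve export.
    """
    P = np.asarray(proba, dtype=float)
    yt = np.asarray(y_true, dtype=int)
    if P.ndim != 2 or P.shape[1] != 2 or len(P) != len(yt):
        raise ValueError("proba must be (n, 2) aligned with y_true")
    vals = [margin(P[i, yt[i]], P[i, 1 - yt[i]]) for i in range(len(yt))]
    return pd.DataFrame({"compound_index": np.arange(1, len(yt) + 1),
                         "margin": vals})


def metrics_report(per_split: dict[str, ScreeningMetrics]) -> pd.DataFrame:
    """Four-column evaluation report (one row per split), 3-dp rounded."""
    rows = {}
    for name, m in per_split.items():
        r = m.round3()
        rows[name] = {
            "Accuracy": r.accuracy,
            "Sensitivity": r.sensitivity,
            "Specificity": r.specificity,
            "Youden's Index": r.youden,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def plot_margins(margins: pd.DataFrame, path=None, ax=None, title=None):
    """Margin curve: compound sequence number against margin value.

    Needs matplotlib (optional dependency); returns the axis.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    ax.plot(margins["margin"], margins["compound_index"], ".-", ms=4)
    ax.set_xlabel("margin")
    ax.set_ylabel("compound")
    ax.set_xlim(-1.05, 1.05)
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
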