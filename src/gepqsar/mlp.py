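"""Single-hidden-layer perceptron baseline trained by backpropagation.

The network mirrors the conventional data-mining-workbench setup the
benchmark used: one hidden layer of sigmoid units whose size follows the
rule  a = floor((attributes + classes) / 2),  a softmax output layer,
online (per-pattern) gradient descent with momentum, z-scored inputs, and
early stopping on a held-out validation fraction with a patience counter.
Defaults: learning rate 0.3, momentum 0.2, validation fraction 0.2,
500 epochs, patience 20.

The same model/results split as :mod:`gepqsar.model` applies:
``MLPClassifier(table, config).fit()`` returns an :class:`MLPResults`
carrying weights, training curves, class probabilities and the
per-compound prediction margins used for margin curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import DescriptorTable
from .metrics import ScreeningMetrics, confusion, margins_from_proba, screening_metrics

__all__ = ["MLPConfig", "MLPClassifier", "MLPResults", "hidden_units"]


def hidden_units(attribs: int, classes: int) -> int:
    """Hidden-layer width rule a = floor((attribs + classes)/2), min 1."""
    if attribs < 1 or classes < 1:
        raise ValueError("attribute and class counts must be positive")
    return max(1, (attribs + classes) // 2)


@dataclass(frozen=True)
class MLPConfig:
    hidden: int | None = None        # None -> the (attribs+classes)/2 rule
    epochs: int = 500
    patience: int = 20               # epochs without validation improvement
    learning_rate: float = 0.3
    momentum: float = 0.2
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.patience < 1:
            raise ValueError("epochs >= 0 and patience >= 1 required")
        if self.epochs and self.patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0 or self.momentum < 0:
            raise ValueError("learning_rate > 0 and momentum >= 0 required")

    def as_dict(self) -> dict:
        return asdict(self)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MLPClassifier:
    """Perceptron baseline bound to a labeled descriptor table."""

    def __init__(self, data: DescriptorTable, config: MLPConfig | None = None):
        if not data.is_labeled:
            raise ValueError("training table must be labeled")
        pos, neg = data.class_counts()
        if pos == 0 or neg == 0:
            raise ValueError("training data must contain both classes")
        self.data = data
        self.config = config or MLPConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: MLPConfig | None = None) -> "MLPClassifier":
        return cls(DescriptorTable.from_frame(frame), config)

    def fit(self) -> "MLPResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        X = self.data.X.to_numpy(dtype=float)
        y = self.data.y
        n, d = X.shape

        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        T = np.eye(2)[y]                       # one-hot targets

        h = cfg.hidden if cfg.hidden is not None else hidden_units(d, 2)
        W1 = rng.normal(0.0, 0.5, size=(d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, 0.5, size=(h, 2))
        b2 = np.zeros(2)

        prior = np.array([(y == 0).mean(), (y == 1).mean()])
        if cfg.epochs == 0:
            # untrained network falls back to the class prior
            W2[:] = 0.0
            b2[:] = np.log(prior)
            return MLPResults(W1, b1, W2, b2, mu, sd, list(self.data.descriptors),
                              cfg, 0, [], [], self.data)

        # validation split for early stopping
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx, val_idx = perm, perm
        Xtr, Ttr = Xs[tr_idx], T[tr_idx]
        Xval, Tval = Xs[val_idx], T[val_idx]

        vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)
        lr, mom = cfg.learning_rate, cfg.momentum

        def forward(Xb):
            H = _sigmoid(Xb @ W1 + b1)
            return H, _softmax(H @ W2 + b2)

        def xent(Xb, Tb):
            _, P = forward(Xb)
            return float(-np.mean(np.sum(Tb * np.log(P + 1e-12), axis=1)))

        loss_history: list[float] = []
        val_history: list[float] = []
        best_val = np.inf
        best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
        stall = 0
        epochs_run = 0

        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(Xtr))
            for i in order:                      # online updates, one pattern each
                xi = Xtr[i]
                ti = Ttr[i]
                hi = _sigmoid(xi @ W1 + b1)
                pi = _softmax(hi @ W2 + b2)
                d2 = pi - ti                     # softmax + cross-entropy
                d1 = (W2 @ d2) * hi * (1.0 - hi)
                vW2 = mom * vW2 - lr * np.outer(hi, d2)
                vb2 = mom * vb2 - lr * d2
                vW1 = mom * vW1 - lr * np.outer(xi, d1)
                vb1 = mom * vb1 - lr * d1
                W2 += vW2; b2 += vb2; W1 += vW1; b1 += vb1
            loss_history.append(xent(Xtr, Ttr))
            val_loss = xent(Xval, Tval)
            val_history.append(val_loss)
            epochs_run = epoch
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:       # validation threshold reached
                    break

        W1, b1, W2, b2 = best
        return MLPResults(W1, b1, W2, b2, mu, sd, list(self.data.descriptors),
                          cfg, epochs_run, loss_history, val_history, self.data)


@dataclass
class MLPResults:
    """Trained perceptron with scaler, curves, and provenance."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    mean_: np.ndarray
    scale_: np.ndarray
    schema: list[str]
    config: MLPConfig
    epochs_run: int
    loss_history: list[float]
    val_history: list[float]
    train_data: DescriptorTable | None = None

    def _design(self, data) -> np.ndarray:
        if isinstance(data, DescriptorTable):
            frame = data.X
        elif isinstance(data, pd.DataFrame):
            frame = data
        else:
            raise ValueError("expected a DescriptorTable or DataFrame")
        missing = [c for c in self.schema if c not in frame.columns]
        if missing:
            raise ValueError(f"schema mismatch: missing descriptor column(s) {missing}")
        X = frame[self.schema].to_numpy(dtype=float)
        return (X - self.mean_) / self.scale_

    def predict_proba(self, data) -> np.ndarray:
        Xs = self._design(data)
        H = _sigmoid(Xs @ self.W1 + self.b1)
        return _softmax(H @ self.W2 + self.b2)

    def predict(self, data) -> np.ndarray:
        return self.predict_proba(data).argmax(axis=1)

    def margins(self, data: DescriptorTable) -> pd.DataFrame:
        """Margin records (compound index, p(actual) - p(best wrong))."""
        if not data.is_labeled:
            raise ValueError("margins need a labeled table")
        return margins_from_proba(self.predict_proba(data), data.y)

    def evaluate(self, data: DescriptorTable) -> ScreeningMetrics:
        if not data.is_labeled:
            raise ValueError("evaluation table must be labeled")
        return screening_metrics(confusion(data.y, self.predict(data)))

    def summary(self) -> str:
        lines = [
            "Multilayer-perceptron baseline",
            "=" * 54,
            f"descriptors:   {', '.join(self.schema)}",
            f"hidden units:  {self.W1.shape[1]}",
            f"epochs run:    {self.epochs_run} / {self.config.epochs}"
            f" (patience {self.config.patience})",
            f"learning rate: {self.config.learning_rate}"
            f"   momentum: {self.config.momentum}",
            f"seed:          {self.config.seed}",
        ]
        if self.train_data is not None and self.epochs_run > 0:
            m = self.evaluate(self.train_data).round3()
            lines += [
                "-" * 54,
                "training metrics:",
                f"  accuracy {m.accuracy:.3f}  sensitivity {m.sensitivity:.3f}  "
                f"specificity {m.specificity:.3f}  Youden {m.youden:.3f}",
            ]
        return "\n".join(lines)
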