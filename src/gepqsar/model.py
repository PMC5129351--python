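"""Fitting interface: evolve a symbolic rule into a binary classifier.

Usage follows the model/results convention of statistical modelling
packages::

    table = gepqsar.read_table("train.csv")
    res = gepqsar.GEPClassifier(table, config=GEPConfig(seed=7)).fit()
    print(res.summary())
    labels = res.predict(test_table)

The fitted results object carries the winning chromosome, its decoded
expression, the fitness history, and the full provenance (config + seed),
and serializes to a JSON model file that reloads into an equivalent
predictor.  Classification uses the rule-sign convention: a compound is
assigned the positive (carcinogen) class exactly when the expression
value is strictly greater than zero; a value of exactly zero maps to the
negative class, the conservative choice for a carcinogen screen.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data import DescriptorTable
from .evolution import EvolutionResult, GEPConfig, evolve
from .karva import Chromosome, ExpressionTree, KarvaError, decode
from .metrics import ScreeningMetrics, confusion, screening_metrics
from .reference import VARIABLE_ALIASES, reference_rule

__all__ = [
    "GEPClassifier",
    "GEPResults",
    "decision_values",
    "predict_labels",
    "reference_model_value",
]

MODEL_FORMAT = "gepqsar-model"
MODEL_FORMAT_VERSION = 1


def _coerce_env(data, schema: list[str]) -> dict[str, np.ndarray]:
    """Build an evaluation environment from a table, frame, or mapping,
    enforcing the model's descriptor schema."""
    if isinstance(data, DescriptorTable):
        env = data.env()
    elif isinstance(data, pd.DataFrame):
        env = {c.lower(): data[c].to_numpy(dtype=float) for c in data.columns
               if c.lower() not in ("compound", "label")}
    elif isinstance(data, Mapping):
        env = {str(k).lower(): np.asarray(v, dtype=float) for k, v in data.items()}
    else:
        raise KarvaError(f"cannot evaluate on object of type {type(data).__name__}")
    missing = [c for c in schema if c.lower() not in env]
    if missing:
        raise KarvaError(f"schema mismatch: missing descriptor column(s) {missing}")
    return env


def decision_values(tree: ExpressionTree, data, schema: list[str]) -> np.ndarray:
    env = _coerce_env(data, schema)
    return np.atleast_1d(np.asarray(tree.evaluate(env), dtype=float))


def predict_labels(tree: ExpressionTree, data, schema: list[str]) -> np.ndarray:
    """Label 1 iff the rule value is strictly positive."""
    return (decision_values(tree, data, schema) > 0).astype(int)


def _config_hash(config: GEPConfig, seed: int) -> str:
    payload = json.dumps({"config": config.as_dict(), "seed": seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


class GEPClassifier:
    """Evolved-rule classifier specification bound to a training table."""

    def __init__(self, data: DescriptorTable, config: GEPConfig | None = None):
        if not data.is_labeled:
            raise ValueError("training table must be labeled")
        pos, neg = data.class_counts()
        if pos == 0 or neg == 0:
            raise ValueError("training data must contain both classes")
        self.data = data
        self.config = config or GEPConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: GEPConfig | None = None,
                       id_col: str = "compound", label_col: str = "label") -> "GEPClassifier":
        return cls(DescriptorTable.from_frame(frame, id_col, label_col), config)

    def fit(self) -> "GEPResults":
        evo = evolve(self.data, self.config)
        return GEPResults(
            chromosome=evo.best_chromosome,
            schema=self.data.descriptors,
            config=self.config,
            seed=self.config.seed,
            evolution=evo,
            train_data=self.data,
        )


@dataclass
class GEPResults:
    """Fitted evolved-rule classifier with provenance."""

    chromosome: Chromosome
    schema: list[str]
    config: GEPConfig
    seed: int
    evolution: EvolutionResult | None = None
    train_data: DescriptorTable | None = None
    _tree: ExpressionTree = field(init=False, repr=False)

    def __post_init__(self):
        self._tree = decode(self.chromosome)

    @property
    def expression(self) -> ExpressionTree:
        return self._tree

    @property
    def rule(self) -> str:
        """Deterministic infix rendering of the decoded rule."""
        return self._tree.to_infix()

    @property
    def history(self) -> pd.DataFrame | None:
        return None if self.evolution is None else self.evolution.history_frame()

    def decision_values(self, data) -> np.ndarray:
        return decision_values(self._tree, data, self.schema)

    def predict(self, data) -> np.ndarray:
        return predict_labels(self._tree, data, self.schema)

    def evaluate(self, data: DescriptorTable) -> ScreeningMetrics:
        """Screening metrics of the rule on a labeled table."""
        if not data.is_labeled:
            raise ValueError("evaluation table must be labeled")
        return screening_metrics(confusion(data.y, self.predict(data)))

    def training_metrics(self) -> ScreeningMetrics:
        if self.train_data is None:
            raise ValueError("results were loaded without training data")
        return self.evaluate(self.train_data)

    def summary(self) -> str:
        lines = [
            "Evolved-rule carcinogenicity classifier",
            "=" * 54,
            f"descriptors:     {', '.join(self.schema)}",
            f"function set:    {self.config.function_set}",
            f"head length:     {self.config.head_length}",
            f"fitness mode:    {self.config.fitness_mode}",
            f"seed:            {self.seed}",
            f"config hash:     {_config_hash(self.config, self.seed)}",
            f"rule:            {self.rule}",
            "decision:        class 1 (carcinogen) iff rule value > 0",
        ]
        if self.evolution is not None:
            lines.append(f"generations run: {self.evolution.generations_run}")
            lines.append(f"best fitness:    {self.evolution.best_fitness:g}")
        if self.train_data is not None:
            m = self.training_metrics().round3()
            lines += [
                "-" * 54,
                "training metrics:",
                f"  accuracy {m.accuracy:.3f}  sensitivity {m.sensitivity:.3f}  "
                f"specificity {m.specificity:.3f}  Youden {m.youden:.3f}",
            ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "format": MODEL_FORMAT,
            "format_version": MODEL_FORMAT_VERSION,
            "package_version": _pkg_version,
            "chromosome": self.chromosome.to_json(),
            "schema": list(self.schema),
            "config": self.config.as_dict(),
            "seed": self.seed,
            "config_hash": _config_hash(self.config, self.seed),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GEPResults":
        obj = json.loads(Path(path).read_text())
        if obj.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
        cfg = dict(obj["config"])
        cfg["constants"] = tuple(cfg.get("constants", ()))
        return cls(
            chromosome=Chromosome.from_json(obj["chromosome"]),
            schema=list(obj["schema"]),
            config=GEPConfig(**cfg),
            seed=int(obj["seed"]),
        )


# ---------------------------------------------------------------------------
# published reference rule

def reference_model_value(x, interpretation: str = "product") -> np.ndarray | float:
    """Evaluate the published evolved rule on descriptor values.

    ``x`` maps descriptor names (NCOS..LUMO) or positional aliases
    (x1..x8) to scalars or aligned arrays.  Protected arithmetic makes
    the value finite for any finite input; see
    :func:`gepqsar.reference.reference_rule` for the interpretation flag.
    """
    tree = reference_rule(interpretation)
    if isinstance(x, DescriptorTable):
        env = x.env()
    elif isinstance(x, pd.DataFrame):
        env = {c.lower(): x[c].to_numpy(dtype=float) for c in x.columns}
    else:
        env = {str(k).lower(): v for k, v in x.items()}
    # accept schema names by translating them onto the x1..x8 aliases
    for alias, name in VARIABLE_ALIASES.items():
        if alias not in env and name.lower() in env:
            env[alias] = env[name.lower()]
    missing = sorted(set(tree.variables()) - set(env))
    if missing:
        raise KarvaError(f"schema mismatch: missing descriptor column(s) {missing}")
    return tree.evaluate(env)
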