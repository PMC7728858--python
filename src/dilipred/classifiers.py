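"""The four model families behind one training/scoring contract.

The deep network is this package's own estimator (:mod:`dilipred.nn`); the
KNN, SVM and RF baselines delegate to scikit-learn — the pipeline's
contribution is the evaluation protocol around them, not re-implementations.
Every family is driven by a config dataclass carrying its hyperparameters and
seed, and every fitted model remembers the training gene order and refuses
prediction inputs in any other order.

Score semantics (all in [0, 1], used for ranking/AUC and for the 0.5
threshold rule): DNN — sigmoid output; KNN — positive-neighbor fraction;
RF — positive-vote fraction; SVM — the raw decision value min-max mapped to
[0, 1] within the prediction batch (AUC is invariant to this monotone map).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import GeneOrderError, TrainingError
from .nn import ACTIVATIONS, DEFAULT_HIDDEN_LAYERS, OPTIMIZERS, DNNClassifier
from .profiles import ProfileSet


@dataclass(frozen=True)
class DnnConfig:
    """Deep-network hyperparameters; the grid axes are activation x optimizer."""

    hidden_layer_widths: tuple[int, ...] = DEFAULT_HIDDEN_LAYERS
    activation: str = "elu"
    optimizer: str = "adam"
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-4
    seed: int = 0

    family = "DNN"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_layer_widths",
                           tuple(int(w) for w in self.hidden_layer_widths))
        if len(self.hidden_layer_widths) != 7:
            raise ValueError("the network has exactly 7 hidden layers")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")

    def label(self) -> str:
        return f"DNN(activation={self.activation},optimizer={self.optimizer})"


@dataclass(frozen=True)
class BaselineConfig:
    """Hyperparameters of one KNN/SVM/RF grid point."""

    family: str = "KNN"
    params: tuple[tuple[str, object], ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("KNN", "SVM", "RF"):
            raise ValueError("family must be KNN, SVM or RF")
        object.__setattr__(self, "params", tuple(sorted(dict(self.params).items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def label(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({inner})"


ClassifierConfig = Union[DnnConfig, BaselineConfig]


@dataclass
class FittedModel:
    """A trained estimator plus its config and the gene order it expects."""

    estimator: object
    config: ClassifierConfig
    gene_ids: tuple[str, ...]

    @property
    def family(self) -> str:
        return self.config.family


def with_seed(config: ClassifierConfig, seed: int) -> ClassifierConfig:
    return replace(config, seed=int(seed))


def build_estimator(config: ClassifierConfig):
    """Instantiate the sklearn-style estimator a config describes."""
    if isinstance(config, DnnConfig):
        return DNNClassifier(
            hidden_layer_sizes=config.hidden_layer_widths,
            activation=config.activation,
            optimizer=config.optimizer,
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            batch_size=config.batch_size,
            random_state=config.seed,
        )
    p = config.param_dict
    if config.family == "KNN":
        return KNeighborsClassifier(n_neighbors=int(p.get("k", 3)), metric="euclidean")
    if config.family == "SVM":
        return SVC(
            kernel=str(p.get("kernel", "rbf")).replace("polynomial", "poly"),
            C=float(p.get("C", 1.0)),
            gamma=p.get("gamma", "scale"),
            random_state=config.seed,
        )
    if config.family == "RF":
        return RandomForestClassifier(
            n_estimators=int(p.get("n_trees", 100)),
            max_depth=p.get("max_depth", None),
            min_samples_split=int(p.get("min_split", 2)),
            min_samples_leaf=int(p.get("min_leaf", 1)),
            random_state=config.seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown family {config.family!r}")


def train_classifier(config: ClassifierConfig, train: ProfileSet) -> FittedModel:
    """Fit a config on a labeled profile set; deterministic given config.seed."""
    y = train.labels
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    est = build_estimator(config)
    est.fit(train.X, y)
    return FittedModel(estimator=est, config=config, gene_ids=tuple(train.gene_ids))


def predict_scores(model: FittedModel, data: ProfileSet) -> np.ndarray:
    """Per-profile score in [0, 1]; raises if the gene order differs from
    the one the model was trained on."""
    if tuple(data.gene_ids) != model.gene_ids:
        raise GeneOrderError(
            "prediction input gene order differs from the training gene order"
        )
    X = data.X
    est = model.estimator
    if model.family == "SVM":
        d = est.decision_function(X)
        lo, hi = float(d.min()), float(d.max())
        if hi == lo:
            return np.full(len(d), 0.5)
        return (d - lo) / (hi - lo)
    return est.predict_proba(X)[:, 1]


def classify(scores, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores to 0/1; a score exactly at the threshold is negative."""
    s = np.asarray(scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return (s > threshold).astype(int)


# ----------------------------------------------------------------------
# Hyperparameter grids searched by the evaluation protocol
# ----------------------------------------------------------------------

def dnn_grid(base: DnnConfig | None = None) -> list[DnnConfig]:
    """The 4 activations x 4 optimizers grid (16 combinations)."""
    base = base or DnnConfig()
    return [replace(base, activation=a, optimizer=o)
            for a in ACTIVATIONS for o in OPTIMIZERS]

def knn_grid(seed: int = 0) -> list[BaselineConfig]:
    """k from 3 to 11 in steps of 2."""
    return [BaselineConfig("KNN", (("k", k),), seed) for k in range(3, 12, 2)]

def svm_grid(seed: int = 0) -> list[BaselineConfig]:
    """Polynomial and RBF kernels over the C and gamma grids."""
    return [
        BaselineConfig("SVM", (("kernel", kern), ("C", C), ("gamma", g)), seed)
        for kern, C, g in product(
            ("polynomial", "rbf"), (0.01, 0.1, 1, 10, 100), (0.1, 0.01, 0.001, 0.0001)
        )
    ]

def rf_grid(seed: int = 0) -> list[BaselineConfig]:
    """Trees x depth x min-split x min-leaf grid."""
    return [
        BaselineConfig(
            "RF",
            (("n_trees", n), ("max_depth", d), ("min_split", s), ("min_leaf", l)),
            seed,
        )
        for n, d, s, l in product(
            (100, 200, 300, 400, 500), (8, 10, 12, None), (2, 5, 10), (1, 2, 4)
        )
    ]


DEFAULT_GRIDS = {"DNN": dnn_grid, "KNN": knn_grid, "SVM": svm_grid, "RF": rf_grid}


# ----------------------------------------------------------------------
# Config (de)serialization for run manifests
# ----------------------------------------------------------------------

def config_to_dict(config: ClassifierConfig) -> dict:
    if isinstance(config, DnnConfig):
        return {
            "family": "DNN",
            "hidden_layer_widths": list(config.hidden_layer_widths),
            "activation": config.activation,
            "optimizer": config.optimizer,
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "seed": config.seed,
        }
    return {"family": config.family, "params": dict(config.params), "seed": config.seed}


def config_from_dict(d: dict) -> ClassifierConfig:
    d = dict(d)
    family = d.pop("family")
    if family == "DNN":
        d["hidden_layer_widths"] = tuple(d["hidden_layer_widths"])
        return DnnConfig(**d)
    return BaselineConfig(family, tuple(d.get("params", {}).items()), d.get("seed", 0))
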