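"""A seeded feed-forward binary classifier with seven hidden layers.

The network is the plain fully-connected architecture: at every hidden node
the pre-activation is the weighted sum of the previous layer's outputs plus a
bias, S^l_j = sum_k W^l_jk x^{l-1}_k + b^l_j, passed through a non-linearity
x^l_j = f(S^l_j); the single output unit is a sigmoid giving the DILI
probability, trained by minimising binary cross-entropy with mini-batch
gradient descent.  Four activations (tanh, relu, selu, elu) and four
optimizers (sgd, adam, adadelta, rmsprop) are supported — the axes of the
hyperparameter grid the evaluation protocol searches.

Implemented directly in numpy so that training is exactly reproducible from
(architecture, seed): weight initialisation and mini-batch shuffling are the
only random elements and both draw from one seeded generator.

The class follows the scikit-learn estimator contract (get_params/set_params,
fit returning self, trailing-underscore fitted attributes) so it drops into
sklearn model-selection tooling unchanged.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import TrainingError

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772

ACTIVATIONS = ("tanh", "relu", "selu", "elu")
OPTIMIZERS = ("adam", "adadelta", "rmsprop", "sgd")

#: Default architecture: seven hidden layers tapering from the ~1000-gene
#: input; widths, epochs, batch size and learning rate are package defaults
#: (every one overridable), not literature-fixed values.
DEFAULT_HIDDEN_LAYERS = (1000, 800, 600, 400, 200, 100, 50)


def _activate(name: str, s: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(s)
    if name == "relu":
        return np.maximum(s, 0.0)
    if name == "elu":
        return np.where(s > 0, s, np.expm1(np.minimum(s, 0.0)))
    if name == "selu":
        return _SELU_LAMBDA * np.where(
            s > 0, s, _SELU_ALPHA * np.expm1(np.minimum(s, 0.0))
        )
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(name: str, s: np.ndarray, x: np.ndarray) -> np.ndarray:
    """df/dS given pre-activation s and output x = f(s)."""
    if name == "tanh":
        return 1.0 - x * x
    if name == "relu":
        return (s > 0).astype(s.dtype)
    if name == "elu":
        return np.where(s > 0, 1.0, x + 1.0)
    if name == "selu":
        return np.where(s > 0, _SELU_LAMBDA, x + _SELU_LAMBDA * _SELU_ALPHA)
    raise ValueError(f"unknown activation {name!r}")


def _sigmoid(s: np.ndarray) -> np.ndarray:
    out = np.empty_like(s)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    out[~pos] = es / (1.0 + es)
    return out


class _Optimizer:
    """Per-parameter adaptive update rules sharing one interface."""

    def __init__(self, kind: str, lr: float, shapes: list[tuple[int, ...]]):
        self.kind = kind
        self.lr = lr
        self.t = 0
        if kind in ("adam",):
            self.m = [np.zeros(s) for s in shapes]
            self.v = [np.zeros(s) for s in shapes]
        elif kind in ("rmsprop",):
            self.v = [np.zeros(s) for s in shapes]
        elif kind == "adadelta":
            self.v = [np.zeros(s) for s in shapes]
            self.u = [np.zeros(s) for s in shapes]
        elif kind != "sgd":
            raise ValueError(f"unknown optimizer {kind!r}")

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        if self.kind == "sgd":
            for p, g in zip(params, grads):
                p -= self.lr * g
        elif self.kind == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            for i, (p, g) in enumerate(zip(params, grads)):
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                mhat = self.m[i] / (1 - b1 ** self.t)
                vhat = self.v[i] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        elif self.kind == "rmsprop":
            rho, eps = 0.9, 1e-8
            for i, (p, g) in enumerate(zip(params, grads)):
                self.v[i] = rho * self.v[i] + (1 - rho) * g * g
                p -= self.lr * g / (np.sqrt(self.v[i]) + eps)
        elif self.kind == "adadelta":
            rho, eps = 0.95, 1e-6
            for i, (p, g) in enumerate(zip(params, grads)):
                self.v[i] = rho * self.v[i] + (1 - rho) * g * g
                dx = -np.sqrt(self.u[i] + eps) / np.sqrt(self.v[i] + eps) * g
                self.u[i] = rho * self.u[i] + (1 - rho) * dx * dx
                p += self.lr * dx


class DNNClassifier(BaseEstimator, ClassifierMixin):
    """Seven-hidden-layer feed-forward network for binary DILI classification.

    Parameters
    ----------
    hidden_layer_sizes : tuple of 7 ints
        Widths of the seven hidden layers.
    activation : {"tanh", "relu", "selu", "elu"}
        Hidden-layer non-linearity (the output unit is always a sigmoid).
    optimizer : {"adam", "adadelta", "rmsprop", "sgd"}
        Mini-batch update rule minimising binary cross-entropy.
    learning_rate, epochs, batch_size : training schedule.
    random_state : seed controlling initialisation and shuffling; training is
        bit-reproducible given identical data and parameters.
    """

    def __init__(self, hidden_layer_sizes=DEFAULT_HIDDEN_LAYERS, activation="elu",
                 optimizer="adam", learning_rate=1e-4, epochs=100, batch_size=128,
                 random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params_strict(self) -> None:
        if len(tuple(self.hidden_layer_sizes)) != 7:
            raise ValueError(
                f"exactly 7 hidden layers required, got {len(tuple(self.hidden_layer_sizes))}"
            )
        if any(int(w) < 1 for w in self.hidden_layer_sizes):
            raise ValueError("hidden layer widths must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs, batch_size must be positive")

    def fit(self, X, y):
        self._validate_params_strict()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-d with one label per row")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        y = y.astype(float)
        classes = np.unique(y)
        if classes.size < 2:
            raise TrainingError("training data contains a single class")

        rng = np.random.default_rng(self.random_state)
        widths = [X.shape[1], *map(int, self.hidden_layer_sizes), 1]
        self.coefs_: list[np.ndarray] = []
        self.intercepts_: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.coefs_.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.intercepts_.append(np.zeros(fan_out))

        params = [*self.coefs_, *self.intercepts_]
        opt = _Optimizer(self.optimizer, self.learning_rate, [p.shape for p in params])
        n = X.shape[0]
        batch = min(int(self.batch_size), n)
        self.loss_curve_: list[float] = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                loss = self._batch_step(X[idx], y[idx], opt)
                epoch_loss += loss * len(idx)
            self.loss_curve_.append(epoch_loss / n)

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _forward(self, Xb: np.ndarray):
        pre, acts = [], [Xb]
        h = Xb
        n_layers = len(self.coefs_)
        for l, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            s = h @ W + b
            pre.append(s)
            h = _sigmoid(s) if l == n_layers - 1 else _activate(self.activation, s)
            acts.append(h)
        return pre, acts

    def _batch_step(self, Xb, yb, opt) -> float:
        pre, acts = self._forward(Xb)
        p = np.clip(acts[-1][:, 0], 1e-12, 1 - 1e-12)
        loss = -np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p))
        m = len(yb)
        # output sigmoid + cross-entropy: dL/dS = (p - y) / m
        delta = ((acts[-1][:, 0] - yb) / m)[:, None]
        grad_W = [np.empty(0)] * len(self.coefs_)
        grad_b = [np.empty(0)] * len(self.coefs_)
        for l in range(len(self.coefs_) - 1, -1, -1):
            grad_W[l] = acts[l].T @ delta
            grad_b[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ self.coefs_[l].T) * _activate_grad(
                    self.activation, pre[l - 1], acts[l]
                )
        opt.step([*self.coefs_, *self.intercepts_], [*grad_W, *grad_b])
        return float(loss)

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was trained on {self.n_features_in_}"
            )
        _, acts = self._forward(X)
        return acts[-1][:, 0]

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        # boundary rule: a score of exactly 0.5 classifies negative
        return (self.decision_function(X) > 0.5).astype(int)
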