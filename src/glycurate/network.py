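"""From-scratch feed-forward logistic binary classifier.

One hidden layer of rectified linear units feeding two *independent*
sigmoid output units (not a softmax: the outputs are each in (0, 1) but do
not sum to 1), trained by full-batch gradient descent on mean binary
cross-entropy with inverted dropout on the hidden layer and a cyclical
learning-rate schedule:

    lr(e) = ilr * d**floor(e / c) * exp(-k * (e mod c))

i.e. within a cycle of ``c`` epochs the rate decays exponentially at rate
``k``, and each new cycle restarts from a peak reduced by the descent
coefficient ``d``.  Early stopping is selection, not halting: all epochs
run, and the parameter snapshot with the highest test-set accuracy is
returned (ties broken by training accuracy, then earliest epoch).

Defaults are the curation classifier's operating point: ilr 0.25, k 0.05,
c 100 epochs, d 0.95, 10 cycles (1000 epochs), 96 hidden units, hidden-unit
retention probability 0.7.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Hyperparams",
    "NetworkParams",
    "Gradients",
    "TrainingTrace",
    "init_params",
    "forward",
    "loss",
    "backward",
    "learning_rate",
    "accuracy",
    "train",
    "TrainingDivergence",
]

_EPS = 1e-12


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite (learning-rate divergence)."""


@dataclass(frozen=True)
class Hyperparams:
    """Training-schedule constants.

    ``dropout`` follows the convention set by ``dropout_is_keep``: by
    default it is the *retention* probability of a hidden unit (0.7 keeps
    70% of units per epoch).  ``dropout = 0`` always disables dropout.
    """

    ilr: float = 0.25
    k: float = 0.05
    c: int = 100
    d: float = 0.95
    dropout: float = 0.7
    dropout_is_keep: bool = True
    n_cycles: int = 10
    hidden_units: int = 96
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ilr <= 0:
            raise ValueError("ilr must be positive")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if not (0 < self.d <= 1):
            raise ValueError("d must be in (0, 1]")
        if not (0 <= self.dropout <= 1):
            raise ValueError("dropout must be in [0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")

    @property
    def n_epochs(self) -> int:
        return self.n_cycles * self.c

    @property
    def keep_prob(self) -> float:
        """Hidden-unit retention probability implied by ``dropout``."""
        if self.dropout == 0:
            return 1.0
        return self.dropout if self.dropout_is_keep else 1.0 - self.dropout


@dataclass
class NetworkParams:
    """Weights and biases: input -> hidden (ReLU) -> 2 sigmoid outputs."""

    W1: np.ndarray  # (n_features, hidden_units)
    b1: np.ndarray  # (hidden_units,)
    W2: np.ndarray  # (hidden_units, 2)
    b2: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        self.b2 = np.asarray(self.b2, dtype=np.float64)
        if self.W1.shape[1] != self.b1.shape[0] or self.W2.shape != (self.b1.shape[0], 2):
            raise ValueError("inconsistent parameter shapes")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite parameter values")

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.ravel().tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.ravel().tolist(),
            "b2": self.b2.tolist(),
            "shape": [int(self.W1.shape[0]), int(self.W1.shape[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        n_in, n_hidden = d["shape"]
        return cls(
            W1=np.array(d["W1"], dtype=np.float64).reshape(n_in, n_hidden),
            b1=np.array(d["b1"], dtype=np.float64),
            W2=np.array(d["W2"], dtype=np.float64).reshape(n_hidden, 2),
            b2=np.array(d["b2"], dtype=np.float64),
        )


@dataclass
class Gradients:
    """Same shapes as :class:`NetworkParams`, without finiteness checks
    (a diverging run must be reported as divergence, not a shape error)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray


@dataclass
class TrainingTrace:
    epochs: list[tuple[int, float, float, float]] = field(default_factory=list)
    best_epoch: int = 0

    def append(self, epoch: int, lr: float, train_acc: float, test_acc: float) -> None:
        self.epochs.append((epoch, lr, train_acc, test_acc))

    def __len__(self) -> int:
        return len(self.epochs)

    def test_accuracies(self) -> np.ndarray:
        return np.array([rec[3] for rec in self.epochs])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "lr", "train_acc", "test_acc"])
            writer.writerows(self.epochs)


def init_params(n_features: int, hidden_units: int, rng: np.random.Generator) -> NetworkParams:
    """Scaled-uniform initialization matched to ReLU fan-in (He limits)."""
    limit1 = np.sqrt(6.0 / n_features) if n_features else 1.0
    limit2 = np.sqrt(6.0 / hidden_units)
    return NetworkParams(
        W1=rng.uniform(-limit1, limit1, size=(n_features, hidden_units)),
        b1=np.zeros(hidden_units),
        W2=rng.uniform(-limit2, limit2, size=(hidden_units, 2)),
        b2=np.zeros(2),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(
    x: np.ndarray,
    params: NetworkParams,
    mode: str = "eval",
    mask: Optional[np.ndarray] = None,
    keep_prob: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """One forward pass; returns (sigmoid outputs, cache for backward).

    ``x`` may be one feature vector or a (n, d) batch.  In train mode a
    dropout ``mask`` (same shape as the hidden activations) zeroes dropped
    units and the survivors are scaled by 1/keep_prob (inverted dropout),
    so eval mode needs no rescaling.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != params.n_features:
        raise ValueError(f"expected {params.n_features} features, got {x.shape[1]}")
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    z1 = x @ params.W1 + params.b1
    hidden = np.maximum(z1, 0.0)
    if mode == "train" and mask is not None:
        mask = np.asarray(mask, dtype=np.float64)
        if mask.shape != hidden.shape:
            mask = np.broadcast_to(mask, hidden.shape)
        hidden_dropped = hidden * mask / keep_prob
    else:
        mask = None
        hidden_dropped = hidden
    z2 = hidden_dropped @ params.W2 + params.b2
    out = _sigmoid(z2)
    cache = {
        "x": x,
        "z1": z1,
        "hidden_dropped": hidden_dropped,
        "mask": mask,
        "keep_prob": keep_prob,
        "out": out,
        "params": params,
    }
    return np.squeeze(out), cache


def loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean binary cross-entropy over the two output units (and batch)."""
    pred = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    label = np.asarray(label, dtype=np.float64)
    return float(np.mean(-label * np.log(pred) - (1.0 - label) * np.log(1.0 - pred)))


def backward(cache: dict, label: np.ndarray) -> Gradients:
    """Gradients of the mean binary cross-entropy w.r.t. every parameter.

    Uses the sigmoid/cross-entropy cancellation d(loss)/dz2 = (out - y)/N.
    Units zeroed by the dropout mask receive zero gradient.
    """
    params: NetworkParams = cache["params"]
    y = np.atleast_2d(np.asarray(label, dtype=np.float64))
    out = cache["out"]
    if y.shape != out.shape:
        raise ValueError(f"label shape {y.shape} does not match output {out.shape}")
    dz2 = (out - y) / y.size
    dW2 = cache["hidden_dropped"].T @ dz2
    db2 = dz2.sum(axis=0)
    dh = dz2 @ params.W2.T
    if cache["mask"] is not None:
        dh = dh * cache["mask"] / cache["keep_prob"]
    dz1 = dh * (cache["z1"] > 0)
    dW1 = cache["x"].T @ dz1
    db1 = dz1.sum(axis=0)
    return Gradients(W1=dW1, b1=db1, W2=dW2, b2=db2)


def learning_rate(epoch: int, h: Hyperparams) -> float:
    """Cyclical schedule: ilr * d**floor(e/c) * exp(-k * (e mod c))."""
    if not (0 <= epoch < h.n_epochs):
        raise ValueError(f"epoch {epoch} outside [0, {h.n_epochs})")
    cycle, within = divmod(epoch, h.c)
    return h.ilr * h.d**cycle * float(np.exp(-h.k * within))


def accuracy(preds: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of samples whose stronger output unit matches the label.

    A sample is called positive when the positive unit strictly exceeds the
    negative unit; an exact tie is a negative call (conservative triage).
    """
    preds = np.atleast_2d(np.asarray(preds, dtype=np.float64))
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if preds.shape != labels.shape or preds.shape[0] == 0:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    called_positive = preds[:, 0] > preds[:, 1]
    is_positive = labels[:, 0] == 1
    return float(np.mean(called_positive == is_positive))


def train(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    h: Hyperparams,
) -> tuple[NetworkParams, TrainingTrace]:
    """Full-batch gradient descent with per-epoch dropout masks.

    Runs every one of the ``n_cycles * c`` epochs, monitoring train and
    test accuracy, and returns the snapshot from the epoch of maximum test
    accuracy together with the full trace.  Ties on test accuracy are
    broken by training accuracy, then by the earliest epoch: when the test
    set saturates (easy desk-scale corpora), the earliest saturating epoch
    is typically undertrained, so among equally test-accurate snapshots the
    one that also best explains its training subset generalises better.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=np.float64))
    train_y = np.atleast_2d(np.asarray(train_y, dtype=np.float64))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=np.float64))
    test_y = np.atleast_2d(np.asarray(test_y, dtype=np.float64))
    if test_x.shape[0] == 0:
        raise ValueError("test set must be non-empty (early stopping needs it)")
    if train_x.shape[1] != test_x.shape[1]:
        raise ValueError("train/test feature dimensions differ")

    rng = np.random.default_rng(h.seed)
    params = init_params(train_x.shape[1], h.hidden_units, rng)
    keep = h.keep_prob
    trace = TrainingTrace()
    best_params = params.copy()
    best_key = (-1.0, -1.0)  # (test_acc, train_acc)
    best_epoch = 0

    for epoch in range(h.n_epochs):
        lr = learning_rate(epoch, h)
        mask = None
        if keep < 1.0:
            mask = (rng.random((train_x.shape[0], h.hidden_units)) < keep).astype(np.float64)
        out, cache = forward(train_x, params, mode="train", mask=mask, keep_prob=keep)
        epoch_loss = loss(out, train_y)
        if not np.isfinite(epoch_loss):
            raise TrainingDivergence(
                f"non-finite loss at epoch {epoch} (lr={lr:.4g}); reduce ilr"
            )
        grads = backward(cache, train_y)
        params.W1 -= lr * grads.W1
        params.b1 -= lr * grads.b1
        params.W2 -= lr * grads.W2
        params.b2 -= lr * grads.b2
        if not all(
            np.isfinite(a).all() for a in (params.W1, params.b1, params.W2, params.b2)
        ):
            raise TrainingDivergence(
                f"non-finite parameters after epoch {epoch} (lr={lr:.4g}); reduce ilr"
            )

        train_out, _ = forward(train_x, params, mode="eval")
        test_out, _ = forward(test_x, params, mode="eval")
        train_acc = accuracy(train_out, train_y)
        test_acc = accuracy(test_out, test_y)
        trace.append(epoch, lr, train_acc, test_acc)
        if (test_acc, train_acc) > best_key:
            best_key = (test_acc, train_acc)
            best_epoch = epoch
            best_params = params.copy()

    trace.best_epoch = best_epoch
    return best_params, trace
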