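"""Bagged ensemble: equal-weight voting with a binomial confidence interval.

Each member classifier is trained on its own half-size resample of the
training set and votes 0/1 on every document (positive unit >= negative
unit).  Votes are averaged into p-hat and wrapped in a normal-approximation
binomial interval p-hat +/- z*sqrt(p-hat(1-p-hat)/n), truncated to [0, 1].
The three-way decision routes wide intervals (width strictly greater than
the threshold, default 0.5) to a human curator as *ambiguous*; otherwise
p-hat rounds to a positive or negative call, with 0.5 rounding to negative
(conservative triage).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from glycurate.network import (
    Hyperparams,
    NetworkParams,
    TrainingTrace,
    forward,
    train,
)
from glycurate.splits import LabeledSet, make_bagging_subsets

__all__ = [
    "EnsembleModel",
    "AggregatedPrediction",
    "Decision",
    "train_ensemble",
    "predict",
    "predict_matrix",
    "decide",
    "evaluate",
]

DEFAULT_Z = 1.96
DEFAULT_AMBIGUITY_THRESHOLD = 0.5


@dataclass
class EnsembleModel:
    members: list[NetworkParams]
    hyper: Hyperparams
    vocab_ref: str = ""
    traces: list[TrainingTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        dims = {m.n_features for m in self.members}
        if len(dims) != 1:
            raise ValueError(f"members disagree on feature dimension: {dims}")

    @property
    def n_models(self) -> int:
        return len(self.members)

    def save(self, path: str | Path) -> None:
        payload = {
            "vocab_ref": self.vocab_ref,
            "hyper": {
                "ilr": self.hyper.ilr,
                "k": self.hyper.k,
                "c": self.hyper.c,
                "d": self.hyper.d,
                "dropout": self.hyper.dropout,
                "dropout_is_keep": self.hyper.dropout_is_keep,
                "n_cycles": self.hyper.n_cycles,
                "hidden_units": self.hyper.hidden_units,
                "seed": self.hyper.seed,
            },
            "members": [m.to_dict() for m in self.members],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            members=[NetworkParams.from_dict(m) for m in payload["members"]],
            hyper=Hyperparams(**payload["hyper"]),
            vocab_ref=payload.get("vocab_ref", ""),
        )


@dataclass(frozen=True)
class AggregatedPrediction:
    doc_id: str
    p_hat: float
    ci_low: float  # truncated to [0, 1]
    ci_high: float
    n_models: int
    votes: tuple[int, ...]
    half_width: float = 0.0  # untruncated z*sqrt(p(1-p)/n)

    @property
    def width(self) -> float:
        """Full untruncated interval width, the quantity the ambiguity
        rule compares against its threshold."""
        return 2.0 * self.half_width


@dataclass(frozen=True)
class Decision:
    call: str  # "positive" | "negative" | "ambiguous"
    outcome: Optional[str] = None  # "correct" | "wrong" | "ambiguous" when truth known


def train_ensemble(
    train_set: LabeledSet,
    train_features: dict[str, np.ndarray],
    test_set: LabeledSet,
    test_features: dict[str, np.ndarray],
    h: Hyperparams,
    n_models: int = 5,
    seed: Optional[int] = None,
    vocab_ref: str = "",
) -> EnsembleModel:
    """Train ``n_models`` members, each on its own half-subset.

    ``*_features`` map doc_id to its descriptor bits; every member shares
    the test set for early stopping, and member m trains with seed
    ``seed + m`` (derived, so the ensemble is reproducible end to end).
    """
    subsets = make_bagging_subsets(train_set, n_models=n_models, seed=seed)
    test_x = np.vstack([test_features[i] for i in test_set.ids])
    test_y = test_set.label_matrix()
    members = []
    traces = []
    for m, subset in enumerate(subsets):
        sub_x = np.vstack([train_features[i] for i in subset.ids])
        sub_y = subset.label_matrix()
        member_h = Hyperparams(
            ilr=h.ilr,
            k=h.k,
            c=h.c,
            d=h.d,
            dropout=h.dropout,
            dropout_is_keep=h.dropout_is_keep,
            n_cycles=h.n_cycles,
            hidden_units=h.hidden_units,
            seed=None if seed is None else seed + m,
        )
        params, trace = train(sub_x, sub_y, test_x, test_y, member_h)
        members.append(params)
        traces.append(trace)
    return EnsembleModel(members=members, hyper=h, vocab_ref=vocab_ref, traces=traces)


def _member_vote(params: NetworkParams, x: np.ndarray) -> int:
    out, _ = forward(x, params, mode="eval")
    out = np.atleast_2d(out)
    return int(out[0, 0] >= out[0, 1])


def predict(
    x: np.ndarray,
    ens: EnsembleModel,
    z: float = DEFAULT_Z,
    doc_id: str = "",
    vocab_ref: Optional[str] = None,
) -> AggregatedPrediction:
    """Aggregate binary member votes with a binomial confidence interval."""
    if vocab_ref is not None and ens.vocab_ref and vocab_ref != ens.vocab_ref:
        raise ValueError(
            f"vocabulary hash mismatch: features {vocab_ref!r} vs model {ens.vocab_ref!r}"
        )
    votes = tuple(_member_vote(m, x) for m in ens.members)
    n = len(votes)
    p_hat = sum(votes) / n
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return AggregatedPrediction(
        doc_id=doc_id,
        p_hat=p_hat,
        ci_low=max(0.0, p_hat - half),
        ci_high=min(1.0, p_hat + half),
        n_models=n,
        votes=votes,
        half_width=half,
    )


def predict_matrix(
    X: np.ndarray,
    ids: Sequence[str],
    ens: EnsembleModel,
    z: float = DEFAULT_Z,
) -> list[AggregatedPrediction]:
    """Vectorised aggregation over a descriptor matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    vote_matrix = np.empty((X.shape[0], ens.n_models), dtype=int)
    for m, params in enumerate(ens.members):
        out, _ = forward(X, params, mode="eval")
        out = np.atleast_2d(out)
        vote_matrix[:, m] = out[:, 0] >= out[:, 1]
    preds = []
    for row, doc_id in zip(vote_matrix, ids):
        votes = tuple(int(v) for v in row)
        n = len(votes)
        p_hat = sum(votes) / n
        half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
        preds.append(
            AggregatedPrediction(
                doc_id=doc_id,
                p_hat=p_hat,
                ci_low=max(0.0, p_hat - half),
                ci_high=min(1.0, p_hat + half),
                n_models=n,
                votes=votes,
                half_width=half,
            )
        )
    return preds


def decide(
    agg: AggregatedPrediction,
    truth: Optional[tuple[int, int]] = None,
    threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
) -> Decision:
    """Three-way decision from an aggregated vote.

    Ambiguous when the interval width strictly exceeds ``threshold``;
    otherwise p-hat rounds to the call, with exactly 0.5 rounding down to
    negative.  With truth supplied, the outcome is ambiguous/correct/wrong
    under the same override.
    """
    ambiguous = agg.width > threshold
    rounded_positive = agg.p_hat > 0.5
    call = "ambiguous" if ambiguous else ("positive" if rounded_positive else "negative")
    outcome = None
    if truth is not None:
        truth_call = "positive" if tuple(truth) == (1, 0) else "negative"
        if ambiguous:
            outcome = "ambiguous"
        else:
            outcome = "correct" if call == truth_call else "wrong"
    return Decision(call=call, outcome=outcome)


def evaluate(
    ens: EnsembleModel,
    data: LabeledSet,
    features: dict[str, np.ndarray],
    z: float = DEFAULT_Z,
    threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
) -> dict:
    """Aggregate metrics over a labelled set.

    ``accuracy`` counts only decisive correct calls; ``accuracy_with_ambiguous``
    additionally credits ambiguous samples (those are routed to a curator,
    so they are never silently wrong).  Precision and recall are computed on
    the positive class over decisive calls only; precision is ``None`` when
    no positive call was made.  Setting ``threshold=1.0`` disables the
    ambiguity override (interval widths never exceed 1 after truncation),
    which scores plain majority voting.
    """
    if not data.ids:
        raise ValueError("cannot evaluate on an empty set")
    X = np.vstack([features[i] for i in data.ids])
    preds = predict_matrix(X, data.ids, ens, z=z)
    n = len(data)
    n_correct = n_ambiguous = 0
    tp = fp = fn = 0
    for agg, truth in zip(preds, data.labels):
        decision = decide(agg, truth=truth, threshold=threshold)
        if decision.outcome == "ambiguous":
            n_ambiguous += 1
            continue
        if decision.outcome == "correct":
            n_correct += 1
        truth_positive = tuple(truth) == (1, 0)
        called_positive = decision.call == "positive"
        if called_positive and truth_positive:
            tp += 1
        elif called_positive and not truth_positive:
            fp += 1
        elif not called_positive and truth_positive:
            fn += 1
    return {
        "n": n,
        "accuracy": n_correct / n,
        "accuracy_with_ambiguous": (n_correct + n_ambiguous) / n,
        "ambiguous_fraction": n_ambiguous / n,
        "precision": tp / (tp + fp) if (tp + fp) > 0 else None,
        "recall": tp / (tp + fn) if (tp + fn) > 0 else None,
    }
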