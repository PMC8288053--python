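"""Balanced train/test/validation splits and bagging subsets.

Splitting is shuffle-and-slice: the pooled document ids are shuffled, cut
into train/test/validation at the configured fractions (1/2, 1/4, 1/4 by
default), and the candidate split is accepted only if every set holds
positives and negatives within a 1% imbalance — rejected candidates trigger
a fresh shuffle.  Bagging subsets are independent half-size slices of the
training set, drawn without replacement within each subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LabeledSet",
    "SplitSpec",
    "BalanceError",
    "encode_label",
    "make_splits",
    "make_bagging_subsets",
]

POSITIVE = (1, 0)
NEGATIVE = (0, 1)


class BalanceError(RuntimeError):
    """Raised when no shuffle satisfies the balance tolerance."""


def encode_label(label: str) -> tuple[int, int]:
    """positive -> (1, 0); negative -> (0, 1)."""
    if label == "positive":
        return POSITIVE
    if label == "negative":
        return NEGATIVE
    raise ValueError(f"cannot encode label {label!r}")


@dataclass(frozen=True)
class LabeledSet:
    ids: tuple[str, ...]
    labels: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels must be parallel")
        for lab in self.labels:
            if tuple(lab) not in (POSITIVE, NEGATIVE):
                raise ValueError(f"label must be (1,0) or (0,1), got {lab}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_positive(self) -> int:
        return sum(1 for lab in self.labels if tuple(lab) == POSITIVE)

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    def imbalance(self) -> float:
        """|n_pos - n_neg| / n."""
        if not self.ids:
            return 0.0
        return abs(self.n_positive - self.n_negative) / len(self)

    def subset(self, indices: Sequence[int]) -> "LabeledSet":
        return LabeledSet(
            ids=tuple(self.ids[i] for i in indices),
            labels=tuple(self.labels[i] for i in indices),
        )

    def label_matrix(self) -> np.ndarray:
        return np.array(self.labels, dtype=np.float64)


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    balance_tol: float = 0.01
    max_retries: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")
        if not (0.0 < self.balance_tol < 1.0):
            raise ValueError("balance_tol must be in (0, 1)")


def _slice_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_test = int(n * fractions[1])
    n_val = int(n * fractions[2])
    n_train = n - n_test - n_val  # train absorbs rounding remainder
    return n_train, n_test, n_val


def make_splits(pool: LabeledSet, spec: SplitSpec) -> tuple[LabeledSet, LabeledSet, LabeledSet]:
    """Shuffle-and-slice the pool into accepted train/test/validation sets.

    A candidate is accepted only when every set satisfies
    ``|n_pos - n_neg| / n < balance_tol`` (strict).  Reshuffles until
    acceptance or ``max_retries`` is exhausted.  With a fixed seed the
    result is bit-reproducible; ``seed=None`` mimics unseeded shuffling.
    """
    n = len(pool)
    if n < 8:
        raise ValueError("pool too small to split (need >= 8 documents)")
    if pool.imbalance() > 0:
        warnings.warn(
            "pool is not class-balanced; the balance tolerance may be hard to satisfy",
            stacklevel=2,
        )
    n_train, n_test, n_val = _slice_sizes(n, spec.fractions)
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_retries):
        order = rng.permutation(n)
        train = pool.subset(order[:n_train])
        test = pool.subset(order[n_train : n_train + n_test])
        val = pool.subset(order[n_train + n_test :])
        if all(s.imbalance() < spec.balance_tol for s in (train, test, val)):
            return train, test, val
    raise BalanceError(
        f"no split satisfied balance_tol={spec.balance_tol} in {spec.max_retries} shuffles"
    )


def make_bagging_subsets(
    train: LabeledSet, n_models: int = 5, seed: Optional[int] = None
) -> list[LabeledSet]:
    """Draw ``n_models`` independent half-size slices of the training set.

    Each subset holds ``floor(|train| / 2)`` distinct documents (a fresh
    shuffle-and-slice per model, without replacement within a subset), the
    resampling scheme behind the bagged ensemble.
    """
    if not train.ids:
        raise ValueError("training set is empty")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    half = len(train) // 2
    subsets = []
    for _ in range(n_models):
        order = rng.permutation(len(train))
        subsets.append(train.subset(order[:half]))
    return subsets


def save_split_manifest(
    path,
    train: LabeledSet,
    test: LabeledSet,
    val: LabeledSet,
    spec: SplitSpec,
) -> None:
    """Write a doc_id,set,label CSV with the seed/tolerance in the header."""
    from pathlib import Path

    lines = [f"# seed={spec.seed} balance_tol={spec.balance_tol}", "doc_id,set,label"]
    for name, part in (("train", train), ("test", test), ("validation", val)):
        for doc_id, lab in zip(part.ids, part.labels):
            label = "positive" if tuple(lab) == POSITIVE else "negative"
            lines.append(f"{doc_id},{name},{label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
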