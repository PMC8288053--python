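"""Tag-pattern vocabulary and binary descriptor vectors.

An *expression* is a whole tag sentence rendered as a space-joined chain
(``PROTEIN OGLCNAC STSITES``).  The vocabulary retains every expression
occurring at least ``min_count`` times across the concatenated training
corpus (corpus-level counting, not per-document), ordered lexicographically
so vector indices are stable across runs.  A document's descriptor is the
binary presence vector of its expressions over that vocabulary — strictly
presence/absence, never counts.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from glycurate.text_pipeline import TaggedDocument

__all__ = [
    "ExpressionVocabulary",
    "DescriptorVector",
    "build_vocabulary",
    "vectorize",
    "vectorize_corpus",
]


@dataclass(frozen=True)
class ExpressionVocabulary:
    expressions: tuple[str, ...]
    min_count: int
    source_doc_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.expressions)) != len(self.expressions):
            raise ValueError("duplicate expressions in vocabulary")
        if list(self.expressions) != sorted(self.expressions):
            raise ValueError("vocabulary must be lexicographically sorted")

    def __len__(self) -> int:
        return len(self.expressions)

    @property
    def content_hash(self) -> str:
        """Hash binding models and vectors to one vocabulary ordering."""
        h = hashlib.sha256()
        for e in self.expressions:
            h.update(e.encode())
            h.update(b"\n")
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        lines = [f"# min_count={self.min_count} hash={self.content_hash}"]
        lines.extend(self.expressions)
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ExpressionVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        min_count = 1
        expressions = []
        for line in lines:
            if line.startswith("#"):
                for part in line[1:].split():
                    if part.startswith("min_count="):
                        min_count = int(part.split("=", 1)[1])
                continue
            if line.strip():
                expressions.append(line.strip())
        return cls(expressions=tuple(expressions), min_count=min_count)


@dataclass(frozen=True)
class DescriptorVector:
    doc_id: str
    bits: np.ndarray  # uint8 {0,1}, aligned with vocabulary order

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("descriptor bits must be 0/1")


def count_expressions(docs: Iterable[TaggedDocument]) -> Counter:
    """Corpus-level occurrence count of every rendered tag sentence."""
    counts: Counter = Counter()
    for doc in docs:
        for sentence in doc.sentences:
            counts[sentence.expression] += 1
    return counts


def build_vocabulary(
    training_docs: Sequence[TaggedDocument], min_count: int = 4
) -> ExpressionVocabulary:
    """Retain expressions seen >= ``min_count`` times in the training corpus.

    Counting is over the concatenation of all training documents; an
    expression appearing twice in each of two documents therefore counts
    four occurrences.  Built from training documents only — pass the
    training list, never held-out material.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = count_expressions(training_docs)
    kept = sorted(e for e, c in counts.items() if c >= min_count)
    return ExpressionVocabulary(
        expressions=tuple(kept),
        min_count=min_count,
        source_doc_ids=tuple(d.doc_id for d in training_docs),
    )


def vectorize(doc: TaggedDocument, vocab: ExpressionVocabulary) -> DescriptorVector:
    """Binary presence vector of ``doc`` over the vocabulary order."""
    present = {s.expression for s in doc.sentences}
    bits = np.fromiter(
        (1 if e in present else 0 for e in vocab.expressions),
        dtype=np.uint8,
        count=len(vocab),
    )
    return DescriptorVector(doc_id=doc.doc_id, bits=bits)


def vectorize_corpus(
    docs: Sequence[TaggedDocument], vocab: ExpressionVocabulary
) -> tuple[list[str], np.ndarray]:
    """Stack descriptors into an (n_docs, |vocab|) matrix."""
    ids = [d.doc_id for d in docs]
    if not docs:
        return ids, np.zeros((0, len(vocab)), dtype=np.uint8)
    X = np.vstack([vectorize(d, vocab).bits for d in docs])
    return ids, X
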