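"""Synthetic labeled corpora with planted, tunable class signal.

Documents are built directly at the tag-sentence level: a positive
(negative) document contains each planted *signal pattern* — a fixed chain
of category tags — with probability ``p_signal_pos`` (``p_signal_neg``),
plus label-independent background patterns and random filler sentences.
Because the class signal lives entirely in a small set of known patterns,
the optimal (Bayes) accuracy is computable by exact enumeration, giving the
classifier stack a ceiling it must not beat.

An optional *surface realization* mode wraps every tag in a literal term
the shipped lexicons recognise (``OGLCNAC`` becomes ``oglcnacylation``,
``PROTEIN`` becomes ``tau``, ...) interleaved with untagged filler words,
so the cleaning/tagging pipeline is exercised end to end and recovers the
planted tag sentences exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from glycurate.text_pipeline import (
    Lexicons,
    RawDocument,
    TaggedDocument,
    TagSentence,
    clean_text,
    load_default_lexicons,
    tag_document,
)

__all__ = ["CorpusSpec", "generate", "bayes_accuracy", "corpus_to_tagged", "write_corpus"]

# Tag alphabet mirroring the default lexicon categories.
TAG_ALPHABET = (
    "PROTEIN",
    "ORGANISM",
    "OGLCNAC",
    "STSITES",
    "PHOSPHO",
    "METHODS",
    "CELLS",
    "BIOLOGY",
    "GLYCOBIOLOGY",
    "CONCLUSION",
    "DESCRIPTION",
    "PEPTIDES",
    "NUCLEICACIDS",
    "PRONOMINIAL",
    "AMINOACIDS",
)

# One surface term per tag, each recognised by exactly that default
# lexicon category after cleaning.
SURFACE_TERMS = {
    "PROTEIN": "tau",
    "ORGANISM": "mouse",
    "OGLCNAC": "oglcnacylation",
    "STSITES": "ser400",
    "PHOSPHO": "phosphorylation",
    "METHODS": "immunoblotting",
    "CELLS": "hela",
    "BIOLOGY": "chromatin",
    "GLYCOBIOLOGY": "glycosylation",
    "CONCLUSION": "demonstrated",
    "DESCRIPTION": "observed",
    "PEPTIDES": "peptides",
    "NUCLEICACIDS": "plasmids",
    "PRONOMINIAL": "we",
    "AMINOACIDS": "leucine",
}

_FILLERS = ("of", "the", "in", "at", "with", "was", "by", "on")


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults are the desk-scale analogue of a balanced curation corpus:
    200 documents, half positive, three signal patterns present in 80% of
    positives and 20% of negatives, ten label-independent background
    patterns, 8-15 sentences per document.
    """

    n_docs: int = 200
    positive_fraction: float = 0.5
    n_signal_patterns: int = 3
    n_background_patterns: int = 10
    p_signal_pos: float = 0.8
    p_signal_neg: float = 0.2
    p_background: float = 0.3
    sentences_per_doc: tuple[int, int] = (8, 15)
    surface: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_docs < 2:
            raise ValueError("n_docs must be >= 2")
        for p in (
            self.positive_fraction,
            self.p_signal_pos,
            self.p_signal_neg,
            self.p_background,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_signal_pos < self.p_signal_neg:
            raise ValueError("p_signal_pos must be >= p_signal_neg for a learnable signal")
        lo, hi = self.sentences_per_doc
        if lo < 1 or hi < lo:
            raise ValueError("sentences_per_doc must be a valid (low, high) range")


def _random_patterns(rng: np.random.Generator, n: int, taken: set[str]) -> list[tuple[str, ...]]:
    patterns: list[tuple[str, ...]] = []
    while len(patterns) < n:
        length = int(rng.integers(3, 6))
        chain = tuple(TAG_ALPHABET[i] for i in rng.integers(0, len(TAG_ALPHABET), size=length))
        key = " ".join(chain)
        if key not in taken:
            taken.add(key)
            patterns.append(chain)
    return patterns


def _realize(tags: Sequence[str], rng: np.random.Generator) -> str:
    """Wrap a tag chain in surface terms with untagged filler words."""
    words = []
    for tag in tags:
        words.append(SURFACE_TERMS[tag])
        words.append(str(_FILLERS[int(rng.integers(0, len(_FILLERS)))]))
    return " ".join(words[:-1])


def generate(spec: CorpusSpec) -> tuple[list[RawDocument], list[dict]]:
    """Generate labeled documents plus the planted-pattern ground truth.

    Returns ``(documents, truth_table)`` where each truth row records a
    pattern, its kind (signal/background) and its per-class inclusion
    probabilities.  Reproducible: a fixed seed yields byte-identical text.
    """
    rng = np.random.default_rng(spec.seed)
    # separate stream for surface filler words so the tag-level structure
    # of a corpus is identical across modes for the same seed
    realize_rng = np.random.default_rng(None if spec.seed is None else spec.seed + 999_983)
    taken: set[str] = set()
    signal = _random_patterns(rng, spec.n_signal_patterns, taken)
    background = _random_patterns(rng, spec.n_background_patterns, taken)

    n_pos = round(spec.n_docs * spec.positive_fraction)
    labels = ["positive"] * n_pos + ["negative"] * (spec.n_docs - n_pos)
    rng.shuffle(labels)

    docs = []
    lo, hi = spec.sentences_per_doc
    for i, label in enumerate(labels):
        p_signal = spec.p_signal_pos if label == "positive" else spec.p_signal_neg
        sentences: list[tuple[str, ...]] = []
        for pattern in signal:
            if rng.random() < p_signal:
                sentences.append(pattern)
        for pattern in background:
            if rng.random() < spec.p_background:
                sentences.append(pattern)
        n_total = int(rng.integers(lo, hi + 1))
        while len(sentences) < n_total:
            length = int(rng.integers(2, 5))
            chain = tuple(
                TAG_ALPHABET[j] for j in rng.integers(0, len(TAG_ALPHABET), size=length)
            )
            # filler must stay label-neutral: never collide with a planted pattern
            if " ".join(chain) in taken:
                continue
            sentences.append(chain)
        rng.shuffle(sentences)
        if spec.surface:
            text = ". ".join(_realize(s, realize_rng) for s in sentences) + "."
        else:
            text = ". ".join(" ".join(s) for s in sentences) + "."
        docs.append(RawDocument(doc_id=f"SYN{i:05d}", text=text, label=label))

    truth = []
    for pattern in signal:
        truth.append(
            {
                "pattern": " ".join(pattern),
                "kind": "signal",
                "p_pos": spec.p_signal_pos,
                "p_neg": spec.p_signal_neg,
            }
        )
    for pattern in background:
        truth.append(
            {
                "pattern": " ".join(pattern),
                "kind": "background",
                "p_pos": spec.p_background,
                "p_neg": spec.p_background,
            }
        )
    return docs, truth


def bayes_accuracy(spec: CorpusSpec, max_patterns: int = 12) -> float:
    """Optimal expected accuracy by exact enumeration over signal patterns.

    Background patterns and filler sentences carry no label information, so
    the optimal classifier observes only the presence/absence configuration
    of the signal patterns; the expected accuracy of the Bayes rule is
    ``sum_v max(pi_pos * P(v|pos), pi_neg * P(v|neg))``.  Enumeration is
    refused above ``max_patterns`` planted patterns (2^k configurations).
    """
    k = spec.n_signal_patterns
    if k > max_patterns:
        raise ValueError(f"enumeration over 2^{k} configurations refused (> {max_patterns} patterns)")
    pi_pos = spec.positive_fraction
    pi_neg = 1.0 - pi_pos
    total = 0.0
    for config in itertools.product((0, 1), repeat=k):
        p_v_pos = 1.0
        p_v_neg = 1.0
        for present in config:
            p_v_pos *= spec.p_signal_pos if present else 1.0 - spec.p_signal_pos
            p_v_neg *= spec.p_signal_neg if present else 1.0 - spec.p_signal_neg
        total += max(pi_pos * p_v_pos, pi_neg * p_v_neg)
    return total


def corpus_to_tagged(
    docs: Sequence[RawDocument], lexicons: Optional[Lexicons] = None
) -> list[TaggedDocument]:
    """Convert generated documents to tagged documents.

    Tag-level documents are parsed directly (segments are already tag
    chains); surface-realized documents are routed through the cleaning and
    tagging pipeline using ``lexicons`` (defaults to the shipped ones).
    Surface text is detected by lower-case content.
    """
    tagged = []
    for doc in docs:
        if doc.text and doc.text != doc.text.upper():
            lex = lexicons if lexicons is not None else load_default_lexicons()
            cleaned = clean_text(doc.text, lex.stop_words)
            tagged.append(tag_document(RawDocument(doc.doc_id, cleaned, doc.label), lex))
        else:
            sentences = []
            for segment in doc.text.split("."):
                tags = tuple(segment.split())
                if len(tags) >= 2:
                    sentences.append(TagSentence(tags=tags, source_text=segment.strip()))
            tagged.append(TaggedDocument(doc_id=doc.doc_id, sentences=tuple(sentences)))
    return tagged


def write_corpus(docs: Sequence[RawDocument], truth: Sequence[dict], out_dir: str | Path) -> None:
    """Write the plain-text + label-CSV layout the real pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label_lines = ["doc_id,label"]
    for doc in docs:
        (out / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        label_lines.append(f"{doc.doc_id},{doc.label}")
    (out / "labels.csv").write_text("\n".join(label_lines) + "\n", encoding="utf-8")
    truth_lines = ["pattern,kind,p_pos,p_neg"]
    for row in truth:
        truth_lines.append(f"{row['pattern']},{row['kind']},{row['p_pos']},{row['p_neg']}")
    (out / "ground_truth.csv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
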