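"""Reduce publication text to sentences of category tags.

Documents are cleaned (bracketed spans, stray punctuation and stop-word
phrases removed), narrowed to results/discussion-like sections, and every
token recognised by a category dictionary or pattern is replaced by its
uppercase category tag (``PROTEIN``, ``OGLCNAC``, ``STSITES``, ...).
Untagged material is dropped, and only period-delimited segments retaining
at least two tags survive — these tag sentences are the unit everything
downstream (vocabulary building, vectorisation) consumes.

Matching is case-insensitive. When candidate matches overlap, the longest
leftmost match wins; exact ties are broken by a fixed dictionary priority:
regex categories > protein names > organism names > word lists.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "LexiconError",
    "Lexicons",
    "RawDocument",
    "TagSentence",
    "TaggedDocument",
    "clean_text",
    "select_sections",
    "tag_document",
    "load_default_lexicons",
    "load_documents",
    "DEFAULT_KEEP_SECTIONS",
]

# Dictionary priority when overlapping matches tie on start and length
# (lower = stronger): regex categories, protein names, organisms, word lists.
_PRIORITY_REGEX = 0
_PRIORITY_PROTEIN = 1
_PRIORITY_ORGANISM = 2
_PRIORITY_WORDLIST = 3

PROTEIN_TAG = "PROTEIN"
ORGANISM_TAG = "ORGANISM"

DEFAULT_KEEP_SECTIONS = ("results", "discussion")


class LexiconError(ValueError):
    """Raised for ambiguous or malformed lexicon configuration."""


@dataclass(frozen=True)
class RawDocument:
    """A publication as plain text, optionally carrying a triage label."""

    doc_id: str
    text: str
    label: Optional[str] = None  # "positive" | "negative" | None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.label not in (None, "positive", "negative", "unknown"):
            raise ValueError(f"unknown label: {self.label!r}")


@dataclass(frozen=True)
class TagSentence:
    """An ordered run of category tags from one period-delimited segment."""

    tags: tuple[str, ...]
    source_text: str = ""

    @property
    def expression(self) -> str:
        """The sentence rendered as a space-joined tag chain."""
        return " ".join(self.tags)


@dataclass(frozen=True)
class TaggedDocument:
    doc_id: str
    sentences: tuple[TagSentence, ...]

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "sentences": [
                {"tags": list(s.tags), "source_text": s.source_text}
                for s in self.sentences
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaggedDocument":
        return cls(
            doc_id=d["doc_id"],
            sentences=tuple(
                TagSentence(tuple(s["tags"]), s.get("source_text", ""))
                for s in d["sentences"]
            ),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TaggedDocument":
        return cls.from_dict(json.loads(s))


def _casefold_terms(terms: Iterable[str]) -> frozenset[str]:
    out = set()
    for t in terms:
        t = t.strip().casefold()
        if t:
            out.add(t)
    return frozenset(out)


def _term_alternation(terms: frozenset[str]) -> Optional[re.Pattern]:
    if not terms:
        return None
    # longest-first so the regex engine itself prefers the longer literal
    ordered = sorted(terms, key=len, reverse=True)
    pattern = r"\b(?:" + "|".join(re.escape(t) for t in ordered) + r")\b"
    return re.compile(pattern, re.IGNORECASE)


@dataclass
class Lexicons:
    """Category dictionaries and patterns driving the tagger.

    ``word_lists`` maps a category name (e.g. ``biology``) to a set of
    literal terms; ``regex_lists`` maps a category name to compiled-on-demand
    pattern strings.  ``tag_symbols`` maps every category to the uppercase
    tag emitted for it.  Literal terms are stored case-folded; a literal
    claimed by two word-list categories is a configuration error.
    """

    word_lists: dict[str, frozenset[str]]
    regex_lists: dict[str, list[str]]
    protein_names: frozenset[str] = frozenset()
    organism_names: frozenset[str] = frozenset()
    stop_words: frozenset[str] = frozenset()
    tag_symbols: dict[str, str] = field(default_factory=dict)
    section_patterns: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.word_lists = {k: _casefold_terms(v) for k, v in self.word_lists.items()}
        self.protein_names = _casefold_terms(self.protein_names)
        self.organism_names = _casefold_terms(self.organism_names)
        self.stop_words = _casefold_terms(self.stop_words)

        overlap = set(self.word_lists) & set(self.regex_lists)
        if overlap:
            raise LexiconError(f"categories defined both as word list and regex list: {sorted(overlap)}")
        for cat, patterns in self.regex_lists.items():
            for p in patterns:
                if not p:
                    raise LexiconError(f"empty pattern in regex category {cat!r}")
                re.compile(p)
        claimed: dict[str, str] = {}
        for cat, terms in self.word_lists.items():
            for t in terms:
                if t in claimed:
                    raise LexiconError(
                        f"term {t!r} claimed by both {claimed[t]!r} and {cat!r}"
                    )
                claimed[t] = cat
        for cat in list(self.word_lists) + list(self.regex_lists):
            self.tag_symbols.setdefault(cat, re.sub(r"[^A-Za-z]", "", cat).upper())
        self._compiled: Optional[list[tuple[re.Pattern, str, int]]] = None

    def _matchers(self) -> list[tuple[re.Pattern, str, int]]:
        """All (pattern, tag, priority) matchers, compiled once."""
        if self._compiled is None:
            out: list[tuple[re.Pattern, str, int]] = []
            for cat, patterns in self.regex_lists.items():
                tag = self.tag_symbols[cat]
                for p in patterns:
                    out.append((re.compile(p, re.IGNORECASE), tag, _PRIORITY_REGEX))
            rx = _term_alternation(self.protein_names)
            if rx is not None:
                out.append((rx, PROTEIN_TAG, _PRIORITY_PROTEIN))
            rx = _term_alternation(self.organism_names)
            if rx is not None:
                out.append((rx, ORGANISM_TAG, _PRIORITY_ORGANISM))
            for cat, terms in self.word_lists.items():
                rx = _term_alternation(terms)
                if rx is not None:
                    out.append((rx, self.tag_symbols[cat], _PRIORITY_WORDLIST))
            self._compiled = out
        return self._compiled


_BRACKETED = re.compile(r"\([^()]*\)|\[[^\[\]]*\]|\{[^{}]*\}")
_DISALLOWED = re.compile(r"[^0-9A-Za-z .]")
_MULTISPACE = re.compile(r" {2,}")


def clean_text(text: str, stop_words: Iterable[str] = ()) -> str:
    """Strip bracketed spans, stray characters and stop-word phrases.

    Bracketed/parenthesized spans are removed innermost-first until none
    remain (so nesting is handled); every character outside alphanumerics,
    space and period is deleted in place, merging its neighbours
    (``O-GlcNAc`` becomes ``OGlcNAc``); stop-word phrases are then excised
    case-insensitively at word boundaries.  The function is total and
    idempotent.
    """
    prev = None
    while prev != text:
        prev = text
        text = _BRACKETED.sub(" ", text)
    text = text.replace("\t", " ").replace("\r", " ").replace("\n", " ")
    text = _DISALLOWED.sub("", text)
    text = _MULTISPACE.sub(" ", text).strip()
    folded = _casefold_terms(stop_words)
    if folded:
        alt = _term_alternation(folded)
        assert alt is not None
        # removal can merge neighbours into a fresh stop phrase; iterate
        prev = None
        while prev != text:
            prev = text
            text = _MULTISPACE.sub(" ", alt.sub(" ", text)).strip()
    return text


def select_sections(
    text: str,
    section_patterns: Mapping[str, str],
    keep: Sequence[str] = DEFAULT_KEEP_SECTIONS,
) -> str:
    """Keep only the text governed by results/discussion-like headers.

    ``section_patterns`` maps a section name to a header regular expression
    (matched with ``re.MULTILINE | re.IGNORECASE``).  Each detected header
    governs the span up to the next detected header.  If no header of a
    kept section is found the full text is returned unchanged — converted
    text frequently loses its headers, and dropping everything would be
    worse than triaging the whole document.
    """
    if not section_patterns:
        raise ValueError("section_patterns must be non-empty")
    hits: list[tuple[int, int, str]] = []
    for name, pattern in section_patterns.items():
        for m in re.finditer(pattern, text, re.MULTILINE | re.IGNORECASE):
            hits.append((m.start(), m.end(), name))
    hits.sort()
    kept_spans: list[str] = []
    keep_set = {k.casefold() for k in keep}
    for i, (start, _end, name) in enumerate(hits):
        if name.casefold() not in keep_set:
            continue
        stop = hits[i + 1][0] if i + 1 < len(hits) else len(text)
        kept_spans.append(text[start:stop])
    if not kept_spans:
        return text
    return "\n".join(s.strip() for s in kept_spans)


def _tag_segment(segment: str, lexicons: Lexicons) -> tuple[str, ...]:
    """Resolve overlapping matches in one segment into an ordered tag run."""
    candidates: list[tuple[int, int, int, str]] = []  # (start, -len, priority, tag)
    for rx, tag, priority in lexicons._matchers():
        for m in rx.finditer(segment):
            if m.end() > m.start():
                candidates.append((m.start(), -(m.end() - m.start()), priority, tag))
    candidates.sort()
    tags: list[str] = []
    cursor = 0
    for start, neglen, _priority, tag in candidates:
        if start < cursor:
            continue
        tags.append(tag)
        cursor = start - neglen
    return tuple(tags)


def tag_document(doc: RawDocument, lexicons: Lexicons) -> TaggedDocument:
    """Tag a cleaned document and keep segments with more than one tag.

    The text is split at periods; within each segment every recognised
    token becomes its category tag and everything else is discarded.
    Deterministic: output depends only on the text and the lexicons.
    """
    sentences: list[TagSentence] = []
    for segment in doc.text.split("."):
        segment = segment.strip()
        if not segment:
            continue
        tags = _tag_segment(segment, lexicons)
        if len(tags) >= 2:
            sentences.append(TagSentence(tags=tags, source_text=segment))
    return TaggedDocument(doc_id=doc.doc_id, sentences=tuple(sentences))


def _read_terms(name: str) -> frozenset[str]:
    ref = resources.files("glycurate.lexicons").joinpath(name)
    lines = ref.read_text(encoding="utf-8").splitlines()
    return _casefold_terms(l for l in lines if l.strip() and not l.lstrip().startswith("#"))


def load_default_lexicons() -> Lexicons:
    """Load the lexicons shipped with the package.

    These are editable plain-text/YAML reconstructions of the categories the
    curation pipeline relies on (biology, glycobiology, cells, methods word
    lists; conclusion, description, peptides, nucleic-acids, pronominial,
    ser/thr, amino-acids, phosphorylation and O-GlcNAc patterns; protein,
    organism and stop-word dictionaries); users with richer dictionaries
    should substitute their own files.
    """
    config = yaml.safe_load(
        resources.files("glycurate.lexicons").joinpath("regexes.yml").read_text(encoding="utf-8")
    )
    regex_lists = {cat: list(entry["patterns"]) for cat, entry in config["categories"].items()}
    tag_symbols = {cat: entry["tag"] for cat, entry in config["categories"].items()}
    sections = yaml.safe_load(
        resources.files("glycurate.lexicons").joinpath("sections.yml").read_text(encoding="utf-8")
    )
    return Lexicons(
        word_lists={
            "biology": _read_terms("biology.txt"),
            "glycobiology": _read_terms("glycobiology.txt"),
            "cells": _read_terms("cells.txt"),
            "methods": _read_terms("methods.txt"),
        },
        regex_lists=regex_lists,
        protein_names=_read_terms("proteins.txt"),
        organism_names=_read_terms("organisms.txt"),
        stop_words=_read_terms("stopwords.txt"),
        tag_symbols=tag_symbols,
        section_patterns=dict(sections),
    )


def load_documents(corpus_dir: str | Path, labels_csv: Optional[str | Path] = None) -> list[RawDocument]:
    """Load one-document-per-file corpora (filename stem = doc_id).

    ``labels_csv`` is a two-column ``doc_id,label`` file; documents missing
    from it get ``label=None``.
    """
    labels: dict[str, str] = {}
    if labels_csv is not None:
        for line in Path(labels_csv).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("doc_id"):
                continue
            doc_id, label = (part.strip() for part in line.split(",", 1))
            labels[doc_id] = label
    docs = []
    for path in sorted(Path(corpus_dir).glob("*.txt")):
        doc_id = path.stem
        docs.append(RawDocument(doc_id=doc_id, text=path.read_text(encoding="utf-8"), label=labels.get(doc_id)))
    return docs
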