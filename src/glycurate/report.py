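"""Per-publication curation reports and update-instruction parsing.

A report gathers what a human curator reviews for one publication: the
ensemble's aggregated prediction and three-way call, counts of critical
keywords (protein, organism and method mentions), and the presumably
informative sentences — those whose tag set contains a target combination
such as PROTEIN + OGLCNAC + STSITES.  Database updates arrive as simple
CSV instructions (action, accession, amino_acid, position, pmid, note);
parsing validates every row against its action schema and collects
malformed rows into an error report instead of dropping them silently.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from glycurate.ensemble import AggregatedPrediction, Decision
from glycurate.text_pipeline import Lexicons, TaggedDocument

__all__ = [
    "CurationReport",
    "UpdateRecord",
    "UpdateParseError",
    "count_keywords",
    "informative_sentences",
    "parse_update_instructions",
    "serialize_update_instructions",
    "DEFAULT_TARGET_COMBINATIONS",
]

DEFAULT_TARGET_COMBINATIONS = (("PROTEIN", "OGLCNAC", "STSITES"),)

UPDATE_HEADER = ["action", "accession", "amino_acid", "position", "pmid", "note"]
UPDATE_SCHEMA_VERSION = "1"

# Required fields per action.
_REQUIRED: dict[str, tuple[str, ...]] = {
    "add_protein": ("accession", "pmid"),
    "add_site": ("accession", "amino_acid", "position", "pmid"),
    "add_reference": ("accession", "pmid"),
    "remove": ("accession",),
}


@dataclass(frozen=True)
class UpdateRecord:
    action: str
    accession: str
    amino_acid: str = ""
    position: Optional[int] = None
    pmid: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.action not in _REQUIRED:
            raise ValueError(f"unknown action {self.action!r}")


@dataclass(frozen=True)
class UpdateParseError:
    row: int  # 1-based data-row number
    reason: str


@dataclass
class CurationReport:
    doc_id: str
    prediction: AggregatedPrediction
    decision: Decision
    keyword_counts: dict[str, dict[str, int]]
    informative_sentences: list[tuple[str, tuple[str, ...]]]

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "prediction": {
                "p_hat": self.prediction.p_hat,
                "ci_low": self.prediction.ci_low,
                "ci_high": self.prediction.ci_high,
                "n_models": self.prediction.n_models,
                "votes": list(self.prediction.votes),
                "call": self.decision.call,
            },
            "keyword_counts": self.keyword_counts,
            "informative_sentences": [
                {"source_text": text, "combination": list(combo)}
                for text, combo in self.informative_sentences
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        lines = [
            f"# Curation report — {self.doc_id}",
            "",
            f"**Call:** {self.decision.call}  ",
            f"**Aggregated vote:** {self.prediction.p_hat:.2f} "
            f"[{self.prediction.ci_low:.2f}, {self.prediction.ci_high:.2f}] "
            f"({self.prediction.n_models} models: {list(self.prediction.votes)})",
            "",
            "## Keywords",
        ]
        for category in sorted(self.keyword_counts):
            terms = self.keyword_counts[category]
            rendered = ", ".join(f"{t} ({n})" for t, n in sorted(terms.items()))
            lines.append(f"- **{category}**: {rendered}")
        if not self.keyword_counts:
            lines.append("- none detected")
        lines.append("")
        lines.append("## Informative sentences")
        if self.informative_sentences:
            for text, combo in self.informative_sentences:
                lines.append(f"- [{' + '.join(combo)}] {text}")
        else:
            lines.append("- none")
        return "\n".join(lines) + "\n"


def count_keywords(
    clean_text: str, lexicons: Lexicons
) -> dict[str, dict[str, int]]:
    """Case-insensitive per-term occurrence counts of critical keywords.

    Counts protein names, organism names and method terms (the dictionaries
    a curator scans first); terms with zero occurrences are omitted.
    """
    dictionaries = {
        "proteins": lexicons.protein_names,
        "organisms": lexicons.organism_names,
        "methods": lexicons.word_lists.get("methods", frozenset()),
    }
    out: dict[str, dict[str, int]] = {}
    for category, terms in dictionaries.items():
        counts: dict[str, int] = {}
        for term in terms:
            n = len(re.findall(rf"\b{re.escape(term)}\b", clean_text, re.IGNORECASE))
            if n:
                counts[term] = n
        if counts:
            out[category] = counts
    return out


def informative_sentences(
    tagged: TaggedDocument,
    targets: Sequence[Sequence[str]] = DEFAULT_TARGET_COMBINATIONS,
) -> list[tuple[str, tuple[str, ...]]]:
    """Sentences whose tag set contains a target combination.

    A sentence is reported once per matching combination (subset
    semantics: the sentence may carry extra tags).
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    out = []
    for sentence in tagged.sentences:
        tag_set = set(sentence.tags)
        for combo in targets:
            if set(combo) <= tag_set:
                out.append((sentence.source_text, tuple(combo)))
    return out


def build_report(
    tagged: TaggedDocument,
    clean_text: str,
    prediction: AggregatedPrediction,
    decision: Decision,
    lexicons: Lexicons,
    targets: Sequence[Sequence[str]] = DEFAULT_TARGET_COMBINATIONS,
) -> CurationReport:
    return CurationReport(
        doc_id=tagged.doc_id,
        prediction=prediction,
        decision=decision,
        keyword_counts=count_keywords(clean_text, lexicons),
        informative_sentences=informative_sentences(tagged, targets),
    )


def parse_update_instructions(
    text: str,
) -> tuple[list[UpdateRecord], list[UpdateParseError]]:
    """Parse CSV update instructions; malformed rows become errors, never drops.

    Expected header: ``action,accession,amino_acid,position,pmid,note``
    (an optional leading ``# version=...`` comment is allowed).  Returns
    ``(records, errors)`` where each error names the 1-based data row and
    the reason.
    """
    lines = [l for l in text.splitlines() if not l.lstrip().startswith("#")]
    if not lines:
        raise ValueError("instruction file has no header row")
    reader = csv.DictReader(io.StringIO("\n".join(lines)))
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != UPDATE_HEADER:
        raise ValueError(
            f"unexpected header {reader.fieldnames}; expected {UPDATE_HEADER}"
        )
    records: list[UpdateRecord] = []
    errors: list[UpdateParseError] = []
    for i, row in enumerate(reader, start=1):
        action = (row.get("action") or "").strip()
        if action not in _REQUIRED:
            errors.append(UpdateParseError(row=i, reason=f"unknown action {action!r}"))
            continue
        missing = [f for f in _REQUIRED[action] if not (row.get(f) or "").strip()]
        if missing:
            errors.append(
                UpdateParseError(row=i, reason=f"{action}: missing field(s) {', '.join(missing)}")
            )
            continue
        position_raw = (row.get("position") or "").strip()
        position: Optional[int] = None
        if position_raw:
            try:
                position = int(position_raw)
                if position < 1:
                    raise ValueError
            except ValueError:
                errors.append(
                    UpdateParseError(row=i, reason=f"invalid position {position_raw!r}")
                )
                continue
        records.append(
            UpdateRecord(
                action=action,
                accession=(row.get("accession") or "").strip(),
                amino_acid=(row.get("amino_acid") or "").strip().upper(),
                position=position,
                pmid=(row.get("pmid") or "").strip(),
                note=(row.get("note") or "").strip(),
            )
        )
    return records, errors


def serialize_update_instructions(records: Iterable[UpdateRecord]) -> str:
    """Inverse of :func:`parse_update_instructions` (round-trip safe)."""
    buf = io.StringIO()
    buf.write(f"# version={UPDATE_SCHEMA_VERSION}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(UPDATE_HEADER)
    for r in records:
        writer.writerow(
            [r.action, r.accession, r.amino_acid, "" if r.position is None else r.position, r.pmid, r.note]
        )
    return buf.getvalue()
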