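"""PTM-site quality control, in-silico digestion and consensus matrices.

Coordinates are 1-based and intervals fully closed throughout, matching
UniProt site-annotation convention.  A claimed O-GlcNAc site passes QC only
if its position lies inside the protein sequence, the sequence letter at
that position equals the claimed residue, and the residue is a serine or
threonine (the modification targets S/T hydroxyls).  Digestion follows the
standard tryptic rule (cleave C-terminal to K or R, blocked when the next
residue is proline) or a user-supplied rule; partial digestion enumerates
peptides with up to ``max_missed`` internal missed cleavages.  Consensus
matrices tally residue frequencies at offsets around aligned sites, with
per-column information content in bits for sequence-logo rendering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "SiteAnnotation",
    "DigestSpec",
    "Peptide",
    "ConsensusMatrix",
    "qc_site",
    "digest",
    "consensus",
    "classify_ptm_overlap",
    "read_fasta",
    "read_sites",
    "plot_logo",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)} "
                "(ambiguity codes B/Z/X/U/O are rejected, not coerced)"
            )


@dataclass(frozen=True)
class SiteAnnotation:
    accession: str
    amino_acid: str
    position: int  # 1-based

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if len(self.amino_acid) != 1:
            raise ValueError("amino_acid must be a single letter")


@dataclass(frozen=True)
class DigestSpec:
    protease: str = "trypsin"  # "trypsin" | "custom"
    custom_rule: Optional[tuple[str, str]] = None  # (cleave-after, blocked-next)
    mode: str = "full"  # "full" | "partial"
    max_missed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "partial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "full" and self.max_missed != 0:
            raise ValueError("full digestion implies max_missed = 0")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.protease == "trypsin":
            pass
        elif self.protease == "custom":
            if self.custom_rule is None:
                raise ValueError("custom protease requires custom_rule")
        else:
            raise ValueError(f"unknown protease {self.protease!r} without custom_rule")

    @property
    def rule(self) -> tuple[str, str]:
        if self.protease == "trypsin":
            return ("KR", "P")
        assert self.custom_rule is not None
        return self.custom_rule


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int  # 1-based, closed interval
    end: int
    missed_cleavages: int


def qc_site(site: SiteAnnotation, record: ProteinRecord) -> str:
    """Validate a claimed site; returns ok / out_of_range / residue_mismatch / not_ser_thr."""
    if site.accession != record.accession:
        raise ValueError(
            f"accession mismatch: site {site.accession!r} vs record {record.accession!r}"
        )
    if site.position > len(record.sequence):
        return "out_of_range"
    actual = record.sequence[site.position - 1]
    if actual != site.amino_acid.upper():
        return "residue_mismatch"
    if actual not in "ST":
        return "not_ser_thr"
    return "ok"


def cleavage_sites(sequence: str, rule: tuple[str, str]) -> list[int]:
    """0-based cut positions (cut between i-1 and i) under (after, blocked)."""
    after, blocked = rule
    cuts = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in after and sequence[i] not in blocked:
            cuts.append(i)
    return cuts


def digest(record: ProteinRecord, spec: DigestSpec) -> list[Peptide]:
    """Cleave a protein into peptides with 1-based closed coordinates.

    Full mode returns the unique maximal cleavage partition (peptides tile
    the sequence).  Partial mode additionally returns every peptide
    spanning up to ``max_missed`` internal cleavage sites, i.e. every run
    of up to ``max_missed + 1`` consecutive fragments.  Output is ordered
    by start position, then length.
    """
    seq = record.sequence
    cuts = cleavage_sites(seq, spec.rule)
    bounds = [0] + cuts + [len(seq)]
    fragments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    max_missed = spec.max_missed if spec.mode == "partial" else 0
    peptides = []
    for i in range(len(fragments)):
        for missed in range(min(max_missed, len(fragments) - 1 - i) + 1):
            start = fragments[i][0]
            end = fragments[i + missed][1]
            peptides.append(
                Peptide(
                    sequence=seq[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=missed,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


@dataclass
class ConsensusMatrix:
    """Residue frequencies around aligned sites, one column per offset."""

    half_window: int
    counts: np.ndarray  # (2w+1, 20) observation counts
    n_sites: int

    @property
    def offsets(self) -> list[int]:
        return list(range(-self.half_window, self.half_window + 1))

    @property
    def freqs(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return f

    @property
    def info_content(self) -> np.ndarray:
        """Per-offset information content: log2(20) minus column entropy."""
        f = self.freqs
        out = np.zeros(f.shape[0])
        for i in range(f.shape[0]):
            if self.counts[i].sum() == 0:
                continue
            p = f[i][f[i] > 0]
            entropy = float(-(p * np.log2(p)).sum())
            out[i] = MAX_BITS - entropy
        return out

    def to_csv(self, path: str | Path) -> None:
        lines = ["offset," + ",".join(AMINO_ACIDS) + ",n,info_bits"]
        info = self.info_content
        f = self.freqs
        for i, offset in enumerate(self.offsets):
            freqs = ",".join(f"{x:.6f}" for x in f[i])
            lines.append(f"{offset},{freqs},{int(self.counts[i].sum())},{info[i]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def consensus(
    sites: Sequence[SiteAnnotation],
    records: Mapping[str, ProteinRecord],
    half_window: int = 7,
) -> ConsensusMatrix:
    """Position-frequency matrix of the residues flanking validated sites.

    Sites failing QC (or lacking a sequence) are excluded with a logged
    warning rather than aborting — a self-maintaining pipeline keeps going.
    Offsets beyond a protein's termini contribute nothing to that column.
    """
    counts = np.zeros((2 * half_window + 1, 20), dtype=np.int64)
    n_valid = 0
    for site in sites:
        record = records.get(site.accession)
        if record is None:
            logger.warning("consensus: no sequence for %s; site skipped", site.accession)
            continue
        flag = qc_site(site, record)
        if flag != "ok":
            logger.warning(
                "consensus: %s %s%d failed QC (%s); site skipped",
                site.accession,
                site.amino_acid,
                site.position,
                flag,
            )
            continue
        n_valid += 1
        for col, offset in enumerate(range(-half_window, half_window + 1)):
            pos = site.position + offset  # 1-based
            if 1 <= pos <= len(record.sequence):
                counts[col, _AA_INDEX[record.sequence[pos - 1]]] += 1
    if n_valid == 0:
        raise ValueError("no site passed QC; cannot build a consensus matrix")
    return ConsensusMatrix(half_window=half_window, counts=counts, n_sites=n_valid)


def classify_ptm_overlap(
    oglcnac_sites: Iterable[int], phospho_sites: Iterable[int]
) -> dict[int, str]:
    """Partition positions into oglcnac / phospho / dual over the union."""
    og = set(oglcnac_sites)
    ph = set(phospho_sites)
    out: dict[int, str] = {}
    for pos in og | ph:
        if pos in og and pos in ph:
            out[pos] = "dual"
        elif pos in og:
            out[pos] = "oglcnac"
        else:
            out[pos] = "phospho"
    return out


def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Load sequences keyed by the first header token (the accession)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        records[accession] = ProteinRecord(accession=accession, sequence=str(rec.seq).upper())
    return records


def read_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read accession/amino_acid/position annotations from CSV or TSV."""
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"accession", "amino_acid", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return [
        SiteAnnotation(
            accession=str(row.accession),
            amino_acid=str(row.amino_acid).upper(),
            position=int(row.position),
        )
        for row in df.itertuples()
    ]


def plot_logo(matrix: ConsensusMatrix, path: str | Path) -> None:
    """Render a simple sequence logo (letters stacked to information content)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freqs = matrix.freqs
    info = matrix.info_content
    fig, ax = plt.subplots(figsize=(max(6, len(matrix.offsets) * 0.5), 3))
    for i, offset in enumerate(matrix.offsets):
        heights = freqs[i] * info[i]
        order = np.argsort(heights)
        y = 0.0
        for j in order:
            if heights[j] <= 0:
                continue
            ax.text(
                offset,
                y + heights[j] / 2,
                AMINO_ACIDS[j],
                ha="center",
                va="center",
                fontsize=8 + 10 * heights[j] / MAX_BITS,
                fontweight="bold",
            )
            y += heights[j]
    ax.set_xlim(matrix.offsets[0] - 1, matrix.offsets[-1] + 1)
    ax.set_ylim(0, MAX_BITS)
    ax.set_xlabel("offset from site")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
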