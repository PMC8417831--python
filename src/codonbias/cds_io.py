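"""CDS FASTA input, completeness filtering, and codon tokenization.

A coding sequence enters the statistics only if it looks like a complete
CDS: longer than 300 bp, in frame, starting with ATG, ending with a
termination codon, with no internal stop and no ambiguous base inside a
codon.  Rejected records carry the first criterion they failed, so a
rejection report can be written alongside the kept set.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .genetic_code import CODON_TO_AA, STOP, STOP_CODONS, dna


@dataclass(frozen=True)
class CdsRecord:
    """One CDS entry: identifier plus upper-case DNA sequence."""

    gene_id: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class CodonCountTable:
    """Per-gene codon counts, the substrate of every statistic.

    ``counts`` covers sense codons only; the terminal stop is recorded
    separately and never enters any statistic.  ``n_codons`` equals the
    sum of the sense-codon counts.
    """

    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)
    stop_codon: str | None = None

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str, default: int = 0) -> int:
        return self.counts.get(codon, default)


#: Rejection reasons, in the order the criteria are checked.
REASON_LENGTH = "length"
REASON_FRAME = "frame"
REASON_START = "start-codon"
REASON_STOP = "stop-codon"
REASON_INTERNAL_STOP = "internal-stop"
REASON_AMBIGUOUS = "ambiguous-base"


def read_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a (optionally gzipped) FASTA file into CDS records.

    The gene id is the first whitespace-delimited token of the header.
    Sequences are upper-cased and RNA is normalized to DNA.

    Raises
    ------
    ValueError
        On an empty file or duplicate gene ids.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[CdsRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id!r}")
            seen.add(rec.id)
            records.append(CdsRecord(rec.id, dna(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[CdsRecord], path: str | Path, width: int = 70) -> None:
    """Write records as multi-line FASTA."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def _first_failure(seq: str, min_length: int) -> str | None:
    if len(seq) <= min_length:
        return REASON_LENGTH
    if len(seq) % 3 != 0:
        return REASON_FRAME
    if seq[:3] != "ATG":
        return REASON_START
    if seq[-3:] not in STOP_CODONS:
        return REASON_STOP
    for i in range(0, len(seq) - 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            return REASON_INTERNAL_STOP
    if "N" in seq:
        return REASON_AMBIGUOUS
    return None


def filter_cds(
    records: Sequence[CdsRecord],
    *,
    min_length: int = 300,
    reject_ambiguous: bool = True,
) -> tuple[list[CdsRecord], list[tuple[CdsRecord, str]]]:
    """Partition records into (kept, rejected-with-reason).

    Kept records are complete CDSs: strictly longer than ``min_length``
    bp, length divisible by 3, ATG start, terminal stop, no internal
    stop, and (by default) no N anywhere.  Each rejected record carries
    the first criterion it failed.  Filtering is idempotent and the two
    outputs partition the input.
    """
    kept: list[CdsRecord] = []
    rejected: list[tuple[CdsRecord, str]] = []
    for rec in records:
        reason = _first_failure(rec.sequence, min_length)
        if reason == REASON_AMBIGUOUS and not reject_ambiguous:
            reason = None
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def rejection_report(rejected: Sequence[tuple[CdsRecord, str]]) -> pd.DataFrame:
    """Rejected records as a two-column table (gene_id, reason)."""
    return pd.DataFrame(
        [(rec.gene_id, reason) for rec, reason in rejected],
        columns=["gene_id", "reason"],
    )


def count_codons(record: CdsRecord) -> CodonCountTable:
    """Tokenize a filtered CDS into non-overlapping codons from position 1.

    The terminal stop is recorded on the table but excluded from
    ``n_codons``.  3 * n_codons + 3 == length_nt for a complete CDS.

    Raises
    ------
    ValueError
        If the sequence length is not a multiple of 3 (unreachable for
        records that passed :func:`filter_cds`).
    """
    seq = record.sequence
    if len(seq) % 3 != 0:
        raise ValueError(
            f"{record.gene_id}: length {len(seq)} not divisible by 3"
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stop = codons[-1] if codons and codons[-1] in STOP_CODONS else None
    if stop is not None:
        codons = codons[:-1]
    counts = Counter(codons)
    bad = [c for c in counts if CODON_TO_AA.get(c, STOP) == STOP]
    if bad:
        raise ValueError(
            f"{record.gene_id}: internal stop or invalid codons {sorted(bad)}"
        )
    return CodonCountTable(record.gene_id, dict(counts), stop)


def pool_counts(tables: Iterable[CodonCountTable], gene_id: str = "pooled") -> CodonCountTable:
    """Sum codon counts over genes (used for group-level RSCU)."""
    total: Counter[str] = Counter()
    for t in tables:
        total.update(t.counts)
    return CodonCountTable(gene_id, dict(total))
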