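"""tRNA gene copy numbers, wobble decoding, and codon-supply correlation.

Anticodon copy numbers come from tRNAscan-SE tabular output (or a plain
two-column anticodon/count TSV).  An anticodon, written 5'->3', pairs
antiparallel with its codon, so without wobble it reads exactly the
reverse-complement codon.  With Crick wobble enabled, the anticodon's
first (5') base relaxes pairing at the codon third position:

* anticodon 5' G reads codon-3' C **and** T (e.g. GCT reads AGC and AGT),
* anticodon 5' T reads codon-3' A **and** G (e.g. TTG reads CAA and CAG),
* anticodon 5' A or C reads a single codon.

Inosine wobble is deliberately not modeled.  Codon usage is then
correlated (Pearson) with tRNA availability — the summed copy number of
anticodons able to read each codon — within degeneracy-class groups:
the nine 2-fold amino acids, or the eight with four or more codons.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .genetic_code import (
    AA_TO_CODONS,
    SENSE_CODONS,
    dna,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: Amino acids with exactly two synonymous codons.
TWO_CODON_GROUP = ("Y", "F", "K", "H", "E", "Q", "C", "D", "N")
#: Amino acids with four or more synonymous codons.
FOUR_PLUS_GROUP = ("V", "T", "S", "P", "L", "G", "R", "A")

_WOBBLE_THIRD = {"G": ("C", "T"), "T": ("A", "G"), "A": ("T",), "C": ("G",)}


class AnticodonTable(dict):
    """anticodon (DNA, 5'->3') -> tRNA gene copy count."""

    @property
    def total_copies(self) -> int:
        return sum(self.values())


def _looks_like_trnascan(lines: list[str]) -> bool:
    return any(set(line.strip()) <= {"-", "\t", " "} and "-" in line for line in lines[:5])


def parse_trnascan(path: str | Path, exclude_pseudogenes: bool = True) -> AnticodonTable:
    """Aggregate anticodon copy counts from tRNAscan-SE output or a 2-column TSV.

    tRNAscan-SE tabular output carries header lines ending in a dashed
    rule; data columns include isotype (5th) and anticodon (6th), with an
    optional note column flagging pseudogenes.  Undetermined anticodons
    (NNN or containing N) are skipped with a logged count.  Malformed rows
    raise with their line number.
    """
    lines = Path(path).read_text().splitlines()
    table = AnticodonTable()
    skipped_undet = 0
    if _looks_like_trnascan(lines):
        in_data = False
        for lineno, line in enumerate(lines, 1):
            if not in_data:
                if set(line.strip()) <= {"-", "\t", " "} and "-" in line:
                    in_data = True
                continue
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed tRNAscan-SE row")
            anticodon = dna(fields[5])
            note = " ".join(fields[9:]).lower()
            if exclude_pseudogenes and "pseudo" in note:
                continue
            if "N" in anticodon:
                skipped_undet += 1
                continue
            if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
                raise ValueError(f"{path}:{lineno}: invalid anticodon {fields[5]!r}")
            table[anticodon] = table.get(anticodon, 0) + 1
    else:
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            anticodon = dna(fields[0])
            if "N" in anticodon:
                skipped_undet += 1
                continue
            if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
                raise ValueError(f"{path}:{lineno}: invalid anticodon {fields[0]!r}")
            try:
                count = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer count {fields[1]!r}") from None
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative copy count")
            table[anticodon] = table.get(anticodon, 0) + count
    if skipped_undet:
        logger.info("skipped %d undetermined anticodons", skipped_undet)
    return table


def decode_anticodon(anticodon: str, wobble: bool = True) -> frozenset[str]:
    """Set of codons an anticodon can read (wobble at the third position only)."""
    anticodon = dna(anticodon)
    if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
        raise ValueError(f"invalid anticodon: {anticodon!r}")
    cognate = reverse_complement(anticodon)
    if not wobble:
        return frozenset({cognate})
    stem = cognate[:2]
    return frozenset(stem + third for third in _WOBBLE_THIRD[anticodon[0]])


def codon_availability(table: AnticodonTable, wobble: bool = True) -> dict[str, int]:
    """codon -> summed copy number of anticodons able to read it."""
    avail = {codon: 0 for codon in SENSE_CODONS}
    for anticodon, copies in table.items():
        for codon in decode_anticodon(anticodon, wobble):
            if codon in avail:
                avail[codon] += copies
    return avail


def group_codons(group: str) -> tuple[str, ...]:
    """Codons belonging to a degeneracy-class group selector."""
    if group == "twofold":
        aas: Iterable[str] = TWO_CODON_GROUP
    elif group == "fourfold_plus":
        aas = FOUR_PLUS_GROUP
    elif group == "all":
        # single-codon amino acids (Met, Trp) have no synonymous choice
        aas = sorted(TWO_CODON_GROUP + FOUR_PLUS_GROUP + ("I",))
    else:
        raise ValueError(f"unknown group {group!r}; use 'twofold', 'fourfold_plus' or 'all'")
    return tuple(c for aa in aas for c in sorted(AA_TO_CODONS[aa]))


def codon_trna_correlation(
    codon_freqs: Mapping[str, float],
    table: AnticodonTable,
    group: str = "twofold",
    wobble: bool = True,
) -> tuple[float, float, int]:
    """Pearson correlation between codon usage and tRNA availability.

    ``codon_freqs`` may be raw counts or frequencies; it is re-normalized
    within the selected group so the statistic is scale-free.  Returns
    (r, two-sided p, number of codon pairs).

    Raises
    ------
    ValueError
        With fewer than 3 usable pairs, or zero variance on either side
        (the correlation is undefined).
    """
    codons = [c for c in group_codons(group) if c in codon_freqs]
    if len(codons) < 3:
        raise ValueError(f"need >= 3 codons with usage data, got {len(codons)}")
    usage = pd.Series([float(codon_freqs[c]) for c in codons], index=codons)
    total = usage.sum()
    if total > 0:
        usage = usage / total
    avail = codon_availability(table, wobble)
    supply = pd.Series([avail[c] for c in codons], index=codons, dtype=float)
    if usage.nunique() == 1 or supply.nunique() == 1:
        raise ValueError("zero variance in usage or tRNA availability; r undefined")
    r, p = stats.pearsonr(usage, supply)
    return float(r), float(p), len(codons)


def correlation_report(
    codon_freqs: Mapping[str, float],
    table: AnticodonTable,
    wobble: bool = True,
) -> pd.DataFrame:
    """Correlation per degeneracy group, as a small report table."""
    rows = []
    for group in ("twofold", "fourfold_plus", "all"):
        try:
            r, p, n = codon_trna_correlation(codon_freqs, table, group, wobble)
        except ValueError:
            r, p, n = math.nan, math.nan, 0
        rows.append((group, n, r, p))
    return pd.DataFrame(rows, columns=["group", "n_pairs", "r", "p"])
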