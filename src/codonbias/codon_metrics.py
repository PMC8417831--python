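"""Per-gene codon usage statistics: RSCU, ENC, and base-composition fractions.

Definitions
-----------
RSCU
    Relative synonymous codon usage.  For codon *j* of amino acid *i*
    with family size ``n_i`` and count ``x_ij``::

        RSCU_ij = x_ij / ((1 / n_i) * sum_j x_ij)

    i.e. observed over expected under uniform synonymous usage; values
    within an observed family average to 1.  Met and Trp offer no choice
    and are excluded, leaving the canonical 59-codon vector.

ENC
    Wright's effective number of codons, estimated from per-family codon
    homozygosity.  For an amino acid used n >= 2 times with synonymous
    proportions p_j, F = (n * sum p_j^2 - 1) / (n - 1).  Class means of F
    over the 2-, 3-, 4- and 6-fold families give

        ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

    capped at 61.  A gene using exactly one codon per amino acid scores
    20; uniform usage approaches 61.  A missing 3-fold mean (no Ile) is
    imputed as (F2 + F4)/2; a missing 2-, 4- or 6-fold mean makes ENC
    undefined (NaN), as does a zero class mean.

GC partitions
    ``gc1``/``gc2``/``gc3`` are G+C fractions by codon position over all
    sense codons (Met and Trp included); ``gc12`` is their positional
    average (gc1 + gc2)/2.  ``gc3s`` and the third-position base
    fractions ``a3s``/``t3s``/``g3s``/``c3s`` are computed over
    synonymous codons only (Met, Trp and stops excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .cds_io import CodonCountTable
from .genetic_code import (
    AA_TO_CODONS,
    FOURFOLD_AAS,
    SENSE_CODONS,
    SIXFOLD_AAS,
    SYNONYMOUS_AAS,
    SYNONYMOUS_CODONS,
    THREEFOLD_AAS,
    TWOFOLD_AAS,
)

NAN = float("nan")


@dataclass
class GeneProfile:
    """Derived codon-usage metrics for a single gene."""

    gene_id: str
    n_codons: int
    enc: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float
    rscu: dict[str, float] = field(default_factory=dict)
    length_nt: int | None = None


def rscu(counts: CodonCountTable) -> dict[str, float]:
    """RSCU over the 59 synonymous sense codons.

    Families with zero total usage yield NaN (missing), never 0: an
    unobserved family carries no usage information.
    """
    out: dict[str, float] = {}
    for aa in SYNONYMOUS_AAS:
        family = sorted(AA_TO_CODONS[aa])
        total = sum(counts.get(c) for c in family)
        if total == 0:
            for c in family:
                out[c] = NAN
        else:
            n_i = len(family)
            for c in family:
                out[c] = counts.get(c) * n_i / total
    return out


def _family_homozygosity(counts: CodonCountTable, aa: str) -> float | None:
    family = AA_TO_CODONS[aa]
    xs = [counts.get(c) for c in family]
    n = sum(xs)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in xs)
    return (n * sum_p2 - 1) / (n - 1)


def enc(counts: CodonCountTable) -> float:
    """Wright's effective number of codons for one gene (NaN if undefined)."""
    class_means: dict[int, float | None] = {}
    for size, aas in ((2, TWOFOLD_AAS), (3, THREEFOLD_AAS), (4, FOURFOLD_AAS), (6, SIXFOLD_AAS)):
        fs = [f for aa in aas if (f := _family_homozygosity(counts, aa)) is not None]
        class_means[size] = sum(fs) / len(fs) if fs else None
    f2, f3, f4, f6 = (class_means[k] for k in (2, 3, 4, 6))
    if f2 is None or f4 is None or f6 is None:
        return NAN
    if f3 is None:
        f3 = (f2 + f4) / 2
    if min(f2, f3, f4, f6) <= 0:
        return NAN
    value = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
    return min(value, 61.0)


def gc_partition(counts: CodonCountTable) -> tuple[float, float, float, float, float]:
    """(gc, gc1, gc2, gc3, gc12) over all sense codons of the gene."""
    n = counts.n_codons
    if n == 0:
        return (NAN,) * 5
    gc_pos = [0, 0, 0]
    for codon, x in counts.counts.items():
        for i, base in enumerate(codon):
            if base in "GC":
                gc_pos[i] += x
    gc1, gc2, gc3 = (g / n for g in gc_pos)
    gc = sum(gc_pos) / (3 * n)
    return gc, gc1, gc2, gc3, (gc1 + gc2) / 2


def gc3s_and_base3s(counts: CodonCountTable) -> tuple[float, float, float, float, float]:
    """(gc3s, a3s, t3s, g3s, c3s) over synonymous codons only.

    All NaN when the gene has no synonymous codons at all.
    """
    base3 = {"A": 0, "T": 0, "G": 0, "C": 0}
    for codon in SYNONYMOUS_CODONS:
        x = counts.get(codon)
        if x:
            base3[codon[2]] += x
    n = sum(base3.values())
    if n == 0:
        return (NAN,) * 5
    a3s, t3s, g3s, c3s = (base3[b] / n for b in "ATGC")
    return g3s + c3s, a3s, t3s, g3s, c3s


def profile_gene(counts: CodonCountTable, length_nt: int | None = None) -> GeneProfile:
    """Compute the full metric set for one gene's codon counts."""
    gc, gc1, gc2, gc3, gc12 = gc_partition(counts)
    gc3s, a3s, t3s, g3s, c3s = gc3s_and_base3s(counts)
    if length_nt is None:
        length_nt = 3 * counts.n_codons + (3 if counts.stop_codon else 0)
    return GeneProfile(
        gene_id=counts.gene_id,
        n_codons=counts.n_codons,
        enc=enc(counts),
        gc=gc, gc1=gc1, gc2=gc2, gc3=gc3, gc12=gc12,
        gc3s=gc3s, a3s=a3s, t3s=t3s, g3s=g3s, c3s=c3s,
        rscu=rscu(counts),
        length_nt=length_nt,
    )


def profile_genes(tables: Sequence[CodonCountTable]) -> list[GeneProfile]:
    """One profile per gene, in input order; per-gene NaNs never abort the batch."""
    if not tables:
        raise ValueError("no codon count tables supplied")
    return [profile_gene(t) for t in tables]


_SCALAR_COLUMNS = (
    "n_codons", "length_nt", "enc", "gc", "gc1", "gc2", "gc3", "gc12",
    "gc3s", "a3s", "t3s", "g3s", "c3s",
)


def profiles_to_frame(profiles: Iterable[GeneProfile], include_rscu: bool = False) -> pd.DataFrame:
    """Tabulate profiles (gene_id index, fixed column order, NaN = missing)."""
    rows = []
    for p in profiles:
        row = {"gene_id": p.gene_id}
        row.update({c: getattr(p, c) for c in _SCALAR_COLUMNS})
        if include_rscu:
            row.update(p.rscu)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def rscu_matrix(profiles: Sequence[GeneProfile]) -> pd.DataFrame:
    """Genes x 59 RSCU matrix in the canonical codon column order."""
    data = {p.gene_id: [p.rscu.get(c, math.nan) for c in SYNONYMOUS_CODONS] for p in profiles}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(SYNONYMOUS_CODONS))
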