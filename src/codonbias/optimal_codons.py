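"""Optimal-codon identification from the ENC-tail contrast.

High- and low-bias gene groups are the 5% lowest- and highest-ENC tails.
A codon is called optimal when, on pooled counts, its RSCU in the
high-bias group exceeds 1 and exceeds the low-bias RSCU by more than a
delta threshold (default 0.08).  Both thresholds are strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cds_io import CodonCountTable, pool_counts
from .codon_metrics import GeneProfile, rscu
from .genetic_code import AA_TO_CODONS, CODON_TO_AA, SYNONYMOUS_AAS

logger = logging.getLogger(__name__)


@dataclass
class OptimalCodonSet:
    species_label: str
    entries: pd.DataFrame  # codon, amino_acid, rscu_high_bias, rscu_low_bias, delta_rscu

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def codons(self) -> list[str]:
        return list(self.entries["codon"])


def split_enc_tails(
    profiles: Sequence[GeneProfile], fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """(high-bias ids, low-bias ids): the lowest- and highest-ENC tails.

    Tail size is ceil(fraction * n) over genes with defined ENC; ties at
    the boundary break lexicographically by gene id, so the split is
    reproducible regardless of input order.
    """
    defined = sorted(
        ((p.enc, p.gene_id) for p in profiles if not math.isnan(p.enc)),
    )
    n = len(defined)
    if n < 40:
        raise ValueError(f"need >= 40 genes with defined ENC to take 5% tails, got {n}")
    size = math.ceil(fraction * n)
    high_bias = [gid for _, gid in defined[:size]]
    low_bias = [gid for _, gid in sorted(defined, key=lambda t: (-t[0], t[1]))[:size]]
    return high_bias, low_bias


def identify_optimal(
    high_counts: CodonCountTable,
    low_counts: CodonCountTable,
    delta: float = 0.08,
    species_label: str = "",
) -> OptimalCodonSet:
    """Optimal codons from pooled high- vs low-bias codon counts.

    Families absent from either pool contribute no candidates (logged).
    """
    rscu_high = rscu(high_counts)
    rscu_low = rscu(low_counts)
    rows = []
    for aa in SYNONYMOUS_AAS:
        family = sorted(AA_TO_CODONS[aa])
        if any(math.isnan(rscu_high[c]) or math.isnan(rscu_low[c]) for c in family):
            logger.info("family %s absent from a pool; codons skipped", aa)
            continue
        for codon in family:
            d = rscu_high[codon] - rscu_low[codon]
            if rscu_high[codon] > 1 and d > delta:
                rows.append((codon, CODON_TO_AA[codon], rscu_high[codon], rscu_low[codon], d))
    entries = pd.DataFrame(
        rows,
        columns=["codon", "amino_acid", "rscu_high_bias", "rscu_low_bias", "delta_rscu"],
    )
    return OptimalCodonSet(species_label, entries)


def find_optimal_codons(
    profiles: Sequence[GeneProfile],
    tables: Sequence[CodonCountTable],
    fraction: float = 0.05,
    delta: float = 0.08,
    species_label: str = "",
) -> OptimalCodonSet:
    """End-to-end: split ENC tails, pool each tail's counts, apply the rule."""
    by_id = {t.gene_id: t for t in tables}
    high_ids, low_ids = split_enc_tails(profiles, fraction)
    high_pool = pool_counts([by_id[g] for g in high_ids], "high_bias")
    low_pool = pool_counts([by_id[g] for g in low_ids], "low_bias")
    return identify_optimal(high_pool, low_pool, delta, species_label)
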