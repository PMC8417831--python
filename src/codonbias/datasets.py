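"""Small published reference tables bundled for worked examples and checks.

The two tables below list grain-size (GS) homoeolog pairs between hexaploid
bread wheat (Triticum aestivum), wild emmer (T. turgidum) and the A-genome
donor T. urartu, with each gene's published synonymous third-position GC
fraction (GC3s).  They serve as a worked example for the delta-GC3s bias
classification: the printed difference column must be recoverable from the
two GC3s columns, and a pair is codon-usage biased when |delta| > 0.1.
"""

from __future__ import annotations

import pandas as pd

#: (aestivum gene, urartu gene, GC3s aestivum, GC3s urartu, published difference)
GS_PAIRS_AESTIVUM_URARTU: tuple[tuple[str, str, float, float, float], ...] = (
    ("TraesCS1A02G083000.1", "TRIUR3_14996-T1", 0.841, 0.524, 0.317),
    ("TraesCS4A02G012100.1", "TRIUR3_05970-T1", 0.975, 0.793, 0.182),
    ("TraesCS2A02G013200.1", "TRIUR3_33526-T1", 0.756, 0.654, 0.102),
    ("TraesCS5A02G215100.1", "TRIUR3_34310-T1", 0.766, 0.953, -0.187),
    ("TraesCS7A02G120000.1", "TRIUR3_08952-T1", 0.603, 0.340, 0.263),
    ("TraesCS7A02G246500.1", "TRIUR3_09477-T1", 0.779, 0.536, 0.243),
    ("TraesCS4A02G430600.1", "TRIUR3_35245-T1", 0.963, 0.566, 0.397),
)

#: (turgidum gene, urartu gene, GC3s turgidum, GC3s urartu, published difference)
GS_PAIRS_TURGIDUM_URARTU: tuple[tuple[str, str, float, float, float], ...] = (
    ("TRIDC4AG041610.1", "TRIUR3_05970-T1", 0.911, 0.793, 0.118),
    ("TRIDC6AG039380.2", "TRIUR3_33526-T1", 0.784, 0.654, 0.130),
    ("TRIDC5AG033880.1", "TRIUR3_34310-T1", 0.763, 0.953, -0.190),
    ("TRIDC7BG002860.6", "TRIUR3_08952-T1", 0.512, 0.340, 0.172),
    ("TRIDC7AG069150.1", "TRIUR3_09477-T1", 0.911, 0.536, 0.375),
    ("TRIDC7AG067090.1", "TRIUR3_33769-T1", 0.910, 0.441, 0.469),
    ("TRIDC7AG065170.7", "TRIUR3_09129-T1", 0.830, 0.655, 0.175),
)

_COLUMNS = ["gene_a", "gene_b", "gc3s_a", "gc3s_b", "published_difference"]


def gs_pairs_aestivum_urartu() -> pd.DataFrame:
    """GS homoeolog pairs, bread wheat (A subgenome) vs T. urartu."""
    return pd.DataFrame(GS_PAIRS_AESTIVUM_URARTU, columns=_COLUMNS)


def gs_pairs_turgidum_urartu() -> pd.DataFrame:
    """GS homoeolog pairs, wild emmer vs T. urartu."""
    return pd.DataFrame(GS_PAIRS_TURGIDUM_URARTU, columns=_COLUMNS)
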