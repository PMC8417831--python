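"""Gene-length bins and chromosome-window tracks.

Two genome-structure summaries: mean GC3s by CDS-length category
(<1000, 1000-2000, 2000-3000, >3000 bp; lower edges inclusive), and
per-window, per-strand gene density plus median GC3 suitable for CIRCOS
style chromosome tracks.  Input gene coordinates are 1-based inclusive
(GFF convention); emitted tracks are 0-based half-open (BED convention).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_metrics import GeneProfile

LENGTH_BINS = ((1, 999, "<1000"), (1000, 1999, "1000-2000"),
               (2000, 2999, "2000-3000"), (3000, None, ">3000"))


def length_bin(length_nt: int) -> str:
    """Length-category label for a CDS of ``length_nt`` bp."""
    if length_nt < 1:
        raise ValueError(f"non-positive CDS length: {length_nt}")
    for lo, hi, label in LENGTH_BINS:
        if length_nt >= lo and (hi is None or length_nt <= hi):
            return label
    raise AssertionError("unreachable: bins partition the positive integers")


def bin_by_length(
    profiles: Sequence[GeneProfile],
    lengths: Mapping[str, int] | None = None,
    group: str = "",
) -> pd.DataFrame:
    """Gene counts and mean GC3s per length category.

    ``lengths`` overrides the per-profile ``length_nt`` when given (e.g.
    genomic CDS spans rather than spliced lengths).  The mean is a simple
    (unweighted) gene mean over genes with defined GC3s.
    """
    labels = [label for _, _, label in LENGTH_BINS]
    rows = {label: [] for label in labels}
    for p in profiles:
        length = lengths[p.gene_id] if lengths is not None else p.length_nt
        if length is None:
            raise ValueError(f"no length available for gene {p.gene_id}")
        rows[length_bin(length)].append(p.gc3s)
    out = []
    for label in labels:
        vals = [v for v in rows[label] if not math.isnan(v)]
        out.append((group, label, len(rows[label]),
                    float(np.mean(vals)) if vals else math.nan))
    return pd.DataFrame(out, columns=["group", "bin", "n_genes", "mean_gc3s"])


def window_tracks(
    gene_table: pd.DataFrame,
    profiles: Sequence[GeneProfile],
    chrom_sizes: Mapping[str, int],
    window_size: int = 10_000_000,
    metric: str = "gc3",
    assign_by: str = "start",
) -> pd.DataFrame:
    """Per-window, per-strand gene count and median GC3 (or GC3s).

    ``gene_table`` needs columns gene_id, chrom, start, end, strand with
    1-based inclusive coordinates.  Windows tile each chromosome from 0
    in steps of ``window_size``; a gene belongs to the window containing
    its start (or midpoint with ``assign_by="midpoint"``).  Every window
    appears for both strands; empty ones carry count 0 and NaN median.

    Raises
    ------
    ValueError
        If any gene sits on a chromosome absent from ``chrom_sizes``
        (all offenders are listed).
    """
    if metric not in ("gc3", "gc3s"):
        raise ValueError(f"metric must be 'gc3' or 'gc3s', got {metric!r}")
    if assign_by not in ("start", "midpoint"):
        raise ValueError(f"assign_by must be 'start' or 'midpoint', got {assign_by!r}")
    values = {p.gene_id: getattr(p, metric) for p in profiles}
    unknown = sorted(set(gene_table["chrom"]) - set(chrom_sizes))
    if unknown:
        raise ValueError(f"genes on unknown chromosomes: {unknown}")

    # accumulate per (chrom, window index, strand)
    bucket: dict[tuple[str, int, str], list[float]] = {}
    for row in gene_table.itertuples(index=False):
        pos0 = (row.start - 1) if assign_by == "start" else (row.start - 1 + row.end) // 2
        widx = pos0 // window_size
        bucket.setdefault((row.chrom, widx, row.strand), []).append(
            values.get(row.gene_id, math.nan)
        )

    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_windows = max(1, math.ceil(size / window_size))
        for widx in range(n_windows):
            start = widx * window_size
            end = min(size, start + window_size)
            for strand in ("+", "-"):
                members = bucket.get((chrom, widx, strand), [])
                defined = [v for v in members if not math.isnan(v)]
                rows.append((chrom, start, end, strand, len(members),
                             float(np.median(defined)) if defined else math.nan))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_count", f"median_{metric}"]
    )


def tracks_to_bedgraph(tracks: pd.DataFrame, column: str, strand: str) -> str:
    """Serialize one (metric, strand) track as bedGraph text (NaN rows dropped)."""
    sel = tracks[(tracks["strand"] == strand) & tracks[column].notna()]
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{getattr(r, column)}"
        for r in sel.itertuples(index=False)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
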