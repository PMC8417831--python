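"""GC/AT-biased gene sets and GO-term over-representation.

Expressed genes (TPM strictly above a threshold, default 1) form the
universe; those above the universe median GC are the GC-biased set,
those below the AT-biased set (median-equal genes join neither).  Each
GO term is tested for over-representation in a biased set with the
upper-tail hypergeometric test

    p = P(X >= k | N, K, n),

where N is the universe size, K the universe genes carrying the term,
n the study-set size and k the study genes carrying the term, followed
by Benjamini-Hochberg adjustment across terms.  Annotations are used as
given: no GO-DAG propagation is performed.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .codon_metrics import GeneProfile


def split_gc_at(
    profiles: Sequence[GeneProfile],
    tpm: Mapping[str, float],
    tpm_min: float = 1.0,
    criterion: str = "gc",
) -> tuple[set[str], set[str], set[str]]:
    """(gc_set, at_set, universe) from a median split of expressed genes.

    ``criterion`` selects the composition metric: whole-CDS ``"gc"``
    (default) or synonymous third-position ``"gc3s"``.  Genes without a
    TPM entry count as unexpressed.

    Raises
    ------
    ValueError
        If no gene passes the expression threshold.
    """
    if criterion not in ("gc", "gc3s"):
        raise ValueError(f"criterion must be 'gc' or 'gc3s', got {criterion!r}")
    expressed = [
        p for p in profiles
        if tpm.get(p.gene_id, 0.0) > tpm_min and not math.isnan(getattr(p, criterion))
    ]
    if not expressed:
        raise ValueError("empty universe: no gene is expressed above the TPM threshold")
    values = np.array([getattr(p, criterion) for p in expressed])
    med = float(np.median(values))
    gc_set = {p.gene_id for p, v in zip(expressed, values) if v > med}
    at_set = {p.gene_id for p, v in zip(expressed, values) if v < med}
    universe = {p.gene_id for p in expressed}
    return gc_set, at_set, universe


def hypergeom_enrich(
    study_set: set[str],
    universe: set[str],
    annotations: Mapping[str, set[str]],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``study_set`` within ``universe``.

    ``annotations`` maps gene -> set of term ids; genes outside the
    universe are ignored.  Rows are sorted by p (term id breaks ties) and
    carry k, K, n, N and the BH-adjusted q.

    Raises
    ------
    ValueError
        If the study set is not contained in the universe.
    """
    if not study_set <= universe:
        raise ValueError("study set must be a subset of the universe")
    term_names = term_names or {}
    N, n = len(universe), len(study_set)
    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in study_set:
                term_study[term] = term_study.get(term, 0) + 1
    rows = []
    for term in sorted(term_universe):
        K = term_universe[term]
        k = term_study.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, term_names.get(term, ""), k, K, n, N, p))
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"]
    )
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def top_terms(result: pd.DataFrame, n: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """The top-``n`` terms with p below ``alpha`` (the reporting view)."""
    return result[result["p"] < alpha].head(n).reset_index(drop=True)


def read_annotations(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene/term TSV (gene_id, term_id[, term_name[, namespace]])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    ann: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        ann.setdefault(row.gene_id, set()).add(row.term_id)
        if hasattr(row, "term_name"):
            names[row.term_id] = row.term_name
    return ann, names
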