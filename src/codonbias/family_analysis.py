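"""Gene-family codon-usage comparison across a polyploid and its progenitors.

Three operations: (1) classify homolog/homoeolog pairs by the GC3s shift
between species — a pair is called codon-usage biased when |delta GC3s|
exceeds 0.1; (2) assemble per-family RSCU matrices over the 59
synonymous codons; (3) cluster family genes by Euclidean distance on
their RSCU rows (average linkage by default) and assign each query gene
to its nearest progenitor gene in that space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

from .cds_io import CodonCountTable
from .codon_metrics import GeneProfile, rscu
from .genetic_code import SYNONYMOUS_CODONS

BIAS_THRESHOLD = 0.1


@dataclass(frozen=True)
class HomologPairRecord:
    """A gene pair across two species with its GC3s shift."""

    gene_a: str
    gene_b: str
    gc3s_a: float
    gc3s_b: float

    @property
    def delta(self) -> float:
        return self.gc3s_a - self.gc3s_b

    @property
    def biased(self) -> bool:
        return abs(self.delta) > BIAS_THRESHOLD


def classify_pairs(
    pairs: Sequence[tuple[str, str, float, float]],
    threshold: float = BIAS_THRESHOLD,
) -> pd.DataFrame:
    """Tabulate (gene_a, gene_b, gc3s_a, gc3s_b) tuples with delta and bias flag.

    ``delta = gc3s_a - gc3s_b`` keeps its sign; ``biased`` is strict on
    ``|delta| > threshold``.
    """
    rows = []
    for gene_a, gene_b, a, b in pairs:
        delta = a - b
        rows.append((gene_a, gene_b, a, b, delta, abs(delta) > threshold))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "gc3s_a", "gc3s_b", "delta", "biased"]
    )


def pair_delta_gc3s(
    pairs: Sequence[tuple[str, str]],
    profiles_a: Mapping[str, GeneProfile] | Sequence[GeneProfile],
    profiles_b: Mapping[str, GeneProfile] | Sequence[GeneProfile],
    threshold: float = BIAS_THRESHOLD,
) -> pd.DataFrame:
    """Delta GC3s per homolog pair, from each species' gene profiles.

    Raises
    ------
    KeyError
        Naming any paired gene that has no profile.
    """
    def as_map(profiles):
        if isinstance(profiles, Mapping):
            return profiles
        return {p.gene_id: p for p in profiles}

    map_a, map_b = as_map(profiles_a), as_map(profiles_b)
    tuples = []
    for gene_a, gene_b in pairs:
        if gene_a not in map_a:
            raise KeyError(f"no profile for gene {gene_a!r} in species A")
        if gene_b not in map_b:
            raise KeyError(f"no profile for gene {gene_b!r} in species B")
        tuples.append((gene_a, gene_b, map_a[gene_a].gc3s, map_b[gene_b].gc3s))
    return classify_pairs(tuples, threshold)


def family_rscu_matrix(
    gene_labels: Mapping[str, str],
    tables: Mapping[str, CodonCountTable] | Sequence[CodonCountTable],
) -> pd.DataFrame:
    """RSCU matrix for a gene family: rows = "label|gene", columns = 59 codons.

    ``gene_labels`` maps gene_id -> species/group label; row index is
    "label|gene_id" so species are visible in downstream clustering.
    Unobserved families stay NaN.
    """
    if not isinstance(tables, Mapping):
        tables = {t.gene_id: t for t in tables}
    rows, index = [], []
    for gene_id, label in gene_labels.items():
        values = rscu(tables[gene_id])
        rows.append([values[c] for c in SYNONYMOUS_CODONS])
        index.append(f"{label}|{gene_id}" if label else gene_id)
    return pd.DataFrame(rows, index=index, columns=list(SYNONYMOUS_CODONS))


def _linkage(matrix: pd.DataFrame, method: str) -> np.ndarray:
    X = matrix.fillna(0.0).to_numpy(dtype=float)
    return hierarchy.linkage(X, method=method, metric="euclidean")


def _newick(node, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left, right = node.get_left(), node.get_right()
    bl_l = max(0.0, (node.dist - left.dist)) / 2
    bl_r = max(0.0, (node.dist - right.dist)) / 2
    return f"({_newick(left, labels)}:{bl_l:.6g},{_newick(right, labels)}:{bl_r:.6g})"


def cluster_rscu(
    matrix: pd.DataFrame,
    method: str = "average",
    n_clusters: int = 2,
) -> tuple[str, dict[str, int], np.ndarray]:
    """Agglomerative Euclidean clustering of RSCU rows.

    Missing entries are imputed as 0 for the distance computation.
    Returns (Newick string with branch lengths, row -> flat cluster label
    for ``n_clusters`` groups, scipy linkage matrix).  Leaf order in the
    Newick string follows the deterministic scipy tree traversal.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 genes")
    Z = _linkage(matrix, method)
    labels = list(matrix.index)
    tree = hierarchy.to_tree(Z)
    newick = _newick(tree, labels) + ";"
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return newick, dict(zip(labels, (int(x) for x in flat))), Z


def nearest_progenitor(
    query: pd.DataFrame, progenitors: pd.DataFrame
) -> pd.Series:
    """For each query RSCU row, the index of the closest progenitor row.

    Euclidean distance on the 59-dimensional RSCU vectors, NaN imputed
    as 0; ties break toward the first progenitor in row order.
    """
    qa = query.fillna(0.0).to_numpy(dtype=float)
    pa = progenitors.fillna(0.0).to_numpy(dtype=float)
    dist = cdist(qa, pa)
    best = dist.argmin(axis=1)
    return pd.Series(
        [progenitors.index[i] for i in best], index=query.index, name="nearest"
    )
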