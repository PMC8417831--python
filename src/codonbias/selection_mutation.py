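"""Mutation-versus-selection diagnostics.

Four complementary views of what shapes synonymous codon usage:

* **ENC plot** — observed ENC against the curve expected if third-position
  composition alone (mutation) set the bias:
  ``ENC_exp(s) = 2 + s + 29 / (s^2 + (1 - s)^2)`` with *s* the GC3s
  fraction.  Genes far below the curve are candidates for selection.
* **Neutrality plot** — OLS regression of GC12 on GC3.  A slope near 1
  means mutational pressure acts equally on all positions; a slope near 0
  means third-position composition varies while the first two are
  constrained (selection/constraint dominant).
* **PR2 bias** — A3/(A3+T3) versus G3/(G3+C3) at fourfold-degenerate third
  positions; (0.5, 0.5) is the no-bias center where parity rule 2 holds.
* **Correspondence analysis** of the genes x 59 RSCU matrix — a chi-square
  metric ordination placing genes and codons in a shared space; axis
  inertia is the share of total variation explained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cds_io import CodonCountTable
from .codon_metrics import GeneProfile
from .genetic_code import FOURFOLD_QUARTETS, SYNONYMOUS_CODONS


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with the Pearson correlation test."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class Pr2Point:
    """One gene's parity-rule-2 coordinates at fourfold third positions."""

    gene_id: str
    at_bias: float  # A3 / (A3 + T3)
    gc_bias: float  # G3 / (G3 + C3)


@dataclass
class CoaResult:
    """Correspondence analysis of an RSCU matrix.

    ``gene_coords`` and ``codon_coords`` are principal coordinates in the
    same space; ``inertia_pct`` holds the percentage of total inertia per
    retained axis (percentages over *all* axes sum to 100, exposed via
    ``inertia_pct_all``).
    """

    gene_coords: pd.DataFrame
    codon_coords: pd.DataFrame
    inertia_pct: np.ndarray
    inertia_pct_all: np.ndarray


def enc_expected(s: float) -> float:
    """Expected ENC under mutation only, at synonymous GC3 fraction ``s``.

    Defined on the open interval (0, 1); at s = 0.5 the curve peaks at 60.5.
    """
    if not 0 < s < 1:
        raise ValueError(f"GC3s fraction must lie in (0, 1), got {s}")
    return 2 + s + 29 / (s * s + (1 - s) ** 2)


def enc_plot_table(
    profiles: Sequence[GeneProfile],
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Per-gene ENC-plot table: gc3s, observed/expected ENC, relative deviation.

    ``deviation = (expected - observed) / expected``; ``within_band`` flags
    genes whose |deviation| <= ``tolerance`` (the "allowable range" of the
    standard curve — a modelling choice, configurable).  Genes with
    undefined ENC or boundary gc3s are excluded; the count is available as
    ``df.attrs["n_excluded"]``.
    """
    rows = []
    excluded = 0
    for p in profiles:
        if math.isnan(p.enc) or math.isnan(p.gc3s) or not 0 < p.gc3s < 1:
            excluded += 1
            continue
        exp = enc_expected(p.gc3s)
        dev = (exp - p.enc) / exp
        rows.append((p.gene_id, p.gc3s, p.enc, exp, dev, abs(dev) <= tolerance))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "gc3s", "enc_observed", "enc_expected", "deviation", "within_band"],
    )
    df.attrs["n_excluded"] = excluded
    return df


def neutrality_fit(profiles: Sequence[GeneProfile]) -> NeutralityFit:
    """Regress GC12 on GC3 across genes (GC3 is the predictor).

    Raises
    ------
    ValueError
        With fewer than 3 genes carrying both metrics, or zero GC3 variance.
    """
    pts = [(p.gc3, p.gc12) for p in profiles
           if not (math.isnan(p.gc3) or math.isnan(p.gc12))]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 genes for a neutrality fit, got {len(pts)}")
    x = np.array([a for a, _ in pts])
    y = np.array([b for _, b in pts])
    if np.ptp(x) == 0:
        raise ValueError("GC3 has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return NeutralityFit(fit.slope, fit.intercept, fit.rvalue, fit.pvalue, len(pts))


def pr2_point(counts: CodonCountTable) -> Pr2Point:
    """PR2 coordinates from the eight fourfold-degenerate codon quartets.

    A coordinate whose denominator is zero is NaN (missing), not 0.
    """
    base3 = {"A": 0, "T": 0, "G": 0, "C": 0}
    for quartet in FOURFOLD_QUARTETS.values():
        for codon in quartet:
            base3[codon[2]] += counts.get(codon)
    at = base3["A"] + base3["T"]
    gc = base3["G"] + base3["C"]
    return Pr2Point(
        counts.gene_id,
        base3["A"] / at if at else math.nan,
        base3["G"] / gc if gc else math.nan,
    )


def pr2_table(tables: Sequence[CodonCountTable]) -> pd.DataFrame:
    points = [pr2_point(t) for t in tables]
    return pd.DataFrame(
        [(pt.gene_id, pt.at_bias, pt.gc_bias) for pt in points],
        columns=["gene_id", "at_bias", "gc_bias"],
    )


def coa_rscu(matrix: pd.DataFrame, n_axes: int = 4) -> CoaResult:
    """Correspondence analysis of a genes x 59 RSCU matrix.

    Missing entries (unobserved families) contribute 0.  Rows or columns
    with zero total are dropped from the decomposition; their coordinates
    are NaN in the output.  Axes are ordered by decreasing inertia, and
    each axis's sign is normalized so that the codon with the largest
    absolute loading is positive.
    """
    if matrix.shape[0] < 2:
        raise ValueError("correspondence analysis needs at least 2 genes")
    full = matrix.reindex(columns=list(SYNONYMOUS_CODONS)).fillna(0.0)
    X = full.to_numpy(dtype=float)
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    Xr = X[np.ix_(row_ok, col_ok)]
    N = Xr / Xr.sum()
    r = N.sum(axis=1)
    c = N.sum(axis=0)
    S = (N - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    nontrivial = sv > 1e-12
    sv = sv[nontrivial]
    U = U[:, nontrivial]
    V = Vt[nontrivial].T
    k = min(n_axes, sv.size)
    inertia = sv ** 2
    inertia_pct_all = 100 * inertia / inertia.sum()

    rows = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    cols = (V[:, :k] * sv[:k]) / np.sqrt(c)[:, None]
    for j in range(k):
        lead = np.argmax(np.abs(cols[:, j]))
        if cols[lead, j] < 0:
            cols[:, j] *= -1
            rows[:, j] *= -1

    axes = [f"axis{i + 1}" for i in range(k)]
    gene_coords = pd.DataFrame(np.nan, index=full.index, columns=axes)
    gene_coords.iloc[np.flatnonzero(row_ok)] = rows
    codon_coords = pd.DataFrame(np.nan, index=full.columns, columns=axes)
    codon_coords.iloc[np.flatnonzero(col_ok)] = cols
    return CoaResult(gene_coords, codon_coords, inertia_pct_all[:k], inertia_pct_all)
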