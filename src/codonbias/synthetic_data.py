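"""Synthetic CDS sets and companion inputs with known ground truth.

Every pipeline input can be generated here with planted parameters, so
each analysis stage has an exact recovery target:

* CDS FASTA — genes built codon by codon: the amino acid is drawn from a
  plant-like composition, then the synonymous codon is drawn with
  third-position G/C probability *w* (uniform within the G/C-ending and
  A/T-ending halves of the family).  ATG is prepended and a stop
  appended, so every clean gene passes the completeness filter; an
  optional corruption rate plants filterable defects.
* Neutrality sets — GC12 is linked to GC3 with a planted slope by mixing
  a GC12=0 amino-acid pool (Phe/Ile/Lys/Asn/Tyr) with a GC12=1 pool
  (Ala/Pro/Gly); the mixing fraction *is* the target GC12.
* Anticodon tables — copy numbers with a planted Pearson correlation to
  a reference codon-usage vector (cognate, wobble-off assignment).
* GO annotations and TPM — one planted term enriched in a designated
  gene set at stated odds; log-normal TPM with a stated fraction below
  the expression threshold.
* Homolog pairs — partner genes regenerated with *w* shifted by a
  planted amount, giving a controlled delta-GC3s distribution.

All generators are pure functions of (config, seed): the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cds_io import CdsRecord
from .genetic_code import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    reverse_complement,
)
from .genome_structure import length_bin
from .trna_adaptation import AnticodonTable

#: Plant-like amino-acid composition (approximate leaf-proteome usage);
#: normalized at import.  Composition is a nuisance parameter for every
#: statistic tested, so one fixed, documented vector is used throughout.
PLANT_AA_COMPOSITION: dict[str, float] = {
    "A": 0.078, "R": 0.054, "N": 0.042, "D": 0.053, "C": 0.018,
    "Q": 0.036, "E": 0.064, "G": 0.067, "H": 0.023, "I": 0.046,
    "L": 0.092, "K": 0.061, "M": 0.024, "F": 0.044, "P": 0.049,
    "S": 0.081, "T": 0.050, "V": 0.065, "W": 0.012, "Y": 0.027,
}

_AA_ORDER = tuple(AMINO_ACIDS)
_GC_SUB = {aa: tuple(sorted(c for c in AA_TO_CODONS[aa] if c[2] in "GC"))
           for aa in _AA_ORDER}
_AT_SUB = {aa: tuple(sorted(c for c in AA_TO_CODONS[aa] if c[2] in "AT"))
           for aa in _AA_ORDER}

#: codon-count (amino acids per gene) ranges for the four CDS length bins
_BIN_AA_RANGES = ((115, 331), (333, 665), (666, 998), (1000, 1800))


def _composition_vector(composition: Mapping[str, float] | None) -> np.ndarray:
    comp = composition or PLANT_AA_COMPOSITION
    vec = np.array([comp.get(aa, 0.0) for aa in _AA_ORDER], dtype=float)
    if vec.sum() <= 0:
        raise ValueError("amino-acid composition sums to zero")
    return vec / vec.sum()


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic genome; defaults emulate a wheat-like CDS set.

    ``w`` is the third-position G/C probability for synonymous choices;
    by default it varies per gene over ``w_range``, matching the wide
    per-gene GC3s spread of Triticeae genomes.  ``length_bin_weights``
    puts the mode of CDS lengths in the 1-2 kb bin.  Setting
    ``n_chromosomes`` > 0 places genes on chromosomes with a distal
    density gradient and a distal G/C boost, so gene density and GC3
    co-vary along each chromosome.
    """

    seed: int = 0
    n_genes: int = 500
    length_bin_weights: tuple[float, float, float, float] = (0.30, 0.45, 0.17, 0.08)
    w: float = 0.6
    w_range: tuple[float, float] | None = (0.2, 0.95)
    length_linked: bool = False
    w_long: float = 0.4
    corruption_rate: float = 0.0
    n_chromosomes: int = 0
    chromosome_size: int = 50_000_000
    distal_fraction: float = 0.6
    distal_arm_width: float = 0.2
    distal_w_boost: float = 0.15
    composition: Mapping[str, float] | None = None
    id_prefix: str = "gene"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 < self.w < 1:
            raise ValueError("w must lie in (0, 1)")
        if self.w_range is not None and not (0 < self.w_range[0] < self.w_range[1] < 1):
            raise ValueError("w_range must be an increasing pair inside (0, 1)")
        if not 0 <= self.corruption_rate < 1:
            raise ValueError("corruption_rate must lie in [0, 1)")
        if abs(sum(self.length_bin_weights) - 1) > 1e-9:
            raise ValueError("length_bin_weights must sum to 1")


def sample_codons(
    rng: np.random.Generator,
    n: int,
    w: float,
    composition: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Draw ``n`` sense codons: amino acid from ``composition``, ending by ``w``.

    Within a family the G/C-ending half is chosen with probability ``w``
    (A/T-ending otherwise), uniformly within the chosen half; families
    with only one ending type (Met, Trp) fall back to what exists.
    """
    comp = _composition_vector(composition)
    aa_idx = rng.choice(len(_AA_ORDER), size=n, p=comp)
    use_gc = rng.random(n) < w
    u = rng.random(n)
    out = np.empty(n, dtype="<U3")
    for i, aa in enumerate(_AA_ORDER):
        mask_aa = aa_idx == i
        if not mask_aa.any():
            continue
        for flag in (True, False):
            subset = (_GC_SUB[aa] or _AT_SUB[aa]) if flag else (_AT_SUB[aa] or _GC_SUB[aa])
            m = mask_aa & (use_gc == flag)
            if not m.any():
                continue
            arr = np.array(subset, dtype="<U3")
            out[m] = arr[(u[m] * len(arr)).astype(int)]
    return out


def generate_gene(
    rng: np.random.Generator,
    n_codons: int,
    w: float,
    gene_id: str = "gene",
    composition: Mapping[str, float] | None = None,
) -> CdsRecord:
    """One complete CDS: ATG + ``n_codons`` sampled codons + a random stop."""
    body = "".join(sample_codons(rng, n_codons, w, composition))
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return CdsRecord(gene_id, "ATG" + body + stop)


_CORRUPTIONS = ("length", "frame", "start-codon", "stop-codon", "internal-stop", "ambiguous-base")


def _corrupt(rng: np.random.Generator, seq: str) -> tuple[str, str]:
    kind = _CORRUPTIONS[rng.integers(len(_CORRUPTIONS))]
    if kind == "length":
        seq = seq[:96] + seq[-3:]  # 99 bp, still framed and terminated
    elif kind == "frame":
        seq = seq[:-1]
    elif kind == "start-codon":
        seq = "GTG" + seq[3:]
    elif kind == "stop-codon":
        seq = seq[:-3] + "AAA"
    elif kind == "internal-stop":
        mid = 3 * (len(seq) // 6)
        seq = seq[:mid] + "TAA" + seq[mid + 3:]
    else:
        pos = int(rng.integers(3, len(seq) - 3))
        seq = seq[:pos] + "N" + seq[pos + 1:]
    return seq, kind


def generate_cds_set(config: GeneratorConfig) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Synthetic CDS FASTA records plus the per-gene truth table.

    Truth columns: gene_id, w (planted G/C weight), n_codons, length_nt,
    length_bin, corruption (empty for clean genes) and, when a
    chromosome layout is configured, chrom/start/end/strand/distal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[CdsRecord] = []
    rows = []
    half = config.chromosome_size / 2
    for i in range(config.n_genes):
        gene_id = f"{config.id_prefix}{i:05d}"
        bin_idx = rng.choice(4, p=config.length_bin_weights)
        lo, hi = _BIN_AA_RANGES[bin_idx]
        n_aa = int(rng.integers(lo, hi + 1))
        length_nt = 3 * (n_aa + 2)

        if config.w_range is not None:
            w = float(rng.uniform(*config.w_range))
        else:
            w = config.w
        if config.length_linked:
            frac = min(length_nt / 3000.0, 1.0)
            w = w - (w - config.w_long) * frac

        chrom = start = end = strand = None
        distal = False
        if config.n_chromosomes > 0:
            chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
            distal = bool(rng.random() < config.distal_fraction)
            if distal:
                rel = rng.uniform(1 - config.distal_arm_width, 1.0)
            else:
                rel = rng.uniform(0.0, 1 - config.distal_arm_width)
            # rel = distance from chromosome midpoint, 0..1; random arm
            offset = rel * (half - length_nt)
            pos = half + offset if rng.random() < 0.5 else half - offset - length_nt
            start = int(max(1, round(pos)))
            end = start + length_nt - 1
            strand = "+" if rng.random() < 0.5 else "-"
            w = w + config.distal_w_boost * (rel - 0.5) * 2

        w = float(np.clip(w, 0.02, 0.98))
        rec = generate_gene(rng, n_aa, w, gene_id, config.composition)
        corruption = ""
        if config.corruption_rate and rng.random() < config.corruption_rate:
            seq, corruption = _corrupt(rng, rec.sequence)
            rec = CdsRecord(gene_id, seq)
        records.append(rec)
        rows.append(
            dict(gene_id=gene_id, w=w, n_codons=n_aa + 1, length_nt=rec.length_nt,
                 length_bin=length_bin(max(rec.length_nt, 1)), corruption=corruption,
                 chrom=chrom, start=start, end=end, strand=strand, distal=distal)
        )
    return records, pd.DataFrame(rows)


# pools with position-1/2 GC fixed at 0 and 1 respectively, so the mixing
# fraction equals the expected GC12 exactly, independent of codon choice
_LOW_GC12_POOL = ("F", "I", "K", "N", "Y")
_HIGH_GC12_POOL = ("A", "P", "G")


def generate_neutrality_set(
    n_genes: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    n_codons: int = 400,
    w_range: tuple[float, float] = (0.25, 0.95),
    seed: int = 0,
    id_prefix: str = "ngene",
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Genes whose GC12 tracks GC3 with a planted linear law.

    Per gene, w ~ U(w_range) sets GC3 (and equals its expectation, since
    the amino-acid pools used here contain no Met/Trp); the target
    GC12 = intercept + slope * w + N(0, noise_sd) is realized by mixing
    the zero-GC12 and unit-GC12 amino-acid pools at that fraction.
    """
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for i in range(n_genes):
        w = float(rng.uniform(*w_range))
        target_gc12 = float(np.clip(intercept + slope * w + rng.normal(0, noise_sd), 0.0, 1.0))
        comp = {aa: (1 - target_gc12) / len(_LOW_GC12_POOL) for aa in _LOW_GC12_POOL}
        comp.update({aa: target_gc12 / len(_HIGH_GC12_POOL) for aa in _HIGH_GC12_POOL})
        body = "".join(sample_codons(rng, n_codons, w, comp))
        stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        gene_id = f"{id_prefix}{i:05d}"
        records.append(CdsRecord(gene_id, "ATG" + body + stop))
        rows.append(dict(gene_id=gene_id, w=w, target_gc12=target_gc12))
    return records, pd.DataFrame(rows)


def generate_trna_counts(
    codon_freqs: Mapping[str, float],
    planted_r: float = 0.7,
    scale: int = 200,
    seed: int = 0,
) -> AnticodonTable:
    """Anticodon copy numbers whose codon supply correlates with usage at ``planted_r``.

    Each codon receives its cognate (wobble-off) anticodon; copy counts
    are a positive affine rescaling of ``r * usage + sqrt(1-r^2) * noise``
    with the noise orthogonalized against usage, so the pre-rounding
    correlation is exactly ``planted_r``.
    """
    if not -1 <= planted_r <= 1:
        raise ValueError("planted_r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    codons = sorted(codon_freqs)
    x = np.array([codon_freqs[c] for c in codons], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("codon usage vector has zero variance")
    xs = (x - x.mean()) / x.std()
    e = rng.normal(size=len(codons))
    e = e - (e @ xs) / (xs @ xs) * xs
    e = e - e.mean()
    es = e / e.std() if e.std() > 0 else e
    y = planted_r * xs + np.sqrt(max(0.0, 1 - planted_r ** 2)) * es
    counts = np.rint((y - y.min()) / max(np.ptp(y), 1e-12) * scale + 1).astype(int)
    table = AnticodonTable()
    for codon, count in zip(codons, counts):
        table[reverse_complement(codon)] = int(count)
    return table


def generate_annotations(
    gene_ids: Sequence[str],
    enriched_genes: set[str] | None = None,
    n_terms: int = 20,
    p_term: float = 0.1,
    planted_odds: float = 1.0,
    tpm_frac_below_1: float = 0.3,
    tpm_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, str], dict[str, float], str]:
    """GO-style annotations with one planted term, plus log-normal TPM.

    The planted term (the first) annotates genes in ``enriched_genes``
    with probability ``min(1, planted_odds * p_term)`` and everything
    else with ``p_term``; ``planted_odds = 1`` is the null.  TPM is
    log-normal with sigma ``tpm_sigma`` and the median chosen so the
    expected fraction of genes below TPM = 1 is ``tpm_frac_below_1``.

    Returns (annotations, term names, tpm, planted term id).
    """
    if not 0 < p_term < 1:
        raise ValueError("p_term must lie in (0, 1)")
    if not 0 < tpm_frac_below_1 < 1:
        raise ValueError("tpm_frac_below_1 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    enriched_genes = enriched_genes or set()
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    names = {t: f"synthetic process {i}" for i, t in enumerate(terms, 1)}
    planted = terms[0]
    p_planted_in = min(1.0, planted_odds * p_term)
    ann: dict[str, set[str]] = {g: set() for g in gene_ids}
    for term in terms:
        for g in gene_ids:
            p = p_planted_in if (term == planted and g in enriched_genes) else p_term
            if rng.random() < p:
                ann[g].add(term)
    mu = -tpm_sigma * float(norm.ppf(tpm_frac_below_1))
    tpm = {g: float(rng.lognormal(mu, tpm_sigma)) for g in gene_ids}
    return ann, names, tpm, planted


def generate_homolog_pairs(
    n_pairs: int,
    delta_w: float = 0.0,
    n_codons: int = 400,
    w_range: tuple[float, float] = (0.35, 0.75),
    seed: int = 0,
) -> tuple[list[CdsRecord], list[CdsRecord], pd.DataFrame]:
    """Homolog pairs across two synthetic species with a planted w shift.

    Species-A genes draw w ~ U(w_range); each partner is regenerated with
    w shifted down by ``delta_w`` (clipped).  Returns the two record
    lists and the pair table (gene_a, gene_b, w_a, w_b).
    """
    rng = np.random.default_rng(seed)
    recs_a, recs_b, rows = [], [], []
    for i in range(n_pairs):
        w_a = float(rng.uniform(*w_range))
        w_b = float(np.clip(w_a - delta_w, 0.02, 0.98))
        ga, gb = f"spA{i:05d}", f"spB{i:05d}"
        recs_a.append(generate_gene(rng, n_codons, w_a, ga))
        recs_b.append(generate_gene(rng, n_codons, w_b, gb))
        rows.append(dict(gene_a=ga, gene_b=gb, w_a=w_a, w_b=w_b))
    return recs_a, recs_b, pd.DataFrame(rows)


def generate_two_group_set(
    n_per_group: int = 10,
    w_low: float = 0.15,
    w_high: float = 0.85,
    n_codons: int = 300,
    seed: int = 0,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Two planted codon-preference clusters (A/T-ending vs G/C-ending)."""
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for label, w in (("at", w_low), ("gc", w_high)):
        for i in range(n_per_group):
            gid = f"{label}{i:03d}"
            records.append(generate_gene(rng, n_codons, w, gid))
            rows.append(dict(gene_id=gid, group=label, w=w))
    return records, pd.DataFrame(rows)
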