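"""Standard genetic code tables and synonymous-family structure.

Every statistic in this package is defined over the standard nuclear code
(NCBI translation table 1): 61 sense codons, 3 stops, 18 amino acids with
a synonymous choice plus Met and Trp which offer none.  The DNA alphabet
(T, not U) is canonical internally; RNA input is normalized at every
boundary with :func:`dna`.

Degeneracy classes (family sizes) drive the effective-number-of-codons
estimator: nine 2-fold amino acids, one 3-fold (Ile), five 4-fold, three
6-fold (Leu, Ser, Arg) and the two single-codon amino acids.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: Translation symbol used for termination codons.
STOP = "*"

_ALL_CODONS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)

#: codon -> amino-acid one-letter symbol, or "*" for a stop. 64 entries.
CODON_TO_AA: dict[str, str] = {
    codon: _TABLE.forward_table.get(codon, STOP) for codon in _ALL_CODONS
}

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in _ALL_CODONS if CODON_TO_AA[c] != STOP
)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(_TABLE.forward_table.values())))

#: amino acid -> frozenset of synonymous codons (its family).
AA_TO_CODONS: dict[str, frozenset[str]] = {
    aa: frozenset(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in AMINO_ACIDS
}

#: amino acid -> n_i, the number of synonymous codons in its family.
FAMILY_SIZE: dict[str, int] = {aa: len(f) for aa, f in AA_TO_CODONS.items()}

#: amino acid -> degeneracy class, one of {1, 2, 3, 4, 6}.
DEGENERACY_CLASS: dict[str, int] = dict(FAMILY_SIZE)

SINGLE_CODON_AAS: tuple[str, ...] = ("M", "W")
TWOFOLD_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if FAMILY_SIZE[aa] == 2
)
THREEFOLD_AAS: tuple[str, ...] = ("I",)
FOURFOLD_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if FAMILY_SIZE[aa] == 4
)
SIXFOLD_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if FAMILY_SIZE[aa] == 6
)

#: amino acids with a synonymous choice (everything but Met/Trp), 18 of them.
SYNONYMOUS_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if FAMILY_SIZE[aa] > 1
)

#: The 59 synonymous sense codons (61 minus ATG and TGG), grouped by amino
#: acid (alphabetical) and alphabetical within each family.  This is the
#: canonical column order for RSCU vectors and matrices.
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    codon
    for aa in SYNONYMOUS_AAS
    for codon in sorted(AA_TO_CODONS[aa])
)

#: Fourfold-degenerate codon quartets used by the PR2-bias plot: the five
#: 4-fold families plus the fourfold blocks of the three 6-fold families
#: (CTN for Leu, TCN for Ser, CGN for Arg).  Within each quartet the third
#: position is free, so base composition there reflects mutation/selection
#: asymmetry, not amino-acid composition.
FOURFOLD_QUARTETS: dict[str, tuple[str, ...]] = {
    "A": tuple(sorted(AA_TO_CODONS["A"])),
    "G": tuple(sorted(AA_TO_CODONS["G"])),
    "P": tuple(sorted(AA_TO_CODONS["P"])),
    "T": tuple(sorted(AA_TO_CODONS["T"])),
    "V": tuple(sorted(AA_TO_CODONS["V"])),
    "L4": ("CTA", "CTC", "CTG", "CTT"),
    "S4": ("TCA", "TCC", "TCG", "TCT"),
    "R4": ("CGA", "CGC", "CGG", "CGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def dna(sequence: str) -> str:
    """Normalize a nucleotide string to upper-case DNA (U -> T)."""
    return sequence.upper().replace("U", "T")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return dna(sequence).translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino-acid symbol (or ``"*"``) for one codon; accepts RNA triplets."""
    codon = dna(codon)
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not a valid codon: {codon!r}") from None


def synonymous_family(amino_acid: str) -> frozenset[str]:
    """All codons translating to ``amino_acid`` under the standard code.

    Raises
    ------
    ValueError
        If the symbol is not one of the 20 standard one-letter codes.
    """
    try:
        return AA_TO_CODONS[amino_acid]
    except KeyError:
        raise ValueError(
            f"unknown amino-acid symbol: {amino_acid!r}"
        ) from None
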