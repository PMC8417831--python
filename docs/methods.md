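# Methods

## Scope and model

`codonbias` implements the desk-scale codon-usage-bias workflow for
nuclear genomes under the standard genetic code (NCBI table 1 only;
alternative codes are rejected).  DNA (T, not U) is the internal
alphabet; RNA input is normalized at every boundary.  All statistics are
defined over sense codons; stop codons are tokenized but never enter any
metric.

## CDS filtering

A record is a complete CDS when it is strictly longer than 300 bp, has
length divisible by 3, starts with ATG, ends with TAA/TAG/TGA, contains
no internal stop, and (by default) no N inside any codon.  "Longer than
300 bp" is a strict inequality; the threshold is a parameter.  Records
with ambiguous bases are rejected whole rather than having codons
skipped, keeping `n_codons` consistent with sequence length; a flag
(`reject_ambiguous=False`) tolerates them instead.  Criteria are checked
in the order listed and the first failure is reported, so rejection
reports are deterministic.  Transcript isoforms are treated as
independent sequences; no longest-isoform collapsing is performed.

## Per-gene statistics

**RSCU.** `RSCU_ij = x_ij · n_i / Σ_j x_ij` per synonymous family.
Unobserved families yield NaN (missing), never 0: zero would assert
maximal avoidance where there is no information.  Met and Trp are
excluded throughout, giving the 59-codon vector used by the RSCU matrix,
correspondence analysis, family heat-map tables and clustering.  Column
order is fixed: families sorted by amino-acid letter, codons
alphabetical within a family.

**ENC.** Wright's estimator.  Per amino acid with usage n ≥ 2,
`F = (n Σp² − 1)/(n − 1)`; amino acids used once are excluded (the
estimator is undefined there).  Class means are taken over the observed
2-, 3-, 4- and 6-fold families; six-fold families (Leu, Ser, Arg) are
treated as single families, not split 4 + 2.  A missing 3-fold mean (no
Ile) is imputed as (F̄₂ + F̄₄)/2; a missing or non-positive 2-, 4- or
6-fold mean makes ENC missing.  The sum `2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
3/F̄₆` is capped at 61.

**GC partitions.** GC1/GC2/GC3 are computed over all sense codons
(Met/Trp included), GC12 = (GC1 + GC2)/2.  GC3s and the A3s/T3s/G3s/C3s
fractions are computed over synonymous codons only.  Both GC3 and GC3s
are kept as distinct outputs; the neutrality regression uses GC3, the
homoeolog comparison and length bins use GC3s.  Genome-level GC3s can be
summarized either as a simple gene mean or weighted by codon count; the
per-gene table supports both.

## Mutation-versus-selection diagnostics

**ENC plot.** Expected curve `2 + s + 29/(s² + (1 − s)²)` on s ∈ (0, 1).
The "allowable range" around the curve is a modelling choice the
literature leaves open; the default band is |relative deviation| ≤ 5%,
exposed as a parameter rather than hidden.

**Neutrality plot.** Ordinary least squares of GC12 on GC3 (GC3 the
predictor), with the Pearson correlation and its two-sided t-test p.
Fewer than 3 genes or zero predictor variance raise an error.

**PR2.** Restricted to the eight fourfold-degenerate quartets (the five
4-fold families plus CTN/TCN/CGN), which removes amino-acid-composition
confounding; an all-third-position variant would answer a different
question and is deliberately not the default.  Zero denominators yield
missing coordinates.

**Correspondence analysis.** Standard CA of the RSCU matrix: divide by
the grand total, form standardized residuals
`(P − rcᵀ)/√(rcᵀ)`, SVD, principal coordinates for both genes and
codons; axis inertia = squared singular value.  Missing RSCU entries
contribute 0 (the gene simply lacks that family); zero rows/columns are
dropped from the decomposition and returned as NaN coordinates.  Because
an SVD axis sign is arbitrary, each axis is normalized so the codon with
the largest |loading| is positive, making results invariant to row
order.

## Optimal codons

Genes with defined ENC are sorted; the lowest-ENC ceil(5% · n) form the
high-bias group, the highest the low-bias group, with lexicographic
gene-id tie-breaks for reproducibility (at least 40 genes required so
each tail has ≥ 2).  RSCU per group is computed on **pooled** counts —
the convention of high/low-bias codon-usage tables — rather than as a
mean of per-gene RSCU; a codon is optimal iff RSCU_high > 1 and
RSCU_high − RSCU_low > 0.08, both strict.  Raising the delta threshold
can only shrink the set.

## tRNA adaptation

tRNAscan-SE tabular output is detected by its dashed header rule;
otherwise a two-column anticodon/count TSV is assumed.  Pseudogene-
flagged rows are excluded by default; undetermined (N-containing)
anticodons are skipped and counted.  Wobble decoding implements exactly
Crick's rule at the anticodon 5′ base — G reads codon-3′ C and T, T (U)
reads A and G, A and C read their single Watson–Crick partner — and
never touches codon positions 1–2.  Inosine (A34) wobble is not modeled.
Codon–tRNA correlation uses usage renormalized within the selected
degeneracy group (two-codon amino acids; four-or-more-codon amino acids;
or all 18 with a choice — Met/Trp never enter) against availability =
summed copy number of anticodons able to read the codon.

## Genome structure

Length bins are [1, 999], [1000, 1999], [2000, 2999], [3000, ∞) bp with
inclusive lower edges; bin means of GC3s are simple gene means.  Window
tracks tile each chromosome from 0 in fixed windows (default 10 Mb,
configurable since published track bin widths are rarely stated); a gene
joins the window containing its start (midpoint assignment behind a
flag), separately per strand.  Input coordinates are 1-based inclusive;
emitted tracks are 0-based half-open, bedGraph-compatible.  The tracked
metric defaults to GC3 with GC3s behind a flag.

## Family comparison

A homolog/homoeolog pair is codon-usage biased when |GC3s_A − GC3s_B| >
0.1, strict, with the signed delta preserved.  Family RSCU matrices keep
the canonical 59-column order with species labels in the row index.
"Euclidean clustering" is agglomerative with average linkage by default
(complete/ward available): the linkage choice is genuinely open in the
source literature, so it is a parameter.  Missing RSCU is imputed as 0
for distances only.  Dendrograms are serialized as Newick with
half-merge-height branch lengths; nearest-progenitor assignment is the
arg-min Euclidean distance to any progenitor row.

## Enrichment

The universe is genes with TPM strictly above the threshold (default 1).
The GC/AT split is a median split on whole-CDS GC (GC3s behind a flag);
median-equal genes join neither set, so the two sets are disjoint and
near-equal for continuous GC.  Each term's p is the upper-tail
hypergeometric probability P(X ≥ k | N, K, n) via `scipy.stats.
hypergeom.sf`, BH-adjusted across tested terms with statsmodels.
Annotations are used exactly as supplied — no GO-DAG ancestor
propagation — which understates enrichment of broad terms relative to
propagating tools; a known divergence.

## Synthetic data: what it emulates and what it does not

Genes are built codon by codon: amino acid from a fixed plant-like
composition (a documented nuisance parameter, normalized at import),
synonymous codon by choosing the G/C-ending half of the family with
probability w (uniform within each half).  Defaults — 500 genes, w
uniform on (0.2, 0.95), CDS length mixture peaking in the 1–2 kb bin —
mirror the broad per-gene GC3s spread and length distribution of
Triticeae CDS sets.  Because codon choice is a pure function of w, the
generator is a *mutation-style* process: generated genes sit on the
expected ENC curve, and selection-like genes for contrast are built by
fixing one codon per family.  Consequences to keep in mind: passing
recovery tests shows the estimators are correct under compositional
bias; it does not show anything about real translational selection,
isoform structure, gBGC, or amino-acid composition variation — none of
which are simulated.

The neutrality generator links GC12 to GC3 by mixing a GC12 = 0
amino-acid pool (Phe, Ile, Lys, Asn, Tyr) with a GC12 = 1 pool (Ala,
Pro, Gly); positions 1–2 of every codon in these pools have fixed GC, so
the mixing fraction equals the expected GC12 exactly and the planted
slope is recovered up to small errors-in-variables attenuation
(binomial noise in realized GC3 at 400 codons/gene attenuates a slope of
0.18 by ≈ 1–2%, well inside the ±0.02 recovery tolerance).

Anticodon tables plant an exact pre-rounding correlation by
orthogonalizing noise against the usage vector; chromosome layouts place
a configurable fraction of genes in distal arms and tilt w with distance
from the centromere, so gene density and GC3 co-vary as in real cereal
chromosomes; GO tables plant one term at stated odds in a designated
gene set (odds = 1 is the null used for type-I calibration); homolog
pairs regenerate the partner with w shifted by a planted amount.  Every
generator is a pure function of (config, seed).

## Problem sizes and numerics

Default test and acceptance runs use 100–2,000 genes of 100–400 codons
(10,000 codons for single-gene weight recovery), 200 replicates for null
calibration, and a 1,000-point grid for the expected-ENC oracle — sizes
chosen so the full suite runs in seconds while Monte-Carlo tolerances
(±0.02 on recovered weights and slopes, ±0.15 on planted correlations,
3σ binomial allowance on the 5% type-I rate) are comfortably resolved.
Ties are broken lexicographically wherever an ordering is needed
(ENC tails, enrichment rows at equal p via stable sort).  Degenerate
inputs (empty families, zero denominators, rank-deficient CA input,
constant predictors) return missing values or explicit errors as
documented per function, never silent zeros.

## Known limitations

CAI/Fop/tAI and codon-pair statistics are out of scope, as are homolog
inference, expression quantification, GO-DAG handling, and figure
rendering (tables and bedGraph/Newick artifacts are the outputs).
Genome-scale published values (mean ENC, GC3s percentages, COA inertia
of real wheat genomes) require the real genome downloads and are not
reproduced at desk scale.
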