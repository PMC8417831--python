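"""Identify optimal codons from the 5% ENC tails of a G/C-preferring genome.

With a planted G/C-ending preference, every codon passing the
RSCU_high > 1 and delta-RSCU > 0.08 rule should end in G or C.
"""

import codonbias as cb
from codonbias.cds_io import count_codons

records, _ = cb.generate_cds_set(
    cb.GeneratorConfig(seed=4, n_genes=300, w_range=None, w=0.8)
)
tables = [count_codons(r) for r in records]
profiles = cb.profile_genes(tables)

result = cb.find_optimal_codons(profiles, tables, species_label="synthetic")
print(result.entries.to_string(index=False))
gc_ending = sum(c[2] in "GC" for c in result.codons)
print(f"\n{len(result)} optimal codons; {gc_ending} end in G/C "
      "(the planted preference).")
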