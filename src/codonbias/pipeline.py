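"""End-to-end workflow driver: simulate (or load) one species, run every
analysis stage, and write all artifact tables with a manifest.

Each emitted TSV starts with comment lines recording the package version
and the parameters that produced it, so artifacts are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .cds_io import count_codons, filter_cds, pool_counts, rejection_report, write_fasta
from .codon_metrics import profile_genes, profiles_to_frame, rscu_matrix
from .enrichment import hypergeom_enrich, split_gc_at, top_terms
from .genome_structure import bin_by_length, window_tracks
from .optimal_codons import find_optimal_codons
from .selection_mutation import coa_rscu, enc_plot_table, neutrality_fit, pr2_table
from .synthetic_data import (
    GeneratorConfig,
    generate_annotations,
    generate_cds_set,
    generate_trna_counts,
)
from .trna_adaptation import correlation_report


def write_tsv(df: pd.DataFrame, path: Path, params: Mapping | None = None,
              index: bool = False) -> None:
    """Write a TSV with '#' header lines carrying version and parameters."""
    with open(path, "w") as out:
        out.write(f"# codonbias {__version__}\n")
        for key, value in (params or {}).items():
            out.write(f"# {key}={value}\n")
        df.to_csv(out, sep="\t", index=index, na_rep="NA")


def run_all(config: GeneratorConfig, outdir: str | Path) -> dict[str, str]:
    """Run the full workflow on one synthetic species; return the manifest.

    Stages: simulate -> filter -> per-gene stats -> ENC plot -> neutrality
    -> PR2 -> correspondence analysis -> optimal codons -> tRNA
    correlation -> length bins -> chromosome tracks -> GC/AT enrichment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame, params: Mapping | None = None,
             index: bool = False) -> None:
        path = outdir / name
        write_tsv(df, path, params, index=index)
        manifest[name.removesuffix(".tsv")] = str(path)

    records, truth = generate_cds_set(config)
    write_fasta(records, outdir / "cds.fasta")
    manifest["cds_fasta"] = str(outdir / "cds.fasta")
    emit("truth.tsv", truth, {"seed": config.seed, "n_genes": config.n_genes})

    kept, rejected = filter_cds(records)
    emit("rejected.tsv", rejection_report(rejected))
    tables = [count_codons(r) for r in kept]
    profiles = profile_genes(tables)
    emit("gene_metrics.tsv", profiles_to_frame(profiles), index=True)

    emit("enc_plot.tsv", enc_plot_table(profiles))
    fit = neutrality_fit(profiles)
    emit("neutrality.tsv", pd.DataFrame([fit.__dict__]),
         {"model": "OLS GC12 ~ GC3"})
    emit("pr2.tsv", pr2_table(tables))

    coa = coa_rscu(rscu_matrix(profiles))
    emit("coa_genes.tsv", coa.gene_coords, index=True)
    emit("coa_codons.tsv", coa.codon_coords, index=True)
    emit("coa_inertia.tsv",
         pd.DataFrame({"axis": range(1, len(coa.inertia_pct_all) + 1),
                       "inertia_pct": coa.inertia_pct_all}))

    optimal = find_optimal_codons(profiles, tables)
    emit("optimal_codons.tsv", optimal.entries,
         {"n_optimal": len(optimal), "rule": "RSCU_high>1 and delta>0.08"})

    pooled = pool_counts(tables)
    trna = generate_trna_counts(pooled.counts, planted_r=0.7, seed=config.seed + 1)
    emit("trna_correlation.tsv", correlation_report(pooled.counts, trna),
         {"planted_r": 0.7})

    emit("length_bins.tsv", bin_by_length(profiles))

    if config.n_chromosomes > 0:
        placed = truth[truth["chrom"].notna() & (truth["corruption"] == "")]
        gene_table = placed[["gene_id", "chrom", "start", "end", "strand"]]
        sizes = {f"chr{i + 1}": config.chromosome_size
                 for i in range(config.n_chromosomes)}
        emit("window_tracks.tsv",
             window_tracks(gene_table, profiles, sizes, window_size=config.chromosome_size // 10))

    gc_genes = {p.gene_id for p in profiles
                if p.gc3s > truth["w"].median()}
    ann, names, tpm, planted = generate_annotations(
        [p.gene_id for p in profiles], gc_genes,
        planted_odds=4.0, seed=config.seed + 2)
    gc_set, at_set, universe = split_gc_at(profiles, tpm)
    enr = hypergeom_enrich(gc_set, universe, ann, names)
    emit("enrichment_gc.tsv", enr, {"planted_term": planted})
    emit("enrichment_gc_top10.tsv", top_terms(enr))
    enr_at = hypergeom_enrich(at_set, universe, ann, names)
    emit("enrichment_at.tsv", enr_at)

    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2)
    manifest["manifest"] = str(outdir / "manifest.json")
    return manifest
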