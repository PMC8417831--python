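import numpy as np
import pytest

import codonbias as cb
from codonbias import datasets
from codonbias.cds_io import CodonCountTable, count_codons
from codonbias.codon_metrics import profile_genes, rscu_matrix
from codonbias import family_analysis as fa
from codonbias.genetic_code import AA_TO_CODONS, SYNONYMOUS_CODONS


class TestClassifyPairs:
    def test_published_wheat_urartu_deltas_reproduced(self):
        table = datasets.gs_pairs_aestivum_urartu()
        result = fa.classify_pairs(
            list(table[["gene_a", "gene_b", "gc3s_a", "gc3s_b"]].itertuples(index=False))
        )
        assert np.allclose(result["delta"].round(3), table["published_difference"])
        assert result["biased"].all()
        assert len(result) == 7

    def test_published_emmer_urartu_deltas_reproduced(self):
        table = datasets.gs_pairs_turgidum_urartu()
        result = fa.classify_pairs(
            list(table[["gene_a", "gene_b", "gc3s_a", "gc3s_b"]].itertuples(index=False))
        )
        assert np.allclose(result["delta"].round(3), table["published_difference"])
        assert result["biased"].all()

    def test_negative_delta_keeps_sign_and_is_biased(self):
        result = fa.classify_pairs([("a", "b", 0.766, 0.953)])
        assert result["delta"].iloc[0] == pytest.approx(-0.187)
        assert bool(result["biased"].iloc[0])

    def test_equal_gc3s_not_biased(self):
        result = fa.classify_pairs([("a", "b", 0.5, 0.5)])
        assert result["delta"].iloc[0] == 0 and not result["biased"].iloc[0]

    def test_threshold_is_strict(self):
        result = fa.classify_pairs([("a", "b", 0.6, 0.5)])
        assert not result["biased"].iloc[0]


class TestPairDeltaFromProfiles:
    def test_profiles_feed_the_classification(self):
        recs_a, recs_b, pairs = cb.generate_homolog_pairs(
            20, delta_w=0.3, n_codons=400, seed=7
        )
        prof_a = profile_genes([count_codons(r) for r in recs_a])
        prof_b = profile_genes([count_codons(r) for r in recs_b])
        result = fa.pair_delta_gc3s(
            list(pairs[["gene_a", "gene_b"]].itertuples(index=False)), prof_a, prof_b
        )
        assert result["biased"].mean() >= 0.9

    def test_null_shift_rarely_flags(self):
        recs_a, recs_b, pairs = cb.generate_homolog_pairs(
            20, delta_w=0.0, n_codons=400, seed=8
        )
        prof_a = profile_genes([count_codons(r) for r in recs_a])
        prof_b = profile_genes([count_codons(r) for r in recs_b])
        result = fa.pair_delta_gc3s(
            list(pairs[["gene_a", "gene_b"]].itertuples(index=False)), prof_a, prof_b
        )
        assert result["biased"].mean() <= 0.1

    def test_unknown_gene_named_in_error(self):
        with pytest.raises(KeyError, match="ghost"):
            fa.pair_delta_gc3s([("ghost", "b")], [], [])


class TestFamilyRscuMatrix:
    def test_shape_and_labels(self):
        records, _ = cb.generate_two_group_set(n_per_group=2, seed=4)
        tables = [count_codons(r) for r in records]
        labels = {t.gene_id: "spX" for t in tables}
        matrix = fa.family_rscu_matrix(labels, tables)
        assert matrix.shape == (4, 59)
        assert all(idx.startswith("spX|") for idx in matrix.index)

    def test_uniform_gene_row_is_ones(self):
        counts = {c: 3 for c in AA_TO_CODONS["L"] | AA_TO_CODONS["K"]}
        matrix = fa.family_rscu_matrix({"u": ""}, [CodonCountTable("u", counts)])
        observed = matrix.loc["u"].dropna()
        assert np.allclose(observed, 1.0)

    def test_gc_preferring_family_overrepresents_gc_columns(self):
        records, _ = cb.generate_two_group_set(n_per_group=8, w_high=0.9, seed=9)
        tables = [count_codons(r) for r in records if r.gene_id.startswith("gc")]
        matrix = fa.family_rscu_matrix({t.gene_id: "" for t in tables}, tables)
        gc_cols = [c for c in SYNONYMOUS_CODONS if c[2] in "GC"]
        assert (matrix[gc_cols].mean() > 1).mean() > 0.9


class TestClustering:
    def test_identical_rows_merge_first_at_zero_distance(self):
        records, _ = cb.generate_two_group_set(n_per_group=2, seed=5)
        tables = [count_codons(r) for r in records]
        matrix = fa.family_rscu_matrix({t.gene_id: "" for t in tables}, tables)
        doubled = matrix.copy()
        doubled.loc["twin"] = matrix.iloc[0]
        newick, labels, Z = fa.cluster_rscu(doubled)
        assert Z[0, 2] == pytest.approx(0.0)
        assert newick.endswith(";") and "twin" in newick

    def test_planted_two_cluster_structure_recovered(self):
        records, truth = cb.generate_two_group_set(n_per_group=10, seed=6)
        tables = [count_codons(r) for r in records]
        matrix = fa.family_rscu_matrix({t.gene_id: "" for t in tables}, tables)
        _, labels, _ = fa.cluster_rscu(matrix, n_clusters=2)
        truth_groups = truth.set_index("gene_id")["group"]
        split = {}
        for gene, cluster in labels.items():
            split.setdefault(cluster, set()).add(truth_groups[gene])
        assert all(len(groups) == 1 for groups in split.values())
        assert len(split) == 2

    def test_row_order_invariance_up_to_relabeling(self):
        records, _ = cb.generate_two_group_set(n_per_group=6, seed=12)
        tables = [count_codons(r) for r in records]
        matrix = fa.family_rscu_matrix({t.gene_id: "" for t in tables}, tables)
        _, labels_a, _ = fa.cluster_rscu(matrix)
        _, labels_b, _ = fa.cluster_rscu(matrix.iloc[::-1])
        genes = list(matrix.index)
        same_a = {(g, h) for g in genes for h in genes if labels_a[g] == labels_a[h]}
        same_b = {(g, h) for g in genes for h in genes if labels_b[g] == labels_b[h]}
        assert same_a == same_b

    def test_nearest_progenitor_identity(self):
        records, _ = cb.generate_two_group_set(n_per_group=3, seed=13)
        tables = [count_codons(r) for r in records]
        matrix = fa.family_rscu_matrix({t.gene_id: "" for t in tables}, tables)
        assignment = fa.nearest_progenitor(matrix.iloc[[0]], matrix)
        assert assignment.iloc[0] == matrix.index[0]
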