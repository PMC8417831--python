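import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonbias as cb
from codonbias.cds_io import CdsRecord, CodonCountTable, count_codons
from codonbias import codon_metrics as cm
from codonbias.genetic_code import AA_TO_CODONS, SENSE_CODONS, SYNONYMOUS_AAS


def table(counts):
    return CodonCountTable("t", dict(counts))


class TestRscu:
    def test_lysine_3_to_1_split(self):
        values = cm.rscu(table({"AAA": 3, "AAG": 1}))
        assert values["AAA"] == pytest.approx(1.5)
        assert values["AAG"] == pytest.approx(0.5)

    def test_uniform_family_is_all_ones(self):
        values = cm.rscu(table({c: 5 for c in AA_TO_CODONS["L"]}))
        for c in AA_TO_CODONS["L"]:
            assert values[c] == pytest.approx(1.0)

    def test_absent_family_is_missing_not_zero(self):
        values = cm.rscu(table({"AAA": 3}))
        assert math.isnan(values["GGG"])

    def test_family_means_are_one_on_synthetic_genes(self, default_profiles):
        profiles, _ = default_profiles
        for p in profiles[:40]:
            for aa in SYNONYMOUS_AAS:
                family = sorted(AA_TO_CODONS[aa])
                vals = [p.rscu[c] for c in family]
                if any(math.isnan(v) for v in vals):
                    assert all(math.isnan(v) for v in vals)
                else:
                    assert np.mean(vals) == pytest.approx(1.0)


class TestEnc:
    def test_one_codon_per_amino_acid_scores_20(self):
        counts = {sorted(f)[0]: 2 for f in AA_TO_CODONS.values()}
        assert cm.enc(table(counts)) == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self):
        counts = {c: 400 for c in SENSE_CODONS}
        assert cm.enc(table(counts)) == pytest.approx(61.0)

    def test_capped_at_61(self, default_profiles):
        profiles, _ = default_profiles
        encs = [p.enc for p in profiles if not math.isnan(p.enc)]
        assert encs and max(encs) <= 61.0 and min(encs) >= 20.0

    def test_skew_never_increases_enc(self):
        # increasing within-family skew in Lys while everything else is uniform
        base = {c: 50 for c in SENSE_CODONS}
        prev = math.inf
        for aaa in (50, 70, 90, 99):
            counts = dict(base)
            counts["AAA"], counts["AAG"] = aaa, 100 - aaa
            value = cm.enc(table(counts))
            assert value <= prev + 1e-12
            prev = value

    def test_singleton_families_excluded(self):
        # every amino acid used exactly once: no family has n >= 2
        counts = {sorted(f)[0]: 1 for f in AA_TO_CODONS.values()}
        assert math.isnan(cm.enc(table(counts)))

    def test_missing_isoleucine_imputed(self):
        counts = {c: 10 for c in SENSE_CODONS if c not in AA_TO_CODONS["I"]}
        assert not math.isnan(cm.enc(table(counts)))


class TestGcPartition:
    def test_all_gcg_gene(self):
        gc, gc1, gc2, gc3, gc12 = cm.gc_partition(table({"GCG": 7}))
        assert (gc, gc1, gc2, gc3, gc12) == (1, 1, 1, 1, 1)

    def test_hand_counted_example(self):
        # ATG contributes G only at position 3; AAA contributes nothing
        gc, gc1, gc2, gc3, gc12 = cm.gc_partition(table({"ATG": 1, "AAA": 1}))
        assert gc1 == 0 and gc2 == 0 and gc3 == pytest.approx(0.5)
        assert gc12 == 0 and gc == pytest.approx(1 / 6)

    def test_gc12_midpoint_identity(self, default_profiles):
        profiles, _ = default_profiles
        for p in profiles[:40]:
            assert p.gc12 == pytest.approx((p.gc1 + p.gc2) / 2)


class TestGc3s:
    def test_met_trp_excluded(self):
        gc3s, *_ = cm.gc3s_and_base3s(
            table({"ATG": 1, "GCG": 1, "GCA": 1, "TGG": 1})
        )
        assert gc3s == pytest.approx(0.5)

    def test_base_fractions_sum_to_one(self, default_profiles):
        profiles, _ = default_profiles
        for p in profiles[:40]:
            assert p.a3s + p.t3s + p.g3s + p.c3s == pytest.approx(1.0)

    def test_all_g_ending_synonymous(self):
        gc3s, a3s, t3s, g3s, c3s = cm.gc3s_and_base3s(table({"GCG": 3, "AAG": 2}))
        assert gc3s == 1 and g3s == 1

    def test_no_synonymous_codons_is_missing(self):
        gc3s, *_ = cm.gc3s_and_base3s(table({"ATG": 5, "TGG": 5}))
        assert math.isnan(gc3s)


class TestProfileGenes:
    def test_one_profile_per_gene_in_order(self, default_profiles):
        profiles, tables = default_profiles
        assert [p.gene_id for p in profiles] == [t.gene_id for t in tables]

    def test_duplicated_gene_profiles_identically(self):
        t = count_codons(CdsRecord("g", "ATG" + "GCA" * 150 + "TAA"))
        p1, p2 = cm.profile_gene(t), cm.profile_gene(t)
        assert p1 == p2

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            cm.profile_genes([])

    def test_mean_gc3s_tracks_planted_weight(self):
        records, _ = cb.generate_cds_set(
            cb.GeneratorConfig(seed=8, n_genes=120, w_range=None, w=0.8)
        )
        profiles = cm.profile_genes([count_codons(r) for r in records])
        assert np.mean([p.gc3s for p in profiles]) == pytest.approx(0.8, abs=0.02)

    def test_frame_and_matrix_round_trip(self, default_profiles):
        profiles, _ = default_profiles
        frame = cm.profiles_to_frame(profiles)
        assert len(frame) == len(profiles)
        assert frame.loc[profiles[0].gene_id, "enc"] == pytest.approx(
            profiles[0].enc, nan_ok=True
        )
        matrix = cm.rscu_matrix(profiles)
        assert matrix.shape == (len(profiles), 59)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                       st.integers(min_value=0, max_value=30),
                       min_size=1, max_size=61))
def test_rscu_family_mean_property(counts):
    values = cm.rscu(table(counts))
    for aa in SYNONYMOUS_AAS:
        family = sorted(AA_TO_CODONS[aa])
        vals = [values[c] for c in family]
        total = sum(counts.get(c, 0) for c in family)
        if total == 0:
            assert all(math.isnan(v) for v in vals)
        else:
            assert sum(vals) == pytest.approx(len(family))
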