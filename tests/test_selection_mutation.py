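import math

import numpy as np
import pandas as pd
import pytest

import codonbias as cb
from codonbias.cds_io import CodonCountTable, count_codons
from codonbias.codon_metrics import GeneProfile, profile_genes, rscu_matrix
from codonbias.genetic_code import AA_TO_CODONS, FOURFOLD_QUARTETS
from codonbias import selection_mutation as sm


def fake_profile(gene_id, gc3=0.5, gc12=0.4, enc=50.0, gc3s=0.5):
    return GeneProfile(
        gene_id=gene_id, n_codons=100, enc=enc, gc=0.5, gc1=gc12, gc2=gc12,
        gc3=gc3, gc12=gc12, gc3s=gc3s, a3s=0.25, t3s=0.25, g3s=0.25, c3s=0.25,
    )


class TestEncExpected:
    def test_symmetric_peak_value(self):
        assert sm.enc_expected(0.5) == pytest.approx(60.5)

    def test_off_center_value(self):
        assert sm.enc_expected(0.1) == pytest.approx(2.1 + 29 / 0.82)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2, 1.7])
    def test_domain_enforced(self, s):
        with pytest.raises(ValueError):
            sm.enc_expected(s)

    def test_continuous_single_peak_on_grid(self):
        grid = np.linspace(0.001, 0.999, 999)
        values = np.array([sm.enc_expected(s) for s in grid])
        diffs = np.sign(np.diff(values))
        # one sign change: rises to the 0.5 peak, then falls
        changes = np.count_nonzero(np.diff(diffs[diffs != 0]))
        assert changes <= 1
        # the linear +s term nudges the peak just above s = 0.5
        assert abs(grid[values.argmax()] - 0.5) < 0.01


class TestEncPlot:
    def test_gene_on_curve_has_zero_deviation(self):
        p = fake_profile("g", gc3s=0.3, enc=sm.enc_expected(0.3))
        df = sm.enc_plot_table([p])
        assert df["deviation"].iloc[0] == pytest.approx(0.0)
        assert bool(df["within_band"].iloc[0])

    def test_missing_enc_excluded_and_counted(self):
        p_ok = fake_profile("ok", gc3s=0.3, enc=45.0)
        p_bad = fake_profile("bad", gc3s=0.3, enc=float("nan"))
        df = sm.enc_plot_table([p_ok, p_bad])
        assert len(df) == 1 and df.attrs["n_excluded"] == 1

    def test_mutation_only_genes_hug_the_curve(self):
        # codon choice depends only on the third-position weight
        records, _ = cb.generate_cds_set(
            cb.GeneratorConfig(seed=21, n_genes=80, w_range=(0.3, 0.9))
        )
        profiles = profile_genes([count_codons(r) for r in records])
        df = sm.enc_plot_table(profiles)
        assert df["deviation"].abs().median() < 0.05

    def test_selection_genes_fall_far_below_curve(self):
        # one fixed codon per family: maximal bias at balanced gc3s
        counts = {}
        for aa, family in AA_TO_CODONS.items():
            ordered = sorted(family)
            counts[ordered[0]] = 30
        profiles = profile_genes([CodonCountTable("sel", counts)])
        df = sm.enc_plot_table(profiles)
        assert df["deviation"].iloc[0] > 0.3


class TestNeutralityFit:
    def test_noiseless_line_recovered(self):
        profiles = [
            fake_profile(f"g{i}", gc3=x, gc12=0.2 * x + 0.3)
            for i, x in enumerate(np.linspace(0.1, 0.9, 20))
        ]
        fit = sm.neutrality_fit(profiles)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(0.3)
        assert fit.r == pytest.approx(1.0)
        assert fit.n == 20

    def test_independent_gc12_gives_near_zero_slope(self, rng):
        profiles = [
            fake_profile(f"g{i}", gc3=rng.uniform(0.2, 0.9), gc12=rng.normal(0.45, 0.02))
            for i in range(500)
        ]
        fit = sm.neutrality_fit(profiles)
        assert abs(fit.slope) < 0.02

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 3 genes"):
            sm.neutrality_fit([fake_profile("a"), fake_profile("b")])

    def test_zero_gc3_variance_rejected(self):
        profiles = [fake_profile(f"g{i}", gc3=0.5) for i in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            sm.neutrality_fit(profiles)

    def test_planted_slope_recovered(self):
        records, _ = cb.generate_neutrality_set(
            600, slope=0.18, intercept=0.30, noise_sd=0.02, n_codons=400, seed=5
        )
        profiles = profile_genes([count_codons(r) for r in records])
        fit = sm.neutrality_fit(profiles)
        assert fit.slope == pytest.approx(0.18, abs=0.03)
        assert fit.p < 0.001


class TestPr2:
    def test_balanced_gene_sits_at_center(self):
        counts = {c: 5 for quartet in FOURFOLD_QUARTETS.values() for c in quartet}
        pt = sm.pr2_point(CodonCountTable("g", counts))
        assert pt.at_bias == pytest.approx(0.5)
        assert pt.gc_bias == pytest.approx(0.5)

    def test_all_t_ending_fourfold(self):
        counts = {c: 5 for quartet in FOURFOLD_QUARTETS.values()
                  for c in quartet if c.endswith("T")}
        pt = sm.pr2_point(CodonCountTable("g", counts))
        assert pt.at_bias == 0.0

    def test_zero_denominator_is_missing(self):
        counts = {c: 5 for quartet in FOURFOLD_QUARTETS.values()
                  for c in quartet if c.endswith(("G", "C"))}
        pt = sm.pr2_point(CodonCountTable("g", counts))
        assert math.isnan(pt.at_bias) and pt.gc_bias == pytest.approx(0.5)

    def test_twofold_codons_do_not_enter(self):
        pt = sm.pr2_point(CodonCountTable("g", {"AAA": 50, "TTT": 50}))
        assert math.isnan(pt.at_bias) and math.isnan(pt.gc_bias)

    def test_batch_table_shape(self, default_profiles):
        _, tables = default_profiles
        df = sm.pr2_table(tables)
        assert list(df.columns) == ["gene_id", "at_bias", "gc_bias"]
        ok = df.dropna()
        assert ((ok[["at_bias", "gc_bias"]] >= 0) & (ok[["at_bias", "gc_bias"]] <= 1)).all().all()


class TestCoa:
    def test_inertia_sums_to_100(self, default_profiles):
        profiles, _ = default_profiles
        res = sm.coa_rscu(rscu_matrix(profiles))
        assert res.inertia_pct_all.sum() == pytest.approx(100.0)
        assert (res.inertia_pct_all >= 0).all()

    def test_axis1_separates_disjoint_preference_groups(self):
        records, truth = cb.generate_two_group_set(n_per_group=15, seed=31)
        profiles = profile_genes([count_codons(r) for r in records])
        res = sm.coa_rscu(rscu_matrix(profiles))
        ax1 = res.gene_coords["axis1"]
        gc_side = ax1[[g.startswith("gc") for g in ax1.index]]
        at_side = ax1[[g.startswith("at") for g in ax1.index]]
        assert gc_side.min() > at_side.max() or at_side.min() > gc_side.max()
        assert res.inertia_pct[0] > 50

    def test_axis1_tracks_gc3s(self, default_profiles):
        profiles, _ = default_profiles
        res = sm.coa_rscu(rscu_matrix(profiles))
        gc3s = np.array([p.gc3s for p in profiles])
        r = np.corrcoef(gc3s, res.gene_coords["axis1"])[0, 1]
        assert abs(r) > 0.9

    def test_row_order_invariance_with_sign_convention(self, default_profiles):
        profiles, _ = default_profiles
        matrix = rscu_matrix(profiles[:50])
        shuffled = matrix.sample(frac=1, random_state=0)
        a = sm.coa_rscu(matrix).gene_coords
        b = sm.coa_rscu(shuffled).gene_coords.loc[a.index]
        pd.testing.assert_frame_equal(a, b, atol=1e-8)

    def test_tiny_rank_deficient_input_survives(self):
        matrix = rscu_matrix(
            profile_genes([
                CodonCountTable("a", {"AAA": 2, "AAG": 1}),
                CodonCountTable("b", {"AAA": 1, "AAG": 2}),
            ])
        )
        res = sm.coa_rscu(matrix)
        assert res.gene_coords.shape[1] >= 1
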