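"""Differential expression machinery: normalization, dispersion, Wald,
BH, PCA, distances, gene-wise reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import streamtx.de as de
from streamtx.simulate import simulate_nb_counts

GROUPS_3V3 = pd.Series({"A_1": "A", "A_2": "A", "A_3": "A",
                        "B_1": "B", "B_2": "B", "B_3": "B"})


def _sf1(counts):
    return pd.Series(1.0, index=counts.columns)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 30, 7], "s2": [10, 30, 7]})
        assert np.allclose(de.size_factors(counts), 1.0)

    def test_hand_computed_two_by_two(self):
        # geometric means: sqrt(10*20)=14.1421, sqrt(30*60)=42.4264;
        # ratios per column are 1/sqrt(2) and sqrt(2) for both genes
        counts = pd.DataFrame({"s1": [10, 30], "s2": [20, 60]})
        sf = de.size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["s2"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_genes_with_zeros_excluded(self):
        counts = pd.DataFrame({"s1": [0, 10, 20], "s2": [5, 10, 20]})
        assert np.allclose(de.size_factors(counts), [1.0, 1.0])

    def test_error_when_no_gene_positive_everywhere(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]})
        with pytest.raises(ValueError, match="depth"):
            de.size_factors(counts)

    def test_scaling_one_sample_scales_its_factor_exactly(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(100, 4)) + 1,
                              columns=list("abcd"))
        sf = de.size_factors(counts)
        scaled = counts.copy()
        scaled["b"] *= 3
        sf2 = de.size_factors(scaled)
        assert sf2["b"] == pytest.approx(3 * sf["b"] / 3 ** 0.25, rel=1e-12)
        # normalized values are invariant under the rescaling
        n1 = de.normalize(counts, sf)
        n2 = de.normalize(scaled, sf2)
        assert np.allclose(n1 / n1.iloc[0], n2 / n2.iloc[0])

    def test_invariant_to_gene_reordering(self, rng):
        counts = pd.DataFrame(rng.poisson(30, size=(50, 3)) + 1)
        sf = de.size_factors(counts)
        shuffled = counts.sample(frac=1, random_state=0)
        assert np.allclose(de.size_factors(shuffled), sf)


class TestNormalize:
    def test_unit_factors_are_identity(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]})
        assert de.normalize(counts, _sf1(counts)).equals(
            counts.astype(float))

    def test_zero_row_stays_zero(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 5]})
        sf = pd.Series({"s1": 0.5, "s2": 2.0})
        assert (de.normalize(counts, sf).loc[0] == 0).all()


class TestDispersions:
    def test_poisson_counts_give_near_zero_alpha(self):
        counts, groups = simulate_nb_counts(500, 5, mu=100.0, alpha=0.0,
                                            seed=1)
        disp = de.estimate_dispersions(
            de.normalize(counts, de.size_factors(counts)), groups)
        assert disp.alpha.median() < 0.05

    def test_nb_alpha_point_two_recovered(self):
        counts, groups = simulate_nb_counts(2000, 10, mu=100.0, alpha=0.2,
                                            seed=2)
        disp = de.estimate_dispersions(
            de.normalize(counts, de.size_factors(counts)), groups)
        assert 0.1 <= disp.alpha.median() <= 0.3

    def test_constant_gene_hits_floor(self):
        counts = pd.DataFrame([[50] * 6, [10, 20, 15, 30, 12, 22]],
                              index=["flat", "var"],
                              columns=GROUPS_3V3.index)
        disp = de.estimate_dispersions(counts.astype(float), GROUPS_3V3)
        assert disp.genewise["flat"] == de.ALPHA_FLOOR

    def test_single_replicate_group_rejected(self):
        counts = pd.DataFrame(np.ones((5, 3)),
                              columns=["A_1", "A_2", "B_1"])
        groups = pd.Series({"A_1": "A", "A_2": "A", "B_1": "B"})
        with pytest.raises(ValueError, match="replicates"):
            de.estimate_dispersions(counts, groups)


class TestWald:
    def test_identical_groups_give_zero_lfc_unit_p(self):
        block = np.tile([[20.0], [40.0], [100.0]], (1, 3))
        counts = pd.DataFrame(np.hstack([block, block]),
                              columns=GROUPS_3V3.index)
        disp = de.estimate_dispersions(counts, GROUPS_3V3)
        res = de.wald_test(counts, _sf1(counts), disp, GROUPS_3V3,
                           ("A", "B"))
        assert np.allclose(res["log2FC"], 0.0, atol=1e-6)
        assert np.allclose(res["pvalue"], 1.0, atol=1e-6)

    def test_agrees_with_statsmodels_nb_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        counts, groups = simulate_nb_counts(25, 3, mu=80.0, alpha=0.1,
                                            seed=5)
        sf = de.size_factors(counts)
        disp = de.estimate_dispersions(de.normalize(counts, sf), groups)
        res = de.wald_test(counts, sf, disp, groups, ("A", "B"))
        X = np.column_stack([np.ones(6), (groups == "B").astype(float)])
        offset = np.log(sf.to_numpy())
        for g in counts.index:
            fam = sm.families.NegativeBinomial(alpha=float(disp.alpha[g]))
            fit = sm.GLM(counts.loc[g].to_numpy(), X, family=fam,
                         offset=offset).fit()
            assert res.loc[g, "log2FC"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4)

    def test_fourfold_shift_recovered(self):
        # 5% of genes shifted, as in a typical perturbation; much larger
        # one-sided DE fractions bias median-of-ratios factors themselves
        lfc = np.zeros(600)
        lfc[:30] = 2.0
        counts, groups = simulate_nb_counts(600, 3, mu=100.0, alpha=0.05,
                                            log2fc=lfc, seed=6)
        sf = de.size_factors(counts)
        disp = de.estimate_dispersions(de.normalize(counts, sf), groups)
        res = de.wald_test(counts, sf, disp, groups, ("A", "B"))
        hi = res.iloc[:30].query("baseMean >= 50")
        assert (hi["log2FC"] - 2.0).abs().median() <= 0.25

    def test_complete_separation_is_significant_with_correct_sign(self):
        counts = pd.DataFrame(
            {"A_1": [0, 50], "A_2": [0, 60], "A_3": [0, 45],
             "B_1": [200, 55], "B_2": [180, 60], "B_3": [210, 50]},
            index=["marker", "ctrl"])
        disp = de.estimate_dispersions(counts.astype(float), GROUPS_3V3)
        res = de.wald_test(counts, _sf1(counts), disp, GROUPS_3V3,
                           ("A", "B"))
        assert res.loc["marker", "pvalue"] < 1e-6
        assert res.loc["marker", "log2FC"] > 0
        assert np.sign(res.loc["marker", "stat"]) == \
            np.sign(res.loc["marker", "log2FC"])
        down = de.wald_test(counts, _sf1(counts), disp, GROUPS_3V3,
                            ("B", "A"))
        assert down.loc["marker", "log2FC"] < 0

    def test_low_count_features_filtered_to_null(self):
        counts = pd.DataFrame(
            {"A_1": [1, 50], "A_2": [0, 60], "A_3": [1, 45],
             "B_1": [2, 55], "B_2": [0, 60], "B_3": [1, 50]},
            index=["rare", "ok"])
        disp = de.estimate_dispersions(counts.astype(float), GROUPS_3V3)
        res = de.wald_test(counts, _sf1(counts), disp, GROUPS_3V3,
                           ("A", "B"), min_total_count=10)
        assert np.isnan(res.loc["rare", "pvalue"])
        assert np.isnan(res.loc["rare", "padj"])
        assert np.isfinite(res.loc["ok", "pvalue"])


class TestBH:
    def test_hand_stepup_example(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_unchanged(self):
        assert np.allclose(de.bh_adjust([0.2] * 5), 0.2)

    def test_matches_statsmodels(self, rng):
        stats_mod = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.random(200)
        ours = de.bh_adjust(p)
        theirs = stats_mod.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_adjusted_at_least_raw_and_at_most_one(self, pvals):
        adj = de.bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


class TestTopK:
    def _frame(self, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2FC": lfc,
                             "baseMean": 10.0})

    def test_empty_input(self):
        assert len(de.top_k(self._frame([], []))) == 0

    def test_only_significant_kept(self):
        res = self._frame([0.01] * 5 + [0.5] * 95, [1.0] * 100)
        assert len(de.top_k(res, k=20)) == 5

    def test_tie_broken_by_effect_size(self):
        res = self._frame([0.01, 0.01], [1.0, 3.0])
        assert de.top_k(res).index.tolist() == [1, 0]


class TestTransformAndViews:
    def test_log_transform_basics(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [0, 7]})
        t = de.transform_log(counts, _sf1(counts))
        assert (t.loc[0] == 0).all()
        assert t.at[1, "s2"] == pytest.approx(3.0)

    def test_transform_invariant_under_depth_scaling(self, rng):
        counts = pd.DataFrame(rng.poisson(40, size=(200, 4)) + 1,
                              columns=list("abcd"))
        doubled = counts.copy()
        doubled["c"] *= 2
        n1 = de.normalize(counts, de.size_factors(counts))
        n2 = de.normalize(doubled, de.size_factors(doubled))
        # the size-factor contract: doubling one of four columns doubles its
        # factor and rescales every factor by 2^(1/4) through the geometric
        # means, so normalized matrices agree up to that global constant
        assert np.allclose(n2, n1 * 2 ** 0.25, rtol=1e-10)
        t2 = de.transform_log(doubled, de.size_factors(doubled))
        assert np.allclose(t2, np.log2(n1 * 2 ** 0.25 + 1.0), rtol=1e-10)

    def test_pca_duplicated_sample_has_identical_coordinates(self, rng):
        mat = pd.DataFrame(rng.normal(5, 1, size=(100, 3)),
                           columns=["s1", "s2", "s3"])
        mat["s4"] = mat["s3"]
        res = de.pca(mat)
        assert np.allclose(res.coordinates.loc["s3"],
                           res.coordinates.loc["s4"], atol=1e-8)

    def test_pca_separates_strong_conditions(self):
        lfc = np.concatenate([np.full(100, 3.0), np.zeros(400)])
        counts, groups = simulate_nb_counts(500, 3, mu=200.0, alpha=0.02,
                                            log2fc=lfc, seed=8)
        sf = de.size_factors(counts)
        res = de.pca(de.transform_log(counts, sf))
        pc1 = res.coordinates["PC1"]
        signs_a = np.sign(pc1[groups == "A"])
        signs_b = np.sign(pc1[groups == "B"])
        assert len(set(signs_a)) == 1 and len(set(signs_b)) == 1
        assert signs_a.iloc[0] != signs_b.iloc[0]

    def test_pca_variance_fractions_well_formed(self, rng):
        mat = pd.DataFrame(rng.normal(size=(50, 5)))
        res = de.pca(mat)
        evf = res.explained_variance_fraction
        assert (np.diff(evf) <= 1e-12).all()
        assert evf.sum() <= 1.0 + 1e-9
        assert (evf >= 0).all()

    def test_distances_metric_properties(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        mat["b"] = mat["a"]
        d = de.sample_distances(mat)
        assert d.at["a", "b"] == pytest.approx(0.0)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        d2 = de.sample_distances(mat * 3.0)
        assert np.allclose(d2, 3.0 * d)

    def test_genewise_reports_raw_and_normalized(self):
        counts = pd.DataFrame(
            {"A_1": [0, 10], "A_2": [0, 20], "A_3": [0, 15],
             "B_1": [0, 12], "B_2": [0, 18], "B_3": [0, 9]},
            index=["knockout", "g2"])
        table = de.genewise(counts, _sf1(counts), ["knockout", "g2"],
                            GROUPS_3V3)
        ko = table[table["gene_id"] == "knockout"]
        assert (ko["raw"] == 0).all() and (ko["normalized"] == 0).all()
        g2 = table[table["gene_id"] == "g2"]
        assert np.allclose(g2["raw"], g2["normalized"])

    def test_genewise_unknown_gene_suggests_near_matches(self):
        counts = pd.DataFrame({"A_1": [1], "A_2": [1], "A_3": [1],
                               "B_1": [1], "B_2": [1], "B_3": [1]},
                              index=["ACTB"])
        with pytest.raises(KeyError, match="ACTB"):
            de.genewise(counts, _sf1(counts), ["ACTB1"], GROUPS_3V3)
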