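import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epioutlier import (ExpressionMatrix, bh_adjust, fit_moderated_t,
                        gene_set_test, split_by_marker_gene)
from epioutlier.pathway import estimate_variance_prior
from .oracles import bh_stepup_brute, pooled_t_brute, rank_sum_exact_brute


def _expr(n_genes, n_tumor, n_normal, rng, sd=0.5):
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"T{i:02d}" for i in range(n_tumor)] + \
              [f"N{i:02d}" for i in range(n_normal)]
    vals = pd.DataFrame(rng.normal(8, sd, (n_genes, n_tumor + n_normal)),
                        index=genes, columns=samples)
    cls = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    return ExpressionMatrix(vals, cls)


class TestMarkerSplit:
    def test_44_tumors_split_into_equal_halves(self, rng):
        expr = _expr(5, 44, 25, rng)
        design = split_by_marker_gene(expr, "G0")
        counts = design.groups.value_counts()
        assert counts["marker_low"] == 22
        assert counts["marker_high"] == 22
        assert counts["normal"] == 25
        low = design.members("marker_low")
        high = design.members("marker_high")
        assert expr.values.loc["G0", low].max() <= expr.values.loc["G0", high].min()

    def test_two_tumors_split_one_and_one(self, rng):
        design = split_by_marker_gene(_expr(3, 2, 3, rng), "G1")
        assert len(design.members("marker_low")) == 1
        assert len(design.members("marker_high")) == 1

    def test_odd_count_median_sample_goes_low(self, rng):
        design = split_by_marker_gene(_expr(3, 5, 3, rng), "G0")
        assert len(design.members("marker_low")) == 3
        assert len(design.members("marker_high")) == 2

    def test_median_ties_break_by_sample_id_deterministically(self):
        samples = [f"T{i}" for i in range(4)] + ["N0", "N1"]
        vals = pd.DataFrame([[5.0, 5.0, 5.0, 5.0, 4.0, 4.0]], index=["M"],
                            columns=samples)
        cls = pd.Series(["tumor"] * 4 + ["normal"] * 2, index=samples)
        expr = ExpressionMatrix(vals, cls)
        designs = [split_by_marker_gene(expr, "M") for _ in range(3)]
        for d in designs[1:]:
            pd.testing.assert_series_equal(d.groups, designs[0].groups)
        assert sorted(designs[0].members("marker_low")) == ["T0", "T1"]

    def test_absent_marker_is_an_error_naming_it(self, rng):
        with pytest.raises(ValueError, match="NOPE"):
            split_by_marker_gene(_expr(3, 4, 3, rng), "NOPE")


class TestModeratedT:
    def test_equal_group_means_give_null_statistic(self, rng):
        expr = _expr(20, 6, 4, rng)
        design = split_by_marker_gene(expr, "G1")
        # construct a gene with exactly equal group means
        low, high = design.members("marker_low"), design.members("marker_high")
        v = expr.values.copy()
        v.loc["G0", low] = [1.0, 2.0, 3.0]
        v.loc["G0", high] = [3.0, 1.0, 2.0]
        res, _ = fit_moderated_t(ExpressionMatrix(v, expr.sample_class), design)
        row = res.set_index("gene_id").loc["G0"]
        assert row["t_mod"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_zero_prior_df_recovers_ordinary_pooled_t(self, rng):
        expr = _expr(50, 10, 6, rng)
        design = split_by_marker_gene(expr, "G0")
        res, prior = fit_moderated_t(expr, design, prior_df=0)
        assert prior.d0 == 0
        low, high = design.members("marker_low"), design.members("marker_high")
        for gene in ["G1", "G7", "G33"]:
            t_ref, p_ref = pooled_t_brute(expr.values.loc[gene, low],
                                          expr.values.loc[gene, high])
            row = res.set_index("gene_id").loc[gene]
            assert row["t_mod"] == pytest.approx(t_ref, abs=1e-10)
            assert row["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_infinite_prior_pools_all_variances(self, rng):
        expr = _expr(30, 8, 4, rng)
        design = split_by_marker_gene(expr, "G0")
        res, prior = fit_moderated_t(expr, design, prior_df=np.inf)
        se_ratio = res["t_mod"] / res["log_fc"]
        # constant posterior variance => t proportional to log_fc
        assert np.allclose(se_ratio.dropna(), se_ratio.dropna().iloc[0])

    def test_hyperparameter_recovery_from_scaled_f_variances(self):
        # gene variances drawn from the model: s2 ~ s0^2 * chi2_d / d with
        # infinite-prior limit replaced by finite d0 via an F draw
        rng = np.random.default_rng(42)
        d_g, d0_true, s0_true = 10, 8.0, 0.25
        n = 2000
        chi_num = rng.chisquare(d_g, n)
        chi_den = rng.chisquare(d0_true, n)
        s2 = s0_true * (chi_num / d_g) / (chi_den / d0_true)
        prior = estimate_variance_prior(s2, d_g)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)
        assert prior.d0 == pytest.approx(d0_true, rel=0.35)

    def test_common_variance_genes_recover_prior_variance(self):
        rng = np.random.default_rng(7)
        d_g, s0_true = 12, 0.4
        s2 = s0_true * rng.chisquare(d_g, 2000) / d_g
        prior = estimate_variance_prior(s2, d_g)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_moderation_shrinks_extreme_ordinary_t(self, rng):
        expr = _expr(200, 8, 4, rng)
        design = split_by_marker_gene(expr, "G0")
        # a gene with tiny variance but modest fold change inflates the
        # ordinary t; moderation reins it in
        low, high = design.members("marker_low"), design.members("marker_high")
        v = expr.values.copy()
        v.loc["G1", low] = 8.0 + rng.normal(0, 1e-4, len(low))
        v.loc["G1", high] = 8.3 + rng.normal(0, 1e-4, len(high))
        expr2 = ExpressionMatrix(v, expr.sample_class)
        res_mod, _ = fit_moderated_t(expr2, design)
        res_ord, _ = fit_moderated_t(expr2, design, prior_df=0)
        t_mod = abs(res_mod.set_index("gene_id").loc["G1", "t_mod"])
        t_ord = abs(res_ord.set_index("gene_id").loc["G1", "t_mod"])
        assert t_mod < t_ord

    def test_small_groups_rejected(self, rng):
        expr = _expr(5, 2, 3, rng)
        design = split_by_marker_gene(expr, "G0")
        with pytest.raises(ValueError, match=">= 2"):
            fit_moderated_t(expr, design)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_stepup_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        p = rng.uniform(size=rng.integers(2, 21))
        assert bh_adjust(p) == pytest.approx(bh_stepup_brute(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGeneSetTest:
    def test_top_ranked_set_is_enriched(self, rng):
        x = rng.normal(size=50)
        top = np.argsort(x)[-5:]
        assert gene_set_test(x, top, "up") < 0.01
        assert gene_set_test(x, top, "down") > 0.5

    @pytest.mark.parametrize("alternative", ["up", "down"])
    def test_exact_mode_equals_enumeration(self, alternative, rng):
        x = rng.choice(np.arange(8.0), 12)     # ties included
        idx = [0, 3, 5]
        p = gene_set_test(x, idx, alternative, exact=True)
        ranks = stats.rankdata(x)
        assert p == pytest.approx(rank_sum_exact_brute(ranks, idx, alternative))

    def test_either_doubles_smaller_tail_without_ties(self, rng):
        x = rng.normal(size=40)
        idx = rng.choice(40, 8, replace=False)
        p_up = gene_set_test(x, idx, "up")
        p_down = gene_set_test(x, idx, "down")
        assert gene_set_test(x, idx, "either") == pytest.approx(
            min(1.0, 2 * min(p_up, p_down)))

    def test_normal_approximation_close_to_exact(self, rng):
        x = rng.normal(size=22)
        idx = [1, 4, 9, 15]
        p_exact = gene_set_test(x, idx, "up", exact=True)
        p_approx = gene_set_test(x, idx, "up", exact=False)
        assert p_approx == pytest.approx(p_exact, abs=0.03)

    def test_null_p_values_are_calibrated(self):
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(500):
            x = rng.normal(size=80)
            idx = rng.choice(80, 10, replace=False)
            ps.append(gene_set_test(x, idx, "up"))
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_sets_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="empty"):
            gene_set_test(x, [], "up")
        with pytest.raises(ValueError, match="every gene"):
            gene_set_test(x, list(range(10)), "up")


class TestEndToEndPathway:
    def test_planted_coshifted_set_is_detected(self, small_cohort):
        cohort = small_cohort
        marker = cohort.truth.silenced_genes[0]
        design = split_by_marker_gene(cohort.expression, marker)
        res, _ = fit_moderated_t(cohort.expression, design)
        idx = res.index[res["gene_id"].isin(cohort.truth.pathway_genes)].to_numpy()
        assert gene_set_test(res["t_mod"].to_numpy(), idx, "either") < 0.05

    def test_random_same_size_sets_are_not_enriched(self, small_cohort):
        cohort = small_cohort
        marker = cohort.truth.silenced_genes[0]
        design = split_by_marker_gene(cohort.expression, marker)
        res, _ = fit_moderated_t(cohort.expression, design)
        background = res.index[~res["gene_id"].isin(
            cohort.truth.pathway_genes + cohort.truth.silenced_genes
            + cohort.truth.up_outlier_genes)].to_numpy()
        rng = np.random.default_rng(99)
        k = len(cohort.truth.pathway_genes)
        ps = [gene_set_test(res["t_mod"].to_numpy(),
                            rng.choice(background, k, replace=False), "either")
              for _ in range(30)]
        assert np.median(ps) > 0.1
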