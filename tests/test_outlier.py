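import numpy as np
import pandas as pd
import pytest

from epioutlier import (ExpressionMatrix, OutlierParams, delta_sweep,
                        empirical_null, outlier_score_gene,
                        rank_outlier_candidates)
from .oracles import outlier_score_brute

UP, DOWN = "up", "down"


def _labels(n_tumor, n_normal):
    return np.array(["tumor"] * n_tumor + ["normal"] * n_normal)


class TestEmpiricalNull:
    def test_decile_interpolation_on_1_to_10(self):
        nq = empirical_null(np.arange(1, 11), 0.10, 0.90)
        assert nq.q_low_value == pytest.approx(1.9)
        assert nq.q_high_value == pytest.approx(9.1)
        assert nq.n_normals == 10

    def test_constant_vector_collapses(self):
        nq = empirical_null([7.0] * 5)
        assert nq.q_low_value == nq.q_high_value == 7.0

    def test_quantiles_monotone_in_q(self, rng):
        x = rng.normal(size=25)
        qs = np.linspace(0.05, 0.95, 10)
        vals = [empirical_null(x, q, 0.99).q_low_value for q in qs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_requires_two_normals(self):
        with pytest.raises(ValueError, match="2 normal"):
            empirical_null([1.0])


class TestOutlierScoreGene:
    def test_tumors_at_normal_median_score_zero(self):
        normals = np.arange(1.0, 11.0)
        values = np.concatenate([[5.5, 5.5, 5.5], normals])
        res = outlier_score_gene(values, _labels(3, 10))
        assert res.score == 0.0
        assert res.n_outliers == 0

    def test_single_extreme_tumor_gets_maximal_normalized_rank(self):
        values = np.concatenate([[100.0], np.arange(1.0, 26.0)])
        res = outlier_score_gene(values, _labels(1, 25))
        assert res.score_right == pytest.approx(1.0)  # rank 26 / N 26
        assert res.n_outliers == 1
        assert res.direction == UP

    def test_three_extreme_tumors_sum_top_ranks(self):
        # N = 28: three high tumors take ranks 26, 27, 28
        values = np.concatenate([[50.0, 60.0, 70.0], np.arange(1.0, 26.0)])
        res = outlier_score_gene(values, _labels(3, 25))
        assert res.score_right == pytest.approx((26 + 27 + 28) / 28)
        assert res.n_outliers == 3

    def test_low_tumors_score_on_left_tail_with_descending_ranks(self):
        values = np.concatenate([[-50.0], np.arange(1.0, 26.0)])
        res = outlier_score_gene(values, _labels(1, 25))
        assert res.direction == DOWN
        assert res.score_left == pytest.approx(26 / 26)

    def test_label_value_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            outlier_score_gene([1.0, 2.0], _labels(2, 1))

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            outlier_score_gene([np.nan, 1, 2, 3], _labels(1, 3))


class TestBruteForceEquivalence:
    """The vectorized score must equal direct enumeration on random
    small instances (exhaustive over many seeds, N <= 12)."""

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_oracle_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_normal = rng.integers(2, 8)
        n_tumor = rng.integers(1, 12 - n_normal + 1)
        # discrete support makes ties frequent
        values = rng.choice(np.arange(0.0, 6.0), n_tumor + n_normal)
        delta = float(rng.choice([0.0, 0.14, 0.5, 1.0]))
        params = OutlierParams(delta=delta)
        res = outlier_score_gene(values, _labels(n_tumor, n_normal), params)
        sr, sl = outlier_score_brute(values, _labels(n_tumor, n_normal) == "tumor",
                                     params.q_low, params.q_high, delta)
        assert res.score_right == pytest.approx(sr, abs=1e-12)
        assert res.score_left == pytest.approx(sl, abs=1e-12)
        assert res.score == pytest.approx(max(sr, sl), abs=1e-12)


class TestScoreProperties:
    def test_raising_an_outlier_never_decreases_right_score(self, rng):
        base = np.concatenate([rng.normal(8, 1, 6), rng.normal(8, 1, 10)])
        labels = _labels(6, 10)
        prev = -1.0
        bumped = base.copy()
        for bump in [0.0, 1.0, 2.0, 5.0, 10.0]:
            bumped[0] = base[0] + bump
            score = outlier_score_gene(bumped, labels).score_right
            assert score >= prev - 1e-12
            prev = score

    def test_each_outlier_contributes_at_most_one(self, rng):
        for _ in range(20):
            values = rng.normal(0, 3, 15)
            res = outlier_score_gene(values, _labels(5, 10))
            assert res.score <= 5  # number of tumors
            assert res.score <= res.n_outliers + 1e-12  # each contributes <= 1

    def test_tail_symmetry_under_negation(self, rng):
        values = rng.normal(0, 2, 18)
        labels = _labels(8, 10)
        p = OutlierParams(q_low=0.1, q_high=0.9, delta=0.3)
        res = outlier_score_gene(values, labels, p)
        res_neg = outlier_score_gene(-values, labels, p)
        assert res_neg.score_left == pytest.approx(res.score_right, abs=1e-12)
        assert res_neg.score_right == pytest.approx(res.score_left, abs=1e-12)

    def test_huge_delta_silences_everything(self, rng):
        values = rng.normal(0, 5, 20)
        res = outlier_score_gene(values, _labels(10, 10), OutlierParams(delta=1e9))
        assert res.score == 0.0

    def test_zero_delta_counts_every_quantile_exceedance(self):
        normals = np.arange(1.0, 11.0)          # q90 = 9.1
        values = np.concatenate([[9.2], normals])
        res = outlier_score_gene(values, _labels(1, 10), OutlierParams(delta=0.0))
        assert res.n_outliers == 1
        res2 = outlier_score_gene(values, _labels(1, 10), OutlierParams(delta=0.14))
        assert res2.n_outliers == 0             # 0.1 exceedance < delta

    def test_zero_score_iff_no_outliers(self, rng):
        for _ in range(30):
            values = rng.normal(0, 2, 12)
            res = outlier_score_gene(values, _labels(4, 8))
            assert (res.score == 0) == (res.n_outliers == 0)


class TestRankCandidates:
    @pytest.fixture()
    def expr(self, rng):
        genes = [f"G{i}" for i in range(30)]
        samples = [f"T{i}" for i in range(6)] + [f"N{i}" for i in range(8)]
        vals = pd.DataFrame(rng.normal(8, 0.4, (30, 14)), index=genes,
                            columns=samples)
        vals.iloc[0, :3] += 6.0   # strong up-outlier gene
        vals.iloc[1, :3] -= 6.0   # strong down-outlier gene
        cls = pd.Series(["tumor"] * 6 + ["normal"] * 8, index=samples)
        return ExpressionMatrix(vals, cls)

    def test_rowwise_consistency_with_single_gene_scorer(self, expr):
        df = rank_outlier_candidates(expr).set_index("gene_id")
        for gene in expr.gene_ids:
            res = outlier_score_gene(expr.values.loc[gene],
                                     expr.sample_class.to_numpy(), gene_id=gene)
            assert df.loc[gene, "score"] == pytest.approx(res.score, abs=1e-12)
            assert df.loc[gene, "direction"] == res.direction

    def test_sorted_descending_with_gene_id_tiebreak(self, expr):
        df = rank_outlier_candidates(expr)
        scores = df["score"].to_numpy()
        assert (np.diff(scores) <= 1e-12).all()
        assert df["rank"].tolist() == list(range(1, len(df) + 1))

    def test_planted_genes_lead_and_both_directions_kept(self, expr):
        df = rank_outlier_candidates(expr, OutlierParams(delta=1.0))
        assert set(df.head(2)["gene_id"]) == {"G0", "G1"}
        assert set(df.head(2)["direction"]) == {"up", "down"}

    def test_top_k_overrides_cutoff(self, expr):
        df = rank_outlier_candidates(expr, OutlierParams(top_k=5))
        assert int(df["selected"].sum()) == 5

    def test_single_class_matrix_rejected(self, rng):
        vals = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"),
                            columns=list("wxyz"))
        cls = pd.Series(["tumor"] * 4, index=list("wxyz"))
        with pytest.raises(ValueError, match="normal"):
            rank_outlier_candidates(ExpressionMatrix(vals, cls))

    def test_delta_sweep_counts_fall_as_delta_rises(self, expr):
        sweep = delta_sweep(expr, [0.0, 1.0, 3.0, 8.0])
        for _, grp in sweep.groupby("rank_norm"):
            counts = grp.sort_values("delta")["n_selected"].to_numpy()
            assert (np.diff(counts) <= 0).all()


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [{"q_low": 0.9, "q_high": 0.1},
                                        {"q_low": 0.0}, {"delta": -1.0}])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OutlierParams(**kwargs)
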