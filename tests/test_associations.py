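from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp, rankdata

from tsog import (
    bh_adjust,
    cnv_expression_cdf_gap,
    expression_by_cnv_bins,
    generate_cohort,
    normal_deviation_filter,
    per_gene_correlation,
    rank_sum_test,
    threshold_sweep,
    wilcoxon_cnv_screen,
)
from tsog.config import SimulationConfig, ThresholdConfig
from tests.conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_rank_sum_p(low, high):
    """Exact two-sided rank-sum p by full enumeration of group labelings."""
    pooled = np.concatenate([low, high])
    ranks = rankdata(pooled)
    n1 = len(low)
    def u_of(sel):
        return ranks[list(sel)].sum() - n1 * (n1 + 1) / 2
    u_obs = u_of(range(n1))
    us = np.array([u_of(sel) for sel in combinations(range(len(pooled)), n1)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def step_up_bh(p):
    """BH q-values straight from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_separated_groups_exact_p(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.10)  # 2 extreme labelings of C(6,3)=20

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            n1, n2 = rng.integers(2, 7, size=2)
            vals = rng.permutation(40)[: n1 + n2].astype(float)  # tie-free
            low, high = vals[:n1], vals[n1:]
            _, p = rank_sum_test(low, high)
            assert p == pytest.approx(enumerate_rank_sum_p(low, high), abs=1e-12)

    def test_large_groups_use_tie_corrected_approximation(self):
        rng = np.random.default_rng(8)
        low = np.round(rng.normal(size=30), 1)  # ties by rounding
        high = np.round(rng.normal(0.5, size=30), 1)
        _, p = rank_sum_test(low, high)
        assert 0 < p < 1


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_step_up_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), step_up_bh(p), atol=1e-12)


# ---------------------------------------------------------------------------
# CDF gap
# ---------------------------------------------------------------------------

class TestCdfGap:
    def test_identical_multisets_zero(self):
        assert cnv_expression_cdf_gap([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fully_separated_one(self):
        assert cnv_expression_cdf_gap([1, 2], [5, 6]) == 1.0

    def test_enumerated_step_functions(self):
        assert cnv_expression_cdf_gap([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            cnv_expression_cdf_gap([], [1.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    def test_equals_two_sample_ks_statistic(self, a, b):
        gap = cnv_expression_cdf_gap(np.array(a, float), np.array(b, float))
        assert gap == pytest.approx(ks_2samp(a, b).statistic)


# ---------------------------------------------------------------------------
# Pearson screens
# ---------------------------------------------------------------------------

class TestPerGeneCorrelation:
    def test_linear_relation_r_one(self):
        x = make_matrix([[1, 2, 3, 4]], modality="cnv")
        y = make_matrix([[3, 5, 7, 9]])
        t = per_gene_correlation(x, y, min_pairs=3)
        assert t["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelation_r_minus_one(self):
        x = make_matrix([[1, 2, 3]], modality="cnv")
        y = make_matrix([[-1, -2, -3]])
        assert per_gene_correlation(x, y)["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        x = make_matrix([[1, 2, 3]], modality="cnv")
        y = make_matrix([[1, 3, 2]])
        assert per_gene_correlation(x, y)["r"].iloc[0] == pytest.approx(0.5)

    def test_zero_variance_gives_missing_r(self):
        x = make_matrix([[1, 1, 1]], modality="cnv")
        y = make_matrix([[1, 2, 3]])
        assert np.isnan(per_gene_correlation(x, y)["r"].iloc[0])

    def test_too_few_pairs_untested(self):
        x = make_matrix([[1, 2, np.nan, np.nan]], modality="cnv")
        y = make_matrix([[1, 2, 3, 4]])
        t = per_gene_correlation(x, y, min_pairs=3)
        assert np.isnan(t["r"].iloc[0]) and t["n"].iloc[0] == 2

    def test_meth_expr_sign_convention(self):
        meth = make_matrix([[0.1, 0.5, 0.9]], modality="methylation")
        expr = make_matrix([[9.0, 7.0, 5.0]])  # repression
        t = per_gene_correlation(meth, expr, negate_x=True)
        assert t["r"].iloc[0] == pytest.approx(1.0)  # repressive scores positive
        assert t["sign_flipped"].iloc[0]


# ---------------------------------------------------------------------------
# CNV-stratified screen
# ---------------------------------------------------------------------------

def planted_screen_matrices(seed=21, n_genes=80, n_tumor=30):
    cfg = SimulationConfig(
        n_genes=n_genes, n_tumor=n_tumor, n_normal=4, n_chromosomes=4, seed=seed,
        planted_fractions={"oncogene_like": 0.10, "ts_like": 0.10},
    )
    c = generate_cohort(cfg)
    from tsog import assign_segments_to_genes

    cnv = assign_segments_to_genes(c.segments, c.annotation,
                                   sample_groups=c.sample_groups)
    return c, cnv


class TestWilcoxonScreen:
    def test_gate_skips_underpopulated_genes(self):
        c, cnv = planted_screen_matrices()
        thr = ThresholdConfig(high_screen_threshold=0.8, low_screen_threshold=-0.8)
        res = wilcoxon_cnv_screen(c.expression, cnv, thr)
        skipped = res[~res["tested"]]
        assert (skipped["skip_reason"] != "").all()
        assert np.isnan(skipped["p_value"]).all()

    def test_q_values_only_over_tested_family(self):
        c, cnv = planted_screen_matrices()
        # high cut at one gained copy, low cut at the platform-specific <0.0
        thr = ThresholdConfig(high_screen_threshold=0.5, low_screen_threshold=0.0,
                              min_sample_fraction=0.2)
        res = wilcoxon_cnv_screen(c.expression, cnv, thr)
        tested = res[res["tested"]]
        assert len(tested) > 0
        np.testing.assert_allclose(
            tested["q_value"].to_numpy(), step_up_bh(tested["p_value"].to_numpy()),
            atol=1e-12,
        )

    def test_screen_does_not_use_normal_samples(self):
        c, cnv = planted_screen_matrices()
        thr = ThresholdConfig(high_screen_threshold=0.5, low_screen_threshold=0.0)
        res_full = wilcoxon_cnv_screen(c.expression, cnv, thr)
        tumors = c.tumor_samples
        res_tumor = wilcoxon_cnv_screen(
            c.expression.subset_samples(tumors), cnv.subset_samples(tumors), thr
        )
        np.testing.assert_allclose(
            res_full["p_value"].to_numpy(), res_tumor["p_value"].to_numpy(),
            equal_nan=True,
        )

    def test_planted_dosage_genes_rank_ahead_of_nulls(self):
        c, cnv = planted_screen_matrices()
        thr = ThresholdConfig(high_screen_threshold=0.5, low_screen_threshold=0.0)
        res = wilcoxon_cnv_screen(c.expression, cnv, thr).set_index("gene_id")
        truth = c.truth.table.set_index("gene_id")["planted_class"]
        tested = res[res["tested"]]
        planted_p = tested.loc[
            tested.index.intersection(truth[truth != "null"].index), "p_value"
        ]
        assert len(planted_p) > 0
        assert planted_p.median() < 0.01


class TestThresholdSweep:
    def test_single_value_grid_matches_single_screen(self):
        c, cnv = planted_screen_matrices()
        thr = ThresholdConfig()
        sweep = threshold_sweep(c.expression, cnv, [0.5], low_fixed=0.0, config=thr)
        single = wilcoxon_cnv_screen(
            c.expression, cnv,
            ThresholdConfig(high_screen_threshold=0.5, low_screen_threshold=0.0),
        )
        assert sweep["tested"].iloc[0] == int(single["tested"].sum())
        assert sweep["significant"].iloc[0] == int((single["q_value"] < 0.05).sum())

    def test_tested_count_non_increasing_in_high_threshold(self):
        c, cnv = planted_screen_matrices()
        sweep = threshold_sweep(c.expression, cnv, [0.3, 0.5, 0.8, 1.2],
                                low_fixed=0.0)
        assert (np.diff(sweep["tested"]) <= 0).all()

    def test_empty_grid_rejected(self):
        c, cnv = planted_screen_matrices()
        with pytest.raises(ValueError):
            threshold_sweep(c.expression, cnv, [])


# ---------------------------------------------------------------------------
# binned means / normal-deviation filter
# ---------------------------------------------------------------------------

class TestExpressionBins:
    def test_single_bin_is_grand_mean(self):
        expr = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        cnv = make_matrix(np.zeros((2, 2)), modality="cnv")
        bins = expression_by_cnv_bins(expr, cnv, [-1, 1])
        assert bins["mean_expression"].iloc[0] == pytest.approx(2.5)

    def test_empty_bin_missing(self):
        expr = make_matrix([[1.0]])
        cnv = make_matrix([[0.5]], modality="cnv")
        bins = expression_by_cnv_bins(expr, cnv, [-1, 0, 1])
        assert np.isnan(bins["mean_expression"].iloc[0])
        assert bins["mean_expression"].iloc[1] == 1.0

    def test_unordered_edges_rejected(self):
        expr = make_matrix([[1.0]])
        cnv = make_matrix([[0.5]], modality="cnv")
        with pytest.raises(ValueError):
            expression_by_cnv_bins(expr, cnv, [1, 0])

    def test_dosage_cohort_bin_means_increase(self):
        c, cnv = planted_screen_matrices(seed=31)
        tumors = c.tumor_samples
        bins = expression_by_cnv_bins(
            c.expression.subset_samples(tumors), cnv.subset_samples(tumors),
            [-1.5, -0.5, 0.5, 1.5],
        )
        means = bins["mean_expression"].to_numpy()
        assert means[0] < means[1] < means[2]


class TestNormalDeviationFilter:
    def _matrices(self, tumor_expr, cnv_row, normal_expr):
        samples = [f"T{i}" for i in range(len(tumor_expr))] + ["N1", "N2"]
        groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
        expr = make_matrix([list(tumor_expr) + list(normal_expr)], samples=samples,
                           groups=groups)
        cnv = make_matrix([list(cnv_row) + [0.0, 0.0]], samples=samples,
                          modality="cnv", groups=groups)
        return expr, cnv

    def test_equal_means_not_retained(self):
        expr, cnv = self._matrices([5, 5, 5, 5, 5], [0.8] * 5, [5, 5])
        res = normal_deviation_filter(expr, cnv)
        assert not res["retained"].iloc[0]

    def test_three_sd_shift_retained(self):
        tumor = np.array([8.0, 8.1, 7.9, 8.05, 7.95])  # sd ~ 0.08, shift 3 from 5
        expr, cnv = self._matrices(tumor, [0.8] * 5, [5.0, 5.0])
        res = normal_deviation_filter(expr, cnv)
        assert res["retained"].iloc[0]

    def test_gate_requires_min_fraction_of_tumors(self):
        expr, cnv = self._matrices([9.0] * 10, [0.8] + [0.0] * 9, [5.0, 5.0])
        res = normal_deviation_filter(expr, cnv)  # 10% gated < 20%
        assert not res["passes_gate"].iloc[0] and not res["retained"].iloc[0]
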