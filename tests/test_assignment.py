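import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tsog import (
    GeneAnnotation,
    ProbeRecord,
    SegmentRecord,
    alteration_frequency,
    assign_methylation_to_genes,
    assign_segments_to_genes,
    calibrate_platform_threshold,
    classify_cnv_state,
    cnv_state_matrix,
    extract_breakpoints,
    methylation_tumor_normal_ranking,
    quantile_normalize,
    trim_near_zero,
)
from tsog.config import ThresholdConfig
from tests.conftest import make_matrix


def seg(sample, chrom, start, end, num_info=12, seg_mean=0.0):
    return SegmentRecord(sample, chrom, start, end, num_info, seg_mean)


def gene(gid, chrom, start, end, strand="+"):
    return GeneAnnotation(gid, chrom, start, end, strand)


class TestSegmentAssignment:
    def test_contained_gene_gets_seg_mean(self):
        m = assign_segments_to_genes(
            [seg("S1", "chr1", 0, 1000, 12, 0.45)], [gene("g1", "chr1", 100, 200)]
        )
        assert m.data.loc["g1", "S1"] == pytest.approx(0.45)

    def test_gene_split_across_segments_is_missing(self):
        segs = [seg("S1", "chr1", 0, 150, 12, 0.4), seg("S1", "chr1", 150, 1000, 12, 0.4)]
        m = assign_segments_to_genes(segs, [gene("g1", "chr1", 100, 200)])
        assert np.isnan(m.data.loc["g1", "S1"])

    def test_low_num_info_segment_is_missing(self):
        m = assign_segments_to_genes(
            [seg("S1", "chr1", 0, 1000, 3, 0.45)], [gene("g1", "chr1", 100, 200)]
        )
        assert np.isnan(m.data.loc["g1", "S1"])

    def test_uncovered_gene_is_missing(self):
        m = assign_segments_to_genes(
            [seg("S1", "chr1", 0, 50)], [gene("g1", "chr1", 100, 200)]
        )
        assert np.isnan(m.data.loc["g1", "S1"])

    def test_overlapping_segments_rejected(self):
        segs = [seg("S1", "chr1", 0, 500), seg("S1", "chr1", 400, 900)]
        with pytest.raises(ValueError, match="overlapping"):
            assign_segments_to_genes(segs, [gene("g1", "chr1", 100, 200)])

    def test_agrees_with_brute_force_scan(self):
        """Interval search matches an exhaustive per-gene scan over segments."""
        rng = np.random.default_rng(202)
        cfg = ThresholdConfig()
        for _ in range(100):
            n_seg = rng.integers(1, 8)
            bounds = np.sort(rng.choice(np.arange(1, 100), size=n_seg + 1, replace=False))
            segs = [
                seg("S1", "chr1", int(a), int(b), int(rng.integers(1, 10)),
                    float(rng.normal()))
                for a, b in zip(bounds, bounds[1:])
            ]
            genes = []
            for gi in range(rng.integers(1, 6)):
                a, b = np.sort(rng.choice(np.arange(0, 110), size=2, replace=False))
                genes.append(gene(f"g{gi}", "chr1", int(a), int(b)))
            m = assign_segments_to_genes(segs, genes, cfg)
            for g in genes:
                covering = [
                    s for s in segs if s.start <= g.start and s.end >= g.end
                    and s.num_info >= cfg.min_num_info
                ]
                expected = covering[0].seg_mean if len(covering) == 1 else np.nan
                got = m.data.loc[g.gene_id, "S1"]
                assert (np.isnan(expected) and np.isnan(got)) or got == expected


class TestTrimNearZero:
    def test_smallest_positive_masked(self):
        vals = np.arange(1, 21, dtype=float).reshape(4, 5)  # 20 positive cells
        m = trim_near_zero(make_matrix(vals, modality="cnv"), 0.05)
        assert int(m.data.isna().sum().sum()) == 1  # ceil(0.05*20) = 1
        assert np.isnan(m.data.iloc[0, 0])  # the minimum positive value

    def test_symmetric_for_negatives(self):
        vals = -np.arange(1, 21, dtype=float).reshape(4, 5)
        m = trim_near_zero(make_matrix(vals, modality="cnv"), 0.05)
        assert int(m.data.isna().sum().sum()) == 1
        assert np.isnan(m.data.iloc[0, 0])  # -1, smallest magnitude

    def test_trim_zero_is_identity(self):
        vals = np.random.default_rng(0).normal(size=(3, 4))
        m0 = make_matrix(vals, modality="cnv")
        m = trim_near_zero(m0, 0.0)
        pd.testing.assert_frame_equal(m.data, m0.data)

    def test_all_zero_matrix_unchanged(self):
        m = trim_near_zero(make_matrix(np.zeros((3, 3)), modality="cnv"), 0.1)
        assert (m.data.to_numpy() == 0).all()


class TestCnvState:
    @pytest.mark.parametrize(
        "value,state",
        [
            (0.68, "amplified"),   # amplified CCNE1-like mean
            (0.50, "amplified"),   # boundary is inclusive for amplification
            (-0.05, "deleted"),    # deleted CCNE1-like mean
            (0.00, "neutral"),     # deletion bound is strict
            (0.49, "neutral"),
        ],
    )
    def test_state_boundaries(self, value, state):
        assert classify_cnv_state(value) == state

    def test_missing_propagates(self):
        assert np.isnan(classify_cnv_state(np.nan))

    def test_states_partition_non_missing_cells(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.6, size=(30, 10))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        states = cnv_state_matrix(make_matrix(vals, modality="cnv"))
        finite = np.isfinite(vals)
        labels = states.to_numpy(dtype=object)[finite]
        assert all(s in ("amplified", "neutral", "deleted") for s in labels)
        assert states.isna().to_numpy().sum() == (~finite).sum()


class TestAlterationFrequency:
    def test_all_deleted(self):
        states = pd.DataFrame([["deleted"] * 10], index=["g1"])
        f = alteration_frequency(states)
        assert f.loc["g1", "deleted"] == 1.0

    def test_half_amplified_half_neutral(self):
        states = pd.DataFrame([["amplified"] * 5 + ["neutral"] * 5], index=["g1"])
        f = alteration_frequency(states)
        assert (f.loc["g1", "amplified"], f.loc["g1", "deleted"],
                f.loc["g1", "neutral"]) == (0.5, 0.0, 0.5)

    def test_missing_excluded_from_denominator(self):
        row = ["deleted", "deleted", "neutral", "neutral"] + [np.nan] * 6
        f = alteration_frequency(pd.DataFrame([row], index=["g1"]))
        assert f.loc["g1", "deleted"] == 0.5

    def test_all_missing_gene_reports_missing(self):
        f = alteration_frequency(pd.DataFrame([[np.nan] * 4], index=["g1"]))
        assert f.loc["g1"].isna().all()


class TestBreakpoints:
    def test_gain_to_loss_boundary(self):
        segs = [seg("S1", "chr1", 0, 1000, 12, 0.3),
                seg("S1", "chr1", 1000, 2000, 12, -0.2)]
        bp = extract_breakpoints(segs)
        assert len(bp) == 1
        assert bp.iloc[0]["position"] == 1000 and bp.iloc[0]["direction"] == "loss"

    def test_single_segment_no_breakpoints(self):
        assert extract_breakpoints([seg("S1", "chr1", 0, 1000, 12, 0.8)]).empty

    def test_two_neutral_segments_no_breakpoint(self):
        segs = [seg("S1", "chr1", 0, 1000, 12, 0.0),
                seg("S1", "chr1", 1000, 2000, 12, 0.1)]
        assert extract_breakpoints(segs).empty

    def test_exit_from_amplified_into_neutral_is_gain(self):
        segs = [seg("S1", "chr1", 0, 1000, 12, 0.9),
                seg("S1", "chr1", 1000, 2000, 12, 0.1)]
        bp = extract_breakpoints(segs)
        assert bp.iloc[0]["direction"] == "gain"


class TestCalibration:
    def test_identity_platform_recovers_reference(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.5, size=(60, 7))
        a = make_matrix(vals, modality="cnv")
        ref = ThresholdConfig(del_threshold=-0.50)
        res = calibrate_platform_threshold(a, a, a.samples, ref,
                                           grid=np.round(np.arange(-1, 0.001, 0.05), 2))
        assert res.threshold == pytest.approx(-0.50)
        assert res.sensitivity == 1.0 and res.fpr == 0.0

    def test_half_scale_platform_recovers_half_threshold(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 0.5, size=(200, 7))
        a = make_matrix(vals, modality="cnv")
        b = make_matrix(vals * 0.5, modality="cnv")
        ref = ThresholdConfig(del_threshold=-0.50)
        res = calibrate_platform_threshold(a, b, a.samples, ref,
                                           grid=np.round(np.arange(-1, 0.001, 0.05), 2))
        assert res.threshold == pytest.approx(-0.25)

    def test_no_shared_samples_errors(self):
        a = make_matrix(np.zeros((2, 2)), modality="cnv")
        with pytest.raises(ValueError, match="shared"):
            calibrate_platform_threshold(a, a, [])


class TestQuantileNormalize:
    def test_two_column_example(self):
        m = quantile_normalize(make_matrix([[1, 4], [2, 5], [3, 6]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(m.data.to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        vals = np.array([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        m = quantile_normalize(make_matrix(vals))
        np.testing.assert_allclose(m.data.to_numpy(), vals)

    def test_ties_get_mean_of_reference_values(self):
        # column 2 has a tie at ranks 1-2; reference = mean of sorted columns
        m = quantile_normalize(make_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 9.0]]))
        ref = np.array([3.0, 3.5, 6.0])  # mean of sorted cols [1,2,3] & [5,5,9]
        np.testing.assert_allclose(m.data["s1"].to_numpy(), ref)
        np.testing.assert_allclose(
            m.data["s2"].to_numpy(), [ref[:2].mean(), ref[:2].mean(), ref[2]]
        )

    def test_columns_share_sorted_values_and_preserve_ranks(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(50, 6)) * rng.gamma(2, size=6)  # no ties a.s.
        m = quantile_normalize(make_matrix(vals))
        out = m.data.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=0, atol=1e-12)
            rho = spearmanr(vals[:, j], out[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_missing_cells_stay_missing(self):
        vals = np.array([[1.0, 4.0], [np.nan, 5.0], [3.0, 6.0], [2.0, 7.0]])
        m = quantile_normalize(make_matrix(vals))
        assert np.isnan(m.data.iloc[1, 0])
        assert m.data.iloc[:, 1].notna().all()

    def test_underpopulated_column_errors(self):
        vals = np.array([[1.0, 4.0], [np.nan, 5.0], [np.nan, 6.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            quantile_normalize(make_matrix(vals))


def probe(pid, fid, chrom, start, end, values):
    return ProbeRecord(pid, fid, chrom, start, end, tuple(values.items()))


class TestMethylationAssignment:
    def test_moma_fragment_takes_max_probe(self):
        probes = [
            probe("p1", "f1", "chr1", 100, 150, {"S1": 0.8}),
            probe("p2", "f1", "chr1", 150, 200, {"S1": 1.2}),
        ]
        genes = [gene("g1", "chr1", 300, 800)]
        m = assign_methylation_to_genes(probes, genes, "moma_ratio")
        assert m.data.loc["g1", "S1"] == pytest.approx(1.2)

    def test_moma_gene_takes_max_fragment_and_closest_tss(self):
        probes = [
            probe("p1", "f1", "chr1", 100, 200, {"S1": 0.9}),
            probe("p2", "f2", "chr1", 250, 350, {"S1": 1.1}),
            # far fragment, nearer g2's TSS (g2 is on '-' so TSS = end = 5000)
            probe("p3", "f3", "chr1", 4800, 4900, {"S1": 2.0}),
        ]
        genes = [gene("g1", "chr1", 400, 900, "+"), gene("g2", "chr1", 4000, 5000, "-")]
        m = assign_methylation_to_genes(probes, genes, "moma_ratio")
        assert m.data.loc["g1", "S1"] == pytest.approx(1.1)  # max of f1, f2
        assert m.data.loc["g2", "S1"] == pytest.approx(2.0)

    def test_beta_mean_of_two_probes(self):
        probes = [
            probe("p1", "p1", "chr1", 100, 102, {"S1": 0.2}),
            probe("p2", "p2", "chr1", 110, 112, {"S1": 0.4}),
        ]
        m = assign_methylation_to_genes(probes, [gene("g1", "chr1", 100, 500)], "beta")
        assert m.data.loc["g1", "S1"] == pytest.approx(0.3)

    def test_beta_single_probe_gene_is_missing(self):
        probes = [probe("p1", "p1", "chr1", 100, 102, {"S1": 0.2})]
        m = assign_methylation_to_genes(probes, [gene("g1", "chr1", 100, 500)], "beta")
        assert np.isnan(m.data.loc["g1", "S1"])

    def test_all_nan_fragment_warns_and_skips(self):
        probes = [probe("p1", "f1", "chr1", 100, 102, {"S1": np.nan})]
        with pytest.warns(UserWarning, match="no observed probe"):
            m = assign_methylation_to_genes(probes, [gene("g1", "chr1", 100, 500)],
                                            "moma_ratio")
        assert np.isnan(m.data.loc["g1", "S1"])


class TestMethylationRanking:
    def test_ratio_semantics(self):
        groups = {"T1": "tumor", "T2": "tumor", "N1": "normal"}
        vals = np.array([[1.56, 1.56, 1.0]])
        m = make_matrix(vals, samples=["T1", "T2", "N1"], modality="methylation",
                        groups=groups)
        table = methylation_tumor_normal_ranking(m, 0.5)
        assert table["ratio"].iloc[0] == pytest.approx(1.56)  # 56% increase

    def test_equal_means_no_flag(self):
        groups = {"T1": "tumor", "N1": "normal"}
        m = make_matrix(np.ones((1, 2)), samples=["T1", "N1"],
                        modality="methylation", groups=groups)
        table = methylation_tumor_normal_ranking(m, 0.0)
        assert table["flag"].iloc[0] == ""

    def test_tail_counts_are_order_statistics(self):
        rng = np.random.default_rng(5)
        groups = {"T1": "tumor", "T2": "tumor", "N1": "normal"}
        vals = np.column_stack([rng.uniform(0.5, 1.5, 100),
                                rng.uniform(0.5, 1.5, 100),
                                np.ones(100)])
        m = make_matrix(vals, samples=["T1", "T2", "N1"], modality="methylation",
                        groups=groups)
        table = methylation_tumor_normal_ranking(m, 0.10)
        assert (table["flag"] == "hypermethylated").sum() == 10
        assert (table["flag"] == "hypomethylated").sum() == 10
        hyper = table[table["flag"] == "hypermethylated"]["ratio"]
        rest = table[table["flag"] == ""]["ratio"]
        assert hyper.min() >= rest.max()

    def test_zero_normal_mean_skipped_with_warning(self):
        groups = {"T1": "tumor", "N1": "normal"}
        vals = np.array([[1.0, 0.0], [1.2, 1.0]])
        m = make_matrix(vals, samples=["T1", "N1"], modality="methylation",
                        groups=groups)
        with pytest.warns(UserWarning, match="skipped"):
            table = methylation_tumor_normal_ranking(m, 0.0)
        assert list(table["gene_id"]) == ["g2"]
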