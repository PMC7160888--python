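"""Windowed depth scan: windowing, normalization, t-tests, M-values, calls."""

import numpy as np
import pytest
from scipy import stats

from depthdiff import cnv
from depthdiff.core import DepthTrack, GenomicInterval

from conftest import make_window_table


class TestWindowDepth:
    def test_uniform_depth(self):
        tracks = {"a": DepthTrack("c", np.full(5000, 10.0))}
        wt = cnv.window_depth(tracks, 1000)
        np.testing.assert_allclose(wt.depth[0], 10.0)
        assert wt.n_windows == 5

    def test_gap_window_zero(self):
        d = np.full(3000, 8.0)
        d[1000:2000] = 0.0
        wt = cnv.window_depth({"a": DepthTrack("c", d)}, 1000)
        assert wt.depth[0, 1] == 0.0

    def test_linear_ramp_closed_form(self):
        wt = cnv.window_depth({"a": DepthTrack("c", np.arange(1000.0))}, 1000)
        assert wt.depth[0, 0] == pytest.approx(499.5)

    def test_terminal_partial_window_flagged(self):
        wt = cnv.window_depth({"a": DepthTrack("c", np.ones(2500))}, 1000)
        assert wt.terminal_partial
        assert wt.ends[-1] == 2500 and wt.starts[-1] == 2001

    def test_q0_fraction_from_mask(self):
        wt = cnv.window_depth(
            {"a": DepthTrack("c", np.ones(2000))},
            1000,
            q0_intervals=[GenomicInterval("c", 1, 500)],
        )
        assert wt.q0_fraction[0] == pytest.approx(0.5)
        assert wt.q0_fraction[1] == 0.0

    def test_empty_tracks_rejected(self):
        with pytest.raises(ValueError):
            cnv.window_depth({}, 1000)


class TestNormalize:
    def test_reference_sample_unchanged(self, rng):
        wt = make_window_table(np.vstack([np.full(10, 8.0), rng.uniform(2, 4, 10)]))
        cnv.normalize_windows(wt)
        np.testing.assert_allclose(wt.normalized_depth[0], wt.depth[0])

    def test_half_coverage_sample_doubled(self):
        wt = make_window_table(np.vstack([np.full(10, 8.0), np.full(10, 4.0)]))
        cnv.normalize_windows(wt)
        np.testing.assert_allclose(wt.normalized_depth[1], 8.0)

    def test_normalized_means_equal(self, rng):
        wt = make_window_table(rng.uniform(2, 12, size=(4, 50)))
        cnv.normalize_windows(wt)
        means = wt.normalized_depth.mean(axis=1)
        np.testing.assert_allclose(means, means[0])

    def test_profile_shape_preserved(self, rng):
        wt = make_window_table(rng.uniform(2, 12, size=(3, 20)))
        cnv.normalize_windows(wt)
        for i in range(3):
            ratios = wt.normalized_depth[i] / wt.depth[i]
            np.testing.assert_allclose(ratios, ratios[0])

    def test_zero_mean_sample_rejected(self):
        wt = make_window_table(np.vstack([np.full(5, 8.0), np.zeros(5)]))
        with pytest.raises(ValueError):
            cnv.normalize_windows(wt)


class TestExcludeWindows:
    def test_all_low_window_excluded(self):
        depth = np.full((3, 4), 10.0)
        depth[:, 2] = 0.5
        wt = make_window_table(depth)
        mask = cnv.exclude_windows(wt, 2.0)
        assert mask.tolist() == [False, False, True, False]

    def test_single_covered_sample_retains_window(self):
        depth = np.full((3, 2), 1.0)
        depth[0, 1] = 5.0
        wt = make_window_table(depth)
        mask = cnv.exclude_windows(wt, 2.0)
        assert mask.tolist() == [True, False]


class TestWindowGroupTest:
    def test_null_window_matches_welch_oracle(self, rng):
        depth = rng.normal(10, 1, size=(8, 6))
        wt = make_window_table(depth, samples=[f"s{i}" for i in range(8)])
        scan = cnv.window_group_test(wt, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        oracle = stats.ttest_ind(depth[:4], depth[4:], axis=0, equal_var=False).pvalue
        np.testing.assert_allclose(scan.table["p"].to_numpy(), oracle)

    def test_bonferroni_denominator_excludes_masked_windows(self):
        depth = np.full((4, 10), 10.0)
        depth[:, 0] = 0.1
        wt = make_window_table(depth)
        cnv.exclude_windows(wt, 2.0)
        scan = cnv.window_group_test(wt, ["s000", "s001"], ["s002", "s003"])
        assert scan.n_tested == 9
        assert scan.bonferroni_threshold == pytest.approx(0.05 / 9)

    def test_published_threshold_arithmetic(self):
        assert float(f"{cnv.bonferroni_threshold(74_216 - 634):.1e}") == 6.8e-07

    def test_deletion_windows_form_significant_run(self, rng):
        n_win = 60
        depth = rng.normal(6.8, 0.15, size=(20, n_win))
        depth[10:, 28:33] *= 0.5  # control het deletion, windows 28..32
        wt = make_window_table(depth, samples=[f"s{i:02d}" for i in range(20)])
        scan = cnv.window_group_test(wt, [f"s{i:02d}" for i in range(10)],
                                     [f"s{i:02d}" for i in range(10, 20)])
        assert (28, 32) in scan.significant_runs

    def test_small_group_rejected(self):
        wt = make_window_table(np.ones((3, 5)))
        with pytest.raises(ValueError):
            cnv.window_group_test(wt, ["s000"], ["s001", "s002"])


class TestMValues:
    def test_signature_values(self):
        depth = np.array([[8.0, 8.0], [8.0, 4.0], [8.0, 16.0]])
        wt = make_window_table(depth)
        mv = cnv.m_values(wt, ["s000"])  # case group = first sample
        assert mv.iloc[1, 0] == pytest.approx(0.0)
        assert mv.iloc[1, 1] == pytest.approx(-1.0)  # half the case mean
        assert mv.iloc[2, 1] == pytest.approx(1.0)  # double the case mean

    def test_case_mean_profile_has_zero_m(self, rng):
        depth = rng.uniform(4, 12, size=(6, 10))
        wt = make_window_table(depth)
        cases = [f"s{i:03d}" for i in range(3)]
        mv = cnv.m_values(wt, cases)
        case_mean = depth[:3].mean(axis=0)
        np.testing.assert_allclose(np.log2(case_mean / mv.attrs["case_group_mean"]), 0.0)
        # Jensen: log2 of the mean >= mean of logs over the case group
        assert (np.log2(mv.attrs["case_group_mean"]) >= mv.iloc[:3].mean(axis=0) - 1e-12).all()

    def test_zero_depth_flagged_undefined(self):
        depth = np.array([[4.0, 4.0], [0.0, 4.0]])
        wt = make_window_table(depth)
        mv = cnv.m_values(wt, ["s000"])
        assert not mv.attrs["defined"][1, 0]


class TestCaller:
    def test_flat_profile_yields_no_calls(self, rng):
        wt = make_window_table(rng.normal(46, 0.5, size=(1, 200)))
        assert cnv.call_cnvs(wt, "s000") == []

    def test_embedded_het_deletion_recovered(self, rng):
        depth = rng.normal(46, 1.0, size=(1, 200))
        depth[0, 100:104] *= 0.5  # 4-kb region at half coverage
        wt = make_window_table(depth)
        calls = cnv.call_cnvs(wt, "s000")
        dels = [c for c in calls if c.kind == "deletion"]
        assert len(dels) == 1
        truth = GenomicInterval("chr1", 100_001, 104_000)
        ovl = dels[0].interval.overlap_bp(truth)
        assert ovl / truth.span >= 0.75
        assert ovl / dels[0].interval.span >= 0.75

    def test_homozygous_deletion_near_zero_rd(self, rng):
        depth = rng.normal(46, 1.0, size=(1, 200))
        depth[0, 50:58] = rng.normal(0.0, 0.05, 8).clip(min=0)
        wt = make_window_table(depth)
        dels = [c for c in cnv.call_cnvs(wt, "s000") if c.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].normalized_rd < 0.05

    def test_duplication_direction(self, rng):
        depth = rng.normal(30, 0.5, size=(1, 100))
        depth[0, 40:45] *= 1.6
        calls = cnv.call_cnvs(make_window_table(depth), "s000")
        assert any(c.kind == "duplication" for c in calls)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            cnv.call_cnvs(make_window_table(np.ones((1, 1))), "s000")


class TestFilterCalls:
    def _call(self, **kw):
        base = dict(
            sample="s",
            interval=GenomicInterval("c", 10_001, 18_000),
            kind="deletion",
            normalized_rd=0.5,
            p_mean_diff=1e-5,
            q0=0.0,
        )
        base.update(kw)
        from depthdiff.core import CNVCall

        return CNVCall(**base)

    def test_passing_call_kept(self):
        kept, report = cnv.filter_calls([self._call()], gaps=[])
        assert len(kept) == 1 and report.empty

    @pytest.mark.parametrize(
        "kw,gaps,reason",
        [
            (dict(q0=0.1), [], "q0"),
            (dict(interval=GenomicInterval("c", 1, 900)), [], "length"),
            (dict(p_mean_diff=0.01), [], "p_value"),
            (dict(), [GenomicInterval("c", 18_000, 19_000)], "gap"),  # 1-bp overlap
        ],
    )
    def test_removal_reasons(self, kw, gaps, reason):
        kept, report = cnv.filter_calls([self._call(**kw)], gaps=gaps)
        assert kept == []
        assert report.iloc[0]["reason"] == reason

    def test_exactly_1000bp_call_removed(self):
        call = self._call(interval=GenomicInterval("c", 1, 1000))
        kept, report = cnv.filter_calls([call], gaps=[])
        assert kept == [] and report.iloc[0]["reason"] == "length"


def test_gc_correction_flattens_gc_trend(rng):
    gc = rng.uniform(30, 60, 500)
    depth = 20 + (gc - 45) * 0.4 + rng.normal(0, 0.3, 500)
    corrected = cnv.gc_correct(depth, gc)
    slope_before = np.polyfit(gc, depth, 1)[0]
    slope_after = np.polyfit(gc, corrected, 1)[0]
    assert abs(slope_after) < abs(slope_before) / 5
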