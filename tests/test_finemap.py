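"""Fine-mapping filters: pruning, monomorphic screen, imputation QC, merge."""

import numpy as np
import pandas as pd
import pytest

from depthdiff.finemap import (
    assay_success_rate,
    filter_imputed,
    merge_genotype_sets,
    monomorphic_filter,
    prune_identical,
    rank_by_tracks,
)
from depthdiff.core import GenomicInterval

from conftest import make_genotypes


def trio_fixture(n_total=18_470, n_identical=5_264, seed=0):
    """Three-sample genotype series with a known identical subset."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"v{i:05d}" for i in range(n_total)])
    case1 = pd.Series(rng.integers(0, 3, n_total), index=idx)
    case2 = case1.copy()
    control = case1.copy()
    # make the tail discordant: the control differs there
    diff = idx[n_identical:]
    control.loc[diff] = (case1.loc[diff] + 1) % 3
    return case1, case2, control


class TestPruneIdentical:
    def test_reproduces_fixture_bookkeeping(self):
        case1, case2, control = trio_fixture()
        retained, report = prune_identical(case1, case2, control)
        assert len(retained) == 13_206
        assert (report["outcome"] == "pruned_identical").sum() == 5_264

    def test_all_identical_prunes_everything(self):
        s = pd.Series([0, 1, 2, 1])
        retained, _ = prune_identical(s, s.copy(), s.copy())
        assert len(retained) == 0

    def test_all_discordant_keeps_everything(self):
        a = pd.Series([0, 1, 2])
        retained, _ = prune_identical(a, a.copy(), (a + 1) % 3)
        assert len(retained) == 3

    def test_missing_genotype_retained_with_flag(self):
        a = pd.Series([0.0, 1.0])
        c = pd.Series([0.0, np.nan])
        retained, report = prune_identical(a, a.copy(), c)
        assert list(retained) == [1]
        assert report.loc[1, "outcome"] == "kept_missing"


class TestMonomorphicFilter:
    def test_reproduces_fixture_bookkeeping(self, rng):
        dos = rng.binomial(2, 0.3, size=(50, 707)).astype(float)
        mono = rng.choice(707, size=69, replace=False)
        dos[:, mono] = 2.0
        G = make_genotypes(dos)
        kept, removed = monomorphic_filter(G, 0.001)
        assert kept.n_markers == 638
        assert len(removed) == 69

    def test_zero_threshold_keeps_all(self, rng):
        G = make_genotypes(np.zeros((5, 10)))
        kept, _ = monomorphic_filter(G, 0.0)
        assert kept.n_markers == 10

    def test_all_monomorphic_empties_matrix(self):
        G = make_genotypes(np.zeros((5, 4)))
        kept, removed = monomorphic_filter(G, 0.001)
        assert kept.n_markers == 0 and len(removed) == 4


def imputed_fixture(n_total=7_293, n_pass=4_876, seed=1):
    """Long-format imputed calls arranged so exactly n_pass survive."""
    rng = np.random.default_rng(seed)
    n_markers = 11
    per = int(np.ceil(n_total / n_markers))
    rows = []
    k = 0
    for j in range(n_markers):
        # first markers fail the R^2 screen outright
        r2 = 0.5 if j < 2 else 0.95
        for i in range(per):
            if k >= n_total:
                break
            rows.append((f"v{j}", f"s{i}", int(rng.integers(0, 3)), r2, 1.0))
            k += 1
    df = pd.DataFrame(
        rows, columns=["marker", "sample", "dosage", "allelic_r2", "genotype_probability"]
    )
    good = df.index[df["allelic_r2"] >= 0.75]
    n_drop = len(good) - n_pass
    df.loc[good[:n_drop], "genotype_probability"] = 0.5
    return df


class TestFilterImputed:
    def test_clean_input_fully_retained(self):
        df = pd.DataFrame(
            {
                "marker": ["a", "a"],
                "sample": ["s1", "s2"],
                "dosage": [0, 1],
                "allelic_r2": [1.0, 1.0],
                "genotype_probability": [1.0, 1.0],
            }
        )
        assert filter_imputed(df).retention_fraction == 1.0

    def test_low_r2_marker_dropped_regardless_of_probability(self):
        df = pd.DataFrame(
            {
                "marker": ["a", "a", "b"],
                "sample": ["s1", "s2", "s1"],
                "dosage": [0, 1, 2],
                "allelic_r2": [0.5, 0.5, 0.9],
                "genotype_probability": [1.0, 1.0, 1.0],
            }
        )
        res = filter_imputed(df)
        assert set(res.genotypes["marker"]) == {"b"}

    def test_reproduces_reported_retention(self):
        df = imputed_fixture()
        res = filter_imputed(df)
        assert res.n_total == 7_293
        assert res.n_retained == 4_876
        assert round(100 * res.retention_fraction) == 67

    def test_step_order_matters(self):
        # a genotype that fails step 2 on a marker that fails step 1 must be
        # counted once (dropped at step 1), not rescued or double-dropped
        df = pd.DataFrame(
            {
                "marker": ["a", "b"],
                "sample": ["s1", "s1"],
                "dosage": [1, 1],
                "allelic_r2": [0.5, 0.9],
                "genotype_probability": [0.5, 0.9],
            }
        )
        res = filter_imputed(df)
        assert res.n_retained == 1
        reverse = df[df["genotype_probability"] >= 0.8]
        reverse = reverse[reverse["allelic_r2"] >= 0.75]
        assert len(reverse) == res.n_retained  # same here...
        df2 = df.copy()
        df2.loc[0, "genotype_probability"] = 0.9
        # ...but the counts reported per step differ when step-1 markers
        # carry passing probabilities; total retention stays step-order-fixed
        assert filter_imputed(df2).n_retained == 1

    def test_never_increases_genotype_count(self, rng):
        df = imputed_fixture(n_total=500, n_pass=300, seed=3)
        assert filter_imputed(df).n_retained <= len(df)


class TestAssaySuccess:
    def test_reported_success_rate(self):
        assert round(100 * assay_success_rate(740, 33), 1) == 95.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            assay_success_rate(0, 0)


class TestMerge:
    def _pair(self, rng, pos_p=(100, 200), pos_s=(300, 400)):
        n = 20
        Gp = make_genotypes(
            rng.binomial(2, 0.4, size=(n, len(pos_p))).astype(float), positions=list(pos_p)
        )
        Gs = make_genotypes(
            rng.binomial(2, 0.4, size=(n, len(pos_s))).astype(float), positions=list(pos_s)
        )
        Gs.marker_map.index = pd.Index([f"x{j}" for j in range(len(pos_s))], name="marker")
        return Gp, Gs

    def test_disjoint_sets_simple_union(self, rng):
        Gp, Gs = self._pair(rng)
        merged, report = merge_genotype_sets(Gp, Gs)
        assert merged.n_markers == 4
        assert report.empty
        assert list(merged.marker_map["pos"]) == sorted(merged.marker_map["pos"])

    def test_duplicate_keeps_higher_call_rate(self, rng):
        Gp, Gs = self._pair(rng, pos_p=(100, 200), pos_s=(200, 400))
        Gp.dosage[:5, 1] = np.nan  # primary copy of pos 200: call rate 0.75
        merged, report = merge_genotype_sets(Gp, Gs)
        assert merged.n_markers == 3
        assert "x0" in merged.markers  # secondary copy won
        assert (report["action"] == "replaced_primary").any()

    def test_duplicate_tie_keeps_primary(self, rng):
        Gp, Gs = self._pair(rng, pos_p=(100, 200), pos_s=(200, 400))
        merged, report = merge_genotype_sets(Gp, Gs)
        assert "x0" not in merged.markers
        assert report.iloc[0]["reason"].startswith("duplicate_lower_call_rate")

    def test_swapped_alleles_flip_dosage(self, rng):
        Gp, Gs = self._pair(rng, pos_p=(100, 200), pos_s=(200, 400))
        Gs.marker_map.loc["x0", ["ref", "alt"]] = ["G", "A"]  # swapped
        Gp.dosage[:, 1] = np.nan  # force secondary to win
        merged, _ = merge_genotype_sets(Gp, Gs)
        j = merged.markers.index("x0")
        np.testing.assert_array_equal(merged.dosage[:, j], 2.0 - Gs.dosage[:, 0])

    def test_incompatible_alleles_dropped_and_reported(self, rng):
        Gp, Gs = self._pair(rng, pos_p=(100, 200), pos_s=(200, 400))
        Gs.marker_map.loc["x0", ["ref", "alt"]] = ["C", "T"]
        merged, report = merge_genotype_sets(Gp, Gs)
        assert "x0" not in merged.markers
        assert (report["reason"] == "incompatible_alleles").any()


def test_rank_by_tracks_orders_by_overlap_count():
    mm = pd.DataFrame(
        {"chrom": ["c", "c"], "pos": [100, 900]},
        index=pd.Index(["a", "b"], name="marker"),
    )
    tracks = {
        "conserved": [GenomicInterval("c", 50, 150)],
        "promoter": [GenomicInterval("c", 90, 110)],
    }
    ranked = rank_by_tracks(mm, tracks)
    assert ranked.index[0] == "a"
    assert ranked.loc["a", "n_categories"] == 2
    assert ranked.loc["b", "n_categories"] == 0
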