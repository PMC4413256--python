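"""Quantification: site levels, efficiencies, windows, GBM classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methclime import quant
from methclime.datatypes import AnnotationSet

from conftest import make_counts


def _sites(n, chrom="Chr1", context="CG", spacing=10):
    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(n) * spacing + 1,
        "strand": "+",
        "context": context,
    })


class TestSiteLevels:
    def test_basic_fraction_and_missing(self):
        c = make_counts(_sites(3), np.array([3, 0, 2]), np.array([10, 0, 4]))
        lv = quant.site_levels(c, min_coverage=1)
        assert lv[0, 0] == pytest.approx(0.3)
        assert np.isnan(lv[1, 0])
        lv5 = quant.site_levels(c, min_coverage=5)
        assert np.isnan(lv5[2, 0])

    def test_meth_exceeding_total_rejected(self):
        c = make_counts(_sites(1), np.array([5]), np.array([4]))
        with pytest.raises(ValueError, match="meth > total"):
            quant.site_levels(c)


class TestConversionEfficiency:
    def test_paper_scale_arithmetic(self):
        """41 methylated of 10000 chloroplast reads -> 0.9959."""
        c = make_counts(_sites(2, chrom="ChrC"),
                        np.array([40, 1]), np.array([9000, 1000]))
        assert quant.conversion_efficiency(c)[0] == pytest.approx(0.9959)

    def test_extremes(self):
        all_un = make_counts(_sites(2, chrom="ChrC"),
                             np.array([0, 0]), np.array([50, 50]))
        assert quant.conversion_efficiency(all_un)[0] == 1.0
        all_m = make_counts(_sites(2, chrom="ChrC"),
                            np.array([50, 50]), np.array([50, 50]))
        assert quant.conversion_efficiency(all_m)[0] == 0.0

    def test_missing_chloroplast_is_error(self):
        c = make_counts(_sites(2), np.array([0, 0]), np.array([5, 5]))
        with pytest.raises(ValueError, match="chloroplast"):
            quant.conversion_efficiency(c)


class TestContextAverages:
    def test_constant_sites(self):
        c = make_counts(_sites(4), np.array([5] * 4), np.array([10] * 4))
        out = quant.context_averages(c, contexts=("CG",))
        assert out["level"].iloc[0] == pytest.approx(0.5)

    def test_duplicated_accession_identical(self):
        m = np.array([[3, 3], [7, 7], [1, 1]])
        t = np.array([[10, 10], [10, 10], [10, 10]])
        c = make_counts(_sites(3), m, t)
        out = quant.context_averages(c, contexts=("CG",))
        assert out["level"].iloc[0] == out["level"].iloc[1]

    def test_absent_context_missing_with_warning(self):
        c = make_counts(_sites(2, context="CG"),
                        np.array([1, 1]), np.array([2, 2]))
        with pytest.warns(UserWarning, match="absent"):
            out = quant.context_averages(c, contexts=("CHH",))
        assert out["level"].isna().all()


class TestFeatureAverage:
    def _annot(self, rows):
        feats = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "kind", "family",
                           "superfamily", "variable", "id"])
        return AnnotationSet(feats, {"Chr1": 10_000})

    def test_count_weighted_not_mean_of_levels(self):
        """Two sites 1/10 and 9/10 average to 10/20 = 0.5."""
        c = make_counts(_sites(2), np.array([1, 9]), np.array([10, 10]))
        annot = self._annot([("Chr1", 1, 100, "gene", "", "", False, "g1")])
        out = quant.feature_average(c, annot, kind="gene")
        assert out.iloc[0, 0] == pytest.approx(0.5)

    def test_single_site_feature(self):
        c = make_counts(_sites(2), np.array([3, 9]), np.array([10, 10]))
        annot = self._annot([("Chr1", 1, 5, "gene", "", "", False, "g1")])
        out = quant.feature_average(c, annot)
        assert out.iloc[0, 0] == pytest.approx(0.3)

    def test_length_filter_row_count(self):
        c = make_counts(_sites(5), np.arange(5), np.full(5, 10))
        annot = self._annot([
            ("Chr1", 1, 2500, "te", "F", "S", False, "t1"),
            ("Chr1", 3000, 4000, "te", "F", "S", False, "t2"),
            ("Chr1", 5000, 7500, "te", "F", "S", False, "t3"),
        ])
        out = quant.feature_average(c, annot, kind="te", min_length=2000)
        assert list(out.index) == ["t1", "t3"]

    def test_out_of_bounds_feature_rejected(self):
        c = make_counts(_sites(2), np.array([1, 1]), np.array([2, 2]))
        annot = self._annot([("Chr1", 1, 99_999, "gene", "", "", False, "g")])
        with pytest.raises(ValueError, match="bounds"):
            quant.feature_average(c, annot)


class TestSlidingWindows:
    def test_window_count_on_1kb_chromosome(self):
        """Length 1000, size 200, step 100 -> exactly 9 full windows."""
        sites = _sites(100, context="CHH")
        sites["pos"] = np.linspace(1, 1000, 100).astype(int)
        c = make_counts(sites, np.ones(100, int), np.full(100, 2))
        wm = quant.sliding_windows(c, size=200, step=100, context="CHH",
                                   exclude_chrom=None)
        assert wm.n_windows == 9
        assert wm.windows["start"].tolist() == list(range(1, 802, 100))

    def test_site_counted_in_two_windows(self):
        sites = _sites(1, context="CHH")
        sites["pos"] = [250]
        c = make_counts(sites, np.array([4]), np.array([10]))
        # chromosome length must come from site table; add a far site
        sites2 = pd.concat([sites, _sites(1, context="CHH").assign(pos=600)],
                           ignore_index=True)
        c = make_counts(sites2, np.array([4, 0]), np.array([10, 0]))
        wm = quant.sliding_windows(c, size=200, step=100, context="CHH",
                                   exclude_chrom=None)
        covered = wm.windows[(wm.windows["start"] <= 250)
                             & (wm.windows["end"] >= 250)]
        vals = wm.level[covered.index.to_numpy(), 0]
        assert np.allclose(vals, 0.4)
        assert len(vals) == 2

    def test_uncovered_windows_missing(self):
        sites = _sites(2, context="CHH")
        sites["pos"] = [50, 950]
        c = make_counts(sites, np.array([0, 0]), np.array([0, 0]))
        wm = quant.sliding_windows(c, size=200, step=100, context="CHH",
                                   exclude_chrom=None)
        assert np.isnan(wm.level).all()

    def test_invalid_size_rejected(self, small_sim):
        with pytest.raises(ValueError):
            quant.sliding_windows(small_sim["methylomes"], size=0)


class TestSelectVariableWindows:
    def _wm(self, level):
        from methclime.datatypes import WindowMatrix

        n = level.shape[0]
        windows = pd.DataFrame({"chrom": "Chr1",
                                "start": np.arange(n) * 100 + 1,
                                "end": np.arange(n) * 100 + 200,
                                "context": "CHH"})
        samples = pd.DataFrame({
            "accession": [f"a{i}" for i in range(level.shape[1])],
            "environment": "10C"})
        return WindowMatrix(windows, level, np.ones_like(level), samples,
                            "CHH")

    def test_highest_variance_first_and_identity(self):
        lv = np.zeros((5, 4))
        lv[2] = [0, 1, 0, 1]
        wm = self._wm(lv)
        assert quant.select_variable_windows(wm, top_n=1).tolist() == [2]
        assert quant.select_variable_windows(wm, top_n=5).tolist() == \
            [0, 1, 2, 3, 4]

    def test_tie_breaks_to_earlier_coordinate(self):
        lv = np.tile([0.0, 1.0, 0.0, 1.0], (4, 1))
        wm = self._wm(lv)
        assert quant.select_variable_windows(wm, top_n=2).tolist() == [0, 1]

    def test_missing_filter_and_warning(self):
        lv = np.array([[0.1, np.nan], [0.4, 0.2], [0.0, 0.9]])
        wm = self._wm(lv)
        idx = quant.select_variable_windows(wm, top_n=2, max_missing=0.0)
        assert 0 not in idx
        with pytest.warns(UserWarning, match="missingness"):
            idx = quant.select_variable_windows(wm, top_n=3, max_missing=0.0)
        assert len(idx) == 2


class TestGbmClassification:
    def _mats(self, cg, chg, chh):
        idx = list(cg)
        return {
            "CG": pd.DataFrame({0: pd.Series(cg)}, index=idx),
            "CHG": pd.DataFrame({0: pd.Series(chg)}, index=idx),
            "CHH": pd.DataFrame({0: pd.Series(chh)}, index=idx),
        }

    def test_three_way_labels(self):
        mats = self._mats(
            cg={"a": 0.30, "b": 0.04, "c": 0.80, "d": np.nan},
            chg={"a": 0.01, "b": 0.01, "c": 0.40, "d": 0.0},
            chh={"a": 0.01, "b": 0.01, "c": 0.30, "d": 0.0})
        lab = quant.classify_gbm_genes(mats)
        assert lab["a"] == "gbm"
        assert lab["b"] == "unmethylated"  # below the 5% cutoff
        assert lab["c"] == "te_like"
        assert lab["d"] == "excluded"

    def test_permutation_invariance_and_idempotence(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        cg = pd.DataFrame(rng.random((20, 6)) * 0.4, index=genes)
        chg = pd.DataFrame(rng.random((20, 6)) * 0.1, index=genes)
        chh = pd.DataFrame(rng.random((20, 6)) * 0.1, index=genes)
        mats = {"CG": cg, "CHG": chg, "CHH": chh}
        lab1 = quant.classify_gbm_genes(mats)
        perm = rng.permutation(6)
        mats_p = {k: v.iloc[:, perm] for k, v in mats.items()}
        lab2 = quant.classify_gbm_genes(mats_p)
        pd.testing.assert_series_equal(lab1, lab2)


class TestSiteGroupComparison:
    def test_identical_groups_zero_difference(self):
        m = np.tile([[3], [7]], (1, 4))
        t = np.full((2, 4), 10)
        c = make_counts(_sites(2), m, t)
        labels = pd.Series({"s0": "n", "s1": "n", "s2": "s", "s3": "s"})
        out = quant.site_group_comparison(c, labels)
        assert np.allclose(out["difference"], 0.0)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(2)
        n_sites, delta = 400, 0.15
        t = rng.poisson(40, (n_sites, 8))
        p = np.full(n_sites, 0.3)
        m = np.column_stack(
            [rng.binomial(t[:, j], p + (delta if j < 4 else 0))
             for j in range(8)])
        c = make_counts(_sites(n_sites), m, t)
        labels = pd.Series({f"s{j}": ("n" if j < 4 else "s")
                            for j in range(8)})
        out = quant.site_group_comparison(c, labels)
        assert np.nanmedian(out["difference"]) == pytest.approx(delta,
                                                                abs=0.03)

    def test_zero_cutoff_counts_all_covered(self):
        m = np.zeros((3, 4), int)
        t = np.full((3, 4), 10)
        c = make_counts(_sites(3), m, t)
        labels = pd.Series({f"s{j}": ("n" if j < 2 else "s")
                            for j in range(4)})
        out = quant.site_group_comparison(c, labels, detect_cutoff=0.0)
        assert out["detected_sites"]["n"] == 3

    def test_empty_group_is_error(self):
        c = make_counts(_sites(2), np.ones((2, 2), int),
                        np.full((2, 2), 5))
        labels = pd.Series({"s0": "n", "s1": "n"})
        with pytest.raises(ValueError):
            quant.site_group_comparison(c, labels)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                min_size=1, max_size=30))
def test_aggregation_equals_count_ratio(pairs):
    """Region aggregation equals sum(meth)/sum(total) exactly."""
    meth = np.array([min(a, b) for a, b in pairs])
    tot = np.array([max(a, b) for a, b in pairs])
    sites = _sites(len(pairs))
    c = make_counts(sites, meth, tot)
    annot = AnnotationSet(pd.DataFrame(
        [("Chr1", 1, int(sites["pos"].max()), "gene", "", "", False, "g")],
        columns=["chrom", "start", "end", "kind", "family", "superfamily",
                 "variable", "id"]), {"Chr1": 100_000})
    out = quant.feature_average(c, annot)
    if tot.sum() == 0:
        assert np.isnan(out.iloc[0, 0])
    else:
        assert out.iloc[0, 0] == pytest.approx(meth.sum() / tot.sum())
        assert 0.0 <= out.iloc[0, 0] <= 1.0
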