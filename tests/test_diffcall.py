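"""Differential calling: BH, binning, DMR/DAR/DEG tests, curation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import cistrans as ct
from cistrans.diffcall import (
    BinnedMethylation,
    bh_adjust,
    curate_annotated,
    log_cpm,
    moderated_test,
    size_factors,
)


class TestBhAdjust:
    def test_step_up_worked_example(self):
        # hand application of q_(i) = min_{j>=i} p_(j) m / j
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.3] * 5), 0.3)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_p(self, p):
        q = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()
        # monotone in the sorted order
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestBinning:
    def test_half_open_bin_arithmetic(self, small_meth_matrix):
        binned = ct.bin_methylation(small_meth_matrix, bin_bp=100, min_cov=0)
        # sites at 100 and 150 pool into [100, 200); 210 into [200, 300)
        assert binned.bins.start.tolist() == [100, 200, 400]
        assert binned.meth.loc[0, "FA_1"] == 9 + 8
        assert binned.total.loc[0, "FA_1"] == 20

    def test_min_cov_in_any_sample_excludes_bin(self, small_meth_matrix):
        m = small_meth_matrix
        m.total.loc[3, "PM_2"] = 4  # one sample below threshold in last bin
        m.meth.loc[3, "PM_2"] = 2
        binned = ct.bin_methylation(m, bin_bp=100, min_cov=10)
        assert binned.tested.tolist() == [True, True, False]

    def test_pooled_level(self, small_meth_matrix):
        binned = ct.bin_methylation(small_meth_matrix, bin_bp=100, min_cov=0)
        assert binned.levels.loc[0, "FA_1"] == pytest.approx(17 / 20)


def _binned_from_levels(meth, total, bin_bp=100):
    n = len(meth)
    bins = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * bin_bp,
         "end": (np.arange(n) + 1) * bin_bp, "n_sites": 2}
    )
    samples = pd.DataFrame(
        {"sample_id": list(meth.columns),
         "group": [c.split("_")[0] for c in meth.columns]}
    )
    return BinnedMethylation(
        bins=bins, meth=meth, total=total, samples=samples,
        tested=pd.Series([True] * n),
    )


def _planted_binned(rng, n_bins=60, planted=(10, 11), p1=0.9, p2=0.1, cov=50):
    cols = ["FA_1", "FA_2", "FA_3", "PM_1", "PM_2", "PM_3"]
    total = pd.DataFrame(np.full((n_bins, 6), cov), columns=cols)
    base = rng.binomial(cov, 0.5, size=(n_bins, 6))
    meth = pd.DataFrame(base, columns=cols)
    for b in planted:
        meth.iloc[b, :3] = rng.binomial(cov, p1, 3)
        meth.iloc[b, 3:] = rng.binomial(cov, p2, 3)
    return _binned_from_levels(meth, total)


class TestCallDmrs:
    def test_identical_groups_yield_no_dmrs(self):
        cols = ["FA_1", "FA_2", "PM_1", "PM_2"]
        meth = pd.DataFrame(np.tile([[5, 5, 5, 5]], (20, 1)), columns=cols)
        total = pd.DataFrame(np.full((20, 4), 10), columns=cols)
        out = ct.call_dmrs(_binned_from_levels(meth, total))
        assert len(out) == 0

    def test_planted_bin_recovered_hypo_with_expected_effect(self):
        binned = _planted_binned(np.random.default_rng(0))
        out = ct.call_dmrs(binned)
        assert len(out) == 1
        region = out.iloc[0]
        assert region.status == "hypo"
        assert region.effect == pytest.approx(-0.8, abs=0.08)
        # independent oracle: Welch t on the transformed levels of one bin
        lv = binned.levels.iloc[10]
        y = np.arcsin(np.sqrt(lv.astype(float)))
        t, p = stats.ttest_ind(y[3:], y[:3], equal_var=False)
        assert p < 0.05
        welch = ct.call_dmrs(binned, method="welch")
        assert len(welch) <= 1  # welch may lack power but never invents calls

    def test_welch_pvalue_matches_scipy(self):
        binned = _planted_binned(np.random.default_rng(3))
        lv = binned.levels
        y = np.arcsin(np.sqrt(lv.to_numpy(dtype=float)))
        t_ref, p_ref = stats.ttest_ind(y[:, 3:], y[:, :3], axis=1, equal_var=False)
        # merge_gap=-1 disables merging so each called region is one bin
        out = ct.call_dmrs(binned, method="welch", alpha=0.5, delta_min=0.0,
                           merge_gap=-1, min_bins=1)
        row = out[out.start == 1000].iloc[0]
        assert row.z == pytest.approx(t_ref[10], abs=1e-9)
        assert row.p == pytest.approx(p_ref[10], abs=1e-12)

    def test_adjacent_same_sign_bins_merge(self):
        binned = _planted_binned(np.random.default_rng(1), planted=(10, 11))
        out = ct.call_dmrs(binned)
        assert len(out) == 1
        assert (out.iloc[0].start, out.iloc[0].end) == (1000, 1200)
        assert out.iloc[0].n_bins == 2

    def test_opposite_sign_bins_do_not_merge(self):
        rng = np.random.default_rng(2)
        binned = _planted_binned(rng, planted=(10,))
        # make bin 11 significant in the opposite direction
        binned.meth.iloc[11, :3] = rng.binomial(50, 0.1, 3)
        binned.meth.iloc[11, 3:] = rng.binomial(50, 0.9, 3)
        out = ct.call_dmrs(binned, min_bins=1)
        assert len(out) == 2
        assert set(out.status) == {"hyper", "hypo"}

    def test_single_sample_group_is_hard_error(self):
        cols = ["FA_1", "PM_1", "PM_2"]
        meth = pd.DataFrame(np.full((5, 3), 5), columns=cols)
        total = pd.DataFrame(np.full((5, 3), 10), columns=cols)
        with pytest.raises(ValueError, match=">=2 samples"):
            ct.call_dmrs(_binned_from_levels(meth, total))


class TestModeratedTest:
    def _signal(self, rng, n=200):
        cols = ["FA_1", "FA_2", "FA_3", "PM_1", "PM_2", "PM_3"]
        return pd.DataFrame(rng.standard_normal((n, 6)), columns=cols), ["FA"] * 3 + ["PM"] * 3

    def test_equal_means_give_zero_statistic(self):
        x, groups = self._signal(np.random.default_rng(0))
        x.iloc[0] = [1.0, 2.0, 3.0, 3.0, 1.0, 2.0]  # same mean both groups
        res = moderated_test(x, groups)
        assert res.iloc[0].z == pytest.approx(0.0)
        assert res.iloc[0].p == pytest.approx(1.0)

    def test_zero_variance_feature_still_finite(self):
        x, groups = self._signal(np.random.default_rng(1))
        x.iloc[0] = [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]  # s2 = 0, delta = 1
        res = moderated_test(x, groups)
        assert np.isfinite(res.iloc[0].z)
        assert res.iloc[0].s2_post > 0

    def test_infinite_prior_df_limit_matches_closed_form(self):
        x, groups = self._signal(np.random.default_rng(2))
        s02 = 1.3
        res = moderated_test(x, groups, prior=(1e8, s02))
        delta = x[["PM_1", "PM_2", "PM_3"]].mean(1) - x[["FA_1", "FA_2", "FA_3"]].mean(1)
        expected = delta / (np.sqrt(s02) * np.sqrt(1 / 3 + 1 / 3))
        assert np.allclose(res.z, expected, atol=1e-6)

    def test_identical_data_degenerate_but_defined(self):
        cols = ["FA_1", "FA_2", "PM_1", "PM_2"]
        x = pd.DataFrame(np.ones((10, 4)), columns=cols)
        res = moderated_test(x, ["FA", "FA", "PM", "PM"])
        assert (res.p == 1.0).all()


class TestCallCounts:
    def _counts(self, rng, n=300, lfc_rows=(), lfc=1.5):
        cols = ["FA_1", "FA_2", "FA_3", "PM_1", "PM_2", "PM_3"]
        mu = 200 * np.exp(rng.standard_normal(n))
        mean = np.tile(mu[:, None], (1, 6))
        for i in lfc_rows:
            mean[i, 3:] *= 2.0 ** lfc
        counts = rng.negative_binomial(20, 20 / (20 + mean))
        cm = ct.CountMatrix(
            counts=pd.DataFrame(counts, columns=cols,
                                index=[f"f{i}" for i in range(n)]),
            samples=pd.DataFrame({"sample_id": cols, "group": [c[:2] for c in cols]}),
        )
        return cm

    def test_all_equal_counts_yield_no_calls(self):
        cols = ["FA_1", "FA_2", "PM_1", "PM_2"]
        cm = ct.CountMatrix(
            counts=pd.DataFrame(np.full((20, 4), 7), columns=cols,
                                index=[f"f{i}" for i in range(20)]),
            samples=pd.DataFrame({"sample_id": cols, "group": ["FA", "FA", "PM", "PM"]}),
        )
        assert len(ct.call_dars(cm)) == 0

    def test_planted_fold_change_called_with_direction(self):
        rng = np.random.default_rng(5)
        cm = self._counts(rng, lfc_rows=range(10), lfc=1.5)
        out = ct.call_dars(cm)
        called = set(out.feature_id)
        assert len(called & {f"f{i}" for i in range(10)}) >= 8
        assert (out.set_index("feature_id").loc[list(called & {"f0", "f1"})].status == "GA").all()
        assert np.isfinite(out.attrs["zcut"])

    def test_library_size_invariance(self):
        rng = np.random.default_rng(6)
        cm = self._counts(rng)
        doubled = cm.counts.copy()
        doubled["PM_1"] = doubled["PM_1"] * 2
        res1 = moderated_test(log_cpm(cm.counts), cm.samples.group)
        res2 = moderated_test(log_cpm(doubled), cm.samples.group)
        assert np.allclose(res1.z, res2.z, atol=1e-9)

    def test_label_swap_flips_everything(self):
        rng = np.random.default_rng(7)
        cm = self._counts(rng, lfc_rows=range(15))
        a = ct.call_dars(cm, group_labels=("FA", "PM"))
        b = ct.call_dars(cm, group_labels=("PM", "FA"))
        a = a.set_index("feature_id").sort_index()
        b = b.set_index("feature_id").sort_index()
        assert list(a.index) == list(b.index)
        assert np.allclose(a.effect, -b.effect, atol=1e-12)
        assert np.allclose(a.p, b.p, atol=1e-12)
        assert (a.status.map({"GA": "LA", "LA": "GA"}) == b.status).all()

    def test_zero_library_is_hard_error(self):
        cols = ["FA_1", "FA_2", "PM_1", "PM_2"]
        counts = pd.DataFrame(np.ones((5, 4), dtype=int), columns=cols,
                              index=[f"f{i}" for i in range(5)])
        counts["PM_2"] = 0
        cm = ct.CountMatrix(
            counts=counts,
            samples=pd.DataFrame({"sample_id": cols, "group": ["FA", "FA", "PM", "PM"]}),
        )
        with pytest.raises(ValueError, match="library size"):
            ct.call_dars(cm)

    def test_size_factors_counter_composition(self):
        # doubling one sample's depth doubles its factor relative to the rest
        rng = np.random.default_rng(8)
        cm = self._counts(rng, n=100)
        sf = size_factors(cm.counts)
        doubled = cm.counts.copy()
        doubled["FA_1"] = doubled["FA_1"] * 2
        sf2 = size_factors(doubled)
        rel_before = sf["FA_1"] / sf["FA_2"]
        rel_after = sf2["FA_1"] / sf2["FA_2"]
        assert rel_after / rel_before == pytest.approx(2.0, rel=1e-9)


class TestCuration:
    def _annotated(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [100, 900, 2_000, 3_000],
                "end": [300, 1_100, 2_200, 3_200],
                "region_id": ["r1", "r2", "r3", "r4"],
                "q": [0.04, 0.01, 0.02, 0.03],
                "status": ["hyper", "hyper", "hypo", "hyper"],
                "target_gene": ["gA", "gA", "gB", None],
                "tss_distance": [-400.0, 400.0, 100.0, 900.0],
            }
        )

    def test_smallest_q_wins_within_gene_status(self):
        out = curate_annotated(self._annotated())
        kept = set(out.region_id)
        assert "r2" in kept and "r1" not in kept

    def test_unannotated_calls_dropped(self):
        out = curate_annotated(self._annotated())
        assert "r4" not in set(out.region_id)

    def test_already_unique_is_identity(self):
        tab = self._annotated().iloc[[1, 2]].reset_index(drop=True)
        out = curate_annotated(tab)
        assert set(out.region_id) == {"r2", "r3"}

    def test_tie_broken_by_distance(self):
        tab = self._annotated()
        tab.loc[0, "q"] = 0.01  # tie with r2; r2 has equal |distance|? no: 400 both
        tab.loc[0, "tss_distance"] = -500.0
        out = curate_annotated(tab)
        assert "r2" in set(out.region_id) and "r1" not in set(out.region_id)
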