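"""PLS pairing: coefficient identities, permutation thresholds, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression

import cistrans as ct
from cistrans import integrate


def _std(a):
    a = np.asarray(a, dtype=float)
    return (a - a.mean(0)) / a.std(0, ddof=1)


def _frames(X, Y):
    return (
        pd.DataFrame(X, columns=[f"r{i}" for i in range(X.shape[1])]),
        pd.DataFrame(Y, columns=[f"g{i}" for i in range(Y.shape[1])]),
    )


class TestFitMpls:
    def test_univariate_coefficient_is_pearson_r(self):
        rng = np.random.default_rng(0)
        x = _std(rng.standard_normal((8, 1)))
        y = _std(0.7 * x + 0.5 * rng.standard_normal((8, 1)))
        X, Y = _frames(x, y)
        beta = ct.fit_mpls(X, Y, K=1)
        r = np.corrcoef(x[:, 0], y[:, 0])[0, 1]
        assert beta.iloc[0, 0] == pytest.approx(r, abs=1e-10)

    def test_orthogonal_response_gets_zero_coefficient(self):
        rng = np.random.default_rng(1)
        x = _std(rng.standard_normal((20, 2)))
        y = rng.standard_normal((20, 1))
        y -= x @ np.linalg.lstsq(x, y, rcond=None)[0]  # project out
        X, Y = _frames(x, _std(y))
        beta = ct.fit_mpls(X, Y, K=2)
        assert np.abs(beta.to_numpy()).max() < 1e-10

    def test_full_rank_components_reduce_to_ols(self):
        rng = np.random.default_rng(2)
        x = _std(rng.standard_normal((20, 5)))
        y = _std(x @ rng.standard_normal((5, 3)) + 0.3 * rng.standard_normal((20, 3)))
        X, Y = _frames(x, y)
        beta = ct.fit_mpls(X, Y, K=5)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.allclose(beta.to_numpy(), ols, atol=1e-8)

    def test_agrees_with_sklearn_nipals(self):
        rng = np.random.default_rng(3)
        x = _std(rng.standard_normal((20, 6)))
        y = _std(x @ rng.standard_normal((6, 4)) + 0.5 * rng.standard_normal((20, 4)))
        X, Y = _frames(x, y)
        beta = ct.fit_mpls(X, Y, K=3).to_numpy()
        ref = PLSRegression(n_components=3, scale=False, tol=1e-12, max_iter=10_000)
        ref.fit(x, y)
        assert np.allclose(beta, ref.coef_.T, atol=1e-5)

    def test_out_of_range_components_rejected(self):
        rng = np.random.default_rng(4)
        X, Y = _frames(_std(rng.standard_normal((8, 3))), _std(rng.standard_normal((8, 2))))
        with pytest.raises(ValueError, match="out of range"):
            ct.fit_mpls(X, Y, K=8)

    def test_nan_rejected(self):
        X, Y = _frames(np.full((8, 2), np.nan), np.ones((8, 2)))
        with pytest.raises(ValueError, match="NaN"):
            ct.fit_mpls(X, Y, K=1)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = _std(rng.standard_normal((12, 5)))
        y = _std(rng.standard_normal((12, 3)))
        X, Y = _frames(x, y)
        b1 = ct.fit_mpls(X, Y, K=2)
        b2 = ct.fit_mpls(X, Y, K=2)
        pd.testing.assert_frame_equal(b1, b2)


class TestPermutationThresholds:
    def test_alpha_one_means_everything_significant(self):
        rng = np.random.default_rng(0)
        X, Y = _frames(_std(rng.standard_normal((8, 3))), _std(rng.standard_normal((8, 3))))
        th = ct.permutation_thresholds(X, Y, alpha=1.0, B=50, seed=0)
        assert th.r_star == 0.0 and th.beta_star == 0.0

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        X, Y = _frames(_std(rng.standard_normal((8, 4))), _std(rng.standard_normal((8, 4))))
        a = ct.permutation_thresholds(X, Y, B=60, seed=9)
        b = ct.permutation_thresholds(X, Y, B=60, seed=9)
        assert a == b

    def test_null_r_quantile_matches_exact_distribution(self):
        # under independence r^2 ~ Beta(1/2, (n-2)/2); compare the pooled
        # permutation quantile of |r| with the analytic 95th percentile at n=8
        rng = np.random.default_rng(2)
        X, Y = _frames(_std(rng.standard_normal((8, 30))), _std(rng.standard_normal((8, 30))))
        th = ct.permutation_thresholds(X, Y, alpha=0.05, B=100, seed=0, K=1)
        exact = float(np.sqrt(sps.beta.ppf(0.95, 0.5, 3.0)))
        assert th.r_star == pytest.approx(exact, abs=0.04)

    def test_threshold_converges_in_permutation_count(self):
        rng = np.random.default_rng(3)
        X, Y = _frames(_std(rng.standard_normal((8, 20))), _std(rng.standard_normal((8, 20))))
        a = ct.permutation_thresholds(X, Y, B=200, seed=0, K=1)
        b = ct.permutation_thresholds(X, Y, B=400, seed=0, K=1)
        assert abs(a.r_star - b.r_star) < 0.02

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(4)
        X, Y = _frames(_std(rng.standard_normal((8, 2))), _std(rng.standard_normal((8, 2))))
        with pytest.raises(ValueError, match="50"):
            ct.permutation_thresholds(X, Y, B=10)


class TestSignalMatrices:
    def test_region_signal_is_pooled_fraction(self, small_meth_matrix):
        calls = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200],
             "region_id": ["chr1:100-200"]}
        )
        raw_first = (9 + 8) / 20  # FA_1 pooled fraction before standardization
        X = integrate.region_signal_matrix(calls, small_meth_matrix)
        col = X["chr1:100-200"]
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        # standardization is affine: recover the raw value ordering
        fracs = [(9 + 8) / 20, (7 + 9) / 20, (2 + 1) / 20, (1 + 2) / 20]
        assert np.allclose(np.argsort(col.to_numpy()), np.argsort(fracs))
        assert raw_first == fracs[0]

    def test_constant_region_dropped_with_warning(self, small_meth_matrix):
        m = small_meth_matrix
        calls = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 400], "end": [200, 401],
             "region_id": ["a", "b"]}
        )
        m.meth.loc[3] = [5, 5, 5, 5]  # site 400: constant fraction
        with pytest.warns(UserWarning, match="constant"):
            X = integrate.region_signal_matrix(calls, m)
        assert list(X.columns) == ["a"]

    def test_zero_coverage_region_dropped(self, small_meth_matrix):
        m = small_meth_matrix
        m.total.loc[3, "FA_1"] = 0
        m.meth.loc[3, "FA_1"] = 0
        calls = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 400], "end": [200, 401],
             "region_id": ["a", "b"]}
        )
        with pytest.warns(UserWarning, match="zero coverage"):
            X = integrate.region_signal_matrix(calls, m)
        assert list(X.columns) == ["a"]


class TestClassifyPairs:
    def _setup(self, toy_annotation):
        # region in gA's promoter whose signal equals gA's expression
        rng = np.random.default_rng(0)
        x = _std(rng.standard_normal((8, 1)))
        X = pd.DataFrame(x, columns=["chr1:10400-10600"])
        Y = pd.DataFrame(np.column_stack([x[:, 0], _std(rng.standard_normal(8))]),
                         columns=["gA", "gB"])
        region_calls = pd.DataFrame(
            {"region_id": ["chr1:10400-10600"], "chrom": ["chr1"],
             "start": [10_400], "end": [10_600], "status": ["hyper"]}
        )
        gene_calls = pd.DataFrame({"gene_id": ["gA", "gB"], "status": ["up", "down"]})
        return X, Y, region_calls, gene_calls

    def test_identical_signal_in_promoter_is_significant_homologous(self, toy_annotation):
        X, Y, region_calls, gene_calls = self._setup(toy_annotation)
        beta = ct.fit_mpls(X, Y, K=1)
        th = integrate.PairThresholds(0.7, 0.7, 0.05, 200, 0)
        pairs = ct.classify_pairs(X, Y, beta, th, toy_annotation, region_calls, gene_calls)
        top = pairs.iloc[0]
        assert top.gene_id == "gA" and top.type == "homologous"
        assert top.r == pytest.approx(1.0)
        assert bool(top.significant)

    def test_asymmetric_rule(self, toy_annotation):
        # one criterion suffices for homologous, both needed for heterologous
        X, Y, region_calls, gene_calls = self._setup(toy_annotation)
        beta = ct.fit_mpls(X, Y, K=1)
        th = integrate.PairThresholds(r_star=0.5, beta_star=2.0, alpha=0.05,
                                      n_permutations=200, seed=0)
        pairs = ct.classify_pairs(X, Y, beta, th, toy_annotation, region_calls, gene_calls)
        byg = pairs.set_index("gene_id")
        assert bool(byg.loc["gA", "sig_r"]) and not bool(byg.loc["gA", "sig_beta"])
        assert bool(byg.loc["gA", "significant"])  # homologous: OR
        hetero = byg.loc["gB"]
        assert hetero.type == "heterologous"
        assert not bool(hetero.significant)  # would need AND

    def test_types_partition_the_pairs(self, toy_annotation):
        X, Y, region_calls, gene_calls = self._setup(toy_annotation)
        beta = ct.fit_mpls(X, Y, K=1)
        th = integrate.PairThresholds(0.7, 0.7, 0.05, 200, 0)
        pairs = ct.classify_pairs(X, Y, beta, th, toy_annotation, region_calls, gene_calls)
        assert pairs.groupby(["region_id", "gene_id"]).type.nunique().max() == 1
        assert set(pairs.type) <= {"homologous", "heterologous"}

    def test_sorted_by_significance_then_r(self, toy_annotation):
        X, Y, region_calls, gene_calls = self._setup(toy_annotation)
        beta = ct.fit_mpls(X, Y, K=1)
        th = integrate.PairThresholds(0.7, 0.7, 0.05, 200, 0)
        pairs = ct.classify_pairs(X, Y, beta, th, toy_annotation, region_calls, gene_calls)
        sig = pairs.significant.to_numpy()
        assert not (~sig[:-1] & sig[1:]).any()  # significant block first
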