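import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from scipy.stats import rankdata

import nirsfusion as nf
from nirsfusion.stats import (
    channelwise_comparison,
    cohens_d_paired,
    fdr_bh,
    friedman_test,
    power_paired,
    wilcoxon_signed_rank,
)


def _friedman_oracle(x):
    """Rank-then-formula recomputation, independent of the implementation."""
    n, k = x.shape
    ranks = np.vstack([rankdata(row) for row in x])
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3 * n * (k + 1)


def _wilcoxon_brute(x, y):
    """Full 2^n enumeration of the signed-rank null."""
    d = x - y
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    wp = ranks[d > 0].sum()
    dist = np.array([np.sum(np.array(signs) * ranks)
                     for signs in itertools.product([0, 1], repeat=d.size)])
    cdf = (dist <= wp).mean()
    sf = (dist >= wp).mean()
    return min(1.0, 2.0 * min(cdf, sf))


class TestFriedman:
    def test_connectivity_table_statistic(self, table3):
        res = friedman_test(table3[["midgray", "forg", "rorg"]].to_numpy())
        assert res.statistic == 24.0
        assert res.p_value < 1e-4
        assert res.rank_sums.sum() == 12 * 3 * 4 / 2

    def test_identical_conditions_give_zero(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        assert friedman_test(x).statistic == 0.0

    def test_matches_oracle_and_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.normal(size=(5, 3))
            res = friedman_test(x)
            assert res.statistic == pytest.approx(_friedman_oracle(x), abs=1e-10)
            scipy_stat, _ = sps.friedmanchisquare(*x.T)
            assert res.statistic == pytest.approx(scipy_stat, abs=1e-8)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 4))
        base = friedman_test(x).statistic
        assert friedman_test(np.exp(x)).statistic == pytest.approx(base)
        # any per-subject strictly increasing map preserves within-row ranks
        assert friedman_test(x * 3.0 + 7.0).statistic == pytest.approx(base)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, np.nan, 2.0]] * 3))


class TestWilcoxon:
    def test_perfectly_ordered_columns_give_zero(self, table3):
        res = wilcoxon_signed_rank(table3["forg"], table3["rorg"])
        assert res.statistic == 0.0
        assert res.n_effective == 12
        assert res.p_value == pytest.approx(2.0 / 4096)

    def test_channel13_statistic_is_one(self, table5, table6):
        res = wilcoxon_signed_rank(table5.loc["CH13"], table6.loc["CH13"])
        assert res.statistic == 1.0
        assert res.p_value == pytest.approx(4.0 / 4096)

    def test_rank_sum_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x, y = rng.normal(size=(2, 10))
            res = wilcoxon_signed_rank(x, y)
            n = res.n_effective
            assert res.w_plus + res.w_minus == pytest.approx(n * (n + 1) / 2)
            assert 0 <= res.statistic <= n * (n + 1) / 4

    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_p_equals_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = np.round(rng.normal(size=n), 1)  # rounding provokes ties
            y = np.round(rng.normal(size=n), 1)
            if np.all(x == y):
                continue
            res = wilcoxon_signed_rank(x, y, mode="exact")
            assert res.p_value == pytest.approx(_wilcoxon_brute(x, y), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x, y = rng.normal(size=(2, 12))
            mine = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, mode="exact")
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 60))
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal-approx"
        ref = sps.wilcoxon(x, y, correction=False, mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))

    def test_type_one_error_calibrated(self):
        """Exact test at alpha = 0.05 on paired null noise is close to, and
        not above, its nominal size (discreteness makes it conservative)."""
        rng = np.random.default_rng(5)
        reject = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(size=(2, 12))
            reject += wilcoxon_signed_rank(x, y).p_value <= 0.05
        assert 0.03 <= reject / reps <= 0.07


class TestFDR:
    def test_single_p(self):
        res = fdr_bh(np.array([0.03]))
        assert res.adjusted_p[0] == pytest.approx(0.03)
        assert res.significant[0]

    def test_published_channelwise_adjustment(self, table5, table6):
        raw = np.array([wilcoxon_signed_rank(table5.loc[ch], table6.loc[ch]).p_value
                        for ch in table5.index])
        res = fdr_bh(raw)
        by_ch = dict(zip(table5.index, res.adjusted_p))
        assert nf.round_half_up(by_ch["CH13"], 5) == 0.00684
        assert nf.round_half_up(by_ch["CH14"], 5) == 0.00684
        assert nf.round_half_up(by_ch["CH12"], 5) == 0.01139

    def test_all_significant_ladder(self):
        res = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert res.significant.all()

    def test_adjusted_p_properties(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20)
        res = fdr_bh(p)
        assert np.all(res.adjusted_p >= res.raw_p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(res.adjusted_p[order]) >= -1e-15)

    def test_stepup_set_equals_adjusted_threshold(self):
        """The step-up critical-value rule and {adjusted p <= alpha} select
        the same tests, checked against statsmodels on 1000 random vectors."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            res = fdr_bh(p)
            assert np.array_equal(res.significant, res.adjusted_p <= res.alpha)
            ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(res.adjusted_p, ref_adj, atol=1e-12)
            assert np.array_equal(res.significant, ref_rej)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestEffectAndPower:
    def test_channel13_effect_size(self, table5, table6):
        d = cohens_d_paired(table5.loc["CH13"], table6.loc["CH13"])
        assert d == pytest.approx(1.28, abs=0.01)

    def test_constant_shift_degenerate(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="zero standard deviation"):
            cohens_d_paired(x + 2.0, x)

    def test_alternating_differences_zero_d(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert cohens_d_paired(x, np.zeros(4)) == 0.0

    def test_published_power_values(self):
        assert power_paired(1.28, 12) == pytest.approx(0.98, abs=0.01)
        assert power_paired(1.09, 12) == pytest.approx(0.92, abs=0.01)

    def test_null_effect_power_equals_size(self):
        assert power_paired(0.0, 12, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    @given(st.floats(0.2, 2.0), st.floats(0.05, 0.8))
    def test_monotone_in_effect_size(self, d, bump):
        assert power_paired(d + bump, 12) > power_paired(d, 12)

    @given(st.integers(3, 40), st.integers(1, 20))
    def test_monotone_in_n(self, n, extra):
        assert power_paired(0.8, n + extra) >= power_paired(0.8, n)


class TestChannelwisePipeline:
    def test_published_significant_set(self, table5, table6):
        report = channelwise_comparison(table5, table6)
        assert report.significant_channels == ["CH12", "CH13", "CH14"]
        row = report.table.loc["CH12"]
        assert row["statistic"] == 3.0
        assert report.table.loc["CH10", "statistic"] == 33.5

    def test_identical_tables_degenerate(self, table5):
        report = channelwise_comparison(table5, table5)
        assert report.degenerate == list(table5.index)
        assert not report.table["significant"].any()

    def test_shape_mismatch_rejected(self, table5, table6):
        with pytest.raises(ValueError):
            channelwise_comparison(table5.iloc[:10], table6)

    def test_false_positive_control_under_null(self):
        """Global-null simulation: the chance that any channel survives the
        FDR step stays near the nominal 5% level (500 replicates)."""
        rng = np.random.default_rng(0)
        idx = [f"CH{i}" for i in range(1, 15)]
        cols = [f"P{i}" for i in range(1, 13)]
        hits = 0
        reps = 500
        for _ in range(reps):
            a = pd.DataFrame(rng.normal(size=(14, 12)), index=idx, columns=cols)
            b = pd.DataFrame(rng.normal(size=(14, 12)), index=idx, columns=cols)
            hits += channelwise_comparison(a, b).table["significant"].any()
        assert hits / reps <= 0.07
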