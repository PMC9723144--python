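"""Statistical battery: closed-form oracles and type-I behavior."""

import numpy as np
import pandas as pd
import pytest

from ca1pipe import stats


class TestRmAnova:
    def _table(self, rng, n=8, k=4, shift=None):
        data = rng.normal(size=(n, k))
        if shift is not None:
            data += shift
        return pd.DataFrame(data, columns=[f"c{i}" for i in range(k)])

    def test_identical_conditions_f_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        table = pd.DataFrame({"a": base, "b": base, "c": base})
        res = stats.rm_anova_states(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            table = self._table(rng)
            res = stats.rm_anova_states(table)
            x = table.to_numpy()
            n, k = x.shape
            grand = x.mean()
            ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
            ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
            ss_tot = ((x - grand) ** 2).sum()
            ss_err = ss_tot - ss_cond - ss_subj
            df1, df2 = k - 1, (n - 1) * (k - 1)
            F = (ss_cond / df1) / (ss_err / df2)
            from scipy.stats import f as fdist
            p = fdist.sf(F, df1, df2)
            assert res.statistic == pytest.approx(F, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)
            assert res.df == (df1, df2)

    def test_posthoc_matches_paired_t(self):
        rng = np.random.default_rng(1)
        table = self._table(rng, shift=np.array([0, 0, 0, 1.5]))
        res = stats.rm_anova_states(table)
        from scipy.stats import ttest_rel
        expect = ttest_rel(table["c0"], table["c3"]).pvalue
        got = dict(res.post_hoc)["c0 vs c3"]
        assert got == pytest.approx(expect, abs=1e-12)
        assert len(res.effect_summary["post_hoc_holm"]) == len(res.post_hoc)

    def test_incomplete_subjects_dropped(self):
        rng = np.random.default_rng(2)
        table = self._table(rng)
        table.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            res = stats.rm_anova_states(table)
        assert res.df[1] == (len(table) - 2) * (table.shape[1] - 1)


class TestTwoSample:
    def test_textbook_case(self):
        res = stats.two_sample_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == (4,)

    def test_identical_samples(self):
        res = stats.two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_paired_df_and_sides(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + np.array([0.5, 0.7, 0.4, 0.6])
        res = stats.two_sample_test(a, b, paired=True)
        assert res.df == (3,)
        one = stats.two_sample_test(a, b, paired=True, alternative="less")
        assert one.p_value == pytest.approx(res.p_value / 2, rel=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            stats.two_sample_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            stats.two_sample_test([1, 2, 3], [4, 5], paired=True)
        with pytest.raises(ValueError):
            stats.two_sample_test([1.0, 2.0], [1.5, 2.5], paired=True)


class TestChi2:
    def test_balanced_table_zero(self):
        res = stats.proportion_chi2([[50, 50], [50, 50]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_calculation(self):
        # [[90,10],[50,50]]: E = [[70,30],[70,30]], so
        # chi2 = 400*(2/70 + 2/30) = 38.0952 with df=1, no correction
        res = stats.proportion_chi2([[90, 10], [50, 50]])
        assert res.statistic == pytest.approx(400 * (2 / 70 + 2 / 30),
                                              abs=1e-10)
        assert res.df == (1,)

    def test_row_swap_symmetry(self):
        a = stats.proportion_chi2([[90, 10], [50, 50]])
        b = stats.proportion_chi2([[50, 50], [90, 10]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_bad_tables(self):
        with pytest.raises(ValueError):
            stats.proportion_chi2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            stats.proportion_chi2([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            stats.proportion_chi2([[0, 0], [3, 4]])


class TestKs:
    def test_identical_zero(self):
        x = np.linspace(0, 1, 50)
        res = stats.ks_compare(x, x)
        assert res.statistic == 0.0

    def test_shifted_uniform(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 1000)
        res = stats.ks_compare(a, a + 0.5)
        assert res.statistic == pytest.approx(0.5, abs=0.05)
        assert res.p_value < 1e-3

    def test_matches_bruteforce_ecdf(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = rng.normal(0.3, 1.2, size=55)
        res = stats.ks_compare(a, b)
        grid = np.sort(np.r_[a, b])
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert res.statistic == pytest.approx(np.abs(ecdf_a - ecdf_b).max(),
                                              abs=1e-12)

    def test_min_n(self):
        with pytest.raises(ValueError):
            stats.ks_compare([1, 2, 3], [1, 2, 3, 4, 5])


@pytest.mark.parametrize("test_fn", ["t", "chi2", "ks"])
def test_type_I_error_rates(test_fn):
    """Each test at alpha=0.05 rejects matched-null data at ~5%."""
    rng = np.random.default_rng(12)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        if test_fn == "t":
            p = stats.two_sample_test(rng.normal(size=8),
                                      rng.normal(size=8)).p_value
        elif test_fn == "chi2":
            a = rng.binomial(200, 0.3)
            b = rng.binomial(200, 0.3)
            p = stats.proportion_chi2([[a, 200 - a], [b, 200 - b]]).p_value
        else:
            p = stats.ks_compare(rng.normal(size=30),
                                 rng.normal(size=30)).p_value
        rejections += p < 0.05
    assert 0.03 <= rejections / n_rep <= 0.08
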