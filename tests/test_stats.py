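"""Agreement, equivalence, contrasts, power and outlier removal."""

import numpy as np
import pytest
from scipy import stats as st

import tremorkit as tk
from tremorkit.io_formats import ParameterError


class TestAgreement:
    def test_identity_perfect_agreement(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        r = tk.agreement_report(a, a)
        assert r.correlation == pytest.approx(1.0)
        assert r.mae == 0.0
        assert r.loa_high - r.loa_low == 0.0

    def test_constant_offset(self):
        rng = np.random.default_rng(51)
        a = rng.normal(10, 2, 30)
        r = tk.agreement_report(a, a - 5.0)
        assert r.mae == pytest.approx(5.0)
        assert r.bland_altman_bias == pytest.approx(5.0)
        assert r.loa_low <= r.bland_altman_bias <= r.loa_high

    def test_reversed_ranks_spearman_minus_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = tk.agreement_report(a, a[::-1], method="spearman")
        assert r.correlation == pytest.approx(-1.0)

    def test_mae_antisymmetric(self):
        rng = np.random.default_rng(52)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert tk.agreement_report(a, b).mae == pytest.approx(
            -tk.agreement_report(b, a).mae)

    def test_loa_cover_95pct_gaussian(self):
        rng = np.random.default_rng(53)
        a = rng.normal(50, 10, 20000)
        b = a + rng.normal(1.0, 2.0, 20000)
        r = tk.agreement_report(a, b, method="pearson")
        d = a - b
        inside = np.mean((d >= r.loa_low) & (d <= r.loa_high))
        assert inside == pytest.approx(0.95, abs=0.015)

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            tk.agreement_report([1, 2, 3], [1, 2])
        with pytest.raises(ParameterError):
            tk.agreement_report([1, 2, 3], [1, 2, 3])


class TestTOST:
    def test_all_zero_differences_equivalent(self):
        r = tk.tost_equivalence(np.zeros(10), sesoi=10.0)
        assert r.equivalent and r.degenerate
        assert r.mean_diff == 0.0

    def test_large_mean_not_equivalent(self):
        rng = np.random.default_rng(54)
        d = rng.normal(12.0, 1.0, 20)
        r = tk.tost_equivalence(d, sesoi=10.0)
        assert not r.equivalent
        assert r.ci90[1] > 10.0

    def test_p_values_match_closed_form(self):
        rng = np.random.default_rng(55)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            d = rng.normal(rng.normal(0, 5), rng.uniform(0.5, 5), n)
            sesoi = float(rng.uniform(1, 10))
            r = tk.tost_equivalence(d, sesoi)
            m, s = d.mean(), d.std(ddof=1)
            se = s / np.sqrt(n)
            assert r.p_lower == pytest.approx(
                st.t.sf((m + sesoi) / se, n - 1), abs=1e-9)
            assert r.p_upper == pytest.approx(
                st.t.cdf((m - sesoi) / se, n - 1), abs=1e-9)
            ci_inside = -sesoi < r.ci90[0] and r.ci90[1] < sesoi
            assert ci_inside == r.equivalent


class TestPairedContrast:
    def test_uniform_shift_gives_rank_biserial_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r = tk.paired_contrast(x, x + 2.0, method="wilcoxon")
        assert r.effect_size == 1.0

    def test_no_change_degenerate(self):
        x = np.arange(6.0)
        r = tk.paired_contrast(x, x)
        assert r.degenerate

    def test_rank_biserial_matches_enumeration(self):
        rng = np.random.default_rng(56)
        for _ in range(50):
            n = int(rng.integers(5, 11))
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            d = y - x
            d = d[d != 0]
            ranks = st.rankdata(np.abs(d))
            expected = (ranks[d > 0].sum() - ranks[d < 0].sum()) / ranks.sum()
            assert tk.matched_rank_biserial(x, y) == pytest.approx(expected)
            r = tk.paired_contrast(x, y, method="wilcoxon")
            assert r.effect_size == pytest.approx(expected)
            assert -1.0 <= r.effect_size <= 1.0

    def test_rank_biserial_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(73)
        x = rng.normal(size=15)
        y = x + rng.normal(0.4, 1.0, 15)
        ours = tk.matched_rank_biserial(x, y)
        theirs = float(pingouin.wilcoxon(y, x)["RBC"].iloc[0])
        assert abs(abs(ours) - abs(theirs)) < 1e-12

    def test_auto_picks_t_for_normal_differences(self):
        rng = np.random.default_rng(57)
        x = rng.normal(size=40)
        y = x + rng.normal(0.5, 1.0, 40)
        r = tk.paired_contrast(x, y)
        assert r.test_name in ("paired_t", "wilcoxon")
        oracle = st.ttest_rel(y, x)
        if r.test_name == "paired_t":
            assert r.statistic == pytest.approx(oracle.statistic)


class TestPower:
    def test_printed_value_reproduced(self):
        # reported achieved power at the observed correlation of the 8-person
        # validation sample
        p = tk.posthoc_power_correlation(rho=0.72, n=8, alpha=0.05, sided="one")
        assert p == pytest.approx(0.69, abs=0.03)

    def test_null_power_is_alpha(self):
        for n in (6, 10, 50):
            assert tk.posthoc_power_correlation(0.0, n) == 0.05

    def test_large_n_consistency(self):
        assert tk.posthoc_power_correlation(0.5, 2000) > 0.999

    def test_monotone_in_rho_and_n(self):
        powers_rho = [tk.posthoc_power_correlation(r, 20)
                      for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(powers_rho) > 0)
        powers_n = [tk.posthoc_power_correlation(0.5, n)
                    for n in (8, 16, 32, 64, 128)]
        assert np.all(np.diff(powers_n) > 0)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            tk.posthoc_power_correlation(1.0, 8)
        with pytest.raises(ParameterError):
            tk.posthoc_power_correlation(0.5, 3)


class TestROUT:
    def test_clean_linear_data_no_outliers(self):
        rng = np.random.default_rng(58)
        x = np.linspace(0, 10, 40)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.5, 40)
        r = tk.rout_outliers(x, y, Q=0.01)
        assert r.outlier_mask.sum() == 0
        assert r.slope == pytest.approx(2.0, abs=0.1)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(59)
        x = np.linspace(0, 10, 40)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.5, 40)
        base = tk.rout_outliers(x, y, Q=0.01)
        y[7] += 10 * base.rsdr
        r = tk.rout_outliers(x, y, Q=0.01)
        # independent oracle: residual t-score against BH threshold
        resid = y - (r.slope * x + r.intercept)
        tval = abs(resid[7]) / r.rsdr
        p = 2 * st.t.sf(tval, df=38)
        assert p < 0.01 / 40  # smallest BH threshold => must be flagged
        assert r.outlier_mask[7]

    def test_q_zero_never_flags(self):
        rng = np.random.default_rng(60)
        x = np.linspace(0, 10, 30)
        y = x + rng.normal(0, 1, 30)
        y[3] += 50.0
        assert tk.rout_outliers(x, y, Q=0.0).outlier_mask.sum() == 0

    def test_rank_deficient_rejected(self):
        with pytest.raises(ParameterError):
            tk.rout_outliers(np.ones(10), np.arange(10.0), Q=0.01)
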