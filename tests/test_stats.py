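"""Agreement, sample-size, dose and ANOVA statistics against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from osteotrack import stats as osx


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_identical_raters(self):
        ba = osx.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == 0 and ba.limits_low == 0 and ba.limits_high == 0

    def test_hand_computed_differences(self):
        # diffs {-1, +1}: mean 0, SD (n-1 denominator) = sqrt(2)
        ba = osx.bland_altman([0.0, 1.0], [1.0, 0.0])
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.limits_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert ba.limits_low == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="length"):
            osx.bland_altman([1.0, 2.0], [1.0])

    def test_noisy_observers_limits_near_theory(self):
        """Two raters = truth + independent N(0, sigma^2): the limits of
        agreement converge to +/-1.96 sigma sqrt(2)."""
        rng = np.random.default_rng(12)
        truth = rng.uniform(500, 1500, 4000)
        sigma = 50.0
        a = truth + rng.normal(0, sigma, truth.size)
        b = truth + rng.normal(0, sigma, truth.size)
        ba = osx.bland_altman(a, b)
        assert ba.limits_high == pytest.approx(1.96 * sigma * np.sqrt(2), rel=0.05)

    def test_limits_cover_95pct_of_differences(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 5000)
        b = rng.normal(0, 1, 5000)
        ba = osx.bland_altman(a, b)
        d = a - b
        cover = np.mean((d >= ba.limits_low) & (d <= ba.limits_high))
        assert cover >= 0.93

    def test_pairwise_three_observers(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {
                "A": rng.uniform(800, 1200, 18),
                "B": rng.uniform(800, 1200, 18),
                "C": rng.uniform(800, 1200, 18),
            }
        )
        out = osx.bland_altman_pairwise(table)
        assert set(out["pairs"]) == {"A-B", "B-C", "C-A"}
        assert out["pooled"].n == 3 * 18
        # pooled limits recompute from the stacked differences
        d = np.concatenate(
            [table["A"] - table["B"], table["B"] - table["C"], table["C"] - table["A"]]
        )
        assert out["pooled"].limits_high == pytest.approx(
            d.mean() + 1.96 * d.std(ddof=1)
        )
        assert np.isfinite(out["percent_of_mean"])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def _icc_bruteforce(data):
    """Mean squares from first principles, by explicit looping."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.sum() / (n * k)
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc3 = (msr - mse) / (msr + (k - 1) * mse)
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return icc3, icc2


TOY_TABLE = np.array(
    [
        [9.0, 2.0, 5.0],
        [6.0, 1.0, 3.0],
        [8.0, 4.0, 6.0],
        [7.0, 1.0, 2.0],
    ]
)


class TestIcc:
    def test_identical_observers_icc_one(self):
        data = np.tile(np.array([[10.0], [20.0], [30.0]]), (1, 3))
        res = osx.icc(data)
        assert res.icc_single == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model", ["ICC3", "ICC2"])
    def test_toy_table_matches_bruteforce(self, model):
        res = osx.icc(TOY_TABLE, model=model)
        icc3, icc2 = _icc_bruteforce(TOY_TABLE)
        expected = icc3 if model == "ICC3" else icc2
        assert res.icc_single == pytest.approx(expected, abs=1e-12)

    def test_toy_table_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        n, k = TOY_TABLE.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": TOY_TABLE.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "targets", "raters", "scores").set_index("Type")
        ours3 = osx.icc(TOY_TABLE, model="ICC3")
        ours2 = osx.icc(TOY_TABLE, model="ICC2")
        # pingouin labels: ICC(C,1) = two-way consistency, ICC(A,1) = agreement
        assert ours3.icc_single == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-6)
        assert ours2.icc_single == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-6)
        assert ours3.icc_average == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-6)
        assert ours3.p_value == pytest.approx(ref.loc["ICC(C,1)", "pval"], rel=1e-6)

    def test_pure_noise_icc_near_zero(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, size=(600, 3))
        res = osx.icc(data)
        assert abs(res.icc_single) < 0.08

    def test_cronbach_alpha_is_average_measure_consistency(self):
        res = osx.icc(TOY_TABLE, model="ICC3")
        assert res.cronbach_alpha == pytest.approx(res.icc_average, abs=1e-12)

    def test_zero_between_target_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            osx.icc(np.array([[1.0, 2.0], [1.0, 2.0]]) * 0.0 + 3.0)

    def test_incomplete_table_rejected(self):
        bad = TOY_TABLE.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            osx.icc(bad)


# ---------------------------------------------------------------------------
# Sample size / dose
# ---------------------------------------------------------------------------


class TestSampleSize:
    def test_worked_example(self):
        assert osx.sample_size(7.85, 0.255, 0.36) == 6

    def test_unit_ratio(self):
        assert osx.sample_size(7.85, 1.0, 1.0) == 10  # ceil(2 + 7.85)

    def test_huge_difference_floor(self):
        assert osx.sample_size(7.85, 0.1, 1e9) == 2

    @pytest.mark.parametrize("s,d", [(0.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_inputs(self, s, d):
        with pytest.raises(ValueError):
            osx.sample_size(7.85, s, d)

    @given(
        s=st.floats(0.01, 10.0),
        d1=st.floats(0.01, 10.0),
        d2=st.floats(0.01, 10.0),
    )
    def test_monotone_in_detectable_difference(self, s, d1, d2):
        lo, hi = sorted((d1, d2))
        assert osx.sample_size(7.85, s, lo) >= osx.sample_size(7.85, s, hi)


class TestDoseLedger:
    def test_ten_scan_protocol(self):
        ledger = osx.dose_ledger(11.7, range(10))
        assert ledger.cumulative == pytest.approx(117.0)
        assert ledger.under(120.0)

    def test_empty_schedule(self):
        assert osx.dose_ledger(11.7, []).cumulative == 0.0

    def test_single_scan(self):
        assert osx.dose_ledger(11.7, [0]).cumulative == pytest.approx(11.7)


# ---------------------------------------------------------------------------
# Sidak + two-way ANOVA
# ---------------------------------------------------------------------------


class TestSidak:
    def test_single_comparison_unchanged(self):
        assert osx.sidak_adjust(0.05, 1) == pytest.approx(0.05)

    @given(
        p=st.floats(0.0, 1.0),
        m=st.integers(1, 20),
    )
    def test_adjusted_at_least_raw(self, p, m):
        p_adj = osx.sidak_adjust(p, m)
        assert p_adj >= p - 1e-12
        assert 0.0 <= p_adj <= 1.0

    @given(p=st.floats(0.001, 0.999), m=st.integers(1, 19))
    def test_monotone_in_m(self, p, m):
        assert osx.sidak_adjust(p, m + 1) >= osx.sidak_adjust(p, m)


def _balanced_frame(rng, a_shift=0.0, times=(0, 7, 14, 21), n=4):
    rows = []
    for g, shift in (("unreamed", 0.0), ("reamed", a_shift)):
        for t in times:
            for _ in range(n):
                rows.append({"group": g, "time": t, "value": rng.normal(shift, 1.0)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_statsmodels_on_balanced_table(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(21)
        df = _balanced_frame(rng, a_shift=1.0)
        ours = osx.two_way_anova_sidak(df)
        fit = ols("value ~ C(group) * C(time)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours.anova_table.loc["group", "F"] == pytest.approx(
            ref.loc["C(group)", "F"], rel=1e-8
        )
        assert ours.anova_table.loc["time", "F"] == pytest.approx(
            ref.loc["C(time)", "F"], rel=1e-8
        )
        assert ours.anova_table.loc["interaction", "F"] == pytest.approx(
            ref.loc["C(group):C(time)", "F"], rel=1e-8
        )

    def test_identical_groups_give_unit_adjusted_p(self):
        rng = np.random.default_rng(2)
        df = _balanced_frame(rng)
        half = df[df.group == "unreamed"].copy()
        mirrored = half.assign(group="reamed")
        sym = pd.concat([half, mirrored], ignore_index=True)
        res = osx.two_way_anova_sidak(sym)
        assert (res.contrasts["mean_diff"] == 0).all()
        np.testing.assert_allclose(res.contrasts["p_sidak"], 1.0, atol=1e-12)

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(4)
        df = _balanced_frame(rng).iloc[:-1]
        with pytest.raises(ValueError, match="nbalanced|cell"):
            osx.two_way_anova_sidak(df)

    def test_single_subject_per_cell_rejected(self):
        rng = np.random.default_rng(4)
        df = _balanced_frame(rng, n=1)
        with pytest.raises(ValueError, match="subjects per cell"):
            osx.two_way_anova_sidak(df)

    def test_type_one_error_controlled_under_null(self):
        """Family-wise false-positive rate of the Sidak-adjusted per-time
        contrasts stays within alpha + 1% over 1000 null replicates."""
        rng = np.random.default_rng(123)
        hits = 0
        reps = 1000
        for _ in range(reps):
            df = _balanced_frame(rng)
            res = osx.two_way_anova_sidak(df)
            hits += int((res.contrasts["p_sidak"] < 0.05).any())
        assert hits / reps <= 0.06
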