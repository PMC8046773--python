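import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teloscore_mr.mr import (MrSummarySet, cochran_q, i2_gx, ivw, mr_egger,
                             mr_report, summary_from_tables, wald_ratio)
from teloscore_mr.published import snp_os_allelic_ds


def _set(bx, by, byse, bxse=None):
    k = len(bx)
    bxse = np.full(k, np.nan) if bxse is None else np.asarray(bxse, float)
    return MrSummarySet(tuple(f"rs{i}" for i in range(k)),
                        np.asarray(bx, float), bxse,
                        np.asarray(by, float), np.asarray(byse, float))


class TestWaldRatio:
    def test_simple_ratio(self):
        est, se = wald_ratio(0.1, 0.01, 0.2, 0.05)
        assert est == pytest.approx(2.0) and se == pytest.approx(0.5)

    def test_null_outcome(self):
        est, se = wald_ratio(0.1, 0.01, 0.0, 0.05)
        assert est == 0.0 and se == pytest.approx(0.5)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.2, 0.05)


class TestIvw:
    def test_single_instrument_reduces_to_wald_ratio(self):
        res = ivw(_set([0.5], [1.0], [0.2]))
        assert res.slope == pytest.approx(2.0)
        assert res.slope_se == pytest.approx(0.4)

    def test_equal_weights_average_the_ratios(self):
        res = ivw(_set([1.0, 1.0], [1.0, 3.0], [1.0, 1.0]))
        assert res.slope == pytest.approx(2.0)

    def test_inverse_variance_weighting(self):
        res = ivw(_set([1.0, 1.0], [1.0, 3.0], [1.0, 2.0]))
        assert res.slope == pytest.approx(1.4)

    def test_noiseless_proportional_inputs_recover_theta_with_zero_q(self):
        bx = np.array([0.3, 0.7, 1.1])
        res = ivw(_set(bx, 1.7 * bx, [0.2, 0.4, 0.1]))
        assert res.slope == pytest.approx(1.7, rel=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-20) and res.q_p == pytest.approx(1.0)

    def test_fixed_and_mre_share_the_slope_and_mre_never_shrinks_se(self, rng):
        for _ in range(10):
            k = rng.integers(2, 11)
            s = _set(rng.normal(size=k), rng.normal(size=k), rng.uniform(0.1, 1, k))
            fixed, mre = ivw(s, "fixed"), ivw(s, "mre")
            assert fixed.slope == mre.slope
            assert mre.slope_se >= fixed.slope_se - 1e-15

    def test_all_zero_bx_errors(self):
        with pytest.raises(ValueError):
            ivw(_set([0.0, 0.0], [1.0, 2.0], [1.0, 1.0]))

    def test_matches_wls_through_origin_oracle(self, rng):
        import statsmodels.api as sm
        for _ in range(20):
            k = int(rng.integers(2, 11))
            s = _set(rng.normal(1, 0.5, k), rng.normal(size=k), rng.uniform(0.05, 1, k))
            res = ivw(s)
            oracle = sm.WLS(s.by, s.bx, weights=s.byse**-2).fit()
            assert res.slope == pytest.approx(oracle.params[0], abs=1e-10)


class TestEgger:
    def test_collinear_points_fit_exactly(self):
        res = mr_egger(_set([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [0.5, 0.5, 0.5]))
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-18)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        import statsmodels.api as sm
        for _ in range(20):
            k = int(rng.integers(3, 11))
            bx = rng.normal(1, 0.5, k)
            s = _set(bx, rng.normal(size=k), rng.uniform(0.05, 1, k))
            res = mr_egger(s)
            sign = np.where(s.bx < 0, -1, 1)
            X = np.column_stack([np.ones(k), s.bx * sign])
            oracle = sm.WLS(s.by * sign, X, weights=s.byse**-2).fit()
            assert res.intercept == pytest.approx(oracle.params[0], abs=1e-10)
            assert res.slope == pytest.approx(oracle.params[1], abs=1e-10)

    def test_too_few_or_constant_instruments_error(self):
        with pytest.raises(ValueError):
            mr_egger(_set([1.0, 2.0], [1.0, 2.0], [1.0, 1.0]))
        with pytest.raises(ValueError):
            mr_egger(_set([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0]))


class TestCochranQ:
    def test_perfect_fit(self):
        q, df, p = cochran_q(_set([1.0, 2.0], [2.0, 4.0], [1.0, 1.0]), slope=2.0)
        assert q == 0.0 and p == 1.0

    def test_hand_computed_value(self):
        q, df, p = cochran_q(_set([1.0, 1.0], [1.0, 3.0], [1.0, 1.0]), slope=2.0)
        assert q == pytest.approx(2.0) and df == 1
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-12)
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_invariant_under_instrument_reordering(self, rng):
        k = 7
        s = _set(rng.normal(1, 0.4, k), rng.normal(size=k), rng.uniform(0.1, 1, k))
        perm = rng.permutation(k)
        s2 = MrSummarySet(tuple(np.array(s.rsid)[perm]), s.bx[perm], s.bxse[perm],
                          s.by[perm], s.byse[perm])
        assert cochran_q(s, 1.3)[0] == pytest.approx(cochran_q(s2, 1.3)[0], rel=1e-12)

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            cochran_q(_set([1.0], [1.0], [1.0]), slope=1.0)


class TestI2gx:
    def test_boundary_q_equals_df_gives_zero(self):
        # bx = (1, 2, 3) with unit ses: Q_GX = 2 = K - 1 exactly
        assert i2_gx([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == 0.0

    def test_identical_bx_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="weak"):
            assert i2_gx([1.0, 1.0, 1.0], [0.1, 0.1, 0.1]) == 0.0

    def test_strong_instruments_approach_one(self):
        assert i2_gx([0.5, 1.0, 1.5, 2.0], [0.01] * 4) > 0.99

    def test_truncated_at_zero_and_bounded(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 12))
            v = i2_gx(rng.normal(1, 0.3, k), rng.uniform(0.05, 2, k))
            assert 0.0 <= v < 1.0


class TestInvariances:
    def test_scale_equivariance(self, rng):
        k = 8
        s = _set(rng.normal(1, 0.4, k), rng.normal(size=k), rng.uniform(0.1, 1, k),
                 bxse=rng.uniform(0.05, 0.2, k))
        c = 3.7
        s_scaled = MrSummarySet(s.rsid, s.bx * c, s.bxse * c, s.by, s.byse)
        r1, r2 = ivw(s), ivw(s_scaled)
        assert r2.slope == pytest.approx(r1.slope / c, rel=1e-12)
        assert r2.q == pytest.approx(r1.q, rel=1e-12)
        e1, e2 = mr_egger(s), mr_egger(s_scaled)
        assert e2.slope == pytest.approx(e1.slope / c, rel=1e-12)
        assert e2.intercept == pytest.approx(e1.intercept, rel=1e-10)
        assert e2.intercept_p == pytest.approx(e1.intercept_p, rel=1e-9)

    def test_joint_sign_flip_invariance(self, rng):
        k = 9
        s = _set(rng.normal(1, 0.5, k), rng.normal(size=k), rng.uniform(0.1, 1, k),
                 bxse=rng.uniform(0.05, 0.2, k))
        flip = rng.random(k) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        s2 = MrSummarySet(s.rsid, s.bx * sign, s.bxse, s.by * sign, s.byse)
        assert ivw(s2).slope == pytest.approx(ivw(s).slope, rel=1e-12)
        e1, e2 = mr_egger(s), mr_egger(s2)
        assert e2.slope == pytest.approx(e1.slope, rel=1e-12)
        assert e2.intercept == pytest.approx(e1.intercept, rel=1e-10)


class TestSummaryFromTables:
    def test_byse_recovered_from_printed_interval(self, weighted_panel):
        s = summary_from_tables(snp_os_allelic_ds(), weighted_panel)
        i = s.rsid.index("rs10936599")
        # HR 1.20 (1.00-1.43) per minor allele; the effect allele is the major
        # C, so the log-HR flips sign
        assert s.by[i] == pytest.approx(-np.log(1.20), rel=1e-12)
        assert s.byse[i] == pytest.approx((np.log(1.43) - np.log(1.00)) / 3.92, rel=1e-9)
        assert s.byse[i] == pytest.approx(0.0912, abs=2e-4)
        assert (s.bx > 0).all()

    def test_unit_odds_ratio_maps_to_zero(self, weighted_panel):
        df = pd.DataFrame({"rsid": ["rs2736100"], "model": ["allelic"],
                           "effect": [1.0], "ci_low": [0.9], "ci_high": [1.11]})
        with pytest.warns(UserWarning):  # other panel SNPs have no estimate
            s = summary_from_tables(df, weighted_panel)
        assert s.by[0] == 0.0

    def test_missing_ci_drops_snp_with_warning(self, weighted_panel):
        df = snp_os_allelic_ds()
        df.loc[df["rsid"] == "rs755017", "ci_low"] = np.nan
        with pytest.warns(UserWarning, match="rs755017"):
            s = summary_from_tables(df, weighted_panel)
        assert "rs755017" not in s.rsid and s.k == 10

    def test_unconfigured_weights_error(self):
        from teloscore_mr.panel import builtin_panel
        with pytest.raises(ValueError, match="weights"):
            summary_from_tables(snp_os_allelic_ds(), builtin_panel())


class TestMrReport:
    def test_bundle_contents_and_consistency(self, weighted_panel):
        s = summary_from_tables(snp_os_allelic_ds(), weighted_panel)
        rep = mr_report(s)
        assert set(rep["results"]) == {"ivw-fixed", "ivw-mre", "egger"}
        assert rep["results"]["ivw-fixed"].slope == rep["results"]["ivw-mre"].slope
        assert 0 <= rep["i2_gx"] <= 1 and 0 <= rep["i2_gx_outcome_weighted"] <= 1
        assert len(rep["forest"]) == s.k + 3
        assert len(rep["scatter"]) == s.k

    def test_null_simulation_calibrates_egger_intercept(self, rng):
        # by pure noise: the Egger intercept p-value should be uniform
        bx = np.linspace(0.04, 0.12, 11)
        byse = np.full(11, 0.08)
        pvals = []
        for _ in range(500):
            s = _set(bx, rng.normal(0, byse), byse)
            pvals.append(mr_egger(s).intercept_p)
        rej = np.mean(np.asarray(pvals) < 0.05)
        assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_parameter_recovery_and_pleiotropy_detection(self, rng):
        # true slope theta with Gaussian outcome noise: IVW unbiased with
        # nominal coverage; adding a constant pleiotropic shift biases IVW
        # while the Egger intercept gains power to detect it
        theta = 1.175
        bx = np.linspace(0.04, 0.12, 11)
        byse = np.full(11, 0.08)
        reps = 1000
        cover = bias = 0.0
        egger_hits = 0
        slopes = []
        for _ in range(reps):
            s = _set(bx, theta * bx + rng.normal(0, byse), byse)
            res = ivw(s)
            slopes.append(res.slope)
            cover += abs(res.slope - theta) < 1.96 * res.slope_se
            s_pleio = _set(bx, theta * bx + 0.2 + rng.normal(0, byse), byse)
            egger_hits += mr_egger(s_pleio).intercept_p < 0.05
        assert 0.92 <= cover / reps <= 0.98
        se = ivw(_set(bx, theta * bx, byse)).slope_se
        assert abs(np.mean(slopes) - theta) < 0.1 * se
        assert egger_hits / reps > 0.5
        biased = ivw(_set(bx, theta * bx + 0.2, byse))
        assert biased.slope - theta > 3 * biased.slope_se
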