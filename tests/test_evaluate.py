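import numpy as np
import pytest

from gosurv.cox import RiskModelInput, fit_penalized_cox
from gosurv.data import SurvivalResponse
from gosurv.evaluate import (
    PredictionErrorCurve,
    assign_risk_groups,
    breslow_baseline,
    brier_score,
    integrated_brier_score,
    km_censoring,
    logrank_test,
    pi_lrt,
    predict_survival,
    prediction_error_curve,
)

from conftest import make_survival


class TestAssignRiskGroups:
    def test_median_rule(self):
        labels = assign_risk_groups(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])

    def test_all_equal_warns_all_low(self):
        with pytest.warns(UserWarning, match="identical"):
            labels = assign_risk_groups(np.array([1.0, 1.0, 1.0]))
        assert labels.sum() == 0

    def test_odd_count_strictly_above(self, rng):
        pi = rng.standard_normal(101)
        labels = assign_risk_groups(pi)
        assert labels.sum() == 50  # strictly-above-median count for odd n

    def test_tie_at_median_goes_low(self):
        labels = assign_risk_groups(np.array([1.0, 2.0, 2.0, 3.0]))
        np.testing.assert_array_equal(labels, [0, 0, 0, 1])


class TestLogrank:
    def test_identical_groups_null(self, rng):
        surv0 = make_survival(rng, 15)
        surv = SurvivalResponse(np.r_[surv0.time, surv0.time], np.r_[surv0.event, surv0.event])
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        stat, p = logrank_test(labels, surv)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariant(self, rng):
        surv = make_survival(rng, 40)
        labels = (rng.random(40) < 0.5).astype(int)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        s1, p1 = logrank_test(labels, surv)
        s2, p2 = logrank_test(1 - labels, surv)
        assert s1 == pytest.approx(s2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_hand_worked_example(self):
        # 10 patients; observed/expected table computed step by step below
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0])
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0])
        surv = SurvivalResponse(time, event)
        o_minus_e, var = 0.0, 0.0
        for t in time[event == 1]:
            at_risk = time >= t
            nk, n1k = at_risk.sum(), (at_risk & (labels == 1)).sum()
            dk = ((time == t) & (event == 1)).sum()
            d1k = ((time == t) & (event == 1) & (labels == 1)).sum()
            o_minus_e += d1k - dk * n1k / nk
            var += dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
        from scipy import stats

        stat, p = logrank_test(labels, surv)
        assert stat == pytest.approx(o_minus_e**2 / var, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(o_minus_e**2 / var, 1), abs=1e-12)

    def test_matches_sksurv(self, rng):
        from sksurv.compare import compare_survival

        surv = make_survival(rng, 60)
        labels = (rng.random(60) < 0.5).astype(int)
        stat, p = logrank_test(labels, surv)
        y = np.array(
            [(bool(e), t) for e, t in zip(surv.event, surv.time)],
            dtype=[("e", bool), ("t", float)],
        )
        chi2_ref, p_ref = compare_survival(y, labels)
        assert stat == pytest.approx(chi2_ref, rel=1e-8)
        assert p == pytest.approx(p_ref, rel=1e-8)

    def test_empty_group_rejected(self, rng):
        surv = make_survival(rng, 10)
        with pytest.raises(ValueError, match="nonempty"):
            logrank_test(np.zeros(10, int), surv)


class TestPiLrt:
    def test_constant_pi_errors(self, rng):
        surv = make_survival(rng, 20)
        with pytest.raises(ValueError, match="constant"):
            pi_lrt(np.ones(20), surv)

    def test_strong_signal_power(self):
        rejections = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            pi = rng.standard_normal(100)
            surv = make_survival(rng, 100, eta=1.5 * pi)
            if pi_lrt(pi, surv) < 0.001:
                rejections += 1
        assert rejections >= 0.95 * reps

    def test_null_uniformity_quick(self):
        # full calibration lives in the acceptance suite; smoke-level here
        ps = []
        for rep in range(100):
            rng = np.random.default_rng(900 + rep)
            surv = make_survival(rng, 100)
            ps.append(pi_lrt(rng.standard_normal(100), surv))
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.0 <= frac <= 0.12


class TestBreslowBaseline:
    def test_zero_coefficients_reduce_to_nelson_aalen(self, rng):
        surv = make_survival(rng, 25)
        inp = RiskModelInput(rng.standard_normal((25, 2)), np.empty((25, 0)), surv)
        fit = fit_penalized_cox(inp, "l2", 1e10)  # beta ~ 0
        fit.beta[:] = 0.0
        bh = breslow_baseline(fit, inp)
        # oracle: Nelson-Aalen sum d_k / n_k
        t_sorted = np.unique(surv.time[surv.event == 1])
        na = np.cumsum(
            [((surv.time == t) & (surv.event == 1)).sum() / (surv.time >= t).sum() for t in t_sorted]
        )
        np.testing.assert_allclose(bh.cumulative_hazard, na, atol=1e-12)

    def test_single_event_one_step(self):
        surv = SurvivalResponse(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 0, 0, 0]))
        inp = RiskModelInput(np.zeros((4, 1)), np.empty((4, 0)), surv)
        fit = fit_penalized_cox(inp, "l2", 1e10)
        fit.beta[:] = 0.0
        bh = breslow_baseline(fit, inp)
        assert bh(1.0) == pytest.approx(0.25)
        assert bh(0.5) == pytest.approx(0.0)

    def test_matches_enumeration(self, rng):
        surv = make_survival(rng, 15)
        inp = RiskModelInput(rng.standard_normal((15, 2)), np.empty((15, 0)), surv)
        fit = fit_penalized_cox(inp, "none", 0.0)
        bh = breslow_baseline(fit, inp)
        eta = inp.X @ fit.beta
        for t in np.unique(surv.time[surv.event == 1]):
            expected = sum(
                ((surv.time == tk) & (surv.event == 1)).sum() / np.exp(eta[surv.time >= tk]).sum()
                for tk in np.unique(surv.time[surv.event == 1])
                if tk <= t
            )
            assert bh(t) == pytest.approx(expected, abs=1e-10)


class TestPredictSurvival:
    def _fit(self, rng, n=20):
        surv = make_survival(rng, n)
        inp = RiskModelInput(rng.standard_normal((n, 2)), np.empty((n, 0)), surv)
        fit = fit_penalized_cox(inp, "l2", 1.0)
        return fit, inp, breslow_baseline(fit, inp)

    def test_time_zero_is_one(self, rng):
        fit, inp, bh = self._fit(rng)
        S = predict_survival(fit, bh, inp.X, inp.Z, 0.0)
        np.testing.assert_allclose(S, 1.0)

    def test_baseline_patient(self, rng):
        fit, inp, bh = self._fit(rng)
        t = float(np.median(inp.survival.time))
        S = predict_survival(fit, bh, np.zeros((1, 2)), np.empty((1, 0)), t)
        assert S[0] == pytest.approx(np.exp(-bh(t)))

    def test_monotone_in_time_and_eta(self, rng):
        fit, inp, bh = self._fit(rng)
        ts = np.linspace(0, inp.survival.time.max(), 25)
        S = predict_survival(fit, bh, inp.X, inp.Z, ts)
        assert np.all(np.diff(S, axis=1) <= 1e-12)
        eta = inp.X @ fit.beta
        order = np.argsort(eta)
        t_mid = ts[len(ts) // 2]
        S_mid = predict_survival(fit, bh, inp.X, inp.Z, t_mid)
        assert np.all(np.diff(S_mid[order]) <= 1e-12)


class TestKmCensoring:
    def test_no_censoring_identity(self, rng):
        time = rng.uniform(1, 5, 12)
        surv = SurvivalResponse(time, np.ones(12, int))
        G = km_censoring(surv)
        np.testing.assert_allclose(G(np.sort(time)), 1.0)

    def test_all_censored_is_plain_km(self, rng):
        time = np.sort(rng.uniform(1, 5, 6))
        surv = SurvivalResponse(time, np.zeros(6, int))
        # can't build SurvivalResponse? zero events is fine for KM itself
        G = km_censoring(surv)
        # oracle: ordinary product-limit over distinct censoring times
        expected = np.cumprod([1 - 1 / (6 - i) for i in range(6)])
        np.testing.assert_allclose(G(time), expected, atol=1e-12)

    def test_hand_computed_mixed(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 0, 0, 1])
        surv = SurvivalResponse(time, event)
        G = km_censoring(surv)
        # censorings at t=2 (n=5), t=4 (n=3), t=5 (n=2)
        assert G(1.5) == pytest.approx(1.0)
        assert G(2.0) == pytest.approx(4 / 5)
        assert G(4.5) == pytest.approx(4 / 5 * 2 / 3)
        assert G(5.0) == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)
        assert G.left(2.0) == pytest.approx(1.0)
        assert G.left(4.0) == pytest.approx(4 / 5)


class TestBrierScore:
    def test_zero_at_time_zero(self, rng):
        surv = make_survival(rng, 10)
        G = km_censoring(surv)
        assert brier_score(0.0, surv, np.ones(10), G) == pytest.approx(0.0)

    def test_constant_half_uncensored(self, rng):
        time = rng.uniform(1, 5, 20)
        surv = SurvivalResponse(time, np.ones(20, int))
        G = km_censoring(surv)
        t = float(np.median(time))
        assert brier_score(t, surv, np.full(20, 0.5), G) == pytest.approx(0.25)

    def test_spreadsheet_oracle_with_censoring(self):
        time = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
        event = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        surv = SurvivalResponse(time, event)
        G = km_censoring(surv)
        rng = np.random.default_rng(0)
        s_hat = rng.uniform(0.1, 0.9, 8)
        t = 2.2
        total = 0.0
        for i in range(8):
            if time[i] <= t and event[i] == 1:
                total += s_hat[i] ** 2 / G.left(time[i])
            elif time[i] > t:
                total += (1 - s_hat[i]) ** 2 / G(t)
        assert brier_score(t, surv, s_hat, G) == pytest.approx(total / 8, abs=1e-12)

    def test_km_null_model_binomial_variance(self, rng):
        # uncensored data, S-hat = empirical survivor fraction -> p(1-p)
        time = rng.uniform(1, 10, 50)
        surv = SurvivalResponse(time, np.ones(50, int))
        G = km_censoring(surv)
        t = float(np.median(time))
        p_surv = np.mean(time > t)
        bs = brier_score(t, surv, np.full(50, p_surv), G)
        assert bs == pytest.approx(p_surv * (1 - p_surv), abs=1e-12)

    def test_perfect_oracle_predictions_zero(self, rng):
        time = rng.uniform(1, 10, 30)
        surv = SurvivalResponse(time, np.ones(30, int))
        G = km_censoring(surv)
        for t in np.quantile(time, [0.25, 0.5, 0.75]):
            s_hat = (time > t).astype(float)
            assert brier_score(float(t), surv, s_hat, G) == pytest.approx(0.0)

    def test_g_zero_errors(self):
        # a G estimated on the scored set can only hit 0 when nobody remains
        # at risk, so exercise the guard with an external G
        from gosurv.evaluate import CensoringDistribution

        surv = SurvivalResponse(np.array([1.0, 5.0]), np.array([1, 0]))
        G = CensoringDistribution(np.array([2.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="smaller t"):
            brier_score(3.0, surv, np.array([0.5, 0.5]), G)


class TestIntegratedBrierScore:
    def test_constant_curve(self):
        curve = PredictionErrorCurve(np.array([0.0, 5.0, 10.0]), np.array([0.3, 0.3, 0.3]))
        assert integrated_brier_score(curve, 10.0) == pytest.approx(0.3)

    def test_linear_curve(self):
        t = np.linspace(0, 10, 101)
        curve = PredictionErrorCurve(t, t / 10.0)
        assert integrated_brier_score(curve, 10.0) == pytest.approx(0.5, abs=1e-6)

    def test_step_curve_exact(self):
        # step function represented with near-duplicate abscissae at jumps
        eps = 1e-9
        t = np.array([0.0, 4.0, 4.0 + eps, 10.0])
        bs = np.array([0.2, 0.2, 0.4, 0.4])
        curve = PredictionErrorCurve(t, bs)
        exact = (0.2 * 4 + 0.4 * 6) / 10
        assert integrated_brier_score(curve, 10.0) == pytest.approx(exact, abs=1e-8)

    def test_grid_refinement_invariant(self, rng):
        t = np.sort(rng.uniform(0, 10, 8))
        t = np.unique(np.r_[0.0, t, 10.0])
        bs = rng.uniform(0, 0.5, len(t))
        curve = PredictionErrorCurve(t, bs)
        v1 = integrated_brier_score(curve, 10.0)
        # refine by inserting linear-interpolation points: integral unchanged
        mids = (t[:-1] + t[1:]) / 2
        t2 = np.sort(np.r_[t, mids])
        curve2 = PredictionErrorCurve(t2, np.interp(t2, t, bs))
        assert integrated_brier_score(curve2, 10.0) == pytest.approx(v1, abs=1e-12)

    def test_short_curve_errors(self):
        curve = PredictionErrorCurve(np.array([0.0, 5.0]), np.array([0.1, 0.1]))
        with pytest.raises(ValueError, match="t\\*"):
            integrated_brier_score(curve, 10.0)


class TestPredictionErrorCurve:
    def test_single_curve_identity(self):
        c = PredictionErrorCurve(np.array([0.0, 1.0]), np.array([0.1, 0.2]))
        avg = prediction_error_curve([c])
        np.testing.assert_allclose(avg.bs, c.bs)

    def test_identical_curves(self):
        c = PredictionErrorCurve(np.array([0.0, 1.0, 2.0]), np.array([0.1, 0.2, 0.15]))
        avg = prediction_error_curve([c, c])
        np.testing.assert_allclose(avg.bs, c.bs)

    def test_mean_oracle(self, rng):
        curves = []
        for _ in range(4):
            t = np.unique(np.r_[0.0, np.sort(rng.uniform(0, 10, 6))])
            curves.append(PredictionErrorCurve(t, rng.uniform(0, 0.5, len(t))))
        avg = prediction_error_curve(curves)
        grid = np.unique(np.concatenate([c.time for c in curves]))
        oracle = np.mean([c.at(grid) for c in curves], axis=0)
        np.testing.assert_allclose(avg.bs, oracle, atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            prediction_error_curve([])
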