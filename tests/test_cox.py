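"""Cox engine: closed forms, brute-force oracles, invariances, and the
lifelines cross-check."""

import numpy as np
import pandas as pd
import pytest

from coxmediate.cox import ConvergenceError, fit_cox, schoenfeld_test

from conftest import simulate_ph_data


def brute_force_loglik(beta, time, event, x):
    """Independent O(n^2) Breslow/Efron partial log-likelihood for a single
    covariate with distinct event times (the two coincide there)."""
    ll = 0.0
    for i in np.nonzero(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestFitCox:
    def test_null_model_loglik_closed_form(self):
        # with no ties and beta-free model, loglik = -sum over events of
        # ln(risk-set size); check against a one-covariate fit at beta ~ 0
        rng = np.random.default_rng(1)
        n = 40
        time = rng.uniform(1, 10, n)
        event = rng.binomial(1, 0.5, n).astype(float)
        event[:3] = 1
        expected = -sum(
            np.log((time >= time[i]).sum()) for i in np.nonzero(event == 1)[0]
        )
        x = rng.normal(size=n)
        fit = fit_cox(time, event, x[:, None])
        assert fit.null_loglik == pytest.approx(expected, abs=1e-10)

    def test_six_subject_grid_oracle(self):
        # tiny fixture with distinct event times; grid search of the
        # brute-force partial likelihood is the independent oracle
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 1], dtype=float)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        grid = np.linspace(-3, 3, 60001)
        lls = [brute_force_loglik(b, time, event, x) for b in grid]
        oracle = grid[int(np.argmax(lls))]
        fit = fit_cox(time, event, x[:, None])
        assert fit.coefficients[0] == pytest.approx(oracle, abs=1e-4)

    def test_beta_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        beta = np.log(1.5)
        time, event, X = simulate_ph_data(rng, 5000, [beta])
        fit = fit_cox(time, event, X)
        assert abs(fit.coefficients[0] - beta) < 3 * fit.standard_errors[0]

    def test_efron_breslow_agree_without_ties(self):
        rng = np.random.default_rng(2)
        time, event, X = simulate_ph_data(rng, 400, [0.4, -0.2])
        fe = fit_cox(time, event, X, ties="efron")
        fb = fit_cox(time, event, X, ties="breslow")
        assert np.allclose(fe.coefficients, fb.coefficients, atol=1e-10)
        assert fe.partial_loglik == pytest.approx(fb.partial_loglik, abs=1e-10)

    def test_matches_lifelines_with_heavy_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        time, event, X = simulate_ph_data(rng, 800, [0.5, -0.3])
        time = np.ceil(time)  # year-resolution ties
        fit = fit_cox(time, event, X)
        df = pd.DataFrame({"t": time, "e": event, "x0": X[:, 0], "x1": X[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coefficients, cph.params_.values, atol=1e-6)
        assert np.allclose(fit.standard_errors, cph.standard_errors_.values, atol=1e-6)

    def test_hr_invariants(self):
        rng = np.random.default_rng(4)
        time, event, X = simulate_ph_data(rng, 300, [0.3])
        fit = fit_cox(time, event, X)
        assert np.allclose(fit.hr, np.exp(fit.coefficients), atol=1e-12)
        assert fit.hr_ci95[0, 0] <= fit.hr[0] <= fit.hr_ci95[0, 1]
        assert fit.n_events <= fit.n_used

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        time, event, X = simulate_ph_data(rng, 500, [0.4])
        base = fit_cox(time, event, X)
        shifted = fit_cox(time, event, X + 7.0)
        scaled = fit_cox(time, event, X * 2.5)
        assert shifted.coefficients[0] == pytest.approx(base.coefficients[0], abs=1e-7)
        assert scaled.coefficients[0] == pytest.approx(base.coefficients[0] / 2.5, abs=1e-7)

    def test_error_cases(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        with pytest.raises(ValueError, match="at least one event"):
            fit_cox(time, np.zeros(4), x)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_cox(time, np.array([1, 0, 1, 0.0]), np.ones((4, 1)))
        # complete separation: the binary covariate perfectly orders events
        t = np.arange(1.0, 21.0)
        e = np.ones(20)
        xsep = (t <= 10).astype(float)[:, None]
        with pytest.raises(ConvergenceError):
            fit_cox(t, e, xsep)


class TestSchoenfeld:
    def test_requires_three_events(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1.0, 1.0, 0.0, 0.0])
        x = np.array([[0.1], [0.9], [0.4], [0.6]])
        fit = fit_cox(time, event, x)
        with pytest.raises(ValueError, match="fewer than 3 events"):
            schoenfeld_test(fit, time, event, x)

    def test_detects_reversing_effect(self):
        # effect flips sign at the median time: a strong PH violation
        rng = np.random.default_rng(6)
        hits = 0
        reps = 25
        for _ in range(reps):
            n = 2000
            x = rng.normal(size=n)
            # piecewise hazard: beta=+0.8 before t=5, -0.8 after
            u = rng.uniform(size=n)
            rate = 0.08
            t1 = -np.log(u) / (rate * np.exp(0.8 * x))
            t = np.where(t1 <= 5, t1, 5 - np.log(rng.uniform(size=n)) / (rate * np.exp(-0.8 * x)))
            c = rng.uniform(4, 16, n)
            time = np.minimum(t, c)
            event = (t <= c).astype(float)
            fit = fit_cox(time, event, x[:, None])
            res = schoenfeld_test(fit, time, event, x[:, None])
            hits += res.p[0] < 0.05
        assert hits / reps >= 0.8

    def test_agrees_with_lifelines_rank_test(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import proportional_hazard_test

        rng = np.random.default_rng(7)
        time, event, X = simulate_ph_data(rng, 1200, [0.5, -0.2])
        fit = fit_cox(time, event, X)
        res = schoenfeld_test(fit, time, event, X)
        df = pd.DataFrame({"t": time, "e": event, "x0": X[:, 0], "x1": X[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        ll = proportional_hazard_test(cph, df, time_transform="rank")
        # variance estimators differ in detail; agreement to ~0.05 in p
        assert np.allclose(res.p, ll.summary["p"].values, atol=0.05)
        assert np.all(np.abs(res.rho) <= 1)
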