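"""Cox engine, scan, multiplicity and diagnostics tests.

The engine is checked against two independent routes: a brute-force
maximization of a naively-coded Efron partial likelihood on tiny data, and
lifelines on moderate data with ties.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from glycoprog.survival import (
    CoxError, ModelSpec, association_scan, bh_adjust, build_design,
    cox_partial_loglik, crc_outcome_view, fit_cox, fit_cox_records,
    linearity_check, ph_diagnostics, predict_risk,
)
from glycoprog.synthetic import GeneratorConfig, simulate_trait_scan


def naive_efron_loglik(beta, x, time, event):
    """Straight-from-the-definition Efron partial likelihood (single covariate)."""
    ll = 0.0
    for t in sorted(set(time[event])):
        tied = np.flatnonzero((time == t) & event)
        risk = np.flatnonzero(time >= t)
        s_risk = np.exp(beta * x[risk]).sum()
        s_tied = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        d = len(tied)
        for l in range(d):
            ll -= np.log(s_risk - l / d * s_tied)
    return ll


def oracle_coef(x, time, event, bound=10.0):
    """Grid bracket + scalar maximization of the naive partial likelihood."""
    grid = np.linspace(-bound, bound, 81)
    values = [naive_efron_loglik(b, x, time, event) for b in grid]
    i = int(np.argmax(values))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda b: -naive_efron_loglik(b, x, time, event),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestEngine:
    def test_matches_brute_force_on_four_patients(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([True, True, True, True])
        fit = fit_cox(x.reshape(-1, 1), time, event)
        assert fit.coef[0] == pytest.approx(oracle_coef(x, time, event),
                                            abs=1e-6)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        X = rng.normal(size=(n, 3))
        t = np.round(rng.exponential(np.exp(-(X @ [0.5, -0.3, 0.0]))), 1) + 0.1
        e = rng.uniform(size=n) < 0.7
        fit = fit_cox(X, t, e, ["a", "b", "c"])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(),
                                   atol=1e-6)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, rel=1e-9)

    def test_duplication_leaves_coef_halves_se(self, rng):
        n = 200
        X = rng.normal(size=(n, 1))
        t = rng.exponential(np.exp(-0.4 * X[:, 0]))
        e = rng.uniform(size=n) < 0.8
        fit1 = fit_cox(X, t, e)
        fit2 = fit_cox(np.vstack([X, X]), np.concatenate([t, t]),
                       np.concatenate([e, e]))
        # duplication creates ties, so Efron invariance is asymptotic
        assert fit2.coef[0] == pytest.approx(fit1.coef[0], rel=0.01)
        assert fit2.se[0] / fit1.se[0] == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_constant_covariate_rejected(self):
        with pytest.raises(CoxError, match="constant"):
            fit_cox(np.zeros((5, 1)), np.arange(1.0, 6.0), np.ones(5, bool))

    def test_no_events_rejected(self):
        with pytest.raises(CoxError, match="no events"):
            fit_cox(np.random.default_rng(0).normal(size=(5, 1)),
                    np.arange(1.0, 6.0), np.zeros(5, bool))

    def test_separation_detected_and_named(self):
        t = np.arange(1.0, 9.0)
        x = -t  # risk perfectly orders failure times -> monotone likelihood
        with pytest.raises(CoxError, match="separation.*x0"):
            fit_cox(x.reshape(-1, 1), t, np.ones(8, bool))

    def test_partial_loglik_helper_consistent(self, rng):
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(size=n)
        e = rng.uniform(size=n) < 0.6
        assert cox_partial_loglik(np.array([0.3]), x.reshape(-1, 1), t, e) == (
            pytest.approx(naive_efron_loglik(0.3, x, t, e))
        )


class TestOutcomeViews:
    @staticmethod
    def _records():
        return pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "stage": [2, 3, 4], "time": [2.0, 3.0, 4.0],
            "event_all": [1, 1, 0], "event_crc": [0, 1, 0],
        })

    def test_other_cause_death_censored_in_crc_view(self):
        view = crc_outcome_view(self._records())
        assert view.loc[0, "event"] == 0 and view.loc[0, "time"] == 2.0

    def test_crc_death_is_event_in_both_views(self):
        view = crc_outcome_view(self._records())
        assert view.loc[1, "event"] == 1

    def test_censored_stays_censored(self):
        view = crc_outcome_view(self._records())
        assert view.loc[2, "event"] == 0


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_q_dominates_p_and_capped(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and q.max() <= 1.0

    def test_matches_hand_coded_step_up(self, rng):
        p = rng.uniform(size=25)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestScan:
    def test_empty_trait_list(self):
        _, rec, _ = simulate_trait_scan(n=60, n_traits=2, seed=0)
        out = association_scan(pd.DataFrame(index=rec.index), rec,
                               ModelSpec("I", "all"))
        assert out.empty

    def test_planted_trait_has_smallest_p(self):
        wins = 0
        for s in range(5):
            traits, rec, _ = simulate_trait_scan(n=800, n_traits=10, seed=40 + s)
            scan = association_scan(traits, rec, ModelSpec("I", "all", "whole",
                                                           "none"))
            ok = scan[scan["status"] == "ok"]
            wins += ok.loc[ok["p"].idxmin(), "trait"] == "T01"
        assert wins >= 4

    def test_null_pvalues_uniform(self):
        traits, rec, _ = simulate_trait_scan(n=600, n_traits=39,
                                             planted_log_hr=0.0, seed=7)
        scan = association_scan(traits, rec, ModelSpec("I", "all", "whole",
                                                       "none"))
        ps = scan.loc[scan["status"] == "ok", "p"]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_stage_dummy_dropped_within_stratum(self):
        spec = ModelSpec("II", "all", "stage4")
        assert "stage" not in spec.covariates
        assert "age" in spec.covariates

    def test_crc_scan_has_fewer_events(self):
        traits, rec, _ = simulate_trait_scan(n=400, n_traits=3, seed=1)
        s_all = association_scan(traits, rec, ModelSpec("I", "all"))
        s_crc = association_scan(traits, rec, ModelSpec("I", "crc"))
        assert (s_crc["n_events"] <= s_all["n_events"]).all()


class TestDiagnostics:
    @staticmethod
    def _fit_exp(n, rng, beta=0.5):
        x = rng.normal(size=(n, 1))
        t = rng.exponential(np.exp(-beta * x[:, 0]))
        e = rng.uniform(size=n) < 0.8
        return fit_cox(x, t, e), x, t, e

    def test_ph_null_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 200
        for _ in range(reps):
            fit, x, t, e = self._fit_exp(120, rng)
            p = ph_diagnostics(fit, x, t, e).iloc[0]
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.10

    def test_ph_detects_sign_flip(self):
        rng = np.random.default_rng(3)
        detected = 0
        for _ in range(6):
            n = 1000
            x = rng.normal(size=(n, 1))
            # hazard ratio e^x before t0, e^-x after: piecewise inverse cdf
            u = rng.exponential(size=n)
            t0 = 0.7
            w = np.exp(x[:, 0])
            early = u / w
            t = np.where(early <= t0, early, t0 + (u - t0 * w) * w)
            e = np.ones(n, bool)
            fit = fit_cox(x, t, e)
            detected += ph_diagnostics(fit, x, t, e).iloc[0] < 0.05
        assert detected >= 4

    def test_single_event_undefined(self):
        x = np.array([[0.0], [1.0]])
        with pytest.raises(CoxError):
            fit = fit_cox(np.array([[0.0], [1.0], [2.0]]),
                          np.array([1.0, 2.0, 3.0]),
                          np.array([True, True, False]))
            ph_diagnostics(fit, x, np.array([1.0, 2.0]),
                           np.array([True, False]))

    def test_linearity_flags_quadratic_effect(self):
        rng = np.random.default_rng(5)
        n = 800
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-(x**2)))
        rec = pd.DataFrame({"sample_id": [str(i) for i in range(n)], "x": x,
                            "stage": 2, "time": t, "event_all": 1,
                            "event_crc": 1})
        assert linearity_check(rec, "x") < 0.01


class TestPrediction:
    def test_zero_coefficient_gives_uniform_risk(self, rng):
        n = 200
        x = rng.normal(size=(n, 1))
        t = rng.exponential(size=n)
        e = rng.uniform(size=n) < 0.7
        fit = fit_cox(x, t, e)
        fit.coef[:] = 0.0
        p = predict_risk(fit, x, 1.0)
        assert np.ptp(p) < 1e-12

    def test_risk_monotone_in_linear_predictor(self, rng):
        n = 300
        x = rng.normal(size=(n, 1))
        t = rng.exponential(np.exp(-0.8 * x[:, 0]))
        e = np.ones(n, bool)
        fit = fit_cox(x, t, e)
        p = predict_risk(fit, x, 2.0)
        order = np.argsort(fit.linear_predictor(x))
        assert (np.diff(p[order]) >= -1e-15).all()

    def test_matches_nelson_aalen_for_exponential_data(self, rng):
        n = 2000
        lam = 0.5
        t = rng.exponential(1 / lam, size=n)
        e = np.ones(n, bool)
        x = rng.normal(size=(n, 1))  # a covariate with no true effect
        fit = fit_cox(x, t, e)
        horizon = 1.5
        p = predict_risk(fit, np.zeros((1, 1)), horizon)[0]
        # Nelson-Aalen of the same data
        order = np.argsort(t)
        na = np.cumsum(1.0 / (n - np.arange(n)))
        h_na = na[np.searchsorted(t[order], horizon, side="right") - 1]
        assert p == pytest.approx(1 - np.exp(-h_na), rel=0.02)

    def test_horizon_beyond_data_uses_last_step(self, rng):
        n = 50
        x = rng.normal(size=(n, 1))
        t = rng.exponential(size=n)
        e = np.ones(n, bool)
        fit = fit_cox(x, t, e)
        assert np.allclose(predict_risk(fit, x, 1e9),
                           predict_risk(fit, x, t.max()))


def test_complete_case_dropping_logged_in_fit(small_cohort):
    clin = small_cohort.clinical
    fit = fit_cox_records(clin, ("age", "sex", "stage", "bmi"), outcome="all")
    assert fit.n + fit.n_dropped == len(clin)
    assert fit.n_dropped == clin["bmi"].isna().sum()


def test_design_matrix_dummy_coding(small_cohort):
    d = build_design(small_cohort.clinical, ("age", "sex", "stage", "op_type"))
    assert {"stage_2", "stage_3", "stage_4", "sex", "age"} <= set(d.columns)
    assert d.filter(like="op_type_").shape[1] == 2  # 3 levels -> 2 dummies
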