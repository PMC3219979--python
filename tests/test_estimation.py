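import numpy as np
import pandas as pd
import pytest

from remisim import (
    EstimationError,
    WeibullParams,
    bootstrap_weibull,
    estimate_constant_hazard,
    estimate_model_parameters,
    estimate_zero_dwell_fraction,
    fit_weibull_censored,
    mean_daily_doses,
    weibull_loglik,
)
from remisim.estimation import DoseRecord


def draw_weibull(L, p, n, rng):
    return rng.exponential(size=n) ** (1.0 / p) / L


def grid_search_loglik(times, events, span=2.5, coarse=60, refinements=4):
    """Independent oracle: nested grid search of the censored log-likelihood
    over (log L, log p), refined to ~1e-4 spacing in log space."""
    a0 = np.log(events.sum() / times.sum())
    a_lo, a_hi = a0 - span, a0 + span
    b_lo, b_hi = -1.5, 1.5
    best = (-np.inf, None, None)
    for _ in range(refinements):
        aa = np.linspace(a_lo, a_hi, coarse)
        bb = np.linspace(b_lo, b_hi, coarse)
        for a in aa:
            for b in bb:
                ll = weibull_loglik(a, b, times, events)
                if ll > best[0]:
                    best = (ll, a, b)
        da, db = (a_hi - a_lo) / (coarse - 1), (b_hi - b_lo) / (coarse - 1)
        a_lo, a_hi = best[1] - 2 * da, best[1] + 2 * da
        b_lo, b_hi = best[2] - 2 * db, best[2] + 2 * db
    return best[0]


class TestWeibullFit:
    def test_matches_grid_search_oracle(self):
        """MLE log-likelihood is never beaten by a brute-force grid search."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 51))
            L, p = rng.uniform(0.005, 0.1), rng.uniform(0.6, 2.5)
            t = draw_weibull(L, p, n, rng)
            e = rng.random(n) > 0.3  # ~30% censored
            if e.sum() < 2:
                e[:2] = True
            fit = fit_weibull_censored(list(zip(t, e)))
            ll_opt = weibull_loglik(np.log(fit.L), np.log(fit.p), t, e)
            ll_grid = grid_search_loglik(t, e)
            assert ll_opt >= ll_grid - 1e-6

    def test_exponential_subcase_closed_form(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(50.0, size=200)
        e = np.ones(200, dtype=bool)
        fit = fit_weibull_censored(list(zip(t, e)), fix_p=1.0)
        assert fit.L == pytest.approx(len(t) / t.sum(), rel=1e-6)
        assert fit.p == 1.0

    def test_parameter_recovery_uncensored(self):
        rng = np.random.default_rng(42)
        t = draw_weibull(0.01, 1.5, 5000, rng)
        fit = fit_weibull_censored(list(zip(t, np.ones(5000, bool))))
        assert fit.L == pytest.approx(0.01, rel=0.05)
        assert fit.p == pytest.approx(1.5, rel=0.05)

    def test_parameter_recovery_with_fixed_censoring(self):
        rng = np.random.default_rng(7)
        t_true = draw_weibull(0.005, 2.0, 10_000, rng)
        c = np.quantile(t_true, 0.5)  # ~50% censored at a fixed time
        e = t_true <= c
        t = np.minimum(t_true, c)
        fit = fit_weibull_censored(list(zip(t, e)))
        assert fit.L == pytest.approx(0.005, rel=0.05)
        assert fit.p == pytest.approx(2.0, rel=0.05)

    def test_mean_relative_bias_below_two_percent(self):
        """Consistency: over 20 seeded replications at n = 5000 the mean
        relative bias of both parameters stays below 2%."""
        errs_L, errs_p = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            t = draw_weibull(0.02, 1.2, 5000, rng)
            fit = fit_weibull_censored(list(zip(t, np.ones(5000, bool))))
            errs_L.append(fit.L / 0.02 - 1.0)
            errs_p.append(fit.p / 1.2 - 1.0)
        assert abs(np.mean(errs_L)) < 0.02
        assert abs(np.mean(errs_p)) < 0.02

    def test_agrees_with_lifelines(self):
        """Independent cross-check against lifelines' censored Weibull MLE
        (their scale lambda is 1/L, their shape rho is p)."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        t_true = draw_weibull(0.015, 1.4, 800, rng)
        c = rng.uniform(20, 200, size=800)
        e = t_true <= c
        t = np.minimum(t_true, c)
        fit = fit_weibull_censored(list(zip(t, e)))
        wf = lifelines.WeibullFitter().fit(t, event_observed=e)
        assert fit.L == pytest.approx(1.0 / wf.lambda_, rel=1e-3)
        assert fit.p == pytest.approx(wf.rho_, rel=1e-3)

    def test_too_few_events_rejected(self):
        with pytest.raises(EstimationError):
            fit_weibull_censored([(5.0, True), (3.0, False), (2.0, False)])

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull_censored([(0.0, True), (3.0, True)])


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        t = draw_weibull(0.02, 1.3, 120, rng)
        dwells = list(zip(t, np.ones(120, bool)))
        a = bootstrap_weibull(dwells, B=150, seed=9)
        b = bootstrap_weibull(dwells, B=150, seed=9)
        assert (a.L, a.p, a.se_L, a.se_p, a.corr_Lp) == (b.L, b.p, b.se_L, b.se_p, b.corr_Lp)

    def test_degenerate_data_zero_spread(self):
        # identical observations with fixed shape: every resample refits to
        # the same rate, so the bootstrap spread collapses to zero
        dwells = [(10.0, True)] * 40
        out = bootstrap_weibull(dwells, B=100, seed=1, fix_p=1.0)
        assert out.se_L == pytest.approx(0.0, abs=1e-12)
        assert out.se_p == 0.0 and out.corr_Lp == 0.0

    def test_matches_analytic_exponential_se(self):
        rng = np.random.default_rng(21)
        n = 1500
        t = rng.exponential(40.0, size=n)
        dwells = list(zip(t, np.ones(n, bool)))
        out = bootstrap_weibull(dwells, B=250, seed=2, fix_p=1.0)
        analytic = out.L / np.sqrt(n)  # exponential MLE SE
        assert out.se_L == pytest.approx(analytic, rel=0.20)

    def test_correlation_within_bounds(self):
        rng = np.random.default_rng(8)
        t = draw_weibull(0.05, 0.8, 150, rng)
        out = bootstrap_weibull(list(zip(t, np.ones(150, bool))), B=120, seed=3)
        assert -1.0 <= out.corr_Lp <= 1.0
        assert out.se_L > 0 and out.se_p > 0


class TestSimpleEstimators:
    @pytest.mark.parametrize("events, exposure, expected", [
        (0, 500.0, 0.0),
        (10, 10_000.0, 1.0 - np.exp(-0.001)),
    ])
    def test_constant_hazard_closed_form(self, events, exposure, expected):
        assert estimate_constant_hazard(events, exposure) == pytest.approx(expected, rel=1e-12)

    def test_constant_hazard_round_trip(self):
        """Simulating with the estimated hourly probability reproduces the
        observed event count in expectation."""
        q = estimate_constant_hazard(10, 10_000.0)
        rng = np.random.default_rng(0)
        events = (rng.random(10_000) < q).sum()
        assert abs(events - 10) <= 3 * np.sqrt(10)

    def test_constant_hazard_domain(self):
        with pytest.raises(ValueError):
            estimate_constant_hazard(-1, 100.0)
        with pytest.raises(ValueError):
            estimate_constant_hazard(1, 0.0)

    def test_zero_dwell_fraction_counting(self):
        assert estimate_zero_dwell_fraction([0, 0, 5, 12]) == 0.5
        assert estimate_zero_dwell_fraction([0.0, 0.0]) == 1.0

    def test_zero_dwell_fraction_recovery(self):
        rng = np.random.default_rng(4)
        zero = rng.random(10_000) < 0.3
        d = np.where(zero, 0.0, rng.exponential(5.0, 10_000))
        assert estimate_zero_dwell_fraction(d) == pytest.approx(0.3, abs=0.02)


class TestMeanDailyDoses:
    def test_single_and_pair(self):
        recs = [DoseRecord("a", "CS", "before_weaning", "morphine", 70.0)]
        out = mean_daily_doses(recs)
        assert out.loc[0, "mean"] == 70.0 and out.loc[0, "se"] == 0.0
        recs = [DoseRecord("a", "CS", "before_weaning", "morphine", 60.0),
                DoseRecord("b", "CS", "before_weaning", "morphine", 80.0)]
        out = mean_daily_doses(recs)
        assert out.loc[0, "mean"] == pytest.approx(70.0)
        assert out.loc[0, "se"] == pytest.approx(10.0)

    def test_recovers_generator_target(self):
        # lognormal cohort calibrated to the published CS before-weaning
        # morphine mean 71.7 (SE 17.8 at n=109)
        rng = np.random.default_rng(12)
        mean, sd = 71.7, 17.8 * np.sqrt(109)
        s2 = np.log1p((sd / mean) ** 2)
        draws = rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), size=109)
        recs = pd.DataFrame({"patient_id": np.arange(109), "arm": "CS",
                             "phase": "before_weaning", "drug": "morphine",
                             "total_mg_per_day": draws})
        out = mean_daily_doses(recs)
        assert out.loc[0, "mean"] == pytest.approx(71.7, abs=2 * 17.8)


class TestFullPipeline:
    def test_estimates_all_components(self):
        from remisim import TrialDesign, generate_trial
        phase_df, _ = generate_trial(TrialDesign(), seed=0)
        params = estimate_model_parameters(phase_df)
        assert set(params.progression) == {"s1_CS", "s1_RS", "s3_CS", "s3_RS", "s5"}
        assert set(params.eligible) == {"s2_CS", "s2_RS", "s4_CS", "s4_RS", "s6"}
        assert params.switch_s1 is not None
        assert 0 < params.death_s3.hourly_prob < 0.01

    def test_bootstrap_fills_uncertainty(self):
        from remisim import TrialDesign, generate_trial
        phase_df, _ = generate_trial(TrialDesign(), seed=1)
        params = estimate_model_parameters(phase_df, bootstrap_B=120, seed=2)
        w = params.progression["s1_CS"]
        assert w.se_L > 0 and w.se_p > 0 and -1 <= w.corr_Lp <= 1
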