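import numpy as np
import pandas as pd
import pytest

from remisim import (
    ARM_CS,
    ARM_RS,
    CostParams,
    ExitCause,
    PhaseTransitionSpec,
    WeibullParams,
    accumulate_costs,
    build_transition_table,
    onlabel_subgroup,
    patient_costs,
    run_cohort,
    simulate_cohort_arrays,
    simulate_patient,
)
from remisim.microsim import histories_to_frame, summarize_patients
from conftest import make_exponential_params


def forced_tables(progress_prob=1.0, death_prob=0.0):
    """Transition tables where states 1/3/5 exit with fixed hourly
    probabilities and the eligible states are always skipped."""
    tables = {}
    for arm in (ARM_RS, ARM_CS):
        for state, dest in ((1, 2), (3, 4), (5, 6)):
            exits = [ExitCause("constant_hazard", "progress", dest, hourly_prob=progress_prob)]
            if death_prob:
                exits.insert(0, ExitCause("constant_hazard", "death", 8, hourly_prob=death_prob))
            tables[(state, arm)] = build_transition_table(PhaseTransitionSpec(state, arm, exits))
        for state, dest in ((2, 3), (4, 5), (6, 7)):
            spec = PhaseTransitionSpec(state, arm, [
                ExitCause("zero_dwell_mixture", "progress", dest, zero_fraction=1.0)])
            tables[(state, arm)] = build_transition_table(spec)
    return tables


class TestSimulatePatient:
    def test_forced_path_discharges_at_hour_three(self):
        rng = np.random.default_rng(0)
        h = simulate_patient(ARM_CS, forced_tables(), rng)
        assert h.segments == [(1, 0, 1), (3, 1, 2), (5, 2, 3)]
        assert h.terminal == "discharged"
        assert h.weaning_start_hour == 1
        assert h.los_mv_hours == 2 and h.los_icu_hours == 3

    def test_certain_death_in_first_hour(self):
        rng = np.random.default_rng(0)
        h = simulate_patient(ARM_CS, forced_tables(progress_prob=1e-9, death_prob=1.0), rng)
        assert h.terminal == "death"
        assert h.segments == [(1, 0, 1)]
        assert h.los_icu_hours == 1

    def test_geometric_dwell_mean(self):
        """With a constant hourly exit probability q the dwell in state 1 is
        geometric with mean 1/q."""
        q = 0.05
        tables = forced_tables(progress_prob=q)
        rng = np.random.default_rng(1)
        n = 30_000
        dwells = np.array([simulate_patient(ARM_CS, tables, rng).segments[0][2]
                           for _ in range(n)])
        mc_se = dwells.std() / np.sqrt(n)
        assert dwells.mean() == pytest.approx(1.0 / q, abs=3 * mc_se)

    def test_horizon_censoring(self):
        tables = forced_tables(progress_prob=1e-7)
        rng = np.random.default_rng(2)
        h = simulate_patient(ARM_CS, tables, rng)
        assert h.terminal == "horizon_censored"
        assert h.segments == [(1, 0, 672)]


class TestRunCohort:
    def test_deterministic_under_fixed_seed(self, demo_params, demo_costs):
        a = run_cohort(demo_params, demo_costs, n_per_arm=500, seed=3)
        b = run_cohort(demo_params, demo_costs, n_per_arm=500, seed=3)
        assert a.to_frame().equals(b.to_frame())
        assert a.differences == b.differences

    def test_symmetric_arms_with_common_random_numbers(self, exponential_params, demo_costs):
        """Identical dynamics plus a shared random stream make the arm
        difference exactly zero (sedation rates still differ by arm, so
        costs are compared on the bed-only component)."""
        costs = CostParams()
        for key in costs.sedation_eur_per_hour:
            costs.sedation_eur_per_hour[key].mean = 0.0
        res = run_cohort(exponential_params, costs, n_per_arm=400, seed=5,
                         common_random_numbers=True)
        assert res.differences["los_icu_days"] == 0.0
        assert res.differences["los_mv_days"] == 0.0
        assert res.differences["cost_eur"] == 0.0

    def test_per_patient_invariants(self, demo_params, demo_costs):
        _, patients = run_cohort(demo_params, demo_costs, n_per_arm=2000, seed=7,
                                 return_patients=True)
        assert (patients["los_mv_hours"] <= patients["los_icu_hours"]).all()
        assert (patients["los_icu_hours"] <= 672).all()
        assert (patients.loc[patients["switched"], "arm"] == ARM_RS).all()
        dead = patients["terminal"] == "death"
        assert 0.05 < dead.mean() < 0.30  # plausible ICU mortality

    def test_faster_arm_dominates(self, demo_params, demo_costs):
        """The remifentanil arm's faster early weaning yields positive
        CS-minus-RS differences across independent seeds."""
        for seed in (11, 12, 13):
            res = run_cohort(demo_params, demo_costs, n_per_arm=3000, seed=seed)
            assert res.differences["los_mv_days"] > 0
            assert res.differences["cost_eur"] > 0

    def test_engines_agree_distributionally(self, demo_params, demo_costs):
        """The vectorised cohort engine and the per-patient reference loop
        draw from the same trajectory distribution."""
        tables = demo_params.build_tables()
        rng = np.random.default_rng(17)
        n = 4000
        hist = [simulate_patient(ARM_RS, tables, rng, patient_id=i) for i in range(n)]
        loop_mv = np.array([h.los_mv_hours for h in hist], dtype=float)
        vec = simulate_cohort_arrays(demo_params, ARM_RS, n, np.random.default_rng(18))
        vec_mv = vec["los_mv_hours"].to_numpy(dtype=float)
        se = np.sqrt(loop_mv.var() / n + vec_mv.var() / n)
        assert loop_mv.mean() == pytest.approx(vec_mv.mean(), abs=4 * se)
        sw_loop = np.mean([h.switched_at is not None for h in hist])
        sw_vec = vec["switched"].mean()
        assert sw_loop == pytest.approx(sw_vec, abs=4 * np.sqrt(0.12 * 0.88 * 2 / n))

    def test_accounting_identity_across_modules(self, demo_params, demo_costs):
        """Vectorised per-patient costs equal accumulate_costs applied to the
        same histories segment by segment."""
        tables = demo_params.build_tables()
        rng = np.random.default_rng(19)
        hist = [simulate_patient(arm, tables, rng, patient_id=i)
                for i, arm in enumerate([ARM_RS, ARM_CS] * 150)]
        frame = histories_to_frame(hist)
        vec = patient_costs(frame, demo_costs)
        scalar = np.array([accumulate_costs(h, demo_costs) for h in hist])
        assert np.allclose(vec, scalar, rtol=1e-12)


class TestOnLabelSubgroup:
    def _frame(self, weaning_hours):
        n = len(weaning_hours)
        return pd.DataFrame({
            "arm": [ARM_CS] * n,
            "d1": 10, "d2": 0, "d3": 10, "d4": 0, "d5": 10, "d6": 0,
            "s1_pre_switch": 10, "switched": False, "switch_hour": -1,
            "weaning_start_hour": weaning_hours,
            "terminal": "discharged",
            "los_mv_hours": 20, "los_icu_hours": 30,
            "cost_eur": 100.0,
        })

    def test_boundary_inclusive_at_72_hours(self):
        sub = onlabel_subgroup(self._frame([72, 73, -1]))
        assert sub.per_arm[ARM_CS].n == 1  # hour-72 starter only

    def test_all_early_weaners_equals_full_cohort(self):
        frame = self._frame([1, 1, 1])
        sub = onlabel_subgroup(frame)
        assert sub.per_arm[ARM_CS].n == 3

    def test_empty_subgroup_is_none(self):
        assert onlabel_subgroup(self._frame([-1, 100])) is None

    def test_subgroup_fraction_matches_weaning_cdf(self, demo_params, demo_costs):
        _, patients = run_cohort(demo_params, demo_costs, n_per_arm=4000, seed=23,
                                 return_patients=True)
        cs = patients[patients["arm"] == ARM_CS]
        frac = ((cs["weaning_start_hour"] >= 0) & (cs["weaning_start_hour"] <= 72)).mean()
        sub = onlabel_subgroup(patients)
        assert sub.per_arm[ARM_CS].n == pytest.approx(frac * len(cs), abs=1e-9)
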