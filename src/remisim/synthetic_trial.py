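"""Synthetic individual-patient trial data with known ground truth.

No public individual-patient data exist for a trial of this design, so
this module generates datasets with the same observational structure: two
arms (conventional analgo-sedation, n = 109, and remifentanil-based,
n = 96), per-phase dwell times drawn in continuous time from known Weibull
curves with competing death and (RS only) switch exits, censoring of the
mechanically ventilated phases once a patient has accumulated 10 days
(240 h) on the ventilator, a hard observation stop at 28 days (672 h), and
per-patient daily drug doses drawn from lognormals calibrated to the
published dose table.

The default ground-truth parameters are *illustrative* "trial-like" values
calibrated so that the generated data reproduce the study's observable
margins - about 21% of conventional-arm and 8% of remifentanil-arm
patients still ventilated at day 10, about 11% of remifentanil patients
switching while ventilated, and model median MV stays near 5.0 (CS) /
3.7 (RS) days.  They are not estimates of any real trial's parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .costing import DEFAULT_DAILY_DOSES, PHASE_BEFORE, PHASE_DURING
from .estimation import (
    DOSE_RECORD_COLUMNS,
    PHASE_RECORD_COLUMNS,
    estimate_model_parameters,
)
from .model_core import (
    ARM_CS,
    ARM_RS,
    ARMS,
    ConfigurationError,
    ConstantHazard,
    EligibleDwell,
    ModelParameters,
    WeibullParams,
)

logger = logging.getLogger(__name__)

#: Standard errors of the published mean daily doses (mg/day), used to set
#: the between-patient spread of the generated doses.
DOSE_TABLE_SE: dict[tuple[str, str], dict[str, float]] = {
    (ARM_CS, PHASE_BEFORE): {
        "morphine": 17.8, "midazolam": 36.2, "fentanyl": 0.1,
        "lorazepam": 0.7, "sufentanil_forte": 0.0, "propofol": 107.0,
        "remifentanil": 0.0,
    },
    (ARM_CS, PHASE_DURING): {
        "morphine": 24.6, "midazolam": 4.7, "fentanyl": 0.0,
        "lorazepam": 0.1, "sufentanil_forte": 0.0, "propofol": 125.9,
        "remifentanil": 0.0,
    },
    (ARM_RS, PHASE_BEFORE): {
        "morphine": 0.4, "midazolam": 22.2, "fentanyl": 0.0,
        "lorazepam": 0.0, "sufentanil_forte": 0.0, "propofol": 129.3,
        "remifentanil": 0.7,
    },
    (ARM_RS, PHASE_DURING): {
        "morphine": 0.9, "midazolam": 0.0, "fentanyl": 0.0,
        "lorazepam": 0.0, "sufentanil_forte": 0.0, "propofol": 154.5,
        "remifentanil": 1.2,
    },
}


def default_truth() -> ModelParameters:
    """Illustrative ground-truth transition parameters (see module docs).

    The maintenance-phase time-to-weaning curves are constructed so their
    hazards cross: the remifentanil curve starts higher (faster early
    weaning) and falls below the conventional curve after about three days,
    while the conventional curve has the heavier right tail that produces
    the larger day-10 censored fraction.  Attached standard errors and L-p
    correlations are likewise illustrative, sized like bootstrap output
    from a trial of ~100 patients per arm, and feed the probabilistic
    sensitivity analysis of the demonstration configuration.
    """

    def w(L, p, rel_se_L=0.18, rel_se_p=0.09, corr=-0.40) -> WeibullParams:
        return WeibullParams(L, p, se_L=rel_se_L * L, se_p=rel_se_p * p, corr_Lp=corr)

    return ModelParameters(
        progression={
            # time to "eligible to start weaning" - the arm-defining curves:
            # the RS hazard starts higher and crosses below CS near hour 56
            "s1_CS": w(0.01120, 1.30),
            "s1_RS": w(0.01656, 0.74),
            # time from start of weaning to "eligible to extubate"; the heavy
            # CS tail carries most of the day-10 censored fraction
            "s3_CS": w(0.01310, 0.60),
            "s3_RS": w(0.01800, 0.90),
            # post-extubation to "eligible for discharge" (pooled)
            "s5": w(0.0165, 1.15),
        },
        eligible={
            "s2_CS": EligibleDwell(0.30, w(0.15, 1.30), se_zero=0.044),
            "s2_RS": EligibleDwell(0.40, w(0.22, 1.30), se_zero=0.052),
            "s4_CS": EligibleDwell(0.45, w(0.20, 1.30), se_zero=0.050),
            "s4_RS": EligibleDwell(0.50, w(0.25, 1.30), se_zero=0.054),
            "s6": EligibleDwell(0.30, w(0.10, 1.20), se_zero=0.035),
        },
        # pooled maintenance-phase death curve; mildly rising hazard, with
        # the wide uncertainty of scarce death data (lognormal in the PSA)
        death_s1=w(0.00180, 1.15, rel_se_L=0.45, rel_se_p=0.15, corr=-0.40),
        # constant hourly death probabilities, weaning / post-extubation
        death_s3=ConstantHazard(4.0e-4, se=1.2e-4),
        death_s5=ConstantHazard(3.0e-4, se=0.9e-4),
        # RS time-to-switch (premature discontinuation) curve
        switch_s1=w(0.00215, 1.00, rel_se_L=0.30, rel_se_p=0.15, corr=-0.40),
    )


@dataclass
class TrialDesign:
    """Design of one synthetic trial draw."""

    n_cs: int = 109
    n_rs: int = 96
    mv_censor_hours: float = 240.0   # day-10 censoring of ventilated phases
    followup_hours: float = 672.0    # 28-day observation stop
    truth: ModelParameters = field(default_factory=default_truth)
    daily_dose_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DAILY_DOSES.items()})
    daily_dose_ses: dict = field(default_factory=lambda: {k: dict(v) for k, v in DOSE_TABLE_SE.items()})
    #: arm sizes the published SEs refer to; converts SE -> between-patient SD
    dose_se_reference_n: dict = field(default_factory=lambda: {ARM_CS: 109, ARM_RS: 96})

    def __post_init__(self) -> None:
        if self.n_cs < 1 or self.n_rs < 1:
            raise ConfigurationError("arm sizes must be >= 1")
        if self.mv_censor_hours > self.followup_hours:
            raise ConfigurationError("MV censoring cannot exceed follow-up")


# ---------------------------------------------------------------------------
# Continuous-time sampling helpers
# ---------------------------------------------------------------------------

def _weibull_times(w: WeibullParams, rng, size: int) -> np.ndarray:
    """Continuous Weibull event times, S(t) = exp(-(L t)^p)."""
    e = rng.exponential(size=size)
    return e ** (1.0 / w.p) / w.L


def _const_hazard_times(hourly_prob: float, rng, size: int) -> np.ndarray:
    """Exponential times matching a constant per-hour event probability."""
    if hourly_prob <= 0:
        return np.full(size, np.inf)
    rate = -np.log1p(-hourly_prob)
    return rng.exponential(1.0 / rate, size=size)


def generate_trial(design: TrialDesign, seed: Optional[int] = None, rng=None):
    """Generate one trial: (phase_records, dose_records) DataFrames.

    Phase records carry per-(patient, state) dwell hours (continuous) and
    the exit event; a ventilated phase still ongoing when the patient's
    cumulative MV time reaches ``mv_censor_hours`` is emitted as censored
    and the patient's observation ends (as does a switch: the switched
    patient leaves the study).  Post-extubation phases are censored only by
    the 28-day stop.  Identical seeds yield identical tables.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    truth = design.truth
    phase_rows: list[dict] = []
    dose_rows: list[dict] = []
    pid = 0
    for arm, n in ((ARM_CS, design.n_cs), (ARM_RS, design.n_rs)):
        ids = [f"{arm}{i:05d}" for i in range(pid, pid + n)]
        pid += n
        _generate_arm(design, arm, ids, rng, phase_rows, dose_rows)
    phase_df = pd.DataFrame(phase_rows, columns=PHASE_RECORD_COLUMNS)
    dose_df = pd.DataFrame(dose_rows, columns=DOSE_RECORD_COLUMNS)
    return phase_df, dose_df


def _generate_arm(design: TrialDesign, arm: str, ids, rng, phase_rows, dose_rows) -> None:
    truth = design.truth
    n = len(ids)
    mv_cap = design.mv_censor_hours
    total_cap = design.followup_hours

    mv_used = np.zeros(n)
    elapsed = np.zeros(n)
    active = np.ones(n, dtype=bool)
    reached_weaning = np.zeros(n, dtype=bool)

    def record(i: int, state: int, dwell: float, event: str) -> None:
        phase_rows.append({"patient_id": ids[i], "arm": arm, "state": state,
                           "dwell_hours": float(dwell), "exit_event": event})

    for state in (1, 2, 3, 4, 5, 6):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        m = len(idx)
        on_mv = state <= 4
        cap = (mv_cap - mv_used[idx]) if on_mv else (total_cap - elapsed[idx])

        # competing continuous event times for this phase
        if state == 1:
            t_prog = _weibull_times(truth.progression[f"s1_{arm}"], rng, m)
            t_death = _weibull_times(truth.death_s1, rng, m)
            t_switch = (_weibull_times(truth.switch_s1, rng, m)
                        if arm == ARM_RS and truth.switch_s1 is not None
                        else np.full(m, np.inf))
        elif state == 3:
            t_prog = _weibull_times(truth.progression[f"s3_{arm}"], rng, m)
            t_death = _const_hazard_times(truth.death_s3.hourly_prob, rng, m)
            t_switch = np.full(m, np.inf)
        elif state == 5:
            t_prog = _weibull_times(truth.progression["s5"], rng, m)
            t_death = _const_hazard_times(truth.death_s5.hourly_prob, rng, m)
            t_switch = np.full(m, np.inf)
        else:  # eligible states: zero-dwell mixture, progression only
            key = "s6" if state == 6 else f"s{state}_{arm}"
            el = truth.eligible[key]
            zero = rng.random(m) < el.zero_fraction
            t_prog = np.zeros(m)
            if el.weibull is not None and (~zero).any():
                t_prog[~zero] = _weibull_times(el.weibull, rng, int((~zero).sum()))
            t_death = np.full(m, np.inf)
            t_switch = np.full(m, np.inf)

        times = np.column_stack([t_death, t_switch, t_prog])
        cause_ix = np.argmin(times, axis=1)
        t_exit = times[np.arange(m), cause_ix]
        censored = t_exit > cap

        for k, i in enumerate(idx):
            if censored[k]:
                record(i, state, cap[k], "censored")
                active[i] = False
                continue
            event = ("death", "switch", "progress")[cause_ix[k]]
            record(i, state, t_exit[k], event)
            if event != "progress":
                active[i] = False
                continue
            if on_mv:
                mv_used[i] += t_exit[k]
            elapsed[i] += t_exit[k]
            if state == 2:
                reached_weaning[i] = True

    # dose records: "before weaning" for everyone, "during weaning" for
    # patients observed to start weaning
    for phase, mask in ((PHASE_BEFORE, np.ones(n, dtype=bool)),
                        (PHASE_DURING, reached_weaning)):
        means = design.daily_dose_means[(arm, phase)]
        ses = design.daily_dose_ses[(arm, phase)]
        ref_n = design.dose_se_reference_n[arm]
        sel = np.flatnonzero(mask)
        for drug, mean in means.items():
            se = ses.get(drug, 0.0)
            sd = se * np.sqrt(ref_n)
            if mean <= 0:
                draws = np.zeros(len(sel))
            elif sd <= 0:
                draws = np.full(len(sel), mean)
            else:
                sigma2 = np.log1p((sd / mean) ** 2)
                mu = np.log(mean) - sigma2 / 2.0
                draws = rng.lognormal(mu, np.sqrt(sigma2), size=len(sel))
            for k, i in enumerate(sel):
                dose_rows.append({"patient_id": ids[i], "arm": arm, "phase": phase,
                                  "drug": drug, "total_mg_per_day": float(draws[k])})


# ---------------------------------------------------------------------------
# Round-trip validation
# ---------------------------------------------------------------------------

def roundtrip_check(design: TrialDesign, n_per_arm: Optional[int] = None,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a trial, re-estimate, and tabulate recovery errors.

    With ``n_per_arm`` the design's arm sizes are overridden (inflated
    sample sizes make the errors interpretable as estimator consistency
    checks; at realistic sizes the table is reporting-only).  Relative
    errors are reported for Weibull rates/shapes and constant hazards,
    absolute errors for the zero-dwell fractions.
    """
    if n_per_arm is not None:
        design = replace(design, n_cs=n_per_arm, n_rs=n_per_arm)
    phase_df, _ = generate_trial(design, seed=seed)
    est = estimate_model_parameters(phase_df)
    truth = design.truth

    rows = []

    def add(name, true_val, est_val, relative=True):
        err = (est_val - true_val) / true_val if relative and true_val != 0 else est_val - true_val
        rows.append({"parameter": name, "truth": true_val, "estimate": est_val,
                     "error": err, "relative": relative})

    for key in truth.progression:
        add(f"{key}.L", truth.progression[key].L, est.progression[key].L)
        add(f"{key}.p", truth.progression[key].p, est.progression[key].p)
    add("death_s1.L", truth.death_s1.L, est.death_s1.L)
    add("death_s1.p", truth.death_s1.p, est.death_s1.p)
    if truth.switch_s1 is not None:
        add("switch_s1.L", truth.switch_s1.L, est.switch_s1.L)
        add("switch_s1.p", truth.switch_s1.p, est.switch_s1.p)
    for key in truth.eligible:
        te, ee = truth.eligible[key], est.eligible[key]
        add(f"{key}.zero_fraction", te.zero_fraction, ee.zero_fraction, relative=False)
        if te.weibull is not None and ee.weibull is not None:
            add(f"{key}.L", te.weibull.L, ee.weibull.L)
            add(f"{key}.p", te.weibull.p, ee.weibull.p)
    add("death_s3.hourly_prob", truth.death_s3.hourly_prob, est.death_s3.hourly_prob)
    add("death_s5.hourly_prob", truth.death_s5.hourly_prob, est.death_s5.hourly_prob)
    return pd.DataFrame(rows)


def observed_margins(phase_df: pd.DataFrame) -> dict[str, float]:
    """Observable calibration margins of a generated trial.

    Per arm: the fraction of patients whose record ends MV-censored
    (still ventilated at the day-10 cap) and, for RS, the fraction with a
    switch record.
    """
    out = {}
    for arm in ARMS:
        sub = phase_df[phase_df["arm"] == arm]
        n = sub["patient_id"].nunique()
        mv_cens = sub[(sub["state"] <= 4) & (sub["exit_event"] == "censored")]
        out[f"mv_censored_{arm}"] = mv_cens["patient_id"].nunique() / n
    rs = phase_df[phase_df["arm"] == ARM_RS]
    out["switched_RS"] = (rs["exit_event"] == "switch").sum() / rs["patient_id"].nunique()
    return out
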