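"""Hour-by-hour patient-level simulation and cohort outcomes.

Every simulated patient starts in the maintenance state at hour 0 and is
followed for at most 28 days (672 one-hour cycles).  Each hour the
competing exits of the current phase are resolved in the fixed priority
order death -> switch -> progression, each as a Bernoulli conditional on
the earlier causes not firing; the phase clock restarts on every state
entry (semi-Markov).  The zero-dwell "eligible" states are resolved by a
single Bernoulli draw at entry.  A remifentanil-arm patient who switches
continues in the maintenance state under conventional-arm dynamics with
the phase clock running on (and accrues conventional-arm sedation costs
from the switch hour onward).

Two equivalent engines are provided: :func:`simulate_patient`, a readable
per-patient reference used for unit testing, and the vectorised cohort
engine behind :func:`run_cohort` and the sensitivity analysis, which
samples exit hours by inverse transform on the precomputed discrete
survival curve of each phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .costing import CostParams, PHASE_BEFORE, PHASE_DURING, accumulate_costs
from .model_core import (
    ARM_CS,
    ARM_RS,
    ARMS,
    DEATH,
    DISCHARGED,
    ELIGIBLE_STATES,
    HORIZON_HOURS,
    NEXT_STATE,
    ConfigurationError,
    ModelParameters,
    TransitionTable,
)

logger = logging.getLogger(__name__)

TERMINAL_DISCHARGED = "discharged"
TERMINAL_DEATH = "death"
TERMINAL_CENSORED = "horizon_censored"


@dataclass
class PatientHistory:
    """One simulated trajectory: ordered (state, entry_hour, exit_hour)."""

    patient_id: object
    arm_initial: str
    segments: list[tuple[int, int, int]]
    terminal: str
    switched_at: Optional[int] = None
    weaning_start_hour: Optional[int] = None

    def hours_in(self, states: Sequence[int]) -> int:
        return sum(e - s for st, s, e in self.segments if st in states)

    @property
    def los_mv_hours(self) -> int:
        return self.hours_in((1, 2, 3, 4))

    @property
    def los_icu_hours(self) -> int:
        return self.hours_in((1, 2, 3, 4, 5, 6))


@dataclass
class ArmOutcome:
    n: int
    mean_los_icu_days: float
    median_los_icu_days: float
    mean_los_mv_days: float
    median_los_mv_days: float
    mean_cost_eur: float


@dataclass
class CohortResult:
    """Per-arm outcome summary and CS-minus-RS differences of the means."""

    per_arm: dict[str, ArmOutcome]
    differences: dict[str, float]  # keys: los_icu_days, los_mv_days, cost_eur
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, o in self.per_arm.items():
            rows.append({"arm": arm, "n": o.n,
                         "mean_los_icu_days": o.mean_los_icu_days,
                         "median_los_icu_days": o.median_los_icu_days,
                         "mean_los_mv_days": o.mean_los_mv_days,
                         "median_los_mv_days": o.median_los_mv_days,
                         "mean_cost_eur": o.mean_cost_eur})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference per-patient engine
# ---------------------------------------------------------------------------

def simulate_patient(arm: str, tables: dict[tuple[int, str], TransitionTable], rng,
                     horizon: int = HORIZON_HOURS, patient_id: object = 0) -> PatientHistory:
    """Simulate one trajectory with an explicit hour loop.

    ``tables`` must cover every reachable ``(state, arm)``; the RS arm also
    needs the CS tables because of switching.
    """
    if arm not in ARMS:
        raise ConfigurationError(f"unknown arm {arm!r}")
    cur_arm = arm
    state = 1
    hour = 0          # global clock
    entry = 0         # global hour of entry into the current state
    segments: list[tuple[int, int, int]] = []
    switched_at: Optional[int] = None
    weaning_start: Optional[int] = None
    terminal = TERMINAL_CENSORED

    def table(s: int) -> TransitionTable:
        key = (s, cur_arm)
        if key not in tables:
            raise ConfigurationError(f"no transition table for {key}")
        return tables[key]

    def enter(s: int, at: int) -> int:
        """Resolve entry point masses; returns the state actually dwelt in."""
        nonlocal weaning_start
        while s not in (DISCHARGED, DEATH):
            if s == 3 and weaning_start is None:
                weaning_start = at
            if s in ELIGIBLE_STATES and rng.random() < table(s).zero_fraction:
                s = NEXT_STATE[s]
                continue
            break
        if s == 3 and weaning_start is None:
            weaning_start = at
        return s

    state = enter(state, 0)
    while hour < horizon and state not in (DISCHARGED, DEATH):
        tab = table(state)
        t_phase = hour - entry + 1  # phase-clock hour about to elapse
        hour += 1
        fired = None
        for j, ex in enumerate(tab.exits):
            if rng.random() < tab.probs[min(t_phase, tab.horizon) - 1, j]:
                fired = ex
                break
        if fired is None:
            continue
        if fired.cause == "switch":
            switched_at = hour
            cur_arm = ARM_CS
            continue  # same state, phase clock keeps running
        segments.append((state, entry, hour))
        if fired.cause == "death":
            state = DEATH
            terminal = TERMINAL_DEATH
            break
        state = enter(fired.destination, hour)
        entry = hour
        if state == DISCHARGED:
            terminal = TERMINAL_DISCHARGED
    if state not in (DISCHARGED, DEATH):
        if hour > entry:
            segments.append((state, entry, hour))
        terminal = TERMINAL_CENSORED
    return PatientHistory(patient_id, arm, segments, terminal,
                          switched_at=switched_at, weaning_start_hour=weaning_start)


# ---------------------------------------------------------------------------
# Vectorised cohort engine
# ---------------------------------------------------------------------------

def _sample_exit(table: TransitionTable, rng, t0: np.ndarray):
    """Vectorised inverse-transform draw of the exit hour and cause.

    ``t0`` is the phase-clock hour each patient has already survived
    (0 on fresh entry).  Returns ``(T, cause_idx)`` where ``T`` is the exit
    hour on the phase clock (``horizon + 1`` when no exit occurs within the
    table) and ``cause_idx`` indexes ``table.exits`` (-1 when censored).
    """
    g = table.survival
    n = len(t0)
    u = rng.random(n) * g[t0]
    T = np.searchsorted(-g, -u, side="right")
    exited = T <= table.horizon
    cause = np.full(n, -1, dtype=int)
    if table.probs.shape[1] and exited.any():
        rows = table.cause_given_exit[np.minimum(T[exited], table.horizon) - 1]
        r = rng.random(int(exited.sum()))
        cum = np.cumsum(rows, axis=1)
        cause[exited] = (r[:, None] >= cum).sum(axis=1)
    T = np.where(exited, T, table.horizon + 1)
    return T, cause


def _cause_index(table: TransitionTable, cause: str) -> int:
    for j, ex in enumerate(table.exits):
        if ex.cause == cause:
            return j
    return -1


def simulate_cohort_arrays(params: ModelParameters, arm: str, n: int, rng,
                           horizon: int = HORIZON_HOURS,
                           tables: Optional[dict] = None) -> pd.DataFrame:
    """Simulate ``n`` patients of one arm; per-patient hour accounting.

    Returns a DataFrame with the dwell hours in each transient state, the
    split of maintenance hours around the switch, the weaning start hour,
    and the terminal status.  Distributionally identical to
    :func:`simulate_patient`; implemented by inverse-transform sampling of
    the discrete per-phase survival curves.
    """
    if tables is None:
        tables = params.build_tables(horizon)
    dwell = {s: np.zeros(n, dtype=int) for s in (1, 2, 3, 4, 5, 6)}
    cum = np.zeros(n, dtype=int)
    switched = np.zeros(n, dtype=bool)
    switch_hour = np.full(n, -1, dtype=int)
    dead = np.zeros(n, dtype=bool)
    s1_pre_switch = np.zeros(n, dtype=int)
    weaning_start = np.full(n, -1, dtype=int)
    alive = np.ones(n, dtype=bool)  # still progressing through states

    # --- state 1 -----------------------------------------------------------
    tab = tables[(1, arm)]
    T, cause = _sample_exit(tab, rng, np.zeros(n, dtype=int))
    if arm == ARM_RS:
        j_sw = _cause_index(tab, "switch")
        sw = cause == j_sw
        if sw.any():
            tab_cs = tables[(1, ARM_CS)]
            T_sw = T[sw]
            T2, cause2 = _sample_exit(tab_cs, rng, T_sw)
            switched[sw] = True
            switch_hour[sw] = T_sw
            s1_pre_switch[sw] = T_sw
            # remap the post-switch exit into the common arrays
            T = T.copy(); cause = cause.copy()
            T[sw] = T2
            c2 = np.full(len(T2), -1, dtype=int)
            for j, ex in enumerate(tab_cs.exits):
                c2[cause2 == j] = {"death": -2, "progress": -3}.get(ex.cause, -1)
            cause[sw] = c2
        # normalise cause codes: -2 death, -3 progress, -1 censored
        norm = np.full(n, -1, dtype=int)
        for j, ex in enumerate(tab.exits):
            mask = (~switched) & (cause == j)
            norm[mask] = {"death": -2, "progress": -3}.get(ex.cause, -1)
        norm[switched] = cause[switched]
        cause = norm
    else:
        norm = np.full(n, -1, dtype=int)
        for j, ex in enumerate(tab.exits):
            norm[cause == j] = {"death": -2, "progress": -3}.get(ex.cause, -1)
        cause = norm

    exit_T = np.minimum(T, horizon)
    dwell[1] = exit_T
    censored_here = (T > horizon)
    dwell[1][censored_here] = horizon
    s1_pre_switch[~switched] = dwell[1][~switched]
    cum = dwell[1].copy()
    dead |= (cause == -2) & ~censored_here
    alive = (cause == -3) & ~censored_here

    eff_cs = (arm == ARM_CS) | switched  # effective arm after state 1

    # --- downstream states -------------------------------------------------
    discharged = np.zeros(n, dtype=bool)
    for state in (2, 3, 4, 5, 6):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        remaining = horizon - cum[idx]
        dw = np.zeros(len(idx), dtype=int)
        ev = np.full(len(idx), -1, dtype=int)  # -2 death, -3 progress, -1 censored

        if state == 3:
            weaning_start[idx] = cum[idx]

        pooled = state in (5, 6)
        arms_here = [True] if pooled else [False, True]  # False: own arm, True: CS
        for use_cs in arms_here:
            if pooled:
                sub = np.arange(len(idx))
                tab = tables[(state, ARM_CS)]  # pooled parameters, same both arms
            else:
                sel = eff_cs[idx] == use_cs
                sub = np.flatnonzero(sel)
                if len(sub) == 0:
                    continue
                tab = tables[(state, ARM_CS if use_cs else arm)]
            m = len(sub)
            if state in ELIGIBLE_STATES:
                zero = rng.random(m) < tab.zero_fraction
            else:
                zero = np.zeros(m, dtype=bool)
            ev_s = np.full(m, -3, dtype=int)  # zero-dwell: instant progression
            dw_s = np.zeros(m, dtype=int)
            nz = np.flatnonzero(~zero)
            if len(nz):
                Ts, cs = _sample_exit(tab, rng, np.zeros(len(nz), dtype=int))
                code = np.full(len(nz), -1, dtype=int)
                for j, ex in enumerate(tab.exits):
                    code[cs == j] = {"death": -2, "progress": -3}.get(ex.cause, -1)
                rem = remaining[sub[nz]]
                over = Ts > rem
                dw_s[nz] = np.minimum(Ts, rem)
                code[over] = -1
                ev_s[nz] = code
            dw[sub] = dw_s
            ev[sub] = ev_s

        dwell[state][idx] = dw
        cum[idx] += dw
        dead[idx[ev == -2]] = True
        nxt = ev == -3  # progression exactly at the horizon still counts
        alive[:] = False
        alive[idx[nxt]] = True
        if state == 6:
            discharged[idx[nxt]] = True

    terminal = np.where(dead, TERMINAL_DEATH,
                        np.where(discharged, TERMINAL_DISCHARGED, TERMINAL_CENSORED))

    df = pd.DataFrame({
        "arm": arm,
        "d1": dwell[1], "d2": dwell[2], "d3": dwell[3],
        "d4": dwell[4], "d5": dwell[5], "d6": dwell[6],
        "s1_pre_switch": s1_pre_switch,
        "switched": switched,
        "switch_hour": switch_hour,
        "weaning_start_hour": weaning_start,
        "terminal": terminal,
    })
    df["los_mv_hours"] = df[["d1", "d2", "d3", "d4"]].sum(axis=1)
    df["los_icu_hours"] = df["los_mv_hours"] + df["d5"] + df["d6"]
    return df


def patient_costs(df: pd.DataFrame, costs: CostParams) -> np.ndarray:
    """Vectorised total cost per patient, same formula as accumulate_costs."""
    mv_rate = costs.icu_eur_per_day_mv.mean / 24.0
    nomv_rate = costs.icu_eur_per_day_nomv.mean / 24.0
    sed = {(a, ph): costs.sedation_eur_per_hour[(a, ph)].mean
           for a in ARMS for ph in (PHASE_BEFORE, PHASE_DURING)}
    mv_h = df["los_mv_hours"].to_numpy(dtype=float)
    icu_nomv_h = (df["d5"] + df["d6"]).to_numpy(dtype=float)
    total = mv_h * mv_rate + icu_nomv_h * nomv_rate

    is_rs = (df["arm"] == ARM_RS).to_numpy()
    switched = df["switched"].to_numpy(dtype=bool)
    d1 = df["d1"].to_numpy(dtype=float)
    d2 = df["d2"].to_numpy(dtype=float)
    pre = df["s1_pre_switch"].to_numpy(dtype=float)
    before_rs = np.where(switched, pre, d1 + d2)
    before_cs = np.where(switched, d1 - pre + d2, d1 + d2)
    during = (df["d3"] + df["d4"]).to_numpy(dtype=float)
    eff_cs = (~is_rs) | switched

    total += np.where(is_rs, before_rs * sed[(ARM_RS, PHASE_BEFORE)], 0.0)
    total += np.where(is_rs & switched, before_cs * sed[(ARM_CS, PHASE_BEFORE)], 0.0)
    total += np.where(~is_rs, (d1 + d2) * sed[(ARM_CS, PHASE_BEFORE)], 0.0)
    total += np.where(eff_cs, during * sed[(ARM_CS, PHASE_DURING)],
                      during * sed[(ARM_RS, PHASE_DURING)])
    return total


def summarize_patients(df: pd.DataFrame, seed: Optional[int] = None) -> CohortResult:
    """Aggregate a per-patient table into per-arm means/medians and diffs."""
    per_arm: dict[str, ArmOutcome] = {}
    for arm in ARMS:
        sub = df[df["arm"] == arm]
        if sub.empty:
            continue
        per_arm[arm] = ArmOutcome(
            n=len(sub),
            mean_los_icu_days=float(sub["los_icu_hours"].mean() / 24.0),
            median_los_icu_days=float(sub["los_icu_hours"].median() / 24.0),
            mean_los_mv_days=float(sub["los_mv_hours"].mean() / 24.0),
            median_los_mv_days=float(sub["los_mv_hours"].median() / 24.0),
            mean_cost_eur=float(sub["cost_eur"].mean()),
        )
    diffs = {}
    if ARM_CS in per_arm and ARM_RS in per_arm:
        cs, rs = per_arm[ARM_CS], per_arm[ARM_RS]
        diffs = {
            "los_icu_days": cs.mean_los_icu_days - rs.mean_los_icu_days,
            "los_mv_days": cs.mean_los_mv_days - rs.mean_los_mv_days,
            "cost_eur": cs.mean_cost_eur - rs.mean_cost_eur,
        }
    return CohortResult(per_arm=per_arm, differences=diffs, seed=seed)


def run_cohort(params: ModelParameters, costs: CostParams, n_per_arm: int = 10_000,
               seed: Optional[int] = None, rng=None,
               common_random_numbers: bool = False,
               horizon: int = HORIZON_HOURS,
               return_patients: bool = False):
    """Simulate both arms and summarise cohort outcomes.

    LOS on MV counts hours in states 1-4, LOS in ICU hours in states 1-6,
    both reported in days; costs follow the costing module.  With
    ``common_random_numbers`` both arms reuse the same random stream (for
    paired comparisons); by default the arms are independent.  Deterministic
    for a fixed ``seed``.
    """
    if n_per_arm < 1:
        raise ConfigurationError("n_per_arm must be >= 1")
    tables = params.build_tables(horizon)
    frames = []
    if rng is None:
        root = np.random.SeedSequence(seed)
        streams = root.spawn(2)
    for i, arm in enumerate((ARM_RS, ARM_CS)):
        if rng is not None:
            arm_rng = rng
        elif common_random_numbers:
            arm_rng = np.random.default_rng(streams[0])
        else:
            arm_rng = np.random.default_rng(streams[i])
        df = simulate_cohort_arrays(params, arm, n_per_arm, arm_rng,
                                    horizon=horizon, tables=tables)
        frames.append(df)
    patients = pd.concat(frames, ignore_index=True)
    patients["cost_eur"] = patient_costs(patients, costs)
    result = summarize_patients(patients, seed=seed)
    if return_patients:
        return result, patients
    return result


def onlabel_subgroup(patients, costs: Optional[CostParams] = None,
                     threshold_hours: int = 72) -> Optional[CohortResult]:
    """Outcomes restricted to patients whose weaning started within 72 h.

    Accepts the per-patient DataFrame from :func:`run_cohort` (with a
    ``cost_eur`` column, or ``costs`` to compute one) or a list of
    :class:`PatientHistory`.  The boundary is inclusive: weaning start at
    exactly 72 h qualifies.  Returns ``None`` for an empty subgroup.
    """
    if not isinstance(patients, pd.DataFrame):
        patients = histories_to_frame(patients, costs)
    if "cost_eur" not in patients.columns:
        if costs is None:
            raise ConfigurationError("need cost params to compute patient costs")
        patients = patients.copy()
        patients["cost_eur"] = patient_costs(patients, costs)
    ws = patients["weaning_start_hour"]
    sub = patients[(ws >= 0) & ws.notna() & (ws <= threshold_hours)]
    if sub.empty:
        return None
    return summarize_patients(sub)


def histories_to_frame(histories: Sequence[PatientHistory],
                       costs: Optional[CostParams] = None) -> pd.DataFrame:
    """Convert PatientHistory objects to the per-patient table layout."""
    rows = []
    for h in histories:
        d = {f"d{s}": h.hours_in((s,)) for s in (1, 2, 3, 4, 5, 6)}
        sw = h.switched_at is not None
        s1 = d["d1"]
        row = {"arm": h.arm_initial, **d,
               "s1_pre_switch": h.switched_at if sw else s1,
               "switched": sw,
               "switch_hour": h.switched_at if sw else -1,
               "weaning_start_hour": -1 if h.weaning_start_hour is None else h.weaning_start_hour,
               "terminal": h.terminal,
               "los_mv_hours": h.los_mv_hours,
               "los_icu_hours": h.los_icu_hours}
        if costs is not None:
            row["cost_eur"] = accumulate_costs(h, costs)
        rows.append(row)
    return pd.DataFrame(rows)
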