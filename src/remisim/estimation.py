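"""Parameter estimation from individual-patient trial records.

Each phase of each patient contributes one record: the dwell time in hours
and how the phase ended (progression to the next phase, death, switch to
the conventional regimen, or censoring).  Cause-specific time-to-event
curves are fitted by treating exits of the competing causes as censored:
for the time-to-next-phase curve, patients who died or switched count as
censored, and symmetrically for the death and switch curves.

Fitting is right-censored Weibull maximum likelihood on the
``S(t) = exp(-(L*t)**p)`` parameterisation, optimised over
``(log L, log p)`` to enforce positivity, multi-started from the
closed-form exponential initialiser.  Standard errors and the L-p
correlation come from a patient-level bootstrap.  Deaths during weaning
and post-extubation are too scarce for curves and enter as constant hourly
probabilities matched to the observed occurrence rate; the eligible states
2, 4 and 6 get a point mass at zero dwell plus a Weibull for the positive
dwell times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import (
    ARM_CS,
    ARM_RS,
    ARMS,
    ELIGIBLE_STATES,
    ConstantHazard,
    DataError,
    EligibleDwell,
    EstimationError,
    ModelParameters,
    WeibullParams,
)

logger = logging.getLogger(__name__)

EXIT_EVENTS = ("progress", "death", "switch", "censored")

PHASE_RECORD_COLUMNS = ["patient_id", "arm", "state", "dwell_hours", "exit_event"]
DOSE_RECORD_COLUMNS = ["patient_id", "arm", "phase", "drug", "total_mg_per_day"]


@dataclass
class PhaseRecord:
    """One observed phase of one patient."""

    patient_id: object
    arm: str
    state: int
    dwell_hours: float
    exit_event: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataError(f"unknown arm {self.arm!r}")
        if self.exit_event not in EXIT_EVENTS:
            raise DataError(f"unknown exit event {self.exit_event!r}")
        if self.dwell_hours < 0:
            raise DataError("dwell_hours must be nonnegative")
        if self.dwell_hours == 0 and self.state not in ELIGIBLE_STATES:
            raise DataError("zero dwell is permitted only for states 2, 4 and 6")
        if self.exit_event == "switch" and not (self.state == 1 and self.arm == ARM_RS):
            raise DataError("switch exits exist only for state 1 under RS")


@dataclass
class DoseRecord:
    """Average daily dose of one drug for one patient in one phase."""

    patient_id: object
    arm: str
    phase: str
    drug: str
    total_mg_per_day: float

    def __post_init__(self) -> None:
        if self.total_mg_per_day < 0:
            raise DataError("total_mg_per_day must be nonnegative")


# ---------------------------------------------------------------------------
# Censored Weibull maximum likelihood
# ---------------------------------------------------------------------------

def _split_dwells(dwells) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(dwells), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError("dwells must be (time, event_flag) pairs")
    times = arr[:, 0]
    events = arr[:, 1].astype(bool)
    if np.any(times <= 0):
        raise ValueError("observed times must be positive")
    return times, events


def weibull_loglik(log_L: float, log_p: float, times: np.ndarray, events: np.ndarray) -> float:
    """Right-censored Weibull log-likelihood at ``(log L, log p)``.

    Events contribute ``log h(t) + log S(t)``, censored observations
    ``log S(t)``, with ``h(t) = p * L**p * t**(p-1)`` and
    ``log S(t) = -(L*t)**p``.
    """
    p = np.exp(log_p)
    logt = np.log(times)
    w = np.minimum(p * (log_L + logt), 300.0)  # log cumulative hazard, overflow-guarded
    z = np.exp(w)
    ll = -z.sum()
    if events.any():
        lt = logt[events]
        ll += events.sum() * (log_p + p * log_L) + (p - 1.0) * lt.sum()
    return float(ll)


def _negll_grad(theta: np.ndarray, logt: np.ndarray, events: np.ndarray):
    a, b = theta
    p = np.exp(b)
    w = np.minimum(p * (a + logt), 300.0)
    z = np.exp(w)
    n_ev = events.sum()
    lt_ev = logt[events]
    ll = n_ev * (b + p * a) + (p - 1.0) * lt_ev.sum() - z.sum()
    d_a = p * (n_ev - z.sum())
    d_b = n_ev * (1.0 + p * a) + p * lt_ev.sum() - (z * p * (a + logt)).sum()
    return -ll, np.array([-d_a, -d_b])


def fit_weibull_censored(dwells, fix_p: Optional[float] = None) -> WeibullParams:
    """Point estimates of ``(L, p)`` by right-censored maximum likelihood.

    ``dwells`` is a sequence of ``(time, event_flag)`` pairs; ``event_flag``
    is truthy when the modelled cause was observed and falsy when the
    observation was censored (including exits of competing causes).  With
    ``fix_p`` the shape is held fixed and only the rate is optimised.

    Raises :class:`EstimationError` with fewer than two observed events and
    ``ValueError`` for nonpositive times.
    """
    times, events = _split_dwells(dwells)
    n_ev = int(events.sum())
    if n_ev < 2:
        raise EstimationError(f"need at least 2 uncensored events, got {n_ev}")
    logt = np.log(times)
    a0 = float(np.log(n_ev / times.sum()))  # exponential closed-form initialiser

    if fix_p is not None:
        if fix_p <= 0:
            raise ValueError("fix_p must be positive")
        b = float(np.log(fix_p))

        def nll1(a):
            v, g = _negll_grad(np.array([a[0], b]), logt, events)
            return v, g[:1]

        res = optimize.minimize(nll1, np.array([a0]), jac=True, method="L-BFGS-B",
                                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500})
        return WeibullParams(float(np.exp(res.x[0])), float(fix_p))

    best = None
    for b0 in (np.log(0.5), 0.0, np.log(2.0)):
        res = optimize.minimize(_negll_grad, np.array([a0, b0]), args=(logt, events),
                                jac=True, method="L-BFGS-B",
                                bounds=[(-30.0, 10.0), (-4.0, 4.0)],
                                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    # polish until the gradient norm meets the convergence contract
    if np.linalg.norm(best.jac) > 1e-8:
        res = optimize.minimize(lambda th: _negll_grad(th, logt, events)[0], best.x,
                                method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        if res.fun <= best.fun:
            v, g = _negll_grad(res.x, logt, events)
            best = optimize.OptimizeResult(x=res.x, fun=v, jac=g)
    return WeibullParams(float(np.exp(best.x[0])), float(np.exp(best.x[1])))


def bootstrap_weibull(dwells, B: int = 1000, rng=None, seed: Optional[int] = None,
                      patient_ids: Optional[Sequence] = None,
                      fix_p: Optional[float] = None) -> WeibullParams:
    """Bootstrap standard errors of ``L`` and ``p`` and their correlation.

    Resampling is at the patient level when ``patient_ids`` is given (one
    id per dwell record, records of a resampled patient travel together),
    otherwise records are resampled directly.  Replicates without enough
    events are discarded and logged; more than 10% discarded is an error.
    Point estimates are those of the full-data fit.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed) if rng is None else rng
    times, events = _split_dwells(dwells)
    full = fit_weibull_censored(list(zip(times, events)), fix_p=fix_p)

    if patient_ids is not None:
        ids = np.asarray(patient_ids)
        if len(ids) != len(times):
            raise DataError("patient_ids must align with dwells")
        unique = np.unique(ids)
        groups = {u: np.flatnonzero(ids == u) for u in unique}
    else:
        unique = None

    fits = []
    dropped = 0
    for _ in range(B):
        if unique is not None:
            take = rng.choice(unique, size=len(unique), replace=True)
            idx = np.concatenate([groups[u] for u in take])
        else:
            idx = rng.integers(0, len(times), size=len(times))
        try:
            f = fit_weibull_censored(list(zip(times[idx], events[idx])), fix_p=fix_p)
        except EstimationError:
            dropped += 1
            continue
        fits.append((f.L, f.p))
    if dropped:
        logger.warning("bootstrap: discarded %d/%d replicates without events", dropped, B)
    if dropped > 0.1 * B:
        raise EstimationError(f"bootstrap discarded {dropped}/{B} replicates")

    arr = np.asarray(fits)
    se_L = float(arr[:, 0].std(ddof=1))
    se_p = float(arr[:, 1].std(ddof=1))
    if se_L > 0 and se_p > 0:
        corr = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        corr = float(np.clip(corr, -1.0, 1.0))
    else:
        corr = 0.0
    return WeibullParams(full.L, full.p, se_L=se_L, se_p=se_p, corr_Lp=corr)


# ---------------------------------------------------------------------------
# Simple estimators
# ---------------------------------------------------------------------------

def estimate_constant_hazard(n_events: int, exposure_hours: float) -> float:
    """Hourly probability whose implied rate matches the observed rate.

    ``1 - exp(-n_events / exposure_hours)``: the exponential-rate MLE
    converted to a per-cycle probability.
    """
    if n_events < 0 or exposure_hours <= 0:
        raise ValueError("need n_events >= 0 and exposure_hours > 0")
    return float(-np.expm1(-n_events / exposure_hours))


def estimate_zero_dwell_fraction(dwells) -> float:
    """Fraction of dwell times that are exactly zero (instant transitions)."""
    arr = np.asarray(list(dwells), dtype=float)
    if arr.size == 0:
        raise DataError("empty dwell list")
    if np.any(arr < 0):
        raise ValueError("dwell times must be nonnegative")
    return float(np.mean(arr == 0.0))


def mean_daily_doses(records) -> pd.DataFrame:
    """Mean and SE of mg/day per (arm, phase, drug) across patients.

    ``records`` is a DataFrame with the :data:`DOSE_RECORD_COLUMNS` schema
    or an iterable of :class:`DoseRecord`.  The SE is the standard error of
    the mean (0 for a single patient).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    if records.empty:
        raise DataError("no dose records")
    grouped = records.groupby(["arm", "phase", "drug"])["total_mg_per_day"]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["arm", "phase", "drug", "mean", "se", "n"]]


# ---------------------------------------------------------------------------
# Full-trial estimation pipeline
# ---------------------------------------------------------------------------

def _cause_dwells(df: pd.DataFrame, cause: str):
    """(time, event) pairs for one cause: competing exits become censored."""
    t = df["dwell_hours"].to_numpy(dtype=float)
    e = (df["exit_event"] == cause).to_numpy()
    return list(zip(t, e)), df["patient_id"].to_numpy()


def _fit(df: pd.DataFrame, cause: str, B: int, rng, label: str) -> WeibullParams:
    pos = df[df["dwell_hours"] > 0]
    dwells, ids = _cause_dwells(pos, cause)
    try:
        if B > 0:
            return bootstrap_weibull(dwells, B=B, rng=rng, patient_ids=ids)
        return fit_weibull_censored(dwells)
    except EstimationError as err:
        raise EstimationError(f"{label}: {err}") from err


def estimate_model_parameters(phase_records: pd.DataFrame, bootstrap_B: int = 0,
                              seed: Optional[int] = None) -> ModelParameters:
    """Fit the complete transition-parameter set from phase records.

    Pooling follows the structure of the analysis: next-phase and
    eligible-state dwell curves are arm-specific while on the ventilator,
    death data are pooled across arms (maintenance-phase deaths as a
    Weibull, weaning and post-extubation deaths as constant hourly
    probabilities), and post-extubation transitions are shared between the
    arms.  With ``bootstrap_B > 0`` every Weibull additionally gets
    bootstrap SEs and the L-p correlation.
    """
    df = phase_records
    missing = [c for c in PHASE_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"phase records missing columns {missing}")
    rng = np.random.default_rng(seed)
    B = bootstrap_B

    progression: dict[str, WeibullParams] = {}
    eligible: dict[str, EligibleDwell] = {}

    for arm in ARMS:
        s1 = df[(df["state"] == 1) & (df["arm"] == arm)]
        progression[f"s1_{arm}"] = _fit(s1, "progress", B, rng, f"s1_{arm} progression")
        s3 = df[(df["state"] == 3) & (df["arm"] == arm)]
        progression[f"s3_{arm}"] = _fit(s3, "progress", B, rng, f"s3_{arm} progression")
        for state in (2, 4):
            sub = df[(df["state"] == state) & (df["arm"] == arm)]
            eligible[f"s{state}_{arm}"] = _eligible_mixture(sub, B, rng, f"s{state}_{arm}")

    # post-extubation: pooled across arms
    s5 = df[df["state"] == 5]
    progression["s5"] = _fit(s5, "progress", B, rng, "s5 progression")
    eligible["s6"] = _eligible_mixture(df[df["state"] == 6], B, rng, "s6")

    # deaths: maintenance-phase Weibull and downstream constants, pooled
    s1_all = df[df["state"] == 1]
    death_s1 = _fit(s1_all, "death", B, rng, "s1 death")
    death_s3 = _constant_death(df[df["state"] == 3])
    death_s5 = _constant_death(df[df["state"] == 5])

    switch = _fit(df[(df["state"] == 1) & (df["arm"] == ARM_RS)], "switch", B, rng, "s1 switch")

    return ModelParameters(progression=progression, eligible=eligible,
                           death_s1=death_s1, death_s3=death_s3,
                           death_s5=death_s5, switch_s1=switch)


def _eligible_mixture(sub: pd.DataFrame, B: int, rng, label: str) -> EligibleDwell:
    if sub.empty:
        raise EstimationError(f"{label}: no records")
    dwell = sub["dwell_hours"].to_numpy(dtype=float)
    frac = estimate_zero_dwell_fraction(dwell)
    n = len(dwell)
    se_zero = float(np.sqrt(frac * (1.0 - frac) / n))
    if frac >= 1.0:
        return EligibleDwell(1.0, None, se_zero)
    weib = _fit(sub, "progress", B, rng, f"{label} dwell")
    return EligibleDwell(frac, weib, se_zero)


def _constant_death(sub: pd.DataFrame) -> ConstantHazard:
    exposure = float(sub["dwell_hours"].sum())
    n_deaths = int((sub["exit_event"] == "death").sum())
    prob = estimate_constant_hazard(n_deaths, exposure)
    rate_se = np.sqrt(max(n_deaths, 1)) / exposure  # Poisson rate SE
    se = float(np.exp(-n_deaths / exposure) * rate_se)
    return ConstantHazard(prob, se)
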