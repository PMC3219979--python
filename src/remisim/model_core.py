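"""Health-state machine and transition-probability mathematics.

The model describes the flow of a mechanically ventilated ICU patient
through eight health states::

    1  MV - maintenance
    2  MV - eligible to start weaning
    3  MV - weaning started
    4  MV - eligible to extubate
    5  post-extubation
    6  post-extubation, eligible for ICU discharge
    7  discharged from ICU        (absorbing)
    8  death                      (absorbing)

Patients move through states 1..7 in sequence; death may interrupt at any
time, and patients on the remifentanil-based regimen (RS) may switch to the
conventional regimen (CS) while in the maintenance state.  The model is a
discrete-time semi-Markov micro-simulation with a one-hour cycle: the clock
of each phase restarts on entry, and the probability of leaving a phase in
hour ``t`` (the interval ``(t-1, t]`` since phase entry) is derived from a
parametric survival curve,

    S(t) = exp(-(L*t)**p),        tp(t) = 1 - S(t) / S(t-1),

the Weibull family with rate ``L`` (per hour) and shape ``p``.  ``p = 1``
recovers the memoryless exponential; ``p > 1`` gives a rising hazard.
Some exits instead carry a constant hourly probability (deaths during
weaning and post-extubation, where events are too scarce to support a
fitted curve), and the "eligible" states 2, 4 and 6 mix a point mass at
zero dwell time with a Weibull for the patients who do wait.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Follow-up horizon of the model, in hours (28 days).
HORIZON_HOURS = 672

ARM_RS = "RS"
ARM_CS = "CS"
ARMS = (ARM_RS, ARM_CS)

#: Fixed resolution order for competing exits within one cycle.
CAUSE_PRIORITY = ("death", "switch", "progress")


class ConfigurationError(ValueError):
    """A model specification or configuration file is inconsistent."""


class DataError(ValueError):
    """Input records violate the documented schema or invariants."""


class EstimationError(RuntimeError):
    """A parameter could not be estimated from the supplied records."""


# ---------------------------------------------------------------------------
# Health states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HealthState:
    id: int
    label: str
    on_mv: bool
    absorbing: bool


STATES: tuple[HealthState, ...] = (
    HealthState(1, "MV-maintenance", True, False),
    HealthState(2, "MV-eligible-to-wean", True, False),
    HealthState(3, "MV-weaning", True, False),
    HealthState(4, "MV-eligible-to-extubate", True, False),
    HealthState(5, "post-extubation", False, False),
    HealthState(6, "post-extubation-eligible-discharge", False, False),
    HealthState(7, "discharged", False, True),
    HealthState(8, "death", False, True),
)

STATE_BY_ID: Mapping[int, HealthState] = {s.id: s for s in STATES}

DISCHARGED = 7
DEATH = 8
MV_STATES = (1, 2, 3, 4)
ICU_STATES = (1, 2, 3, 4, 5, 6)
#: States 2, 4 and 6 may be skipped instantaneously ("zero dwell").
ELIGIBLE_STATES = (2, 4, 6)
#: Successor of each transient state along the recovery pathway.
NEXT_STATE = {1: 2, 2: 3, 3: 4, 4: 5, 5: 6, 6: 7}


# ---------------------------------------------------------------------------
# Weibull survival mathematics
# ---------------------------------------------------------------------------

@dataclass
class WeibullParams:
    """Weibull dwell-time parameters ``S(t) = exp(-(L*t)**p)``.

    ``L`` is a rate per hour, ``p`` the dimensionless shape.  ``se_L``,
    ``se_p`` and ``corr_Lp`` hold bootstrap uncertainty for probabilistic
    sensitivity analysis; they default to zero (a point value).
    """

    L: float
    p: float
    se_L: float = 0.0
    se_p: float = 0.0
    corr_Lp: float = 0.0

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.p > 0):
            raise ConfigurationError(
                f"Weibull parameters must be positive, got L={self.L}, p={self.p}"
            )
        if self.se_L < 0 or self.se_p < 0:
            raise ConfigurationError("Weibull standard errors must be nonnegative")
        if not -1.0 <= self.corr_Lp <= 1.0:
            raise ConfigurationError(f"corr_Lp={self.corr_Lp} outside [-1, 1]")

    def point(self) -> "WeibullParams":
        """The same distribution with uncertainty stripped."""
        return WeibullParams(self.L, self.p)


def cumulative_hazard(t, w: WeibullParams):
    """Integrated hazard ``H(t) = (L*t)**p`` (vectorised over ``t``)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return (w.L * t) ** w.p


def weibull_survival(t, w: WeibullParams):
    """Survival probability ``S(t) = exp(-(L*t)**p)`` at ``t`` hours.

    Accepts scalars or arrays; raises ``ValueError`` for negative times.
    """
    out = np.exp(-cumulative_hazard(t, w))
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def hourly_transition_prob(t, w: WeibullParams):
    """Probability of leaving in hour ``t`` given occupancy at ``t - 1``.

    ``tp(t) = 1 - S(t)/S(t-1)``, computed via the cumulative hazard
    difference so it stays accurate when ``S`` underflows.  ``t`` indexes
    the hour ending at ``t`` since phase entry and must be >= 1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 1):
        raise ValueError("hour index must be >= 1")
    dh = cumulative_hazard(t_arr, w) - cumulative_hazard(t_arr - 1.0, w)
    out = -np.expm1(-dh)
    return float(out) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# Exit causes and phase specifications
# ---------------------------------------------------------------------------

EXIT_KINDS = ("weibull", "constant_hazard", "zero_dwell_mixture")


@dataclass
class ExitCause:
    """One competing way of leaving a phase.

    ``kind`` selects the dwell model: a fitted Weibull curve, a constant
    hourly probability, or a zero-dwell mixture (point mass at zero plus a
    Weibull for the patients who do wait; the point mass is resolved once,
    on phase entry).  ``cause`` labels the event ("progress", "death" or
    "switch") and fixes its priority within a cycle.
    """

    kind: str
    cause: str
    destination: int
    weibull: Optional[WeibullParams] = None
    hourly_prob: Optional[float] = None
    zero_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in EXIT_KINDS:
            raise ConfigurationError(f"unknown exit kind {self.kind!r}")
        if self.cause not in CAUSE_PRIORITY:
            raise ConfigurationError(f"unknown exit cause {self.cause!r}")
        if self.destination not in STATE_BY_ID:
            raise ConfigurationError(f"unknown destination state {self.destination}")
        if self.kind == "weibull":
            if self.weibull is None or self.hourly_prob is not None or self.zero_fraction is not None:
                raise ConfigurationError("weibull exit requires exactly a WeibullParams")
        elif self.kind == "constant_hazard":
            if self.hourly_prob is None or self.weibull is not None or self.zero_fraction is not None:
                raise ConfigurationError("constant_hazard exit requires exactly hourly_prob")
            if not 0.0 <= self.hourly_prob <= 1.0:
                raise ConfigurationError("hourly_prob outside [0, 1]")
        else:  # zero_dwell_mixture
            if self.zero_fraction is None or self.hourly_prob is not None:
                raise ConfigurationError("zero_dwell_mixture requires zero_fraction")
            if not 0.0 <= self.zero_fraction <= 1.0:
                raise ConfigurationError("zero_fraction outside [0, 1]")
            if self.weibull is None and self.zero_fraction < 1.0:
                raise ConfigurationError(
                    "zero_dwell_mixture with zero_fraction < 1 needs a Weibull component"
                )


@dataclass
class PhaseTransitionSpec:
    """All competing exits from one ``(state, arm)`` phase."""

    state: int
    arm: str
    exits: list[ExitCause] = field(default_factory=list)

    def __post_init__(self) -> None:
        st = STATE_BY_ID.get(self.state)
        if st is None:
            raise ConfigurationError(f"unknown state {self.state}")
        if self.arm not in ARMS:
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if st.absorbing:
            if self.exits:
                raise ConfigurationError(f"absorbing state {self.state} cannot have exits")
            return
        causes = [e.cause for e in self.exits]
        if "progress" not in causes:
            raise ConfigurationError(
                f"non-absorbing state {self.state} needs a progression exit"
            )
        if "switch" in causes and not (self.state == 1 and self.arm == ARM_RS):
            raise ConfigurationError("switch exits exist only for state 1 under RS")
        # Keep exits in fixed priority order (death -> switch -> progress).
        self.exits = sorted(self.exits, key=lambda e: CAUSE_PRIORITY.index(e.cause))


# ---------------------------------------------------------------------------
# Transition tables
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    """Precomputed per-hour exit probabilities for one phase.

    ``probs[t-1, j]`` is the marginal probability that exit ``j`` fires in
    hour ``t``, after the row-sum cap.  ``survival[t]`` is the probability
    of still occupying the phase after hour ``t`` under the sequential
    conditional-Bernoulli competing rule (``survival[0] = 1``), and
    ``cause_given_exit[t-1, j]`` the conditional cause split for an exit in
    hour ``t``.  ``zero_fraction`` carries the entry point mass for
    zero-dwell mixtures (0 otherwise).
    """

    spec: PhaseTransitionSpec
    horizon: int
    exits: list[ExitCause]
    probs: np.ndarray
    survival: np.ndarray
    cause_given_exit: np.ndarray
    zero_fraction: float


def build_transition_table(spec: PhaseTransitionSpec, horizon: int = HORIZON_HOURS) -> TransitionTable:
    """Tabulate hourly exit probabilities for hours ``1..horizon``.

    Competing exits are resolved each hour in the fixed priority order
    death -> switch -> progress, each as a Bernoulli conditional on the
    earlier causes not firing.  If the naive sum of marginal probabilities
    in an hour exceeds 1 (possible only at extreme sensitivity-analysis
    draws), the row is renormalised proportionally and a warning logged.
    """
    if horizon < 1:
        raise ConfigurationError("horizon must be >= 1 hour")
    hours = np.arange(1, horizon + 1, dtype=float)
    exits = spec.exits
    zero_fraction = 0.0
    cols = []
    for ex in exits:
        if ex.kind == "weibull":
            cols.append(hourly_transition_prob(hours, ex.weibull))
        elif ex.kind == "constant_hazard":
            cols.append(np.full(horizon, ex.hourly_prob, dtype=float))
        else:  # zero_dwell_mixture: the point mass is applied at entry
            zero_fraction = ex.zero_fraction
            if ex.weibull is not None:
                cols.append(hourly_transition_prob(hours, ex.weibull))
            else:
                cols.append(np.zeros(horizon))
    probs = np.column_stack(cols) if cols else np.zeros((horizon, 0))

    row_sum = probs.sum(axis=1)
    over = row_sum > 1.0
    if np.any(over):
        logger.warning(
            "transition table state %s/%s: capping %d hour(s) whose competing "
            "probabilities sum above 1", spec.state, spec.arm, int(over.sum()),
        )
        probs[over] /= row_sum[over][:, None]

    # Sequential conditional Bernoulli in priority order: the chance that
    # cause j fires in hour t is p_j(t) * prod_{i<j} (1 - p_i(t)).
    n_exits = probs.shape[1]
    seq = np.empty_like(probs)
    cont = np.ones(horizon)
    for j in range(n_exits):
        seq[:, j] = cont * probs[:, j]
        cont = cont * (1.0 - probs[:, j])
    exit_prob = 1.0 - cont
    survival = np.concatenate([[1.0], np.cumprod(cont)])
    with np.errstate(invalid="ignore", divide="ignore"):
        cause_given_exit = np.where(exit_prob[:, None] > 0.0, seq / exit_prob[:, None], 0.0)
    return TransitionTable(spec, horizon, exits, probs, survival, cause_given_exit, zero_fraction)


def transition_table_frame(table: TransitionTable) -> pd.DataFrame:
    """Tidy export: columns state, arm, exit_cause, hour, probability."""
    frames = []
    hours = np.arange(1, table.horizon + 1)
    for j, ex in enumerate(table.exits):
        frames.append(pd.DataFrame({
            "state": table.spec.state,
            "arm": table.spec.arm,
            "exit_cause": ex.cause,
            "hour": hours,
            "probability": table.probs[:, j],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Full model parameter set
# ---------------------------------------------------------------------------

@dataclass
class EligibleDwell:
    """Zero-dwell mixture for the eligible states 2, 4 and 6."""

    zero_fraction: float
    weibull: Optional[WeibullParams]
    se_zero: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ConfigurationError("zero_fraction outside [0, 1]")
        if self.weibull is None and self.zero_fraction < 1.0:
            raise ConfigurationError("nonzero-dwell component missing")


@dataclass
class ConstantHazard:
    """Constant hourly event probability with its standard error."""

    hourly_prob: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hourly_prob <= 1.0:
            raise ConfigurationError("hourly_prob outside [0, 1]")


@dataclass
class ModelParameters:
    """Every transition parameter of the model, both arms.

    Keys follow the pooling structure of the analysis: time-to-next-phase
    curves are arm-specific while on the ventilator (``s1_CS``/``s1_RS``,
    ``s3_CS``/``s3_RS``, likewise the eligible-state mixtures ``s2_*`` and
    ``s4_*``), death in the maintenance phase is a single pooled Weibull,
    deaths during weaning and post-extubation are pooled constant hourly
    probabilities, and everything after extubation (``s5``, ``s6``) is
    shared between the arms.  ``switch_s1`` is the RS time-to-switch curve.
    """

    progression: dict[str, WeibullParams]
    eligible: dict[str, EligibleDwell]
    death_s1: WeibullParams
    death_s3: ConstantHazard
    death_s5: ConstantHazard
    switch_s1: Optional[WeibullParams] = None

    _PROG_KEYS = ("s1_CS", "s1_RS", "s3_CS", "s3_RS", "s5")
    _ELIG_KEYS = ("s2_CS", "s2_RS", "s4_CS", "s4_RS", "s6")

    def __post_init__(self) -> None:
        missing = [k for k in self._PROG_KEYS if k not in self.progression]
        missing += [k for k in self._ELIG_KEYS if k not in self.eligible]
        if missing:
            raise ConfigurationError(f"missing model parameters: {missing}")

    # -- phase specs ------------------------------------------------------

    def spec_for(self, state: int, arm: str) -> PhaseTransitionSpec:
        """The competing-exit specification for one ``(state, arm)`` phase."""
        if arm not in ARMS:
            raise ConfigurationError(f"unknown arm {arm!r}")
        if state in (DISCHARGED, DEATH):
            return PhaseTransitionSpec(state, arm, [])
        if state == 1:
            exits = [
                ExitCause("weibull", "death", DEATH, weibull=self.death_s1),
                ExitCause("weibull", "progress", 2, weibull=self.progression[f"s1_{arm}"]),
            ]
            if arm == ARM_RS:
                if self.switch_s1 is None:
                    raise ConfigurationError("RS maintenance requires a switch curve")
                exits.insert(1, ExitCause("weibull", "switch", 1, weibull=self.switch_s1))
            return PhaseTransitionSpec(1, arm, exits)
        if state == 3:
            return PhaseTransitionSpec(3, arm, [
                ExitCause("constant_hazard", "death", DEATH, hourly_prob=self.death_s3.hourly_prob),
                ExitCause("weibull", "progress", 4, weibull=self.progression[f"s3_{arm}"]),
            ])
        if state == 5:
            return PhaseTransitionSpec(5, arm, [
                ExitCause("constant_hazard", "death", DEATH, hourly_prob=self.death_s5.hourly_prob),
                ExitCause("weibull", "progress", 6, weibull=self.progression["s5"]),
            ])
        if state in ELIGIBLE_STATES:
            key = "s6" if state == 6 else f"s{state}_{arm}"
            el = self.eligible[key]
            return PhaseTransitionSpec(state, arm, [
                ExitCause("zero_dwell_mixture", "progress", NEXT_STATE[state],
                          weibull=el.weibull, zero_fraction=el.zero_fraction),
            ])
        raise ConfigurationError(f"unknown state {state}")

    def build_tables(self, horizon: int = HORIZON_HOURS) -> dict[tuple[int, str], TransitionTable]:
        """Precompute transition tables for every reachable ``(state, arm)``."""
        return {
            (state, arm): build_transition_table(self.spec_for(state, arm), horizon)
            for arm in ARMS for state in (1, 2, 3, 4, 5, 6)
        }

    def point(self) -> "ModelParameters":
        """A copy with all uncertainty stripped (base-case point values)."""
        return ModelParameters(
            progression={k: w.point() for k, w in self.progression.items()},
            eligible={k: EligibleDwell(e.zero_fraction, None if e.weibull is None else e.weibull.point())
                      for k, e in self.eligible.items()},
            death_s1=self.death_s1.point(),
            death_s3=ConstantHazard(self.death_s3.hourly_prob),
            death_s5=ConstantHazard(self.death_s5.hourly_prob),
            switch_s1=None if self.switch_s1 is None else self.switch_s1.point(),
        )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        def wdict(w: WeibullParams) -> dict:
            return {"L": float(w.L), "p": float(w.p), "se_L": float(w.se_L),
                    "se_p": float(w.se_p), "corr_Lp": float(w.corr_Lp)}

        return {
            "progression": {k: wdict(w) for k, w in self.progression.items()},
            "eligible": {
                k: {"zero_fraction": float(e.zero_fraction), "se_zero": float(e.se_zero),
                    "weibull": None if e.weibull is None else wdict(e.weibull)}
                for k, e in self.eligible.items()
            },
            "death_s1": wdict(self.death_s1),
            "death_s3": {"hourly_prob": float(self.death_s3.hourly_prob), "se": float(self.death_s3.se)},
            "death_s5": {"hourly_prob": float(self.death_s5.hourly_prob), "se": float(self.death_s5.se)},
            "switch_s1": None if self.switch_s1 is None else wdict(self.switch_s1),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        def wp(x) -> WeibullParams:
            return WeibullParams(**x)

        return cls(
            progression={k: wp(v) for k, v in d["progression"].items()},
            eligible={
                k: EligibleDwell(v["zero_fraction"],
                                 None if v.get("weibull") is None else wp(v["weibull"]),
                                 v.get("se_zero", 0.0))
                for k, v in d["eligible"].items()
            },
            death_s1=wp(d["death_s1"]),
            death_s3=ConstantHazard(**d["death_s3"]),
            death_s5=ConstantHazard(**d["death_s5"]),
            switch_s1=None if d.get("switch_s1") is None else wp(d["switch_s1"]),
        )


def config_digest(payload: Mapping) -> str:
    """Short stable hash of a configuration mapping, for output provenance."""
    import json

    blob = json.dumps(payload, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
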