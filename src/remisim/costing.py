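"""Cost inputs and cost accumulation over a patient history.

Two components drive the 28-day cost from the hospital perspective (2006
price level): the per-hour cost of an ICU bed, which differs between hours
on and off mechanical ventilation, and the per-hour cost of sedation and
analgesia, which differs by treatment arm and by phase (before weaning has
started, states 1-2, versus during weaning, states 3-4; after extubation no
study drugs are given).  Hourly sedation costs derive from mean daily drug
doses and per-milligram prices via micro-costing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .model_core import (
    ARM_CS,
    ARM_RS,
    ARMS,
    DEATH,
    DISCHARGED,
    HORIZON_HOURS,
    STATE_BY_ID,
    ConfigurationError,
    DataError,
)

PHASE_BEFORE = "before_weaning"
PHASE_DURING = "during_weaning"

#: Drug acquisition prices in EUR per mg (Dutch hospital pharmacies, 2006).
DEFAULT_UNIT_COSTS: dict[str, float] = {
    "morphine": 0.02,
    "midazolam": 0.035,
    "fentanyl": 0.35,
    "lorazepam": 0.04,
    "sufentanil_forte": 25.0,
    "propofol": 0.02,
    "remifentanil": 7.71,
}

#: Mean daily doses (mg/patient/day) by arm and phase, the micro-costing inputs.
DEFAULT_DAILY_DOSES: dict[tuple[str, str], dict[str, float]] = {
    (ARM_CS, PHASE_BEFORE): {
        "morphine": 71.7, "midazolam": 194.2, "fentanyl": 0.8,
        "lorazepam": 2.9, "sufentanil_forte": 0.05, "propofol": 1057.4,
        "remifentanil": 0.0,
    },
    (ARM_CS, PHASE_DURING): {
        "morphine": 46.5, "midazolam": 12.9, "fentanyl": 0.3,
        "lorazepam": 0.1, "sufentanil_forte": 0.0, "propofol": 381.8,
        "remifentanil": 0.0,
    },
    (ARM_RS, PHASE_BEFORE): {
        "morphine": 1.0, "midazolam": 45.9, "fentanyl": 0.0,
        "lorazepam": 0.0, "sufentanil_forte": 0.0, "propofol": 1627.6,
        "remifentanil": 18.8,
    },
    (ARM_RS, PHASE_DURING): {
        "morphine": 2.4, "midazolam": 0.0, "fentanyl": 0.0,
        "lorazepam": 0.0, "sufentanil_forte": 0.0, "propofol": 662.2,
        "remifentanil": 10.3,
    },
}


def sedation_cost_per_hour(daily_doses: Mapping[str, float],
                           unit_costs: Optional[Mapping[str, float]] = None) -> float:
    """Hourly sedation cost from mean daily doses: sum(mg/day * EUR/mg) / 24.

    Raises :class:`ConfigurationError` for a drug without a unit price and
    :class:`ValueError` for negative doses.
    """
    if unit_costs is None:
        unit_costs = DEFAULT_UNIT_COSTS
    total = 0.0
    for drug, mg_per_day in daily_doses.items():
        if drug not in unit_costs:
            raise ConfigurationError(f"no unit cost for drug {drug!r}")
        if mg_per_day < 0:
            raise ValueError(f"negative dose for {drug!r}")
        total += mg_per_day * unit_costs[drug]
    return total / 24.0


@dataclass
class CostValue:
    mean: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ConfigurationError("standard errors must be nonnegative")


@dataclass
class CostParams:
    """Unit costs of the model: sedation EUR/hour by (arm, phase) and ICU
    bed EUR/day by ventilation status, each with its standard error.

    The base-case values are the published micro-costing outputs; the hourly
    sedation figures are inputs in their own right (their SEs already carry
    the dose uncertainty), not recomputed from the dose table.
    """

    sedation_eur_per_hour: dict[tuple[str, str], CostValue] = field(default_factory=lambda: {
        (ARM_CS, PHASE_BEFORE): CostValue(1.30, 0.13),
        (ARM_RS, PHASE_BEFORE): CostValue(7.47, 0.27),
        (ARM_CS, PHASE_DURING): CostValue(0.41, 0.12),
        (ARM_RS, PHASE_DURING): CostValue(3.85, 0.41),
    })
    icu_eur_per_day_mv: CostValue = field(default_factory=lambda: CostValue(2106.0, 102.0))
    icu_eur_per_day_nomv: CostValue = field(default_factory=lambda: CostValue(1645.0, 107.0))

    def __post_init__(self) -> None:
        for key in ((ARM_CS, PHASE_BEFORE), (ARM_RS, PHASE_BEFORE),
                    (ARM_CS, PHASE_DURING), (ARM_RS, PHASE_DURING)):
            if key not in self.sedation_eur_per_hour:
                raise ConfigurationError(f"missing sedation cost for {key}")

    def sedation_rate(self, arm: str, state: int) -> float:
        """EUR/hour of sedation for a patient of ``arm`` occupying ``state``."""
        if state in (1, 2):
            return self.sedation_eur_per_hour[(arm, PHASE_BEFORE)].mean
        if state in (3, 4):
            return self.sedation_eur_per_hour[(arm, PHASE_DURING)].mean
        return 0.0

    def icu_rate(self, state: int) -> float:
        """EUR/hour of ICU stay for ``state`` (zero once discharged or dead)."""
        st = STATE_BY_ID[state]
        if st.absorbing:
            return 0.0
        day = self.icu_eur_per_day_mv.mean if st.on_mv else self.icu_eur_per_day_nomv.mean
        return day / 24.0

    def point(self) -> "CostParams":
        return CostParams(
            sedation_eur_per_hour={k: CostValue(v.mean) for k, v in self.sedation_eur_per_hour.items()},
            icu_eur_per_day_mv=CostValue(self.icu_eur_per_day_mv.mean),
            icu_eur_per_day_nomv=CostValue(self.icu_eur_per_day_nomv.mean),
        )

    def to_dict(self) -> dict:
        return {
            "sedation_eur_per_hour": {
                f"{arm}/{phase}": {"mean": v.mean, "se": v.se}
                for (arm, phase), v in self.sedation_eur_per_hour.items()
            },
            "icu_eur_per_day_mv": {"mean": self.icu_eur_per_day_mv.mean, "se": self.icu_eur_per_day_mv.se},
            "icu_eur_per_day_nomv": {"mean": self.icu_eur_per_day_nomv.mean, "se": self.icu_eur_per_day_nomv.se},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CostParams":
        sed = {}
        for key, v in d["sedation_eur_per_hour"].items():
            arm, phase = key.split("/")
            sed[(arm, phase)] = CostValue(v["mean"], v.get("se", 0.0))
        return cls(
            sedation_eur_per_hour=sed,
            icu_eur_per_day_mv=CostValue(**d["icu_eur_per_day_mv"]),
            icu_eur_per_day_nomv=CostValue(**d["icu_eur_per_day_nomv"]),
        )


def accumulate_costs(history, costs: CostParams) -> float:
    """Total 28-day cost of one simulated patient history.

    Each occupied hour contributes the ICU bed rate of the current state
    plus the sedation rate of the current state and *current* arm: a
    remifentanil patient who switched accrues conventional-arm sedation
    rates from the switch hour onward.  Hours after ICU discharge or death
    contribute nothing.

    ``history`` is a :class:`remisim.microsim.PatientHistory`; segments
    must be contiguous and within the 28-day horizon.
    """
    total = 0.0
    prev_end = None
    for state, entry, exit_ in history.segments:
        if exit_ < entry or entry < 0 or exit_ > HORIZON_HOURS:
            raise DataError(f"segment ({state}, {entry}, {exit_}) outside [0, {HORIZON_HOURS}]")
        if prev_end is not None and entry != prev_end:
            raise DataError("history segments must be contiguous")
        prev_end = exit_
        if STATE_BY_ID[state].absorbing:
            continue
        hours = exit_ - entry
        icu = costs.icu_rate(state)
        sw = history.switched_at
        if (history.arm_initial == ARM_RS and sw is not None and state == 1
                and entry < sw < exit_):
            # split the maintenance segment at the switch hour
            total += (sw - entry) * (icu + costs.sedation_rate(ARM_RS, state))
            total += (exit_ - sw) * (icu + costs.sedation_rate(ARM_CS, state))
            continue
        arm = history.arm_initial
        if arm == ARM_RS and sw is not None and entry >= sw:
            arm = ARM_CS
        total += hours * (icu + costs.sedation_rate(arm, state))
    return total
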