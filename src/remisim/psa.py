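"""Probabilistic sensitivity analysis.

Every model input is redrawn from its uncertainty distribution, the cohort
simulation is rerun, and the spread of the replicate outcomes quantifies
parameter uncertainty.  Scalar inputs (constant death probabilities,
zero-dwell fractions, hourly sedation costs, per-day ICU costs) are drawn
as independent normals with their standard errors, redrawn while outside
their domain.  Each Weibull (L, p) pair is drawn jointly: first L from its
marginal, then p from its conditional distribution given the drawn L under
a bivariate (log-)normal with the bootstrapped correlation.  Pairs whose
normal marginal would put more than 1% of its mass below zero use
lognormal marginals instead (moment-matched); the rest stay normal.

Uncertainty summaries are percentile intervals whose endpoints are exact
order statistics of the replicate differences, plus the probability that
the conventional-minus-remifentanil difference is positive (the
probability that the remifentanil strategy saves time or money).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .costing import CostParams, CostValue
from .microsim import onlabel_subgroup, patient_costs, run_cohort, summarize_patients
from .model_core import (
    ConfigurationError,
    ConstantHazard,
    EligibleDwell,
    ModelParameters,
    WeibullParams,
)

logger = logging.getLogger(__name__)

#: z beyond which a normal marginal keeps < 1% mass below zero.
LOGNORMAL_Z = 2.3263478740408408  # Phi^{-1}(0.99)

DIFF_KEYS = ("los_icu_days", "los_mv_days", "cost_eur")


class DistributionError(ValueError):
    """A parameter distribution kept producing out-of-domain draws."""


@dataclass
class ParameterDistributionSpec:
    """Joint uncertainty specification: base-case parameters with SEs.

    ``lognormal_pairs`` records, per Weibull, whether lognormal marginals
    were selected by the <1%-mass-below-zero rule (resolved at build time
    and logged, so a run documents its own distribution choices).
    """

    params: ModelParameters
    costs: CostParams
    lognormal_pairs: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lognormal_pairs:
            for name, w in self._weibulls():
                self.lognormal_pairs[name] = _needs_lognormal(w)
                if self.lognormal_pairs[name]:
                    logger.info("PSA: lognormal marginals for Weibull pair %s", name)

    def _weibulls(self):
        p = self.params
        for k, w in p.progression.items():
            yield f"progression.{k}", w
        for k, e in p.eligible.items():
            if e.weibull is not None:
                yield f"eligible.{k}", e.weibull
        yield "death_s1", p.death_s1
        if p.switch_s1 is not None:
            yield "switch_s1", p.switch_s1


def _needs_lognormal(w: WeibullParams) -> bool:
    for mean, se in ((w.L, w.se_L), (w.p, w.se_p)):
        if se > 0 and mean / se < LOGNORMAL_Z:
            return True
    return False


# ---------------------------------------------------------------------------
# Drawing
# ---------------------------------------------------------------------------

def _draw_scalar(mean: float, se: float, rng, low: float = 0.0,
                 high: float = math.inf, max_attempts: int = 100,
                 low_open: bool = True) -> float:
    """Normal draw redrawn until inside the domain (max 100 attempts)."""
    if se == 0.0:
        return mean
    for _ in range(max_attempts):
        x = rng.normal(mean, se)
        if (x > low if low_open else x >= low) and x <= high:
            return float(x)
    raise DistributionError(
        f"no in-domain draw from N({mean}, {se}) within {max_attempts} attempts")


def _draw_weibull_pair(w: WeibullParams, rng, lognormal: bool,
                       max_attempts: int = 100) -> WeibullParams:
    """Draw (L, p): L from its marginal, then p | L (bivariate (log)normal)."""
    if w.se_L == 0.0 and w.se_p == 0.0:
        return WeibullParams(w.L, w.p)
    rho = w.corr_Lp
    if lognormal:
        # moment-matched lognormal marginals; the bootstrap correlation is
        # applied on the log scale
        def logmoments(mean, se):
            s2 = math.log1p((se / mean) ** 2)
            return math.log(mean) - s2 / 2.0, math.sqrt(s2)

        mu_L, sd_L = logmoments(w.L, w.se_L) if w.se_L > 0 else (math.log(w.L), 0.0)
        mu_p, sd_p = logmoments(w.p, w.se_p) if w.se_p > 0 else (math.log(w.p), 0.0)
        zL = rng.normal(mu_L, sd_L)
        cond_mu = mu_p + (rho * sd_p / sd_L * (zL - mu_L) if sd_L > 0 else 0.0)
        cond_sd = sd_p * math.sqrt(max(0.0, 1.0 - rho * rho))
        zp = rng.normal(cond_mu, cond_sd)
        return WeibullParams(math.exp(zL), math.exp(zp))
    for _ in range(max_attempts):
        L = rng.normal(w.L, w.se_L)
        if w.se_L > 0 and L <= 0:
            continue
        cond_mu = w.p + (rho * w.se_p / w.se_L * (L - w.L) if w.se_L > 0 else 0.0)
        cond_sd = w.se_p * math.sqrt(max(0.0, 1.0 - rho * rho))
        p = rng.normal(cond_mu, cond_sd)
        if p > 0:
            return WeibullParams(float(L), float(p))
    raise DistributionError("no positive (L, p) draw within 100 attempts")


def draw_parameter_set(spec: ParameterDistributionSpec, rng):
    """One full draw of all model parameters and costs.

    Returns point-valued ``(ModelParameters, CostParams)``.  All SEs zero
    reproduces the base case exactly.
    """
    P = spec.params
    progression = {k: _draw_weibull_pair(w, rng, spec.lognormal_pairs[f"progression.{k}"])
                   for k, w in P.progression.items()}
    eligible = {}
    for k, e in P.eligible.items():
        frac = _draw_scalar(e.zero_fraction, e.se_zero, rng, low=0.0, high=1.0, low_open=False)
        wb = None if e.weibull is None else _draw_weibull_pair(
            e.weibull, rng, spec.lognormal_pairs[f"eligible.{k}"])
        eligible[k] = EligibleDwell(frac, wb)
    params = ModelParameters(
        progression=progression,
        eligible=eligible,
        death_s1=_draw_weibull_pair(P.death_s1, rng, spec.lognormal_pairs["death_s1"]),
        death_s3=ConstantHazard(_draw_scalar(P.death_s3.hourly_prob, P.death_s3.se, rng,
                                             low=0.0, high=1.0, low_open=False)),
        death_s5=ConstantHazard(_draw_scalar(P.death_s5.hourly_prob, P.death_s5.se, rng,
                                             low=0.0, high=1.0, low_open=False)),
        switch_s1=None if P.switch_s1 is None else _draw_weibull_pair(
            P.switch_s1, rng, spec.lognormal_pairs["switch_s1"]),
    )
    C = spec.costs
    costs = CostParams(
        sedation_eur_per_hour={
            k: CostValue(_draw_scalar(v.mean, v.se, rng, low=0.0, low_open=False))
            for k, v in C.sedation_eur_per_hour.items()},
        icu_eur_per_day_mv=CostValue(_draw_scalar(C.icu_eur_per_day_mv.mean,
                                                  C.icu_eur_per_day_mv.se, rng)),
        icu_eur_per_day_nomv=CostValue(_draw_scalar(C.icu_eur_per_day_nomv.mean,
                                                    C.icu_eur_per_day_nomv.se, rng)),
    )
    return params, costs


# ---------------------------------------------------------------------------
# Running the analysis
# ---------------------------------------------------------------------------

def percentile_order_stat(values: np.ndarray, q: float) -> float:
    """Percentile as an exact order statistic: the ceil(q*n)-th smallest."""
    x = np.sort(np.asarray(values, dtype=float))
    k = max(int(math.ceil(q * len(x))), 1)
    return float(x[k - 1])


@dataclass
class PSAResult:
    """Replicate-level outcomes and their uncertainty summaries.

    ``ci`` holds the 2.5th/97.5th exact-order-statistic percentiles of each
    CS-minus-RS difference; ``p_positive`` the fraction of replicates where
    the difference is strictly positive.
    """

    n_reps: int
    replicates: pd.DataFrame
    ci: dict[str, tuple[float, float]]
    p_positive: dict[str, float]
    seed: Optional[int] = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.ci:
            lo, hi = self.ci[key]
            rows.append({"outcome": key, "ci_lower": lo, "ci_upper": hi,
                         "p_diff_positive": self.p_positive[key]})
        return pd.DataFrame(rows)


def run_psa(params: ModelParameters, costs: CostParams, n_reps: int = 1500,
            inner_n: int = 2000, seed: Optional[int] = None,
            record_subgroup: bool = False, max_failure_frac: float = 0.05,
            common_random_numbers: bool = False) -> PSAResult:
    """Draw parameters, rerun the cohort model, summarise the differences.

    Per replicate the full parameter set is redrawn and a cohort of
    ``inner_n`` patients per arm is simulated.  All replicates share one
    inner-simulation random stream (common random numbers across
    replicates), so the spread of the replicate outcomes isolates
    parameter uncertainty from Monte-Carlo noise; with all SEs zero every
    replicate is identical.  A replicate whose draw falls outside its
    domain is redrawn with a fresh stream and logged; more than
    ``max_failure_frac`` failures aborts.  Reproducible for a fixed
    ``seed``.
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2")
    spec = ParameterDistributionSpec(params, costs)
    root = np.random.SeedSequence(seed)
    inner_seed = int(root.generate_state(1)[0] % np.uint32(2**31))
    streams = iter(root.spawn(n_reps * 3))  # headroom for redraws
    rows = []
    failures = 0
    rep = 0
    while rep < n_reps:
        ss = next(streams)
        rng = np.random.default_rng(ss)
        try:
            p_draw, c_draw = draw_parameter_set(spec, rng)
        except DistributionError as err:
            failures += 1
            logger.warning("PSA replicate draw failed (%s); redrawing", err)
            if failures > max_failure_frac * n_reps:
                raise DistributionError(
                    f"more than {max_failure_frac:.0%} of PSA draws failed") from err
            continue
        res, patients = run_cohort(p_draw, c_draw, n_per_arm=inner_n,
                                   seed=inner_seed,
                                   common_random_numbers=common_random_numbers,
                                   return_patients=True)
        row = {"rep": rep}
        for arm, o in res.per_arm.items():
            row[f"los_icu_days_{arm}"] = o.mean_los_icu_days
            row[f"los_mv_days_{arm}"] = o.mean_los_mv_days
            row[f"cost_eur_{arm}"] = o.mean_cost_eur
        for k in DIFF_KEYS:
            row[f"diff_{k}"] = res.differences[k]
        if record_subgroup:
            sub = onlabel_subgroup(patients)
            for k in DIFF_KEYS:
                row[f"subgroup_diff_{k}"] = (np.nan if sub is None or not sub.differences
                                             else sub.differences[k])
        rows.append(row)
        rep += 1

    replicates = pd.DataFrame(rows)
    keys = [f"diff_{k}" for k in DIFF_KEYS]
    if record_subgroup:
        keys += [f"subgroup_diff_{k}" for k in DIFF_KEYS]
    ci = {}
    p_pos = {}
    for key in keys:
        vals = replicates[key].dropna().to_numpy()
        ci[key] = (percentile_order_stat(vals, 0.025), percentile_order_stat(vals, 0.975))
        p_pos[key] = float((vals > 0).sum() / len(vals))
    return PSAResult(n_reps=n_reps, replicates=replicates, ci=ci,
                     p_positive=p_pos, seed=seed)
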