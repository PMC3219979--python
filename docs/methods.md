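# Methods

This note documents the model, its estimation machinery, the synthetic
trial generator, and the numerical and design choices a maintainer needs to
know. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Model structure and assumptions

The model is a discrete-time semi-Markov micro-simulation with a one-hour
cycle and a fixed 28-day (672-hour) horizon. Eight health states describe
an ICU stay on mechanical ventilation (MV): maintenance, eligible-to-wean,
weaning, eligible-to-extubate, post-extubation, eligible-for-discharge,
discharged, death. Progression is strictly sequential; death can interrupt
from any ventilated or post-extubation phase; remifentanil-arm (RS)
patients can switch to the conventional regimen (CS) while in maintenance.

Structural assumptions:

- **Semi-Markov clock.** Each phase's exit probabilities depend on time
  since entering that phase, not calendar time: `tp(t) = 1 − S(t)/S(t−1)`
  with Weibull `S(t) = exp(−(L t)^p)`. `tp` is computed from the
  cumulative-hazard difference `−expm1(−[(Lt)^p − (L(t−1))^p])`, which
  stays accurate when `S` underflows.
- **Pooling.** Death inputs are pooled across arms (no mortality difference
  is modelled); post-extubation transitions are shared between arms. The
  arm effect therefore lives entirely in the ventilated phases, which is
  why the ICU-stay difference is carried by the MV-time difference.
- **Zero-dwell mixtures.** States 2, 4 and 6 mix a point mass at zero dwell
  (resolved by one Bernoulli draw at entry) with a Weibull for patients who
  do wait. Zero-dwell fractions are arm-specific on MV and pooled
  post-extubation.
- **Scarce deaths.** Maintenance deaths follow a fitted Weibull; weaning
  and post-extubation deaths use constant hourly probabilities matched to
  the observed occurrence rate (`1 − exp(−events/exposure)`).
- **Switching.** Time-to-switch is its own Weibull curve (not a fixed
  fraction). After a switch the patient continues in maintenance under CS
  dynamics with the phase clock running on (not reset — a documented choice
  where the design was open), uses CS curves downstream, and accrues CS
  sedation costs from the switch hour onward.

## Within-cycle competing risks

Nothing in the hourly-hazard formulation itself dictates how simultaneous
exits within one cycle are resolved. Chosen rule: evaluate exits in the
fixed priority order
**death → switch → progression**, each as a Bernoulli conditional on the
earlier causes not firing. Because hourly probabilities are small the
ordering is numerically immaterial in practice; it is fixed and documented
so runs are reproducible. If a naive sum of competing marginal
probabilities exceeds 1 (possible only at extreme PSA draws), the row is
renormalised proportionally and a warning logged.

The vectorised cohort engine samples each phase's exit hour by inverse
transform on the discrete survival curve implied by this rule and then the
cause from the conditional cause split of that hour; this is exactly
equivalent to the per-hour Bernoulli loop (`simulate_patient`, kept as a
readable reference and cross-checked distributionally in the tests).

## Costs

Hourly cost = ICU bed rate (EUR 2,106/24 on MV, EUR 1,645/24 off MV, 2006
price level) + sedation rate by current arm and phase: before-weaning rates
in states 1–2, during-weaning rates in states 3–4, zero after extubation.
The published hourly sedation rates are used as inputs with their SEs (the
SEs already carry dose uncertainty); the dose table and per-mg prices are
kept to show the derivation. The published CS during-weaning rate
(EUR 0.41/h) does not recompute exactly from the dose table (≈ EUR 0.38/h,
presumably dose rounding upstream); the published value is taken as the
base case and the discrepancy is pinned in a test. No discounting over the
28-day horizon; prices fixed at 2006 levels. Patients still in a transient
state at hour 672 are administratively censored and contribute their
accrued LOS and costs; with hourly cycles a half-cycle correction is
immaterial and not applied.

## Estimation

Right-censored Weibull maximum likelihood on `(log L, log p)` (positivity
by construction), multi-started from the closed-form exponential
initialiser with shapes {0.5, 1, 2}, L-BFGS-B with analytic gradients, and
a Nelder-Mead polish if the gradient norm exceeds 1e−8. Competing exits are
treated as censored per cause (fitting time-to-next-phase censors deaths
and switches, and symmetrically). Records with zero dwell are excluded from
Weibull fitting — the point mass handles them. At least two observed events
are required per fit. Uncertainty comes from a patient-level bootstrap
(default B = 1,000; point estimates stay at the full-data fit; replicates
without enough events are discarded, more than 10% discarded is an error).
The bootstrap B for the original analysis is unstated; the default is a
conventional choice.

## Probabilistic sensitivity analysis

Scalars (constant death probabilities, zero-dwell fractions, sedation and
ICU day costs) are drawn as independent normals with their SEs, redrawn
while out of domain (≤ 100 attempts, then an error; a failed replicate is
redrawn with a fresh stream, > 5% failures aborts). Weibull pairs are drawn
jointly: L from its marginal, then p from the bivariate-normal conditional
with the bootstrap correlation. Pairs whose normal marginal would put more
than 1% of mass below zero (mean/SE < Φ⁻¹(0.99) ≈ 2.33) switch to
moment-matched lognormal marginals, with the correlation applied on the log
scale (an approximation, logged per pair). Which pairs go lognormal is thus
a data-driven rule, resolved at run time — with the demonstration
parameters it is the scarce-death curve.

All replicates share one inner-cohort random stream (common random numbers
across replicates): with all SEs zero every replicate is exactly identical,
and the replicate spread isolates parameter uncertainty from inner
Monte-Carlo noise. A flag additionally enables common random numbers across
arms (used by the symmetry tests). Interval endpoints are exact order
statistics (the ⌈q·n⌉-th smallest replicate), and P(diff > 0) is the exact
fraction of strictly positive replicate differences. The default outer ×
inner size is 1,500 × 2,000; the inner size keeps a desk-scale runtime and
is a flag.

## Synthetic trial generator

The generator emulates the observable structure of the trial it stands in
for: two arms (CS n = 109, RS n = 96), continuous-time dwell draws from known true
parameters with competing death/switch exits, censoring of ventilated
phases once cumulative MV time reaches 240 h (day 10), observation stop at
672 h, switch records ending observation, and per-patient daily doses from
lognormals moment-matched to the published dose table (between-patient SD
recovered from the published SEs times √n of the reference arm).

The default true parameters are **illustrative**, not estimates of the real
trial: they were calibrated once so that the generated data reproduce the
reported observable margins — ≈ 21% of CS and ≈ 8% of RS patients
MV-censored at day 10, ≈ 11% of RS patients switching — and the model's
median MV stays land near the reference medians of 5.0/3.7 days (the
calibrated configuration gives ≈ 5.2/3.9). The maintenance-phase weaning
hazards cross near hour 56 (RS above CS over the first two days, below
after three), reproducing the known time-dependence of the remifentanil
effect: a large early advantage in reaching weaning that fades after
about three days. Attached SEs are sized
like bootstrap output from a ~100-patient/arm trial and drive the
demonstration PSA.

What the generator does *not* emulate: patient covariates (severity scores,
diagnoses), between-centre variation of the 15-centre crossover design,
informative censoring, or dose–LOS correlation. Passing round-trip tests
therefore demonstrates estimator correctness under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own trade-off between statistical resolution and a
desk-scale run:

- Base-case cohort: 10,000 patients/arm (Monte-Carlo SE of mean LOS
  < 0.05 day). Acceptance script: same; PSA 500 × 1,000 there, with the
  1,500 × 2,000 default available via flags.
- Exponential closed-form limit: 100,000 patients, 3 MC SEs.
- Parameter recovery: 40,000/arm. The recovery tolerance (5%) is only
  meaningful when the estimator's sampling SD is well below it; the
  rare-event curves (switching ≈ 11% of RS patients, maintenance deaths
  ≈ 10%) sit at 4–5% relative SD at 5,000/arm — at their information
  floor — so the recovery check runs at a size where every curve's SD is
  ≤ 2%. Calibration margins are checked at the 5,000/arm scale, averaged
  over four generated trials, against two single-trial binomial SEs of the
  targets.
- PSA contract: exactness properties (zero-width intervals, order
  statistics) at small replicate counts; the symmetry check at 800
  replicates with common random numbers across arms.

## Known limitations

- The hourly discretisation biases dwell means by up to half a cycle
  relative to the continuous-time curves; immaterial at ICU time scales.
- The lognormal pair draw matches moments and applies the bootstrap
  correlation on the log scale rather than the natural scale.
- Constant death probabilities ignore any time trend in late mortality.
- The within-cycle priority order is a convention; with hourly hazards
  ≪ 1 its effect is far below Monte-Carlo noise.
- Ventilator-associated pneumonia, other ICU-acquired infections, and
  withdrawal-syndrome costs are outside the model's scope.
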