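# Methods

## Model structure

The model is a discrete-time (1-day cycle) Markov cohort model of
heart-failure patients followed for 5 years (1825 cycles) after an index
hospital discharge. Nine states are tracked: outpatient care, ER visit,
hospital readmission, discharged (post-readmission) outpatient care,
post-readmission ER visit, subsequent hospital readmission, escalation of
care (EoC), post-EoC, and death. The full cohort starts in outpatient care;
death is absorbing and reachable from every state; post-EoC patients face
only mortality (an escalation removes the patient from the readmission
pathway). First and subsequent readmissions share the same daily
probabilities — the states are distinguished for costing and for routing
(only subsequent readmissions can escalate), not for risk.

At daily cycles, half-cycle correction is negligible and is omitted.

## Rates, effects, and the within-day cascade

Event inputs are cumulative probabilities over an observation window:
"at 3 months" rates over 90 days and "after 3 months" rates over the
remaining 275 days of year 1 (the window length is a config field,
`late_window_days`). They are converted to daily probabilities under a
constant hazard, `p = 1 − (1 − P)^(1/T)`, which is exact in the sense that
applying `p` independently on each of `T` days recovers `P`. The schedule
is a function of day-of-year, so years 2–5 recycle year 1. The intervention
arm applies the readmission hazard ratio (0.62) and mortality risk ratio
(0.66) on the hazard scale, `p' = 1 − (1 − p)^ratio`, during the first 90
absolute days only; afterwards the arms are identical.

Within a day, competing risks are resolved by a fixed multiplicative
cascade: death first (applied to every alive state), then readmission,
then ER visit, each acting on the mass that escaped the previous risk:
`P(death) = p_m`, `P(readmission) = (1 − p_m)·p_h`,
`P(ER) = (1 − p_m)(1 − p_h)·p_e`. The ordering is a modelling choice (the
event ordering within a day is not identifiable from cumulative rates); at
daily probabilities of order 10⁻³ the ordering changes totals by less than
one part in 10³.

A key structural decision is that the daily event hazards act on the whole
surviving cohort: a hospital admission occupies the hospital state for one
cycle (`hospital_hold_days = 1`) rather than suspending the patient's
event risk for a multi-day stay. The printed cumulative rates are
cohort-wide cumulative incidences; holding mass out of risk for a
length-of-stay sojourn would systematically under-reproduce them (a 6-day
hold lowers 90-day expected readmissions from 0.384 to 0.376 under
standard care). Length of stay instead enters the cost side (below). The
dynamic holds remain configurable (`hospital_hold_days`, `eoc_hold_days`
build genuine tunnel states) so the alternative sojourn reading can be run.

ER visits last one cycle; by default no ER visitor is admitted directly
(`er_to_hosp_fraction = 0` — direct ER-to-ward routing would inflate
readmission counts above the cumulative rates that already include all
admissions). A fixed 2.5% of subsequent readmissions (an assumption input)
are routed to EoC at admission.

## Costing

All costs are 2022 USD per modelled patient, payer perspective, discounted
at 3%/year as an annual step function (days 1–365 undiscounted, day `d`
in year `y + 1` scaled by `1.03^−y`). Components:

- outpatient care: $50/day × outpatient occupancy;
- post-readmission outpatient care: $236/day × (discharged + post-EoC
  occupancy), *replacing* the $50 baseline. The $236 figure ships as a
  per-day cost: a per-month reading (≈$7.9/day) is irreconcilable with
  this input being a leading cost driver of any plausible configuration,
  and under it no length of stay reproduces the model's 90-day per-arm
  cost targets. Both the unit and replace-vs-add behaviour are config
  switches (`unit`, `post_readmission_additive`).
- ER visits: $997 per incident visit;
- hospital readmissions: billed as `hospital_los_days` × $2665 per
  admission — one occupied hospital day plus the balance charged on the
  admission day. Setting `hospital_hold_days = hospital_los_days` recovers
  a pure per-occupied-day accrual;
- escalations: billed as `eoc_los_days` (default 5) × $3417 ICU days,
  analogously;
- device: $1300/month over 30-day months for 2 months of wear,
  intervention arm only, charged to the surviving cohort fraction. The
  schedule itself integrates to exactly $2600 per patient.

### Calibration of the billed length of stay

Neither the hospital length of stay nor the EoC stay is a published input.
The billed LOS was set by least squares against the two 90-day per-arm
discounted cost totals the model is meant to reproduce ($14 333 SOC /
$13 384 HFMS): cost is linear in the billed stay, and both arms'
conditions are satisfied almost simultaneously at **6.87 days** (achieved
costs $14 342 / $13 370), a clinically plausible stay for decompensated
heart failure. `hfcea calibrate` re-derives this number from any config;
the packaged base case records it. The EoC stay stays at 5 ICU days (it is
too small a flow — ~2.5% of subsequent admissions — to be identified from
the cost targets).

## Cost-effectiveness metrics

Effectiveness is expected hospital readmissions per patient (fewer is
better), so the incremental effect of an effective intervention is
negative. The ICER is ΔC/ΔE with Δ = intervention − comparator; the result
is labelled *dominant* (cheaper, fewer readmissions) or *dominated* in the
corner quadrants, where a ratio would be misleading, and is undefined at
ΔE = 0. NMB = λ(−ΔE) − ΔC at λ = $10 737 per readmission avoided (an
alternative threshold of $17 830 is also reported in PSA summaries).
Cost-effectiveness-plane quadrants follow the convention that quadrant II
(ΔC < 0, ΔE < 0 in this sign convention) is the dominant region.

## Probabilistic sensitivity analysis

Families are assigned by input class — beta (probabilities), log-normal
(relative risks), gamma (costs), normal (other continuous) — and
moment-matched to (mean, SE): beta via `k = m(1−m)/v − 1`, `α = mk`,
`β = (1−m)k` (infeasible when `v ≥ m(1−m)`, reported as an error); gamma
via `shape = m²/v`, `scale = v/m`; log-normal via `σ² = ln(1 + v/m²)`,
`μ = ln m − σ²/2`. A zero SE yields a point mass. Standard errors come
from printed 95% CIs (`(hi − lo)/3.92`) or are imputed as 10% of the mean
for clinical inputs and 30% for costs.

Sampled set: the six rates (beta), both effects (log-normal; the hazard
ratio has no CI and uses the imputed 10% SE), and five of the six costs
(gamma). The device cost and the EoC fraction are assumption inputs with
no stated variance and are held fixed (`sample_in_psa` exposes the
alternative). Inputs are drawn jointly and independently — no correlation
structure is asserted. Each iteration reruns both arms deterministically.

RNG: one master `SeedSequence` spawns a substream per iteration, so
results are bit-reproducible given the seed and invariant to execution
order; extending the iteration count never rewrites earlier iterations.
`se_scale=0` collapses every distribution to its mean and reproduces the
deterministic base case exactly (used as a self-check). The default run is
1000 iterations; the running standard deviation of the incremental cost
stabilises (< 5% relative change per 100 iterations) by roughly iteration
500. Summaries are percentile-based (linear-interpolation median and
2.5/97.5 credible bounds).

## One-way sensitivity analysis

Each input — all rates, effects, and costs, plus the billed hospital stay,
EoC stay, and EoC fraction — is perturbed alone to mean × (1 ± 0.10) with
a full deterministic rerun per point; probability perturbations leaving
[0, 1] are clamped with a warning. The primary ranking outcome is the
range of the deterministic ICER, computed as the signed ΔC/ΔE ratio in all
quadrants. NMB at the WTP threshold is reported alongside and available as
the ranking outcome (`outcome="nmb"`), but it is not the default: costs
shared symmetrically by both arms (such as the post-readmission outpatient
rate) largely cancel out of ΔC and hence out of NMB, while the ICER —
normalised by the cost-independent ΔE — retains their influence on the
absolute cost of care. Under the ICER ranking the top three drivers are
the readmission hazard ratio, the post-readmission outpatient cost, and
the late readmission rate.

## Microsimulation oracle and synthetic trial data

The patient-level simulator draws each patient's path with the same daily
probabilities, cascade, holds, and cost rules as the cohort engine, using
one uniform per patient-day for the death/readmission/ER cascade and a
second for routing draws. Per-patient Philox streams are keyed by
(seed, arm, patient index), so each trajectory is independent of the
number of patients, chunk size, and order. Sample means of events and
discounted costs are unbiased estimators of the cohort expectations; the
test suite checks agreement within 3.5 Monte-Carlo standard errors at
100 000 patients per arm, at 90 days and 5 years.

`make_synthetic_trial` reduces simulated histories to a two-arm, 90-day
trial table: time to first readmission (censored at death or day 90),
readmission indicator, 90-day death indicator, and 90-day ER count. A Cox
partial-likelihood fit to these data recovers the generating hazard ratio
(checked across seeds at 40 000 patients per arm). What the generator
emulates is the *model's* data-generating process — constant within-window
hazards, independent competing death, exact hazard-scale effects, daily
event resolution. It does not emulate real-trial features such as
enrolment heterogeneity, time-varying hazards within the 90-day window,
loss to follow-up, or correlated event risks, so recovery tests validate
internal consistency of the pipeline, not the behaviour of the estimators
on real trial data.

## Numerical choices and validation sizes

- Cohort mass is conserved to 10⁻¹² per day over the full horizon
  (checked on every row); negative occupancy raises an internal error.
- Validation problem sizes: 100 000 patients per arm for oracle
  equivalence, 1000 PSA iterations, 3 seeds × 40 000 patients per arm for
  hazard-ratio recovery — sizes at which Monte-Carlo error is a few per
  mille of the quantities compared.
- Months are fixed at 30 days wherever monthly quantities are needed
  (device schedule, cumulative-by-month reporting).
- Seeds are plain integers; all stochastic entry points either require a
  seed or take it from the config.

## Known limitations

- Under recurrent year-1 hazards, 5-year expected readmissions are ≈3.97
  (SOC) vs ≈3.88 (HFMS) and 5-year discounted costs ≈$321k vs ≈$318k.
  Published summaries of this comparison report much lower 5-year event
  totals (≈1.2 readmissions), implying a readmission-recurrence rule that
  cannot be reconstructed from the printed cumulative rates; the engine
  exposes the relevant switches (late-window length, holds, units), and
  the 5-year totals should be read as internally consistent projections of
  the stated inputs rather than reproductions of any external figure. The
  90-day outputs, where the inputs fully determine the answer, are
  reproduced closely.
- Effectiveness is readmissions avoided only — no QALYs or survival
  weighting, although mortality shapes both arms' costs and event counts.
- No correlation between sampled inputs in the PSA; no indirect or
  societal costs; costs fixed at 2022 USD with no inflation across the
  horizon; US payer setting only.
- Fixed-duration stays are emulated with one-cycle states plus episode
  billing (or integer-day tunnels); there are no semi-Markov sojourn
  distributions.
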