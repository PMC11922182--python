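# hfcea

A Markov cohort cost-effectiveness model of a wearable heart-failure
management system (HFMS) — continuous remote monitoring of recently
discharged heart-failure patients — against standard of care (SOC), from a
US payer perspective in 2022 USD. The package is aimed at health-economics
analysts and reviewers: every input, structural assumption, and analysis
step is a configurable, tested piece of code rather than a spreadsheet
formula.

## The model

Patients enter the model in outpatient care after an index heart-failure
discharge and are followed in daily cycles over a 5-year horizon through
nine health states: outpatient care, ER visit, hospital readmission,
discharged (post-readmission) outpatient care, post-readmission ER visit,
subsequent hospital readmission, escalation of care (EoC — surgical or
catheter-based intervention), post-EoC, and death (reachable from every
state).

Cumulative event probabilities `P` observed over `T` days are converted to
daily probabilities under a constant hazard,

    p_daily = 1 − (1 − P)^(1/T),

and treatment effects act on the hazard scale, `p' = 1 − (1 − p)^HR`. The
intervention arm applies a hazard ratio of 0.62 to readmission and a risk
ratio of 0.66 to mortality during the first 90 days; afterwards the arms
share the same rates, and years 2–5 recycle the year-1 schedule. Within a
day, risks compete in a fixed cascade — death, then readmission, then ER
visit. A fixed 2.5% of subsequent readmissions escalate to intensive care
and leave the readmission pathway.

Costs accrue per day in state (outpatient $50/day; post-readmission
outpatient $236/day), per event (ER visit $997; hospital readmission billed
as length of stay × $2665/day; escalation billed as 5 ICU days ×
$3417/day), and per device ($1300/month for 2 months of wear, intervention
arm only), discounted at 3% per year after year 1. Effectiveness is counted
in hospital readmissions, so with Δ denoting intervention minus comparator,

    ICER = ΔC / ΔE,    NMB = λ·(−ΔE) − ΔC,

with willingness to pay λ = $10 737 per readmission avoided. A strategy
that saves money and avoids readmissions is *dominant* and no ICER is
reported.

Uncertainty is handled two ways: a probabilistic sensitivity analysis
(beta / log-normal / gamma / normal distributions for probability /
relative-risk / cost / other continuous inputs, moment-matched to each
input's mean and standard error) and a one-way ±10% tornado analysis ranked
by the deterministic ICER range. A patient-level microsimulation that
shares the engine's daily probabilities serves as a brute-force validation
oracle and generates synthetic two-arm trial data.

## Worked example

```python
import hfcea

model = hfcea.CostEffectivenessModel.base_case()   # packaged inputs
results = model.run()
print(results.summary())
```

```
Cost-effectiveness results per patient (1825-day horizon, discounted)
==================================================================
                    cost (USD)    readmissions
SOC                    320,606           3.974
HFMS                   317,623           3.884
incremental             -2,983          -0.089
------------------------------------------------------------------
ICER: dominant
NMB at WTP $10,737/readmission avoided: $3,942 (cost-effective)
```

Monitoring dominates standard care: it saves $2,983 per patient and avoids
0.089 readmissions over 5 years under recurrent year-1 hazards. Over the
90-day window in which the device effect applies, the model expects 0.384
readmissions per SOC patient versus 0.240 with monitoring, and a $972
cost saving ($14,344 vs $13,372) despite the $2,600 device cost:

```python
r90 = model.run(horizon_days=90)
print(r90.cea.eff_soc, r90.cea.eff_hfms)   # 0.3835  0.2399
results.cost_crossing_month()              # 3 — cumulative HFMS cost drops
                                           # below SOC in the third month
```

Sensitivity analyses hang off the same object:

```python
psa = model.run_psa()                  # 1000 iterations, seeded
psa.quadrant_fractions()               # II (dominant): 0.729
psa.fraction_under_wtp()               # 0.765
tornado = model.run_owsa()             # top driver: effects.hr_hosp,
                                       # then costs.post_readmission_outpatient
trial = model.make_synthetic_trial(n_per_arm=261, seed=7)  # 522-patient table
```

## Configuration

Inputs live in one YAML file (see
`src/hfcea/data/base_case.yaml`, loaded by default): `rates` (six
cumulative probabilities with `period_days` and optional 95% CIs),
`effects` (hazard ratio on readmission, risk ratio on mortality), `costs`
(six unit costs with explicit units), and `settings` (horizon, discount
rate, WTP threshold, effect window, EoC fraction, device wear time, PSA
iteration count, billed and dynamic lengths of stay, and seeds). Inputs
with a printed CI get a normal-theory standard error, `(hi − lo)/3.92`;
the rest are imputed at 10% (clinical) or 30% (cost) of the mean. Every
structural assumption — billed hospital stay, EoC stay, ER-to-admission
routing, the post-readmission cost unit — is a config field, not a
constant; see `docs/methods.md` for defaults and rationale.

## Command line

```sh
hfcea run --outdir out            # base case: results, monthly cumulatives, traces
hfcea psa -n 1000 --seed 1 --outdir out
hfcea owsa --outdir out           # sorted tornado table
hfcea microsim -n 261 --seed 1 --outdir out
hfcea calibrate                   # re-derive the billed length of stay
```

Each command writes plain CSV plus a `manifest.json` recording the config
hash, seed, and output list; identical invocations reproduce identical
outputs.

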