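# Methods

## The decision problem

Breast-cancer survivors frequently develop treatment-induced menopausal
symptoms, in particular hot flushes and night sweats. Internet-based
cognitive behavioral therapy (iCBT) reduces these symptoms in two formats —
therapist-guided and self-managed — at very different prices (€226.09 vs
€47.92 per patient including 44% overhead). `menocea` implements the health-
economic evaluation of the two formats against a waiting-list control from
the Dutch healthcare perspective: cost-utility (€/QALY), NNT-based
cost-effectiveness (€ per clinically significant response), and annual
budget impact, with deterministic and probabilistic sensitivity analyses.

## Model structure

A Markov cohort model with a 5-year horizon in ten 6-month cycles. Health
states: *menopausal symptoms* (MS, the initial state), *reduction in
menopausal symptoms* (RED), *recurrence*, and *death*. Recurrence is
expanded into 6-month tunnel sub-states (REC1–REC4, RECPOST) so that
first-year, second-year, and later recurrence costs can differ; clinically
it is one state with utility 0.73.

Transitions per cycle:

- MS → RED with the strategy's response probability (0.44 guided, 0.39
  self-managed, 0.23 waitlist — the trial's proportion of women with a
  ≥ 0.5 SD improvement on the FACT-ES at 24 weeks), **in the first cycle
  only**. Treatment costs and effects are one-off; afterwards all arms
  share the same dynamics.
- MS/RED → recurrence with annual probability 0.01; recurrence → death with
  annual probability 0.04 (registry-derived); background mortality rises
  linearly from 0.0007/year at age 47 to 0.0012/year at age 51. Annual
  probabilities are converted to cycles as 1 − (1 − p)^0.5, so two cycles
  compound exactly to the annual value.
- Within a cycle, recurrence and death act before the response: the
  first-cycle MS → RED flow is `p_response × (1 − p_rec − p_mort)`. In the
  recurrence tunnels, the recurrence-specific mortality *replaces*
  background mortality (it is two orders of magnitude larger; adding the
  two would double-count).

QALY accrual per cycle is occupancy × state utility × 0.5 years, discounted
at 1.5%/year; cost accrual is occupancy × per-cycle state cost, discounted
at 4%/year (Dutch guideline rates). Occupancy is counted at the **start of
each cycle** with discount time (c − 1)/2 years; end-of-cycle and
half-cycle-corrected accrual are available as switches. The one-off
intervention cost enters undiscounted at time zero. The nominal cohort of
1000 patients is cosmetic — the model is linear, and all results are per
patient.

## Calibration of open conventions

Cohort models leave several bookkeeping conventions open (accrual timing,
per-cycle vs annual probabilities, cost accrual beyond the observed
recurrence years). These were fixed **once**, jointly, by matching the
published deterministic totals, and then frozen as package defaults:

| choice | frozen default |
|---|---|
| recurrence / recurrence-death probabilities | annual, converted to 6-month |
| recurrence cost beyond year 2 | €0 per cycle (`rec_post_fraction = 0`) |
| accrual timing | begin-of-cycle |
| state-cost period | per 6-month cycle |
| background mortality | annual schedule, interpolated, converted |

With these defaults the model reproduces the published totals to within
±4%: per-patient costs €5524.60 / €5315.70 / €5169.45 (published €5315.55 /
€5118.22 / €4993.90) and QALYs 4.029 / 4.025 / 4.012 (published 4.119 /
4.117 / 4.106) for guided / self-managed / waitlist.

**State-cost assignment.** The evaluation's source tabulates per-provider
utilization costs in two blocks summing to €503.40 and €580.64 per cycle.
Its results text states — and every downstream published number requires —
that utilization costs were *higher* in the reduced-symptoms state, whereas
the block headings read the other way. This package follows the results:
MS = €503.40, RED = €580.64 per cycle. With the opposite assignment both
iCBT formats would strictly dominate the waitlist (cheaper and more
effective), contradicting every published ICUR, budget impact, and CE-plane
fraction.

## Known irreproducibilities

Two published incremental quantities cannot be reproduced from the
published inputs, under *any* convention:

- The published incremental QALYs (0.0138 guided, 0.01102 self-managed)
  have ratio 1.2506, but the model is strictly linear in the first-cycle
  response split, so their ratio must equal the response-difference ratio —
  1.3125 from the tabulated proportions, ≈ 1.278 from the published NNTs.
  With the tabulated utilities (Δu = 0.02) the model yields ΔQALY ≈ 0.0177
  / 0.0135; the published values imply an unrounded utility difference of
  ≈ 0.0145. Consequently the ICURs computed here are 10–20% below the
  published ones (e.g. €20,031 vs €23,331 guided; intervention-perspective
  self-managed €3,547 vs €4,347), and NNT-based healthcare-perspective
  costs per responder are ~10–18% above. Intervention-perspective
  quantities that do not involve ΔQALY are exact (guided €226.09; budget
  impacts €135,654 / €28,752; cost per responder €1071.51 / €290.39 /
  €1026.45 / €192.64 within rounding).
- The published PSA spread is narrower than what the tabulated standard
  errors imply. The published CE-plane was produced by *bootstrapping the
  trial data*, not by re-sampling the tabulated parameter distributions;
  sampling those distributions (utilities: beta with SE 0.013/0.017/0.020;
  all cost items: gamma with SE = 20% of the mean, per item; response:
  per-arm Dirichlet with effective n = 85) gives a guided CEAC at €30,000
  of ≈ 61% (published 60.5%) but a self-managed CEAC of ≈ 71% (published
  79.5%) and NE-quadrant fractions ≈ 0.83 / 0.78 (published 0.92 / 0.89).
  The corresponding acceptance tests are left failing deliberately.

## Probabilistic sensitivity analysis

5000 Monte Carlo draws. Per draw, one parameter set is sampled
(method-of-moments beta for utilities; per-item gamma for every cost; one
independent two-component Dirichlet per arm for the response probability —
arms are independent samples, so no joint vector is warranted; the
recurrence and recurrence-death probabilities carry no published dispersion
and stay fixed by default) and the cohort model is run for all three
strategies. CEACs use net monetary benefit (NMB = WTP × QALY − cost):
pairwise mode reports P(NMB_intervention > NMB_control), multiway mode the
probability of attaining the maximal NMB, ties split equally (a
measure-zero event handled deterministically). Seeds make draw matrices
bit-reproducible. A sampled set failing validation is redrawn (bounded
retries); this is vanishingly rare with the default specs.

## Deterministic sensitivity and scenarios

Tornado ranges are mean ± 1.96 SE where an SE is configured and ± 20%
otherwise, overridable per parameter; effect duration spans 6–10 cycles
(3–5 years). When a range's extreme flips the incremental comparison into
dominance the swing is reported as infinite and ranks first — this occurs
exactly for the state utilities (and state costs for the cheaper format),
reproducing the published observation that an unfavorable reduced-state
utility is what can push the evaluation past acceptability. Named
scenarios: `effect_duration_3y` (all reduced-state occupancy reverts to MS
in one step at the start of cycle 7 — the simplest reading of a 3-year
effect duration) and `intervention_perspective` (state and recurrence costs
zeroed; intervention costs retained). Scenario evaluation never mutates its
input parameter set.

## Synthetic trial generator

`menocea.trial` emulates the statistical structure the estimation consumes,
at the source study's conditions by default: three arms of 85 patients
(254 randomized), responder flags ~ Bernoulli(0.44/0.39/0.23) — the 0.5-SD
FACT-ES responder definition is emulated directly as a binary outcome,
since the model uses only the responder proportion — utilities ~
moment-matched beta per state (patient-level SDs back-computed from the
reported SEs at n = 85), and per-provider costs ~ gamma with a patient-level
CV implying a 20% SE of the mean. Responders' utilities/costs estimate the
reduced-symptoms state, non-responders' the symptomatic state. What this
does **not** emulate: questionnaire-level measurement, within-patient
correlation between utility and cost, missingness, or longitudinal
trajectories — so recovery tests demonstrate correctness of the
estimation/model plumbing, not robustness to real-data messiness.
Parameter recovery holds by construction: at 10⁵ patients/arm response
probabilities are recovered within ±0.01.

## Numerical notes

- All monetary arithmetic is double precision; rounding only at
  presentation (2 decimals), because ICURs divide by ΔQALY ≈ 0.01.
- Trace conservation is enforced structurally (residual mass stays in
  state); rows sum to 1 within 1e−12 before floating accumulation, 1e−9
  is asserted.
- Degenerate cases: zero-ARR NNT returns a no-benefit flag, not an
  exception; ΔQALY = 0 leaves the ICUR undefined with an explicit flag;
  a Dirichlet component of zero probability is floored at 1e−9
  concentration.
- Problem sizes: deterministic evaluation runs in milliseconds; the
  5000-draw PSA in a few seconds; the test suite's microsimulation oracle
  uses 100,000 individuals against per-cell binomial Monte-Carlo standard
  errors.

## Limitations

- A Dutch single-payer setting is hard-coded in the defaults (discount
  rates 1.5%/4%, €30,000/QALY ceiling, 600 patients/year); all are
  configurable.
- Medication costs, societal costs (productivity), and SF-36→EQ-5D mapping
  are out of scope; utilities enter as state-level means.
- The published evaluation's internal inconsistencies bound achievable
  replication fidelity; see *Known irreproducibilities*.
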