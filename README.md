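# menocea

Cost-utility, cost-effectiveness, and budget-impact modelling of
Internet-based cognitive behavioral therapy (iCBT) for treatment-induced
menopausal symptoms in breast cancer survivors.

Adjuvant breast-cancer treatment often induces menopausal symptoms (hot
flushes, night sweats) that degrade quality of life. iCBT reduces them in
two formats — therapist-guided (€226.09/patient) and self-managed
(€47.92/patient) — and the question for payers is whether either format is
worth funding, and which. `menocea` answers this with a Markov cohort model
(states: menopausal symptoms → reduction / recurrence / death; ten 6-month
cycles; first-cycle-only treatment effect) and the standard health-economic
toolkit on top of it:

- **Cost-utility**: discounted costs (4%/year) and QALYs (1.5%/year) per
  strategy; incremental cost-utility ratios ICUR = ΔC/ΔE against a
  €30,000/QALY willingness-to-pay ceiling.
- **Cost-effectiveness**: number needed to treat, NNT = 1/ARR, and the
  incremental cost to obtain one clinically significant response,
  NNT × ΔC.
- **Budget impact**: per-patient incremental cost × 600 treated
  patients/year (Dutch uptake estimate), including 50/50 uptake mixes.
- **Uncertainty**: probabilistic sensitivity analysis (5000 Monte Carlo
  draws from beta/gamma/Dirichlet parameter distributions) summarized as
  CEACs and cost-effectiveness planes; one-way tornado analyses; scenario
  analyses (3-year effect duration, intervention-cost-only perspective).
- **Synthetic trials**: a generator for three-arm trial data with the
  structure the estimation consumes, plus the estimator mapping trial data
  to a model parameter set, enabling end-to-end parameter-recovery tests.

All model inputs ship as a built-in, validated YAML parameter set
(`menocea.default_parameters()`); every number below is recomputed from it
at run time. See `docs/methods.md` for the model, its frozen calibration
conventions, and known limits of replication fidelity.

## Worked example

```python
from menocea import default_parameters, deterministic_table

print(deterministic_table(default_parameters(), "healthcare"))
```

or, as run by `python analysis/01_base_case.py`:

```
Deterministic base case (healthcare perspective, per patient):
  guided        cost EUR  5524.60  QALY 4.0294  dC  355.15  dQALY 0.01773  ICUR  20031.12  BIA     213092
  self_managed  cost EUR  5315.70  QALY 4.0252  dC  146.25  dQALY 0.01351  ICUR  10826.73  BIA      87753
```

Reading: over 5 years a guided-iCBT patient accrues €5524.60 in discounted
costs and 4.0294 discounted QALYs; versus the waiting list she costs
€355.15 more and gains 0.0177 QALYs, an ICUR of €20,031/QALY — below the
€30,000 ceiling, so cost-effective, but the self-managed format achieves
its gain at €10,827/QALY, and treating the projected 600 patients/year
costs the healthcare budget €213,092 (guided) vs €87,753 (self-managed)
annually. `analysis/02_psa.py` … `05_synthetic_trial.py` run the
probabilistic, tornado, NNT/budget-impact, and synthetic-trial steps, each
writing CSV tables and a reproducibility manifest under `results/`.

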