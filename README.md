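# oacphen

Computable-phenotype validation for **emergency-department oral
anticoagulant (OAC) prescribing in atrial fibrillation**, built on linked
administrative claims.

Health-administrative data sets record ED visits and outpatient drug
claims, but not *who wrote* the prescription behind a claim. To identify ED
OAC prescriptions after an atrial-fibrillation visit, a family of rule-based
algorithms calls a patient **algorithm-positive** when an OAC claim is
filled inside a day window relative to ED departure (day 0 = the day the
patient left the ED), optionally requiring the fill to precede any
follow-up outpatient visit with a *relevant clinician* (family physician,
cardiologist, internist, optionally nephrologist), and optionally forcing
negative anyone who saw a relevant clinician in the 30 days before the ED
visit. Sixteen such variants, each with and without excluding patients with
a 5-year venous-thromboembolism (VTE) history, give 32 algorithms.

Against a chart-review reference standard each algorithm is scored with the
standard test characteristics

> Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),

each with a 95% Wald interval *p* ± 1.96·√(*p*(1−*p*)/*n*), plus the
positivity rate 100·(TP+FP)/*n*.

The package provides:

- `oacphen.simulate` — a seeded generator of the four linked tables
  (patient roster, ED visits, drug claims, outpatient visits) plus ground
  truth, with every error mechanism the algorithms must survive: day-0
  fills written by referring clinicians, outpatient-origin prescriptions,
  primary nonadherence, prior OAC use, VTE history;
- `oacphen.cohort` — the study inclusion/exclusion criteria (age 65+,
  discharged, primary AF diagnosis, 90-day OAC washout, first visit per
  patient as index);
- `oacphen.algorithms` — the 32 built-in variants as data
  (`builtin_algorithms()`) and vectorized classification;
- `oacphen.metrics` — 2×2 tabulation, Wald intervals, display rounding;
- `oacphen.pipeline` / the `oacphen` CLI — seeded end-to-end runs with a
  provenance manifest, and a `from-counts` mode that re-evaluates the
  reported validation counts directly.

## Worked example

```bash
python examples/03_classify_and_score.py
```

```
cohort: 3595 patients

algo  window  gate          sens   spec   ppv    npv    rate%
   2     0-3  none         0.748  0.969  0.863  0.936   18.1
  10    0-30  none         0.838  0.781  0.502  0.948   34.8
  13    0-30  any_relevant 0.784  0.977  0.900  0.945   18.1
```

On a 10 000-patient synthetic population, widening the fill window from
days 0–3 to 0–30 raises sensitivity (0.748 → 0.838) while specificity falls
(0.969 → 0.781) as outpatient-origin fills leak in; gating on "filled
before any relevant follow-up visit" removes most of those false positives
(specificity back to 0.977) at a sensitivity cost. This is the same
qualitative trade-off the published validation of these algorithms reports
on real Ontario data.

Other examples: `01_simulate_linked_tables.py`, `02_build_cohort.py`,
`04_reported_counts_to_metrics.py` (re-derives every printed metric of the
reported validation table from its 2×2 counts), `05_full_validation_run.py`.

Shell interface:

```bash
oacphen run --seed 1 --out run1        # simulate -> cohort -> classify -> evaluate
oacphen from-counts --counts my.csv    # metrics straight from 2x2 counts
```

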