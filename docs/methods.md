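# Methods

## The estimation problem

Administrative claims show that an oral anticoagulant (OAC) was *dispensed*
after an emergency-department (ED) atrial-fibrillation visit; they do not
show who prescribed it. The package treats "was an OAC prescription
provided at the index ED visit" as a latent binary state, observed only
through a chart-review reference standard, and evaluates rule-based
classifiers built from the claim stream. Each classifier is a triple of
choices:

1. **fill window** — an inclusive day interval `[start, end]` relative to
   ED departure (day 0), `start ∈ {0, 1}`, `end ∈ {0, 3, 4, 7, 14, 30}`.
   Day-0 fills matter because a referring clinician may have written the
   prescription the same day;
2. **appointment gate** — optionally require the fill to occur strictly
   before the first post-ED outpatient visit with a relevant clinician
   (family physician, cardiologist, internist; optionally nephrologist),
   since that clinician may have written the prescription being filled. A
   variant restricts family-medicine visits to the patient's rostered
   family physician;
3. **prior-appointment rule** — optionally force-negative patients who saw
   a relevant clinician in the 30 days before the ED visit.

The 16 variants crossed with a VTE-history exclusion (patients with a
venous-thromboembolism diagnosis in the prior 1826 days have an alternative
OAC indication) give the 32 built-in algorithms. Performance is summarized
by sensitivity, specificity, PPV, NPV — binomial proportions with 95% Wald
intervals `p ± 1.96·√(p(1−p)/n)` clipped to [0, 1] — and the positivity
rate.

## Conventions and tie-breaks

- Dates are integer day offsets from a fixed epoch; windows are closed on
  both ends ("0–3" means lags {0, 1, 2, 3}).
- Day 0 is the ED **departure** date; the registration date is carried but
  unused by the algorithms.
- A fill on the same calendar day as a relevant outpatient visit is treated
  as occurring **after** the visit, so the gate disqualifies it. Claims
  carry no intra-day ordering; the conservative reading serves the gate's
  purpose (maximizing specificity).
- The gate looks only at visits on or after day 0; pre-index visits act
  solely through the prior-appointment rule, which force-negatives rather
  than removes patients — the reported validation rows for that variant sum
  to the full cohort, so the denominator was not reduced.
- Any single qualifying fill suffices; the earliest is reported.
- Index visit: first qualifying ED visit per patient (earliest
  registration; ties broken by lowest visit id). Age is completed years at
  registration. The 90-day OAC washout covers `[index − 90, index − 1]`;
  a day-0 fill is a detection candidate, never prior use.
- The "would not benefit" exclusion is a roster boolean stand-in for a
  clinical definition external to this package.
- The prior-appointment flag is precomputed over the base relevant set
  (family medicine, cardiology, internal medicine); the only built-in
  variants that use it do not include the nephrologist.
- Ownership for the "their own clinician" gate is enforceable only for
  family medicine (the roster assigns no cardiologist/internist), so
  specialist visits gate regardless of identity. How the original study
  operationalized "their" specialist is not stated; this choice is
  documented rather than asserted as theirs.

## Display rounding

Proportions are rounded half-up at 3 decimals. The positivity rate uses a
**two-stage** half-up rule — 2 decimals, then 1 — because that is the
convention evident in the reported validation table (13.6476% prints as
13.7 via 13.65; three rows distinguish the rules). Internal values are
never rounded. The Wald z is 1.96 exactly; the test suite cross-checks the
intervals against statsmodels' normal-approximation interval. One reported
interval bound (the day 0–3 sensitivity lower limit, printed 0.794) differs
from the full-precision Wald value, which rounds to 0.795; the package
reproduces point estimates everywhere and interval bounds where the Wald
recomputation agrees.

## The synthetic-data generator

`generate_population` emulates the linked-claims setting with one index ED
visit per patient (a switch adds later duplicate visits to exercise
first-visit selection) and explicit true/false-positive mechanisms:

| parameter | default | role |
|---|---|---|
| `p_ed_prescription` | 0.20 | probability the index visit truly yields an OAC prescription (ground truth) |
| `fill_lag_pmf` | mass on days 0–7, mode 0 | fill lag of a true prescription; not calibrated to any published distribution |
| `p_never_fill` | 0.15 | primary nonadherence — a true prescription never filled (false-negative mechanism) |
| `p_day0_referrer_fill` | 0.02 | day-0 fill written by the referring clinician for a non-prescribed patient |
| `p_outpatient_prescription` | 0.20 | post-ED outpatient prescription; the fill lands on/after that clinician's visit (false-positive mechanism the gate removes) |
| `outpatient_visit_rate` | 2.0 | expected relevant-clinician visits per patient over days −30..+30 |
| `p_vte_history` | 0.03 | 5-year VTE history (≈ the 65/2015 exclusion fraction in the validation cohort) |
| `p_prior_oac` | 0.25 | OAC fill in the 90-day washout |
| `p_admitted` | 0.30 | admitted disposition (excluded) |
| `p_under65` | 0.30 | age under 65 (excluded) |
| `p_would_not_benefit` | 0.02 | roster exclusion flag |

Days supplied default to 7 (warfarin) and 30 (DOAC), echoing the
descriptive medians reported for ED prescribing. Where the source study
reports no value (fill-lag distribution, visit rate, referrer-fill and
outpatient-prescription rates), defaults were chosen once as plausible for
an elderly AF population; the day-0 referrer rate ≈ the day-0 false-positive
fraction and the outpatient-prescription rate ≈ the 30-day false-positive
fraction seen in the reported counts.

The generator is a pure function of its config (fixed RNG seed, stable sort
order), so serialized output is byte-identical across runs — the
determinism contract the pipeline manifest relies on.

**What it does not model:** ICD-10/drug-code vocabularies, the 20-hospital
clustering (so no cluster-adjusted intervals), mortality, stockpiling or
early refills, chart-abstraction error in the reference standard, and any
correlation between age, comorbidity and prescribing. Passing tests
therefore demonstrate internal correctness of the rules and metrics and
qualitative reproduction of the published trade-offs (window widening
trades specificity for sensitivity; the gate reverses it), not calibrated
agreement with Ontario data.

## Problem sizes

Property tests run on seeded populations of 600–2000 patients (50 seeds for
the monotonicity suite); parameter recovery pools ten 20 000-patient
populations, giving ≈14 000 classified reference positives and a
Monte-Carlo SE of ≈0.003 on the recovered sensitivity. Exact-recovery tests
(all mechanisms off, fills on day 0) use 10 000 patients.

## Known limitations

- The Wald interval degenerates at p ∈ {0, 1}; exact or score intervals are
  not implemented because the reported intervals match Wald.
- With `p_under65`, `p_admitted` etc. all nonzero, roughly a third of
  generated patients survive to the cohort; eligibility and ground truth
  are generated independently, which real data would not guarantee.
- The "own clinician" variant's behaviour depends on the ownership
  convention above; its reported counts are not asserted.
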