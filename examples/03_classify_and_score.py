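"""Classify the cohort under three contrasting algorithms and score them.

Algorithm 2 (fills on days 0-3), algorithm 10 (days 0-30) and algorithm 13
(days 0-30, but only fills before any follow-up visit with a family
physician, cardiologist or internist). Widening the window raises
sensitivity and lowers specificity; the appointment gate buys the
specificity back at a sensitivity cost.
"""

from oacphen import SimulationConfig, build_cohort, generate_population, tabulate
from oacphen.algorithms import classify_cohort, get_algorithm
from oacphen.metrics import evaluate

tables = generate_population(SimulationConfig(n_patients=10000, seed=1))
cohort = build_cohort(tables)
print(f"cohort: {len(cohort)} patients\n")
print("algo  window  gate          sens   spec   ppv    npv    rate%")
for algo_id in (2, 10, 13):
    spec = get_algorithm(algo_id)
    counts = tabulate(classify_cohort(cohort, tables, spec), cohort)
    row = evaluate(counts, algo_id).to_row()
    print(f"{algo_id:>4}  {spec.window_label:>6}  {spec.appointment_gate:<12} "
          f"{row['sens']:.3f}  {row['spec']:.3f}  {row['ppv']:.3f}  "
          f"{row['npv']:.3f}  {row['rate_percent']:>5}")
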