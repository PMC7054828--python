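"""Re-derive the reported test characteristics from the reported counts.

The chart-review validation study published the TP/TN/FP/FN counts of all
32 algorithms. Feeding those counts through the metrics engine reproduces
every printed sensitivity, specificity, PPV, NPV and positivity rate —
the ``from-counts`` route that decouples the arithmetic from simulation.
"""

from oacphen.pipeline import evaluate_from_counts, published_counts_frame, render_table

results = evaluate_from_counts(published_counts_frame(vte_excluded=False))
print(render_table(results))
# Each "Rate, %" is the share of the 2015-patient cohort the algorithm
# labels as having received an ED oral-anticoagulant prescription.
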