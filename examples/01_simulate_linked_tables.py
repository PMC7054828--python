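"""Generate synthetic linked administrative tables with known ground truth.

Builds a small population and prints the table sizes and the share of
patients whose index ED visit truly produced an oral-anticoagulant
prescription (the chart-review reference standard the algorithms are
validated against).
"""

from oacphen import SimulationConfig, generate_population

config = SimulationConfig(n_patients=2000, seed=1)
tables = generate_population(config)

print(f"patients:          {len(tables.patients)}")
print(f"ED visits:         {len(tables.ed_visits)}")
print(f"drug claims:       {len(tables.drug_claims)}")
print(f"outpatient visits: {len(tables.outpatient_visits)}")
truth = tables.ground_truth["ed_oac_prescribed"].mean()
print(f"true ED prescription rate: {truth:.3f} (configured {config.p_ed_prescription})")
# The drug-claim table mixes real ED-prescription fills with fills that only
# look like them: washout-window fills, day-0 fills by referring clinicians,
# and outpatient-origin prescriptions.
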