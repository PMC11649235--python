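"""Full pipeline to a tidy metrics table and the statistical battery.

Simulates small PA and UN cohorts on CD2, computes per-(animal, trial,
period) metrics, and compares WN-period activity between groups with
Welch's t-test and a trial x group two-way ANOVA.
"""

import pandas as pd

import ethoflight as ef

tables = []
for group, n in (("PA", 8), ("UN", 8)):
    for animal in ef.simulate_cohort(group, n, ["CD2"], seed=2):
        ann = animal.sessions["CD2"]
        speed = ef.compute_speed(ann.trajectory)
        bouts = (ef.detect_freezing(speed) + ef.detect_darts(speed)
                 + ef.extract_jumps(ann.trajectory))
        tables.append(ef.session_metrics(speed, bouts, ann.schedule,
                                         animal_id=animal.animal_id,
                                         sex=animal.sex))
metrics = pd.concat(tables, ignore_index=True)
print(ef.summarize(metrics, "activity_index")
      .query("period == 'wn'").to_string(index=False))

comparisons = [
    {"test": "welch_t", "value": "activity_index", "period": "wn",
     "groups": ["PA", "UN"], "name": "WN activity PA vs UN"},
    {"test": "anova2", "value": "activity_index", "period": "wn",
     "groups": ["PA", "UN"], "name": "WN activity trial x group"},
]
results = ef.run_comparisons(metrics, comparisons)
print()
print(results.to_string(index=False))
# The Welch test contrasts per-animal mean WN activity; the two-way
# ANOVA partitions trial and group effects (Type II sums of squares).
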