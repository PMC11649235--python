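"""Reproduce the CD2 white-noise activity-index contrast between groups.

The activity index is speed_CS / speed_avg-preSCS + jumps: the ratio of
a trial's CS-period mean speed to the session-wide pooled pre-SCS mean
speed, plus the number of escape jumps in that CS period.  A score of 1
means locomotion unchanged from baseline; paired conditioning drives WN
scores far above 1 via jumping, while unpaired controls show a purely
locomotor elevation.
"""

import numpy as np

import ethoflight as ef

for group, n in (("PA", 32), ("UN", 20)):
    cohort = ef.simulate_cohort(group, n, ["CD2"], seed=1)
    wn_scores, tone_scores = [], []
    for animal in cohort:
        ann = animal.sessions["CD2"]
        speed = ef.compute_speed(ann.trajectory)
        windows = ef.period_windows(ann.schedule)
        denom, _ = ef.pre_scs_average_speed(speed, windows)
        jumps = ef.extract_jumps(ann.trajectory)
        for w in windows:
            if w.period is ef.Period.WN:
                wn_scores.append(ef.activity_index(speed, jumps, w, denom))
            elif w.period is ef.Period.TONE:
                tone_scores.append(ef.activity_index(speed, jumps, w,
                                                     denom))
    print(f"{group}: WN activity index {np.mean(wn_scores):5.2f}, "
          f"tone {np.mean(tone_scores):5.2f}  (n={n})")
# WN >> tone in the paired group (flight to the imminent-shock cue);
# tone scores sit below 1 because the tone evokes freezing.
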