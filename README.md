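# ethoflight

Defensive-ethogram analysis for serial-compound-stimulus (SCS) fear
conditioning in mice — for behavioral neuroscientists who quantify the
transition from freezing to flight along the predatory imminence
continuum from centroid-tracking time series.

## The paradigm and its quantities

The SCS is a 20 s compound cue: ten 0.5 s tone pips at 1 Hz followed by
ten 0.5 s white-noise (WN) pips ("reversed" variants invert the order).
Five group contingencies — paired (PA, SCS co-terminating with a 1 s
footshock), unpaired (UN), shock-only (SO), and the reversed-SCS paired
and unpaired groups (PA-R, UN-R) — are run through pre-exposure (590 s),
two conditioning days (820 s each) and two 16-trial extinction days
(1910 s each), with pseudorandom inter-stimulus intervals.

From a calibrated centroid track sampled at 30 frames/s the package
segments the defensive ethogram:

* **freezing** — speed below ε (default 0.5 cm/s) for ≥ 1 s;
* **darting** — a speed burst detected by hysteresis (open above
  v_start = 10 cm/s from rest, close on return below v_stop = 4 cm/s),
  minimum 8 frames (266 ms);
* **escape jumps / tail rattles** — consumed from annotation channels
  ("all four paws off the floor" is not certifiable from a 2-D centroid).

Per trial and 10 s stimulus period it computes percent freezing,
distance traveled (area under the 0.5 s-binned speed curve), 1 s-bin
peri-stimulus event histograms, first-vs-last-trial and pre-SCS-vs-cue
difference scores, cohort percentages, and the **activity index**

```
AI = Speed_CS / Speed_avg pre-SCS + Jumps
```

— the ratio of a trial's CS-period mean speed to the session-wide mean
speed pooled over all 10 s pre-SCS periods (floored at 0.1 cm/s to keep
the denominator away from zero), plus the number of jumps starting in
that CS period. AI = 1 means locomotion unchanged from baseline. The
statistical battery is Welch's unpaired t-test, one-way ANOVA with
Tukey's HSD, and ordinary two-way (trial × group) ANOVA.

A calibrated synthetic-trajectory generator (semi-Markov behavioral
states over a bounded smooth walk in a 30 cm arena) provides ground
truth for every stage, so the whole pipeline is testable end to end
without behavioral recordings.

## Worked example

`examples/03_cd2_activity_index.py` simulates PA (n = 32) and UN
(n = 20) cohorts on conditioning day 2 with the shipped defaults and
runs the full pipeline (speed → jump extraction → activity index):

```
PA: WN activity index 11.71, tone  1.09  (n=32)
UN: WN activity index  5.13, tone  2.17  (n=20)
```

The paired group's WN score is an order of magnitude above 1 — cue-evoked
flight (jumping and darting) to the imminent-shock portion of the SCS —
while its tone score sits near 1 because the tone evokes freezing. The
unpaired group's elevated WN score reflects faster locomotion without
flight. The other examples build and export schedules
(`01_build_schedules.py`), segment a single simulated session into bouts
(`02_simulate_and_detect.py`), and run the metric table plus statistical
battery (`04_metrics_and_stats.py`).

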