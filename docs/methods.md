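# Methods

## Stimulus schedules

A session is laid out as baseline → stimulus train → tail with a fixed
published total (pre-exposure 590 s; conditioning 820 s; extinction
1910 s). The SCS spans `[onset, onset + 20)` s: twenty 0.5 s pips at a
1 Hz cycle (pip *i* at `onset + i` s), tone pips first for the standard
variant, WN pips first for reversed groups. All stimulus intervals are
half-open and expressed in real-valued seconds from session start.

**ISI placement.** The published protocol fixes each session's total
length and an ISI range (pre-exposure 90–100 s, paired conditioning
90–150 s, unpaired 40–60 s, shock-only 120–160 s, extinction 60–120 s)
but not the individual intervals. We treat the `n − 1` gaps between
consecutive stimuli as the ISIs, draw each uniformly from the range,
then iteratively shift-and-clip them so their sum hits the value forced
by the session total exactly. Feasibility is checked up front and an
infeasible range raises a constraint error naming the deficit.

**Shock placement.** "Co-terminating" is implemented as the shock
interval `[onset + 19, onset + 20)` s, overlapping the final pip cycle.
Unpaired sessions interleave 5 SCS and 5 shocks in a per-seed shuffled
order subject to (i) a 20 s guard gap between any SCS offset and any
shock onset (automatically satisfied by the 40–60 s ISIs, asserted
anyway) and (ii) at most two of five shocks directly following an SCS,
so the SCS never reliably predicts shock. Conditioning days 1 and 2
derive distinct sub-seeds from the base seed, so their stimulus timing
differs; reversed groups share their standard counterpart's timing and
differ only in pip kinds.

## Kinematics

Speed is the per-frame calibrated centroid displacement,
`v[i] = calibration · ‖Δposition‖ · fps` (cm/s), with `v[0]` copying
`v[1]` so series and frame counts match. No smoothing is applied by
default — the base measurement is the raw frame-to-frame speed.
Distance over a window integrates the mean speed of 0.5 s bins, the
partial trailing bin weighted by its actual width. The default
calibration, 1/15 cm per pixel, corresponds to the 30 cm arena spanning
roughly 450 px of a 640×480 frame.

## Bout detection

* **Freezing**: maximal runs of frames with `v < ε`, kept when at least
  1 s long. The commercial tracker's pixel-change criterion is
  proprietary, so freezing is re-based on centroid speed; ε = 0.5 cm/s
  is our documented operational default, not a published value.
* **Darting**: a deterministic hysteresis rule replaces the original
  random-forest classifier. A bout opens at the first frame where speed
  exceeds v_start = 10 cm/s after having been below v_stop = 4 cm/s
  (rest) and closes at the last frame before speed returns below
  v_stop; bouts under 8 frames (266 ms at 30 fps) are discarded. The
  classifier's 0.37 discrimination threshold applies to class
  probabilities and has no analogue here.
* **Jumps / tail rattles**: maximal runs of the `airborne` /
  `tail_rattle` annotation channels. A jump's event time is its start,
  so a bout straddling a window edge is counted once.

Both speed-based detectors are validated frame-for-frame against
brute-force oracles (run-length scan; a segment formulation of the
hysteresis rule) on fuzzed series, and against simulator ground truth
at bout-level F1 ≥ 0.9 (greedy matching at IoU ≥ 0.5).

## Trial/period metrics

Each trial contributes 10 s `pre_scs`, `tone` and `wn` windows, named by
stimulus content — in reversed sessions the WN window precedes the tone
window — plus 1 s shock windows and the baseline. Percent freezing is
overlap-based (bouts clipped to the window), so it is invariant to
splitting a bout at an interior point and additive over sub-windows.
The activity-index denominator pools per-frame speed over all pre-SCS
windows of the session; when that mean falls below 0.1 cm/s the floor
is substituted and flagged (the published motivation is avoiding
near-zero denominators; the floor value is ours). Event histograms use
half-open 1 s bins (an event on an edge falls in the later bin).
Difference scores report mean(first k) − mean(last k), positive for a
decrease; k = 4 by default. Shock-window event counts extend 1 s past
shock offset to capture the reaction (the published reaction window is
unstated). Cohort subsampling (e.g. 20 of 32 paired animals for
frequency comparisons) is a seeded draw without replacement.

## Synthetic data generator

Behavior is a semi-Markov process over freeze / locomote / dart / jump.
At every bout end — and at every (period, trial) boundary, so each
window's statistics are governed by its own cell — a state is drawn
with probabilities proportional to `occupancy / mean_dwell`, which by
the renewal-reward argument makes configured occupancies equal expected
time fractions; measured percent freezing then converges to `100 p` for
configured occupancy `p` (verified to within 3 points over 50 animals).
Dwell distributions: freeze uniform 1–3 s, locomote 0.5–2 s, dart 14–20
frames, jump 9–15 frames.

Emissions: freezing is sub-ε jitter (≈ 0.15 cm/s); locomotion is an
AR(1) speed process (≈ 0.2 s correlation time) clipped to 0.8–9 cm/s —
below the dart-opening threshold, above the freezing ceiling — on a
heading random walk reflected at the arena wall (all positions stay
inside the 15 cm radius); darts are trapezoidal bursts from rest
(1 cm/s edge frames, peak 18–32 cm/s); jumps emit 4–8 cm/s frames with
the airborne flag set. Positions integrate the speed series directly,
so the pipeline's computed speed equals the emitted speed exactly.
Back-to-back dart draws stay separate truth bouts (each burst returns
to rest); freeze/locomote/jump runs merge.

**What the defaults encode.** The paradigm's published quantitative
results are cohort-level; per-trial state rates are not published.
The shipped tables are therefore calibration choices: occupancies
follow logistic trial ramps per (group, session, period) such that
paired-group tone freezing grows across conditioning, WN flight (jump +
dart occupancy ≈ 0.65 by CD2) appears only with paired contingency,
unpaired/shock-only WN responses are purely locomotor (elevated
locomotion speed, near-zero flight), reversed groups freeze to the tone
with negligible WN jumping, and extinction decays the paired jump rate
to zero by mid-session-1 while WN freezing climbs. The absolute CD2
levels were calibrated once so that the full pipeline reproduces the
published cohort-mean CD2 WN activity indices (PA ≈ 12.5 at n = 32,
UN ≈ 5.4 at n = 20) within one published SEM, and then frozen.

**What passing tests do and do not show.** The generator emulates
occupancy structure, bout durations and the speed scale of real
tracking; it does not emulate tracking noise/dropouts, posture,
thigmotaxis, sex differences, or inter-animal variability beyond
sampling noise. Pipeline correctness on simulated data therefore
validates the measurement constructions and detector logic, not the
biological effect sizes, which enter only through the calibrated state
tables.

## Statistics

Welch's t (scipy), one-way ANOVA with Tukey HSD via the
studentized-range distribution (scipy), and ordinary fixed-effects
two-way ANOVA via an OLS fit with Type II sums of squares
(statsmodels) — the published analyses report ordinary two-way ANOVA,
so no repeated-measures correlation structure is modeled, and the SS
type for unbalanced designs (n = 32 vs 20 vs 10) is our documented
choice. Implementations are cross-checked against hand-written
textbook-formula and sums-of-squares oracles to 1e-10, and type-I error
is verified at ≈ 5 % over 2000 null replicates. Shapiro–Wilk screening
is reported, not acted upon.

## Problem sizes and determinism

Tests and the acceptance script use full-length sessions (24 600 frames
for conditioning, 57 300 for extinction) with cohorts of 32/20 animals
for pipeline-level checks and 120 s single-window sessions for
occupancy-recovery checks — sizes at which cohort means are stable to
well under the tolerances asserted. Every random draw flows from
explicit integer seeds through per-day, per-animal `SeedSequence`-style
sub-seeds, so schedules, simulations and reports are bit-reproducible.
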