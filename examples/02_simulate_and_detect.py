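"""Simulate one conditioned animal and segment its behavior into bouts.

The synthetic generator emits a centroid track (30 frames/s, 30 cm
arena) whose state structure follows the paired-group ethogram; the
detectors then recover freezing (speed < 0.5 cm/s for >= 1 s), darts
(speed hysteresis, >= 8 frames), and jumps (airborne channel).
"""

import ethoflight as ef

schedule = ef.build_schedule(ef.session_spec("CD2", "PA", seed=7))
params = ef.default_params("PA", seed=7)
session = ef.simulate_session(schedule, params, animal_seed=0)

speed = ef.compute_speed(session.trajectory)
freezes = ef.detect_freezing(speed)
darts = ef.detect_darts(speed)
jumps = ef.extract_jumps(session.trajectory)

print(f"{session.trajectory.n_frames} frames "
      f"({session.trajectory.duration:.0f} s)")
print(f"freeze bouts: {len(freezes)}  (total "
      f"{sum(b.duration for b in freezes):.0f} s)")
print(f"dart bouts:   {len(darts)}")
print(f"jump bouts:   {len(jumps)}")

truth_darts = [b for b in session.truth_bouts
               if b.behavior is ef.Behavior.DART]
print(f"ground-truth darts: {len(truth_darts)} "
      "(detected counts should be close; see tests for F1 checks)")

ef.export_bouts(freezes + darts + jumps, "bouts_cd2_pa.csv")
print("bout interval table written to bouts_cd2_pa.csv")
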