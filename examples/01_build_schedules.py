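"""Build the paradigm's stimulus schedules and export one as a table.

Each session is a baseline, a train of 20 s serial-compound-stimulus
(SCS) presentations separated by pseudorandom inter-stimulus intervals,
and a tail, with an exact published total length.
"""

import ethoflight as ef

for session in ("PreExp", "CD1", "CD2", "Ext1"):
    schedule = ef.build_schedule(ef.session_spec(session, "PA", seed=7))
    print(f"{session:>6}: total {schedule.total_duration:6.0f} s, "
          f"{len(schedule.scs_onsets):2d} SCS trials, "
          f"{len(schedule.shocks())} shocks, "
          f"{len(schedule.events)} stimulus events")

cd2 = ef.build_schedule(ef.session_spec("CD2", "PA", seed=7))
path = ef.export_schedule(cd2, "cd2_pa_events.csv")
print(f"\nCD2 (paired) event table written to {path}")
print("First trial SCS onset:", cd2.scs_onsets[0], "s;"
      " shock co-terminates at", cd2.scs_onsets[0] + 20.0, "s")
# The totals are the paradigm's published session lengths (590 / 820 /
# 1910 s); the co-terminating shock occupies the final second of each SCS.
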