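"""Build the four task designs and walk the training staircase.

Run:  python examples/01_task_schedules.py
"""

import neurotopo as nt

pav = nt.build_pavlovian_schedule(seed=1)
print("Pavlovian conditioning:", len(pav), "trials;",
      "per-cue counts:", dict(pav["cs_id"].value_counts()))
print(pav.head(5).to_string(index=False))

fc = nt.build_forced_choice_schedule(seed=1)
print("\nForced choice:", len(fc), "trials;",
      "10 pairings x", len(fc) // 10, "repetitions")

gng = nt.build_gng_schedule(seed=1)
go_share = (gng["trial_type"] == "Go").mean()
print("\nIn-lab Go/NoGo:", len(gng), f"trials, {go_share:.0%} Go")

# the training staircase: difficulty rises one level per 6 straight successes
state = nt.RttState()
for trial in range(30):
    state = nt.advance_rtt(state, trial_success=True)
print("\nAfter 30 straight training successes: level", state.level,
      f"-> deadline {state.rtt_seconds:.3f} s (level 1 starts at "
      f"{nt.rtt_for_level(1):.1f} s)")

# the in-lab deadline instead adapts to the block median
print("Adaptive lab deadline for RTs [280, 300, 340] ms:",
      nt.adaptive_rtt([280, 300, 340]), "ms (1.10 x median)")
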