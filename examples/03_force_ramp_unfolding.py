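"""Simulate magnetic-tweezers force-ramp trajectories of a protein with a
weak and a strong unfolding state, detect the unfolding steps, and convert
them to contour-length increments with the FJC model."""

import numpy as np

from nucleoflux import (
    RampSimSpec,
    detect_steps,
    event_summary,
    fjc_extension,
    gen_ramp_trajectory,
)

print(f"FJC check: a 65 nm contour increment extends "
      f"{fjc_extension(50.0, 65.0):.1f} nm at 50 pN")

# two Bell states: a weak ~15 pN / 22 nm event and a strong ~50 pN / 65 nm one
STATES = ((6.3e-3, 1.0, 22.0), (2.8e-4, 0.5, 65.0))

events = []
for seed in range(200):
    traj, _ = gen_ramp_trajectory(
        RampSimSpec(states=STATES, loading_rate=1.0, noise_sd=1.0, seed=seed)
    )
    events.extend(detect_steps(traj, min_step=5.0))

table, summary = event_summary(events, force_threshold=30.0)
print(f"{len(table)} events detected on 200 traces")
print(f"dLc marginal: weak-class mode {summary['weak_dLc']['mode']:.1f} nm, "
      f"strong-class mode {summary['strong_dLc']['mode']:.1f} nm")
print(f"F_U marginal: weak {summary['weak']['mode']:.1f} pN, "
      f"strong {summary['strong']['mode']:.1f} pN")
print("the two contour-length modes recover the 22 and 65 nm of released")
print("contour per state; forces cluster near each state's Bell-model mode")
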