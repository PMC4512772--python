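"""Simulate one subject through acquisition and extinction.

A "female" parameter set (shock cost -8, critic learning rate 0.01) is
trained on the signalled avoidance protocol: 12 sessions of 20 trials with
shock, then 12 sessions without shock or ITI signal.  The printed curves
are the proportion of avoidance responses (lever press during the 60-s
warning period) per session; the weights show what the critic learned to
expect from each stimulus by the end of acquisition.
"""

import numpy as np

from avoidsim import CHANNELS, ProtocolConfig, run_simulation

config = ProtocolConfig(signal_in_acquisition=True)
run = run_simulation("female", config, seed=42)

trials = run.trials_frame()
for phase in ("acquisition", "extinction"):
    curve = (
        trials[trials.phase == phase]
        .groupby("session")["response"]
        .apply(lambda s: (s == "avoidance").mean())
    )
    print(f"{phase:11s} avoidance by session: {np.round(curve.to_numpy(), 2)}")

print("\nend-of-acquisition critic weights (value each stimulus predicts):")
v_end = run.weights[239, 0]  # trial 240, critic row
for name, value in zip(CHANNELS, v_end):
    print(f"  {name:14s} {value:+.3f}")
print(
    "\nNegative warning/context weights mark learned danger; the positive\n"
    "ITI-signal weight marks the safe period the signal announces."
)
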