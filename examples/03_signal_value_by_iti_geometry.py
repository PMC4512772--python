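"""What the critic thinks the safety signal is worth, by ITI geometry.

The same 30-s signal can act as a conditioned reinforcer (positive value)
or acquire aversive properties (negative value) depending on how far it
sits from the next danger period.  This script trains signal-present
female simulations under three geometries and prints the critic's
end-of-acquisition weight for the signal input.
"""

import numpy as np

from avoidsim import CHANNELS, ProtocolConfig, run_simulation

SIG = CHANNELS.index("iti_signal")

geometries = {
    "180-s ITI, signal throughout": ProtocolConfig(signal_in_acquisition=True),
    "180-s ITI, signal in last 30 s": ProtocolConfig(
        signal_in_acquisition=True, signal_window="last_3"),
    "30-s ITI, signal throughout": ProtocolConfig(
        signal_in_acquisition=True, iti_len=3),
}

for label, config in geometries.items():
    values = [
        run_simulation("female", config, seed=100 + k).weights[239, 0, SIG]
        for k in range(3)
    ]
    print(f"{label:32s} v_signal = {np.mean(values):+.2f}")

print(
    "\nA signal far from the next warning ends up positive (it follows the\n"
    "avoidance response and marks safety); a signal adjacent to the next\n"
    "warning absorbs the anticipatory negative prediction error and ends\n"
    "up negative, like the warning itself."
)
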