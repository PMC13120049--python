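"""How amplitude saturation distorts window features.

Clips a standard-normal window at each threshold of the tau sweep and prints
the fraction of saturated samples (with its Gaussian prediction 2Q(tau/sigma)),
the RMS of the clipped signal, and the zero-crossing count — showing that RMS
contracts toward tau while the sign structure (ZC) survives arbitrary clipping.
"""

import numpy as np

from emgstress.degrade import (
    clip_signal,
    empirical_saturation_fraction,
    saturation_probability,
)
from emgstress.features import rms, zero_crossings

rng = np.random.default_rng(0)
x = rng.standard_normal(481)  # one 250 ms window at 1925.9259 Hz, z-units

print(f"clean window: RMS = {rms(x):.4f}, ZC = {zero_crossings(x)}")
print(f"{'tau':>8} {'P_sat model':>12} {'saturated':>10} {'RMS':>10} {'ZC':>5}")
for tau in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1):
    y = clip_signal(x, tau)
    print(
        f"{tau:8.0e} {saturation_probability(tau, 1.0):12.4f} "
        f"{empirical_saturation_fraction(x, tau):10.4f} "
        f"{rms(y):10.2e} {zero_crossings(y):5d}"
    )
print("\nRMS collapses to ~tau under deep clipping (amplitude information lost)")
print("while ZC is invariant: polarity changes pass through the saturation rails.")
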