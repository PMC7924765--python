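"""Bifurcation structure of one cortical column against its external drive.

Scans the deterministic single-column model over the mean input p,
locating fixed points and the limit-cycle (oscillatory) interval, then
shows how the inhibitory gain beta shifts that interval to stronger drive.
"""

import numpy as np

from neurogain.neural_mass import GainSet, oscillatory_interval, scan_single_node

p_grid = np.arange(0.0, 6.01, 0.25)

for beta in (0.0, 0.3):
    diag = scan_single_node(gains=GainSet(beta=beta), p_grid=p_grid)
    lo, hi = oscillatory_interval(diag)
    freqs = diag.frequency[diag.oscillating]
    print(f"beta={beta}: oscillatory p-interval [{lo:.2f}, {hi:.2f}] impulses/s, "
          f"dominant frequency {np.nanmedian(freqs):.1f} Hz in the cycle")

print()
print("The column is quiescent at weak drive, oscillates in the alpha band")
print("(~10 Hz) for intermediate drive, and settles on a stable focus when")
print("over-excited; raising beta delays the oscillation onset to larger p.")
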