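"""Functional connectivity dynamics of the BOLD-like signals.

Computes the window-by-window FCD matrix (Clarkson distances between
sliding-window FC patterns) and its two scalar summaries: the variance
beyond the diagonal offset (multistability) and the typical speed d_typ.
"""

from dataclasses import replace

from neurogain import generate_synthetic_connectome, normalize_in_strength, simulate_network
from neurogain.fcd import fcd_matrix, fcd_speed, fcd_variance, windowed_fcs
from neurogain.hemodynamics import bandpass, decimate, simulate_bold
from neurogain.neural_mass import GainSet, SimConfig

sc = normalize_in_strength(generate_synthetic_connectome(n=30, seed=1))
cfg = SimConfig(duration=360.0, transient=0.0)

for alpha in (0.0, 0.5):
    traj = simulate_network(sc, gains=GainSet(alpha=alpha, beta=0.25), cfg=cfg, seed=0)
    bold = simulate_bold(traj.rates, dt=1.0 / traj.fs)
    bold = replace(bold, data=bold.data[:, 60_000:])
    bold = decimate(bandpass(bold), target_fs=2.0)

    stream, starts = windowed_fcs(bold, win_len=100.0, step=2.0)
    fcd = fcd_matrix(stream, starts)
    print(f"alpha={alpha}: {stream.shape[0]} windows, "
          f"var(FCD)={fcd_variance(fcd, tau=100.0):.5f}, "
          f"d_typ={fcd_speed(fcd, tau=100.0):.3f}")

print()
print("Asynchronous noise (alpha=0) gives fast, featureless FC evolution")
print("(high d_typ, tiny variance); the integrated regime stabilizes the FC")
print("patterns, lowering the typical reconfiguration speed.")
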