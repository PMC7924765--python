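"""Simulate a coupled 30-node network and measure EEG-timescale metrics.

Builds a synthetic modular connectome, integrates the coupled columns for
two minutes at two gain settings, and compares phase synchrony, SNR and
dominant frequency of the EEG-like signals.
"""

from neurogain import generate_synthetic_connectome, normalize_in_strength, simulate_network
from neurogain.eeg_metrics import spectral_summary
from neurogain.neural_mass import GainSet, SimConfig

sc = normalize_in_strength(generate_synthetic_connectome(n=30, seed=1))
cfg = SimConfig(duration=120.0, transient=30.0)

for alpha in (0.0, 0.5):
    traj = simulate_network(sc, gains=GainSet(alpha=alpha, beta=0.25), cfg=cfg, seed=0)
    spec = spectral_summary(traj.eeg, traj.fs)
    print(f"alpha={alpha}: R_bar={spec.R_bar:.3f}  SNR={spec.snr_db_mean:+.1f} dB  "
          f"mean frequency={spec.omega_mean:.1f} Hz")

print()
print("Uncoupled columns (alpha=0) stay asynchronous and noisy; intermediate")
print("excitatory gain synchronizes the network (R_bar near 1), raises the")
print("signal-to-noise ratio and slows the shared rhythm toward the theta band.")
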