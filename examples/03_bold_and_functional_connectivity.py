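"""From firing rates to a surrogate-thresholded functional network.

Simulates the network, converts pyramidal rates into band-passed BOLD-like
signals with the hemodynamic model, thresholds the static FC against FT
surrogates and reports the weighted graph metrics.
"""

from dataclasses import replace

from neurogain import generate_synthetic_connectome, normalize_in_strength, simulate_network
from neurogain.functional_connectivity import ft_surrogates, static_fc, threshold_fc
from neurogain.graph_metrics import graph_summary
from neurogain.hemodynamics import bandpass, decimate, simulate_bold
from neurogain.neural_mass import GainSet, SimConfig

sc = normalize_in_strength(generate_synthetic_connectome(n=30, seed=1))
cfg = SimConfig(duration=360.0, transient=0.0)
traj = simulate_network(sc, gains=GainSet(alpha=0.5, beta=0.25), cfg=cfg, seed=0)

bold = simulate_bold(traj.rates, dt=1.0 / traj.fs)
bold = replace(bold, data=bold.data[:, 60_000:])  # drop the 60 s warm-up
bold = decimate(bandpass(bold), target_fs=2.0)

fc = static_fc(bold)
ens = ft_surrogates(bold, n=500, seed=7)
tfc = threshold_fc(fc, ens, p=0.05, correction="bh_fdr")
kept = int(tfc.mask.sum() // 2)
print(f"edges surviving the surrogate test: {kept} of {30 * 29 // 2}")

gs = graph_summary(tfc, runs=200, seed=3)
print(f"E_w={gs.E_w:.3f}  Q_w={gs.Q_w:.3f}  T_w={gs.T_w:.3f}  "
      f"mean PC_w={gs.PC_w_mean:.3f}  ({gs.n_modules} modules)")

print()
print("E_w (global efficiency) measures functional integration; Q_w and T_w")
print("measure segregation. At this gain setting the network sits in its")
print("integrated regime: many significant edges and high efficiency.")
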