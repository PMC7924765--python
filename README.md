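# neurogain

Whole-brain simulation of cholinergic and noradrenergic neuromodulation
with a network of modified Jansen & Rit cortical columns, and
quantification of the functional integration/segregation balance of the
resulting BOLD-like activity.

`neurogain` is aimed at computational neuroscientists studying how
neuromodulatory gain mechanisms shape large-scale brain dynamics.  It
simulates EEG-timescale neural mass activity coupled through a structural
connectome, converts firing rates into fMRI-like BOLD signals, and measures
integration (global efficiency, participation coefficient), segregation
(modularity, transitivity), phase synchrony, signal-to-noise ratio and
functional connectivity dynamics (FCD) across neuromodulatory parameter
spaces.

## Model

Each of the *n* network nodes is a cortical column with three populations
(pyramidal cells, excitatory and inhibitory interneurons).  Synaptic
dynamics are second-order PSP filters (EPSP kernel `A a t e^{-at}`, IPSP
kernel `B b t e^{-bt}`); population output is the sigmoid
`S(v, r) = ζ_max / (1 + e^{r(θ − v)})`.  Per node the state
(x0…x3, y0…y3) evolves as

    ẏ0 = A a  S(C2 x1 − C4 x2 + C α z, r0) − 2a y0 − a² x0
    ẏ1 = A a [p(t) + S(C1 x0 − C β x2, r1)] − 2a y1 − a² x1
    ẏ2 = B b  S(C3 x0, r2)                  − 2b y2 − b² x2
    ẏ3 = A ā  S(C2 x1 − C4 x2 + C α z, r0) − 2ā y3 − ā² x3

with `ẋk = yk`, long-range input `z_i = Σ_j M̃_ij x3,j` through the
in-strength-normalized connectome `M̃`, and a Gaussian drive
`p(t) ~ N(μ=2, σ=2)` impulses/s.  Three gains model neuromodulation:

- **α** (excitatory gain, cholinergic) scales long-range
  pyramidal-to-pyramidal coupling;
- **β** (inhibitory gain, cholinergic) scales a local
  inhibitory-to-excitatory interneuron connection that damps the
  excitatory feedback loop;
- **r0** (filter gain, noradrenergic) is the pyramidal sigmoid slope.

The EEG-like signal is `ν_i = C2 x1 − C4 x2 + C α z_i`; pyramidal rates
`ζ_i = S(ν_i, r0)` drive a Balloon–Windkessel hemodynamic model whose
output is band-passed 0.01–0.1 Hz (3rd-order Bessel).  Static FC
(Pearson) is thresholded against Fourier-transform surrogates with BH-FDR
correction; graph metrics use the weighted formulations with
Louvain-consensus community detection; FCD uses 100 s windows, 2 s steps
and the Clarkson angular distance.

## Worked example

`examples/05_gain_sweep.py` sweeps the excitatory gain at β = 0.25 on a
30-node synthetic modular connectome (300 s recordings, 2 seeds per
point):

```
alpha   E_w    Q_w    R_bar  SNR(dB)
 0.00  0.000  0.000  0.163    -4.2
 0.20  0.001  0.250  0.854    +2.7
 0.40  0.020  0.599  0.958   +10.1
 0.50  0.322  0.371  0.958   +11.6
 0.60  0.707  0.039  0.880    +7.8
 0.80  0.000  0.000  0.190    -6.6
 1.00  0.000  0.000  0.164    -8.4
```

Integration (global efficiency `E_w`) follows an inverted-U in α: at
α = 0 the columns are uncoupled noise and the functional graph is empty;
intermediate gain synchronizes the network (Kuramoto `R_bar` ≈ 0.96,
SNR > +10 dB) and maximizes efficiency; past the second critical boundary
the columns are over-excited and both integration and segregation vanish.
Segregation (modularity `Q_w`) peaks near the critical boundary.  The
other examples demonstrate the single-column bifurcation scan (~10 Hz
alpha rhythm shifted to stronger drive by β), EEG metrics, the
BOLD/FC/graph pipeline and the FCD analysis.

A thin CLI mirrors the library:
`neurogain make-connectome | simulate | analyze | scan-node | sweep`.

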