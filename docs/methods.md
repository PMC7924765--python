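# Methods

## Neural mass model

Each node is a modified Jansen & Rit cortical column: pyramidal cells,
excitatory interneurons and inhibitory interneurons, each modeled by a
second-order postsynaptic-potential (PSP) filter followed by a sigmoid
rate function `S(v, r) = ζ_max / (1 + e^{r(θ − v)})`.  The modification
relative to the classic column is an inhibitory-to-excitatory interneuron
connection scaled by the gain β, which damps the local excitatory feedback
to pyramidal cells when their activity is high — an inhibitory homeostatic
loop.  Long-range coupling is pyramidal-to-pyramidal only, scaled by the
gain α and by the global constant C (`C·α` and `C·β` are the effective
couplings, consistent with C1–C4 being multiples of C).  The filter gain
r0 is the pyramidal sigmoid slope.

Parameters (defaults): A = 3.25 mV, B = 22 mV, a = 100 s⁻¹, b = 50 s⁻¹,
ā = a/2 (long-range EPSPs are faster at the soma), ζ_max = 5 s⁻¹,
θ = 6 mV, r1 = r2 = 0.56 mV⁻¹, C = 135, C1 = C, C2 = 0.8C, C3 = C4 = 0.25C.
Gains: α ∈ [0, 1], β ∈ [0, 0.5], r0 ∈ [0, 1] mV⁻¹ (0.56 default).
External drive p(t): Gaussian, μ = 2, σ = 2 impulses/s, independent per
node.  In this formulation the drive p enters the pyramidal input equation
alongside a sigmoid output bounded by ζ_max = 5 s⁻¹, so the single-column
oscillatory window lies at p ≈ 1.3–4 impulses/s and the default μ = 2 sits
inside it — the network regime is then selected by the gains, not by the
drive.

### Stochastic integration

Euler–Maruyama at dt = 1 ms; recordings are the equivalent of 11 min with
the first 60 s discarded; six seeds by default control both the uniform
[−0.1, 0.1] initial conditions and the noise streams.  Two discretization
conventions are implemented for the Gaussian drive:

- `redraw` (default): p(t) is resampled from N(μ, σ) at every step and
  enters the drift term multiplied by dt.  This is the literal reading of
  a Gaussian-distributed input, and it is the convention under which the
  model exhibits its documented regimes (synchronization and integration
  windows in the gains) at σ = 2.
- `white`: μ contributes deterministically and σ√dt scales a Wiener
  increment on the y1 state.  This injects a √(1/dt) ≈ 32× stronger
  effective perturbation at the same nominal σ; at σ = 2 it swamps the
  coupling-induced synchronization entirely, so it is available as a
  config switch (`SimConfig.noise_mode`) rather than the default.

The integration kernel is numba-compiled; chunked noise generation bounds
memory, and a non-finite state aborts with the failing step and gains
named.  Halving dt on a deterministic run moves the mean rate by < 2 %
(weak-convergence check in the tests).

### Single-column bifurcation scan

Brute-force, not numerical continuation: for each drive p the fixed points
are found by reducing the equilibrium to a scalar equation in x0 (all
other coordinates are explicit functions of x0 at equilibrium), bracketing
on a 400-point grid and polishing with Brent's method; stability comes
from the eigenvalues of a central-difference Jacobian (step 1e−6,
real-part threshold 1e−6).  Limit cycles are detected by integrating 20 s
from a perturbed fixed point and thresholding the peak-to-peak EEG
amplitude at 1e−3 mV after a 10 s transient; near the bifurcation
boundaries slow transients can smear the interval edges by one grid step,
which is adequate for locating the oscillatory window.  The diagram
reports the min/max envelope of the EEG-like signal ν on the attractor.

## Connectome

The coupling matrix is a weighted undirected region-by-region matrix in
[0, 1] with zero diagonal (e.g. a 90-region AAL human connectome loaded
from CSV/TSV/npy).  Before simulation every row is divided by the node's
in-strength (off-diagonal row sum), so each node's long-range input is a
convex combination of the other nodes' outputs — homeostatic input
equalization that preserves topology.  Isolated rows are left zero and
logged rather than rejected.  The synthetic generator plants `n_modules`
near-equal blocks with independent edges (probability `p_intra` within,
`p_inter` between; defaults 4 modules, 0.6/0.05 on 90 nodes), uniform
weights in [0.3, 1] (or rescaled lognormal), redrawing and finally
bridging components until connected.  It reproduces the modular,
heterogeneous-weight character of empirical connectomes but not their
geometry, hub topology or weight-distance correlations, so desk-scale
results locate regime boundaries only qualitatively; empirical transition
values (e.g. critical α near 0.3/0.8) require the empirical matrix.

## Hemodynamics

Pyramidal rates drive the Balloon–Windkessel system per node
(τ_s = 0.65, τ_f = 0.41, τ_v = τ_q = 0.98 s, κ = 0.32, E0 = 0.4,
k1 = 2.77, k2 = 0.2, k3 = 0.5), integrated with Euler at the neural dt
from rest (s = 0, f = v = q = 1) with a positivity guard that raises
rather than clamps.  V0 is not constrained by correlation-based analyses
(pure scale factor; FC is V0-invariant, verified in tests) and defaults
to 0.02.  The BOLD nonlinearity is
`B = V0[k1(1 − q) + k2(1 − q/v) + k3(1 − v)]`.

Signals are band-passed 0.01–0.1 Hz with a 3rd-order Bessel filter in SOS
form, zero-phase by default (single-pass available); the zero-phase
response squares the magnitude (gain 0.87 at 0.05 Hz, 1.00 at the
geometric band centre 0.032 Hz, < 1e−5 at 0.5 Hz).  In the pipeline the
hemodynamic model is warmed up over the discarded 60 s and that segment is
dropped *before* filtering: the shared onset step would otherwise leak
about 100 s forward through the non-causal filter and masquerade as
functional connectivity.  The filtered signal is stride-decimated to
0.5 s sampling (no extra anti-alias stage is needed below the band edge);
with 100 s windows this leaves 200 samples per FCD window.  By default
only pyramidal rates drive the model (the hemodynamic response tracks
excitatory activity); `bold_input="summed"` feeds the summed rates of all
three populations instead.

## EEG metrics

Phase synchrony: each node is band-passed (3rd-order Bessel, zero-phase)
around its own Welch spectral peak ± 3 Hz (peak search restricted to
1–30 Hz), phases come from the analytic signal, 1 s is trimmed from each
end against transform edge artifacts, and the Kuramoto order parameter
`R(t) = |⟨e^{jφ}⟩_N|` is averaged over time.  SNR: Welch PSD with 20 s
segments and 50 % overlap (segment length shrinks with a warning on short
test signals); signal power is the band ω_i ± 1 Hz around the node's
peak, noise power is everything else with the 2nd–5th harmonic bands
(± 1 Hz each) excluded; reported as 10·log10 per node and averaged.  A
vanishing noise floor returns a capped 100 dB with a warning.

## Functional connectivity and thresholding

Static FC is the Pearson matrix of the full BOLD-like recording.  The
null is built from 500 Fourier-transform surrogates: per node and per
surrogate, independent phase randomization of the rFFT (DC/Nyquist kept
real), which preserves each node's periodogram exactly and destroys
cross-correlations (phases are not shared across nodes, since the aim is
a correlation null).  A Gaussian is fitted per edge to the surrogate
correlations; one-sided right-tail p-values are corrected across the
(n² − n)/2 edges with Benjamini–Hochberg FDR at p = 0.05.  Non-surviving
entries are zeroed and negative correlations are never retained, so the
thresholded FC is a weighted graph with weights in (0, 1].  A degenerate
zero-sd null degrades to a point comparison and is logged.  Type-I
calibration of the uncorrected test on independent AR(1) signals is part
of the acceptance tests.

## Graph metrics

All metrics operate on the thresholded FC.  Global efficiency averages
inverse shortest-path lengths with edge lengths 1/weight (the standard
toolbox convention for correlation-weighted brain graphs) and disconnected pairs contributing zero.  Weighted transitivity uses
geometric-mean triangle intensities with the binary degree k_i(k_i − 1)
denominator (the reference-toolbox reading; a strict weighted-degree
variant would not be collectively normalized).  Modularity is the Newman
weighted form with both edge orientations counted in l_w.  Participation
is `1 − Σ_m (k_i(m)/k_i)²`, with isolated nodes assigned 0 and included
in the mean.  Communities come from Louvain (networkx implementation,
resolution 1.0) repeated 200 times under seeded tie-breaking, with
consensus clustering: build the pairwise agreement matrix, threshold at
0.5, re-run Louvain on it, and iterate (capped at 50 rounds) until all
runs coincide; partitions are compared after first-appearance canonical
relabeling so label permutations count as equal.

## Functional connectivity dynamics

Sliding windows of 100 s displaced by 2 s (251 windows from 600 s at
0.5 s sampling); per window, Pearson FC with negative values clipped to
zero and the upper triangle vectorized in fixed row-major order.  Window
pairs are compared with the Clarkson angular distance
`λ(x, y) = ½‖x/‖x‖ − y/‖y‖‖`, scale-invariant and bounded by √2/2 for
nonnegative vectors.  var(FCD), the multistability index, is the variance
of upper-triangle entries at window separation ≥ τ = 100 s (the τ line
itself is included, consistent with the speed measure); d_typ is the
median of the entries exactly on the τ-offset subdiagonal (τ must be a
multiple of the window step; an optional band width is deliberately not
pooled — the exact line is used).

## Pipeline and sweeps

`run_point` composes simulate → EEG metrics → BOLD → filter → FC →
surrogate threshold → graph metrics → FCD per seed and averages
arithmetically (maps show seed means).  `run_sweep` covers 1-D/2-D grids
over α, β, r0, C1, μ, σ with an optional linkage rule (e.g. β = 0.5α);
every (cell, replicate) gets an independent reproducible seed substream
derived from the master seed via `SeedSequence`, so cells are
statistically independent and a sweep is resumable from per-cell JSON
caches without changing its result.  Default grids: α in steps of 0.05,
β of 0.025, r0 of 0.05.  Failures abort only their cell and are recorded
with their cause.

## Problem sizes used in the shipped tests and examples

The full study conditions (90 nodes, 660 s, six seeds, 500 surrogates,
200 Louvain runs) are the package defaults.  The test suite and examples
run a reduced profile chosen as the smallest problem that still exhibits
the qualitative regimes: a 30-node synthetic connectome, 300 s analyzed
recordings and 2 seeds for the gain sweep (the inverted-U of E_w, the
Q_w boundary peak and the R̄/SNR co-variation all survive this
reduction), and 8–12 nodes with tens of seconds for unit-level checks.
What passing these tests shows is internal correctness and the
qualitative neuromodulation phenomenology on synthetic connectomes; it
does not certify the quantitative transition values reported for the
empirical human connectome, which require that matrix as input.

## Known limitations

- Brute-force bifurcation scanning cannot separate closely spaced
  attractors or detect unstable cycles; boundaries are resolved to one
  grid step.
- The Gaussian edge-null is an approximation to the surrogate correlation
  distribution; an empirical-quantile mode exists for validation use.
- No conduction delays, regional heterogeneity or time-varying
  neuromodulation; gains are tonic by design.
- FCD windowing assumes stationary sampling of the window stream; window
  length is tied to the 0.01 Hz filter edge and is not adapted.
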