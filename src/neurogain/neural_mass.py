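"""Modified Jansen & Rit column dynamics on a connectome.

Each node is a three-population cortical column (pyramidal cells, excitatory
and inhibitory interneurons).  Postsynaptic-potential (PSP) blocks are
critically damped second-order filters with kernels ``h_E(t) = A a t e^{-at}``
and ``h_I(t) = B b t e^{-bt}``; population output is the sigmoid
``S(v, r) = zeta_max / (1 + exp(r (theta - v)))``.  Relative to the classic
model the column gains an inhibitory-to-excitatory interneuron connection
scaled by the gain ``beta``, long-range pyramidal coupling scaled by
``alpha`` through the in-strength-normalized connectome, and a tunable
pyramidal sigmoid slope ``r0``.

Per node ``i`` the state is (x0..x3, y0..y3) with ``x_k' = y_k`` and

    y0' = A a  S(C2 x1 - C4 x2 + C alpha z_i, r0) - 2 a  y0 - a^2  x0
    y1' = A a [p(t) + S(C1 x0 - C beta x2, r1)]   - 2 a  y1 - a^2  x1
    y2' = B b  S(C3 x0, r2)                        - 2 b  y2 - b^2  x2
    y3' = A a~ S(C2 x1 - C4 x2 + C alpha z_i, r0) - 2 a~ y3 - a~^2 x3

where ``z_i = sum_j M~_ij x3_j`` is the input from other columns and
``p(t)`` is a Gaussian external drive.  The EEG-like signal is the average
pyramidal PSP ``nu_i = C2 x1 - C4 x2 + C alpha z_i`` and the pyramidal
firing rate ``zeta_i = S(nu_i, r0)`` feeds the hemodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .connectome import StructuralConnectome, normalize_in_strength

__all__ = [
    "JRParams",
    "GainSet",
    "NoiseSpec",
    "SimConfig",
    "NetworkTrajectory",
    "BifurcationDiagram",
    "SimulationError",
    "sigmoid",
    "network_input",
    "jr_derivatives",
    "simulate_network",
    "simulate_single_node",
    "scan_single_node",
    "oscillatory_interval",
]


class SimulationError(RuntimeError):
    """Numerical failure (blow-up) during integration."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class JRParams:
    """Jansen & Rit column parameters (original values by default).

    A, B : EPSP/IPSP amplitudes (mV); a, b : inverse synaptic time
    constants (1/s); a_bar : inverse time constant of long-range EPSPs
    (apical-dendrite targets are faster at the soma, a_bar = a/2);
    zeta_max, theta, r1, r2 : sigmoid parameters; C, C1..C4 : intra-column
    connectivity constants.
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    a_bar: float | None = None
    zeta_max: float = 5.0
    theta: float = 6.0
    r1: float = 0.56
    r2: float = 0.56
    C: float = 135.0
    C1: float | None = None
    C2: float | None = None
    C3: float | None = None
    C4: float | None = None

    def __post_init__(self) -> None:
        if self.a_bar is None:
            self.a_bar = 0.5 * self.a
        if self.C1 is None:
            self.C1 = self.C
        if self.C2 is None:
            self.C2 = 0.8 * self.C
        if self.C3 is None:
            self.C3 = 0.25 * self.C
        if self.C4 is None:
            self.C4 = 0.25 * self.C
        for name in ("A", "B", "a", "b", "a_bar", "zeta_max", "theta", "r1", "r2", "C", "C1", "C2", "C3", "C4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"JRParams.{name} must be strictly positive")


@dataclass
class GainSet:
    """Neuromodulatory gains.

    alpha : excitatory gain, scales long-range coupling (cholinergic).
    beta  : inhibitory gain, scales the inhibitory-to-excitatory
            interneuron connection (cholinergic).
    r0    : pyramidal sigmoid slope in 1/mV (noradrenergic filter gain).
    """

    alpha: float = 0.0
    beta: float = 0.0
    r0: float = 0.56

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.r0 < 0:
            raise ValueError("gains must be nonnegative")


@dataclass
class NoiseSpec:
    """Gaussian external drive p(t) to the pyramidal input (impulses/s)."""

    mu: float = 2.0
    sigma: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class SimConfig:
    """Integration settings: Euler-Maruyama, 1 ms step, 11 min with 60 s discarded."""

    dt: float = 0.001
    duration: float = 660.0
    transient: float = 60.0
    seeds: Sequence[int] = (0, 1, 2, 3, 4, 5)
    # "redraw": p(t) resampled from N(mu, sigma) every step (the literal
    # reading of the Gaussian-drive description); "white": mu*dt plus a
    # sigma*sqrt(dt) Wiener increment in the y1 update
    noise_mode: str = "redraw"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.transient < self.duration):
            raise ValueError("require 0 <= transient < duration")
        if self.noise_mode not in ("white", "redraw"):
            raise ValueError("noise_mode must be 'white' or 'redraw'")


@dataclass
class NetworkTrajectory:
    """Recorded network activity after discarding the transient.

    eeg : node x time average pyramidal PSP nu_i(t) (mV).
    rates : node x time pyramidal firing rate zeta_i(t) (1/s).
    time : seconds, starting at 0 at the end of the transient.
    """

    time: np.ndarray
    eeg: np.ndarray
    rates: np.ndarray
    fs: float
    seed: int | None = None
    state: np.ndarray | None = None  # final (n, 8) state
    rates_exc: np.ndarray | None = None  # excitatory interneuron rates, optional
    rates_inh: np.ndarray | None = None  # inhibitory interneuron rates, optional

    @property
    def n_nodes(self) -> int:
        return self.eeg.shape[0]


# ---------------------------------------------------------------------------
# elementary operations (reference NumPy implementations)
# ---------------------------------------------------------------------------


def sigmoid(v, r: float, zeta_max: float = 5.0, theta: float = 6.0):
    """Population input-output sigmoid S(v, r) = zeta_max / (1 + e^{r (theta - v)}).

    Monotone nondecreasing in ``v`` with range (0, zeta_max); ``r = 0``
    returns zeta_max/2 for any input.
    """
    arg = np.clip(r * (theta - np.asarray(v, dtype=float)), -700.0, 700.0)
    return zeta_max / (1.0 + np.exp(arg))


def network_input(x3: np.ndarray, sc: StructuralConnectome) -> np.ndarray:
    """Long-range input z_i = sum_{j != i} M~_ij x3_j from other columns.

    Requires a normalized connectome; for non-isolated nodes the result is a
    convex combination of the other columns' long-range outputs.
    """
    if not sc.normalized:
        raise ValueError("network_input requires an in-strength normalized connectome")
    x3 = np.asarray(x3, dtype=float)
    if x3.shape[0] != sc.n:
        raise ValueError(f"x3 has length {x3.shape[0]}, connectome has {sc.n} nodes")
    return sc.weights @ x3


def jr_derivatives(
    state: np.ndarray,
    z: np.ndarray,
    p: np.ndarray,
    params: JRParams,
    gains: GainSet,
) -> np.ndarray:
    """Drift field of the coupled columns.

    ``state`` is (n, 8) ordered (x0, x1, x2, x3, y0, y1, y2, y3); ``z`` the
    long-range input (mV) and ``p`` the external drive (impulses/s), both
    length n.  Returns the (n, 8) time derivative.
    """
    state = np.atleast_2d(np.asarray(state, dtype=float))
    x = state[:, :4]
    y = state[:, 4:]
    pr = params
    z = np.broadcast_to(np.asarray(z, dtype=float), (state.shape[0],))
    p = np.broadcast_to(np.asarray(p, dtype=float), (state.shape[0],))

    nu = pr.C2 * x[:, 1] - pr.C4 * x[:, 2] + pr.C * gains.alpha * z
    s_pyr = sigmoid(nu, gains.r0, pr.zeta_max, pr.theta)
    s_exc = sigmoid(pr.C1 * x[:, 0] - pr.C * gains.beta * x[:, 2], pr.r1, pr.zeta_max, pr.theta)
    s_inh = sigmoid(pr.C3 * x[:, 0], pr.r2, pr.zeta_max, pr.theta)

    d = np.empty_like(state)
    d[:, :4] = y
    d[:, 4] = pr.A * pr.a * s_pyr - 2 * pr.a * y[:, 0] - pr.a**2 * x[:, 0]
    d[:, 5] = pr.A * pr.a * (p + s_exc) - 2 * pr.a * y[:, 1] - pr.a**2 * x[:, 1]
    d[:, 6] = pr.B * pr.b * s_inh - 2 * pr.b * y[:, 2] - pr.b**2 * x[:, 2]
    d[:, 7] = pr.A * pr.a_bar * s_pyr - 2 * pr.a_bar * y[:, 3] - pr.a_bar**2 * x[:, 3]
    return d


# ---------------------------------------------------------------------------
# Euler-Maruyama integration kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sigm(v, r, zmax, theta):
    arg = r * (theta - v)
    if arg > 700.0:
        arg = 700.0
    elif arg < -700.0:
        arg = -700.0
    return zmax / (1.0 + np.exp(arg))


@njit(cache=True)
def _integrate_chunk(
    W,
    state,
    noise,
    dt,
    A,
    B,
    a,
    b,
    abar,
    zmax,
    theta,
    r0,
    r1,
    r2,
    C,
    C1,
    C2,
    C3,
    C4,
    alpha,
    beta,
    mu,
    sigma,
    white,
    rec_offset,
    eeg,
    rates,
    rates_exc,
    rates_inh,
    record_extra,
):
    """Advance the network ``noise.shape[0]`` steps, recording nu and zeta.

    ``state`` is (n, 8) and mutated in place; recording index for step t is
    rec_offset + t, skipped while negative (transient).  When
    ``record_extra`` the interneuron population rates are stored too.
    """
    n = W.shape[0]
    nsteps = noise.shape[0]
    sqrt_dt = np.sqrt(dt)
    n_rec = eeg.shape[1]
    dy = np.empty((n, 4))
    nu = np.empty(n)
    se = np.empty(n)
    si = np.empty(n)
    x3 = np.empty(n)
    for t in range(nsteps):
        # coupling input from current long-range PSPs
        for i in range(n):
            x3[i] = state[i, 3]
        z = W @ x3
        for i in range(n):
            nu_i = C2 * state[i, 1] - C4 * state[i, 2] + C * alpha * z[i]
            nu[i] = nu_i
            s_pyr = _sigm(nu_i, r0, zmax, theta)
            s_exc = _sigm(C1 * state[i, 0] - C * beta * state[i, 2], r1, zmax, theta)
            s_inh = _sigm(C3 * state[i, 0], r2, zmax, theta)
            se[i] = s_exc
            si[i] = s_inh
            if white:
                p_det = mu
            else:
                p_det = mu + sigma * noise[t, i]
            dy[i, 0] = A * a * s_pyr - 2.0 * a * state[i, 4] - a * a * state[i, 0]
            dy[i, 1] = A * a * (p_det + s_exc) - 2.0 * a * state[i, 5] - a * a * state[i, 1]
            dy[i, 2] = B * b * s_inh - 2.0 * b * state[i, 6] - b * b * state[i, 2]
            dy[i, 3] = A * abar * s_pyr - 2.0 * abar * state[i, 7] - abar * abar * state[i, 3]
        gi = rec_offset + t
        if 0 <= gi < n_rec:
            for i in range(n):
                eeg[i, gi] = nu[i]
                rates[i, gi] = _sigm(nu[i], r0, zmax, theta)
                if record_extra:
                    rates_exc[i, gi] = se[i]
                    rates_inh[i, gi] = si[i]
        for i in range(n):
            for k in range(4):
                state[i, k] += dt * state[i, 4 + k]
                state[i, 4 + k] += dt * dy[i, k]
            if white:
                state[i, 5] += A * a * sigma * sqrt_dt * noise[t, i]
    return state


def simulate_network(
    sc: StructuralConnectome,
    params: JRParams | None = None,
    gains: GainSet | None = None,
    noise: NoiseSpec | None = None,
    cfg: SimConfig | None = None,
    seed: int | None = None,
    initial_state: np.ndarray | None = None,
    chunk_seconds: float = 30.0,
    record_population_rates: bool = False,
) -> NetworkTrajectory:
    """Integrate the coupled columns with Euler-Maruyama.

    The connectome is normalized if raw.  ``seed`` (falling back to
    ``noise.seed``) controls both the uniform [-0.1, 0.1] initial
    conditions and the per-node-independent Gaussian drive; identical
    seeds give bit-identical trajectories.  Activity is recorded at the
    native 1/dt rate after discarding the transient.
    """
    params = params or JRParams()
    gains = gains or GainSet()
    noise = noise or NoiseSpec()
    cfg = cfg or SimConfig()
    if not sc.normalized:
        sc = normalize_in_strength(sc)

    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(seed)
    n = sc.n
    W = np.ascontiguousarray(sc.weights, dtype=float)

    if initial_state is None:
        state = rng.uniform(-0.1, 0.1, (n, 8))
    else:
        state = np.array(initial_state, dtype=float).reshape(n, 8).copy()

    nsteps = int(round(cfg.duration / cfg.dt))
    transient_steps = int(round(cfg.transient / cfg.dt))
    n_rec = nsteps - transient_steps
    eeg = np.empty((n, n_rec))
    rates = np.empty((n, n_rec))
    if record_population_rates:
        rates_exc = np.empty((n, n_rec))
        rates_inh = np.empty((n, n_rec))
    else:
        rates_exc = np.empty((1, 1))
        rates_inh = np.empty((1, 1))

    chunk = max(1, int(round(chunk_seconds / cfg.dt)))
    white = cfg.noise_mode == "white"
    done = 0
    while done < nsteps:
        m = min(chunk, nsteps - done)
        xi = rng.standard_normal((m, n)) if noise.sigma > 0 else np.zeros((m, n))
        _integrate_chunk(
            W, state, xi, cfg.dt,
            params.A, params.B, params.a, params.b, params.a_bar,
            params.zeta_max, params.theta, gains.r0, params.r1, params.r2,
            params.C, params.C1, params.C2, params.C3, params.C4,
            gains.alpha, gains.beta, noise.mu, noise.sigma, white,
            done - transient_steps, eeg, rates,
            rates_exc, rates_inh, record_population_rates,
        )
        done += m
        if not np.all(np.isfinite(state)):
            raise SimulationError(
                f"non-finite state at step {done} (t={done * cfg.dt:.3f} s) "
                f"with alpha={gains.alpha}, beta={gains.beta}, r0={gains.r0}"
            )

    fs = 1.0 / cfg.dt
    time = np.arange(n_rec) * cfg.dt
    return NetworkTrajectory(
        time=time, eeg=eeg, rates=rates, fs=fs, seed=seed, state=state,
        rates_exc=rates_exc if record_population_rates else None,
        rates_inh=rates_inh if record_population_rates else None,
    )


def simulate_single_node(
    p: float,
    params: JRParams | None = None,
    gains: GainSet | None = None,
    duration: float = 60.0,
    transient: float = 10.0,
    dt: float = 0.001,
    initial_state: np.ndarray | None = None,
    seed: int | None = 0,
) -> NetworkTrajectory:
    """Deterministic single-column run with constant external input ``p``."""
    sc = StructuralConnectome(weights=np.zeros((1, 1)), normalized=True)
    cfg = SimConfig(dt=dt, duration=duration, transient=transient, seeds=(0,))
    noise = NoiseSpec(mu=p, sigma=0.0)
    return simulate_network(
        sc, params, gains, noise, cfg, seed=seed, initial_state=initial_state
    )


# ---------------------------------------------------------------------------
# single-node bifurcation scan
# ---------------------------------------------------------------------------


@dataclass
class BifurcationDiagram:
    """Brute-force bifurcation scan of one column against the drive ``p``.

    For each p: the fixed points of the deterministic field (each with an
    8x8 Jacobian stability label), and, when a sustained oscillation is
    found by long integration, the min/max envelope of the EEG-like signal
    nu on the limit cycle and its dominant frequency.
    """

    p_grid: np.ndarray
    fixed_points: list  # list over p of list of (state, label) pairs
    oscillating: np.ndarray  # bool per p
    nu_min: np.ndarray
    nu_max: np.ndarray
    frequency: np.ndarray  # Hz, nan when not oscillating


def _single_node_fixed_points(
    p: float, params: JRParams, gains: GainSet, tol: float = 1e-8
) -> list[np.ndarray]:
    """All fixed points of one uncoupled column at constant drive p.

    At equilibrium the y's vanish and x1, x2, x3 are explicit functions of
    x0, reducing the problem to a scalar root-find in x0 over its reachable
    range [0, A zeta_max / a].
    """
    from scipy.optimize import brentq

    pr = params

    def x_rest(x0: float) -> tuple[float, float, float]:
        x2 = pr.B / pr.b * sigmoid(pr.C3 * x0, pr.r2, pr.zeta_max, pr.theta)
        x1 = pr.A / pr.a * (
            p + sigmoid(pr.C1 * x0 - pr.C * gains.beta * x2, pr.r1, pr.zeta_max, pr.theta)
        )
        nu = pr.C2 * x1 - pr.C4 * x2
        x3 = pr.A / pr.a_bar * sigmoid(nu, gains.r0, pr.zeta_max, pr.theta)
        return x1, x2, x3

    def g(x0: float) -> float:
        x1, x2, _ = x_rest(x0)
        nu = pr.C2 * x1 - pr.C4 * x2
        return x0 - pr.A / pr.a * sigmoid(nu, gains.r0, pr.zeta_max, pr.theta)

    hi = pr.A * pr.zeta_max / pr.a
    grid = np.linspace(-0.05 * hi, 1.05 * hi, 400)
    vals = np.array([g(x) for x in grid])
    roots: list[float] = []
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            roots.append(grid[k])
        elif vals[k] * vals[k + 1] < 0:
            roots.append(brentq(g, grid[k], grid[k + 1], xtol=1e-13))
    states = []
    for x0 in roots:
        x1, x2, x3 = x_rest(x0)
        st = np.array([x0, x1, x2, x3, 0.0, 0.0, 0.0, 0.0])
        d = jr_derivatives(st, np.zeros(1), np.array([p]), params, gains)
        if np.linalg.norm(d) < tol:
            if not any(abs(x0 - s[0]) < 1e-9 for s in states):
                states.append(st)
    return states


def _stability(
    state: np.ndarray, p: float, params: JRParams, gains: GainSet,
    fd_step: float = 1e-6, eig_tol: float = 1e-6,
) -> str:
    """Classify a fixed point from the eigenvalues of a central-difference Jacobian."""
    jac = np.empty((8, 8))
    for k in range(8):
        sp = state.copy()
        sm = state.copy()
        sp[k] += fd_step
        sm[k] -= fd_step
        dp = jr_derivatives(sp, np.zeros(1), np.array([p]), params, gains)[0]
        dm = jr_derivatives(sm, np.zeros(1), np.array([p]), params, gains)[0]
        jac[:, k] = (dp - dm) / (2 * fd_step)
    re = np.real(np.linalg.eigvals(jac))
    if np.all(re < -eig_tol):
        return "stable"
    if np.any(re > eig_tol):
        return "unstable"
    return "marginal"


def scan_single_node(
    params: JRParams | None = None,
    gains: GainSet | None = None,
    p_grid: np.ndarray | None = None,
    sim_duration: float = 20.0,
    sim_transient: float = 10.0,
    osc_threshold: float = 1e-3,
) -> BifurcationDiagram:
    """Brute-force bifurcation diagram of a single column versus the drive p.

    Fixed points come from deterministic root-finding; limit cycles are
    detected by integrating from a perturbed fixed point and measuring the
    peak-to-peak amplitude of x0 after the transient (``osc_threshold`` mV).
    Increasing ``beta`` shifts the oscillatory interval toward larger p.
    """
    params = params or JRParams()
    gains = gains or GainSet()
    if p_grid is None:
        p_grid = np.arange(0.0, 6.01, 0.1)
    p_grid = np.asarray(p_grid, dtype=float)

    fixed_points = []
    oscillating = np.zeros(len(p_grid), dtype=bool)
    nu_min = np.full(len(p_grid), np.nan)
    nu_max = np.full(len(p_grid), np.nan)
    freq = np.full(len(p_grid), np.nan)

    for k, p in enumerate(p_grid):
        fps = _single_node_fixed_points(p, params, gains)
        labeled = [(st, _stability(st, p, params, gains)) for st in fps]
        fixed_points.append(labeled)

        start = None
        if fps:
            start = fps[0] + 0.01  # small perturbation off the equilibrium
        traj = simulate_single_node(
            p, params, gains,
            duration=sim_duration, transient=sim_transient,
            initial_state=start.reshape(1, 8) if start is not None else None,
        )
        nu_t = traj.eeg[0]  # EEG-like signal tracks the oscillation; mV
        amp = np.ptp(nu_t)
        if amp > osc_threshold:
            oscillating[k] = True
            nu_min[k] = nu_t.min()
            nu_max[k] = nu_t.max()
            spec = np.abs(np.fft.rfft(nu_t - nu_t.mean()))
            fgrid = np.fft.rfftfreq(len(nu_t), 1.0 / traj.fs)
            band = (fgrid >= 1.0) & (fgrid <= 30.0)
            if band.any():
                freq[k] = fgrid[band][np.argmax(spec[band])]

    return BifurcationDiagram(
        p_grid=p_grid,
        fixed_points=fixed_points,
        oscillating=oscillating,
        nu_min=nu_min,
        nu_max=nu_max,
        frequency=freq,
    )


def oscillatory_interval(diagram: BifurcationDiagram) -> tuple[float, float]:
    """(p_low, p_high) bounds of the largest contiguous oscillatory p-interval."""
    osc = diagram.oscillating
    if not osc.any():
        raise ValueError("no oscillatory regime found in the scanned p range")
    best, cur = None, None
    for k, flag in enumerate(osc):
        if flag:
            cur = (cur[0], k) if cur else (k, k)
            if best is None or cur[1] - cur[0] > best[1] - best[0]:
                best = cur
        else:
            cur = None
    return float(diagram.p_grid[best[0]]), float(diagram.p_grid[best[1]])
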