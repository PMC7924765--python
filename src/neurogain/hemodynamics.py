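"""Generalized hemodynamic (Balloon-Windkessel) model and BOLD filtering.

Pyramidal firing rates drive, per node, a vasodilatory signal ``s``, blood
inflow ``f``, venous volume ``v`` and deoxyhemoglobin content ``q``:

    s' = zeta(t) - s/tau_s - (f - 1)/tau_f
    f' = s
    v' = (f - v^{1/kappa}) / tau_v
    q' = (f (1 - (1 - E0)^{1/f}) / E0 - q v^{1/kappa - 1}) / tau_q

from the rest state (s, f, v, q) = (0, 1, 1, 1).  The BOLD-like signal is
the static nonlinearity

    B = V0 [k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)].

``V0`` only scales B, so correlation-based analyses are V0-invariant.
Signals are band-pass filtered 0.01-0.1 Hz with a 3rd-order Bessel filter
(zero-phase by default) and decimated for FC/FCD analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import signal

__all__ = ["HemoParams", "BoldSeries", "simulate_bold", "bandpass", "decimate"]


class HemodynamicsError(RuntimeError):
    pass


@dataclass
class HemoParams:
    """Balloon-Windkessel constants (Stephan et al. values)."""

    tau_s: float = 0.65
    tau_f: float = 0.41
    tau_v: float = 0.98
    tau_q: float = 0.98
    kappa: float = 0.32
    E0: float = 0.4
    V0: float = 0.02
    k1: float = 2.77
    k2: float = 0.2
    k3: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_s", "tau_f", "tau_v", "tau_q", "kappa", "E0", "V0", "k1", "k2", "k3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HemoParams.{name} must be strictly positive")


@dataclass
class BoldSeries:
    """Node x time BOLD-like amplitudes (dimensionless)."""

    data: np.ndarray
    fs: float
    filtered: bool = False
    band: tuple[float, float] | None = None

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@njit(cache=True)
def _bold_kernel(rates, dt, tau_s, tau_f, tau_v, tau_q, kappa, E0, V0, k1, k2, k3, out):
    n, T = rates.shape
    ikappa = 1.0 / kappa
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            out[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
            vk = v ** ikappa
            ds = rates[i, t] - s / tau_s - (f - 1.0) / tau_f
            df = s
            dv = (f - vk) / tau_v
            dq = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0 - q * vk / v) / tau_q
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if not (v > 0.0 and q > 0.0 and f > 0.0):
                return i, t
    return -1, -1


def simulate_bold(
    rates: np.ndarray, hp: HemoParams | None = None, dt: float = 0.001
) -> BoldSeries:
    """Integrate the hemodynamic ODEs (Euler, step ``dt``) from rest.

    ``rates`` is node x time, nonnegative, sampled at 1/dt.  The guarded
    integration raises (naming node and time) if blood flow, volume or
    deoxyhemoglobin leave the positive domain, rather than clamping.
    """
    hp = hp or HemoParams()
    rates = np.atleast_2d(np.ascontiguousarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("firing rates must be nonnegative")
    out = np.empty_like(rates)
    i, t = _bold_kernel(
        rates, dt, hp.tau_s, hp.tau_f, hp.tau_v, hp.tau_q,
        hp.kappa, hp.E0, hp.V0, hp.k1, hp.k2, hp.k3, out,
    )
    if i >= 0:
        raise HemodynamicsError(
            f"hemodynamic state left the positive domain at node {i}, t={t * dt:.3f} s"
        )
    if not np.all(np.isfinite(out)):
        raise HemodynamicsError("non-finite BOLD output")
    return BoldSeries(data=out, fs=1.0 / dt, filtered=False)


def bandpass(
    b: BoldSeries,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 3,
    zero_phase: bool = True,
) -> BoldSeries:
    """Band-pass the BOLD series with an order-``order`` Bessel filter.

    Zero-phase (forward-backward) by default to keep windowed correlations
    phase-faithful; ``zero_phase=False`` gives the single-pass filter.
    """
    if high >= b.fs / 2:
        raise ValueError(f"band edge {high} Hz outside Nyquist ({b.fs / 2} Hz)")
    sos = signal.bessel(order, [low, high], btype="bandpass", fs=b.fs, output="sos")
    x = b.data - b.data.mean(axis=1, keepdims=True)
    padlen = min(x.shape[1] - 1, int(3.0 * b.fs / low))
    if zero_phase:
        y = signal.sosfiltfilt(sos, x, axis=1, padtype="even", padlen=padlen)
    else:
        y = signal.sosfilt(sos, x, axis=1)
    y = y - y.mean(axis=1, keepdims=True)
    return replace(b, data=y, filtered=True, band=(low, high))


def decimate(b: BoldSeries, target_fs: float = 2.0) -> BoldSeries:
    """Stride-decimate a (filtered) BOLD series to ``target_fs``.

    Plain subsampling: the band-passed signal has no content near the new
    Nyquist frequency, so no extra anti-alias filter is applied.
    """
    factor = int(round(b.fs / target_fs))
    if factor < 1:
        raise ValueError("target_fs above current sampling rate")
    return replace(b, data=b.data[:, ::factor].copy(), fs=b.fs / factor)
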