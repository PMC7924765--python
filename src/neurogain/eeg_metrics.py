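"""Fast-timescale metrics on EEG-like signals.

Global phase synchrony is the time-averaged Kuramoto order parameter
``R = < | < e^{j phi_i(t)} >_N | >_t`` where instantaneous phases come from
the analytic signal of each node after a narrow Bessel band-pass around its
own spectral peak.  The signal-to-noise ratio compares Welch band power at
the peak frequency (+-1 Hz) to the rest of the spectrum with the 2nd-5th
harmonics excluded from the noise estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectralSummary",
    "phase_synchrony",
    "snr",
    "dominant_frequency",
    "spectral_summary",
]

SNR_CAP_DB = 100.0


@dataclass
class SpectralSummary:
    """Per-node and network-average spectral metrics of the EEG-like signals."""

    omega: np.ndarray  # dominant frequency per node (Hz)
    snr_db: np.ndarray  # per node
    R_bar: float  # time-averaged Kuramoto order parameter, in [0, 1]
    snr_db_mean: float
    omega_mean: float


def _welch(x: np.ndarray, fs: float, seg_seconds: float = 20.0):
    """Welch PSD with 20 s segments and 50% overlap, shrinking for short signals."""
    nper = int(seg_seconds * fs)
    if x.shape[-1] < 2 * nper:
        nper = max(16, x.shape[-1] // 2)
        warnings.warn(
            "signal shorter than two Welch windows; shrinking segment length",
            stacklevel=3,
        )
    return sps.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2, axis=-1)


def _peak_frequencies(
    eeg: np.ndarray, fs: float, band: tuple[float, float] = (1.0, 30.0)
) -> np.ndarray:
    freqs, psd = _welch(eeg, fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("search band contains no Welch frequency bins")
    sub = psd[..., sel]
    if np.any(sub.max(axis=-1) <= 0):
        raise ValueError("flat signal: no spectral peak")
    return freqs[sel][np.argmax(sub, axis=-1)]


def dominant_frequency(
    eeg: np.ndarray, fs: float, search_band: tuple[float, float] = (1.0, 30.0)
) -> tuple[np.ndarray, float]:
    """Per-node argmax of the Welch PSD within ``search_band``; returns (per-node, mean)."""
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    omega = _peak_frequencies(eeg, fs, search_band)
    return omega, float(np.mean(omega))


def phase_synchrony(
    eeg: np.ndarray,
    fs: float,
    half_band: float = 3.0,
    edge_trim: float = 1.0,
    search_band: tuple[float, float] = (1.0, 30.0),
) -> float:
    """Time-averaged Kuramoto order parameter of the node phases.

    Each node is band-passed (3rd-order Bessel, zero-phase) around its own
    spectral peak +-``half_band`` Hz, its instantaneous phase extracted via
    the Hilbert analytic signal, and ``edge_trim`` seconds dropped from
    each end before averaging ``R(t) = |<e^{j phi}>_N|`` over time.
    Returns 1 for perfect in-phase synchrony, near 0 for asynchrony.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if eeg.shape[0] < 2:
        raise ValueError("phase synchrony needs at least 2 nodes")
    omega = _peak_frequencies(eeg, fs, search_band)

    phases = np.empty_like(eeg)
    x = eeg - eeg.mean(axis=1, keepdims=True)
    for i, w in enumerate(omega):
        lo = max(w - half_band, 0.1)
        hi = min(w + half_band, 0.99 * fs / 2)
        sos = sps.bessel(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
        xf = sps.sosfiltfilt(sos, x[i])
        phases[i] = np.angle(sps.hilbert(xf))

    trim = int(edge_trim * fs)
    if 2 * trim >= eeg.shape[1]:
        trim = 0
    ph = phases[:, trim : eeg.shape[1] - trim] if trim else phases
    r_t = np.abs(np.mean(np.exp(1j * ph), axis=0))
    return float(np.mean(r_t))


def snr(
    eeg: np.ndarray,
    fs: float,
    signal_half_width: float = 1.0,
    harmonics: tuple[int, ...] = (2, 3, 4, 5),
    search_band: tuple[float, float] = (1.0, 30.0),
) -> tuple[np.ndarray, float]:
    """Welch signal-to-noise ratio in dB, per node and network mean.

    Signal power is the PSD area within ``omega_i +- 1 Hz`` of each node's
    peak; noise power is the area of everything else with the 2nd-5th
    harmonic bands (each ``k omega_i +- 1 Hz``) excluded.  Amplitude
    rescaling leaves the ratio unchanged.  A vanishing noise floor returns
    a capped maximum with a warning.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    freqs, psd = _welch(eeg, fs)
    omega = _peak_frequencies(eeg, fs, search_band)

    out = np.empty(eeg.shape[0])
    for i, w in enumerate(omega):
        sig_band = np.abs(freqs - w) <= signal_half_width
        noise_band = ~sig_band
        for k in harmonics:
            noise_band &= np.abs(freqs - k * w) > signal_half_width
        p_sig = np.trapezoid(psd[i][sig_band], freqs[sig_band]) if sig_band.sum() > 1 else psd[i][sig_band].sum() * (freqs[1] - freqs[0])
        p_noise = np.trapezoid(psd[i][noise_band], freqs[noise_band])
        if p_noise <= np.finfo(float).tiny * 1e3:
            warnings.warn(f"noise power at numerical floor for node {i}; capping SNR", stacklevel=2)
            out[i] = SNR_CAP_DB
        else:
            out[i] = 10.0 * np.log10(p_sig / p_noise)
    return out, float(np.mean(out))


def spectral_summary(
    eeg: np.ndarray, fs: float, search_band: tuple[float, float] = (1.0, 30.0)
) -> SpectralSummary:
    """All EEG-timescale metrics in one pass."""
    omega, omega_mean = dominant_frequency(eeg, fs, search_band)
    snr_db, snr_mean = snr(eeg, fs, search_band=search_band)
    r_bar = phase_synchrony(eeg, fs, search_band=search_band)
    return SpectralSummary(
        omega=omega, snr_db=snr_db, R_bar=r_bar, snr_db_mean=snr_mean, omega_mean=omega_mean
    )
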