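"""Functional connectivity dynamics (FCD).

Sliding-window FC matrices (100 s windows, 2 s displacement by default;
negative correlations set to zero) are vectorized and compared pairwise
with the Clarkson angular distance ``lambda(x, y) = 1/2 || x/||x|| - y/||y|| ||``,
giving a window-by-window FCD matrix.  The variance of its upper triangle
beyond a ``tau`` = 100 s offset from the diagonal measures multistability;
the median of the entries exactly on the ``tau``-offset line is the typical
FCD speed ``d_typ``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hemodynamics import BoldSeries

__all__ = [
    "FCDMatrix",
    "windowed_fcs",
    "clarkson_distance",
    "fcd_matrix",
    "fcd_variance",
    "fcd_speed",
]


@dataclass
class FCDMatrix:
    """Window x window Clarkson distances between FC patterns."""

    values: np.ndarray
    start_times: np.ndarray  # s
    win_len: float
    step: float

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def windowed_fcs(
    bold, win_len: float = 100.0, step: float = 2.0, fs: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window FC stream.

    Returns ``(stream, start_times)`` where ``stream`` is
    (n_windows, n_edges): per window, the Pearson FC with negative entries
    clipped to zero, upper triangle vectorized in row-major (j > i) order.
    The window count is ``floor((T - win_len)/step) + 1``.
    """
    if isinstance(bold, BoldSeries):
        data, fs = bold.data, bold.fs
    else:
        data = np.atleast_2d(np.asarray(bold, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    n, T = data.shape
    win = int(round(win_len * fs))
    stp = int(round(step * fs))
    if win > T:
        raise ValueError(f"window of {win_len} s exceeds signal length {T / fs} s")
    if stp < 1:
        raise ValueError("step below one sample")
    starts = np.arange(0, T - win + 1, stp)
    iu = np.triu_indices(n, k=1)
    stream = np.empty((len(starts), len(iu[0])))
    for k, s0 in enumerate(starts):
        fc = np.corrcoef(data[:, s0 : s0 + win])
        stream[k] = np.clip(fc[iu], 0.0, None)
    return stream, starts / fs


def clarkson_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Clarkson angular distance: half the Euclidean distance of the unit vectors.

    Scale-invariant, in [0, 1]; for nonnegative vectors (clipped FC
    patterns) the attainable maximum is sqrt(2)/2 (orthogonality).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("Clarkson distance undefined for a zero vector")
    return float(0.5 * np.linalg.norm(u / nu - v / nv))


def fcd_matrix(
    stream: np.ndarray,
    start_times: np.ndarray | None = None,
    win_len: float = 100.0,
    step: float = 2.0,
) -> FCDMatrix:
    """All pairwise Clarkson distances between windowed FC vectors."""
    stream = np.atleast_2d(np.asarray(stream, dtype=float))
    m = stream.shape[0]
    if m < 2:
        raise ValueError("need at least 2 windows")
    norms = np.linalg.norm(stream, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"zero FC vector in window(s) {np.flatnonzero(norms == 0).tolist()}")
    from scipy.spatial.distance import pdist, squareform

    unit = stream / norms[:, None]
    vals = squareform(0.5 * pdist(unit, metric="euclidean"))
    if start_times is None:
        start_times = np.arange(m) * step
    return FCDMatrix(values=vals, start_times=np.asarray(start_times, float), win_len=win_len, step=step)


def _separations(fcd: FCDMatrix) -> np.ndarray:
    t = fcd.start_times
    return np.abs(t[:, None] - t[None, :])


def fcd_variance(fcd: FCDMatrix, tau: float = 100.0) -> float:
    """Variance of upper-triangle FCD entries at window separation >= tau.

    The near-diagonal band (overlapping windows) is excluded; the result
    is the multistability index: 0 for a frozen FC, large when distinct FC
    patterns recur.
    """
    sep = _separations(fcd)
    iu = np.triu_indices(fcd.n_windows, k=1)
    keep = sep[iu] >= tau - 1e-9
    if not keep.any():
        raise ValueError(f"no window pairs separated by >= {tau} s")
    return float(np.var(fcd.values[iu][keep]))


def fcd_speed(fcd: FCDMatrix, tau: float = 100.0) -> float:
    """Typical FCD speed d_typ: median distance at separation exactly tau.

    Collects the entries along the tau-offset subdiagonal (window pairs
    separated by exactly tau seconds) and returns their median; near 0 for
    stable FC patterns, near sqrt(2)/2 for continually reconfiguring ones.
    """
    sep = _separations(fcd)
    iu = np.triu_indices(fcd.n_windows, k=1)
    line = np.abs(sep[iu] - tau) < 1e-9
    if not line.any():
        raise ValueError(
            f"no window pairs separated by exactly {tau} s; "
            "tau must be a multiple of the window step"
        )
    return float(np.median(fcd.values[iu][line]))
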