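"""Static functional connectivity and surrogate-based thresholding.

Static FC is the matrix of pairwise Pearson correlations over the whole
BOLD-like recording.  Instead of absolute or proportional thresholds, each
edge is tested against a null built from Fourier-transform (FT) surrogates:
phase-randomized copies of each node's signal that preserve its power
spectrum exactly while destroying pairwise correlations.  A Gaussian null
is fitted per edge from the surrogate correlations; one-sided (right-tail)
p-values are corrected across edges with Benjamini-Hochberg FDR, and
non-surviving or negative edges are set to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hemodynamics import BoldSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FCMatrix",
    "SurrogateEnsemble",
    "static_fc",
    "ft_surrogate_signals",
    "ft_surrogates",
    "threshold_fc",
]


@dataclass
class FCMatrix:
    """Region x region Pearson correlation matrix.

    Raw matrices are symmetric with unit diagonal; thresholded matrices
    retain only significant positive weights (zeros elsewhere, zero
    diagonal) plus the surviving-edge mask.
    """

    values: np.ndarray
    thresholded: bool = False
    mask: np.ndarray | None = None
    p_raw: np.ndarray | None = None
    p_fdr: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SurrogateEnsemble:
    """Per-edge Gaussian null (mean, sd) fitted to surrogate correlations.

    ``samples`` optionally keeps the raw surrogate correlations
    (n_surrogates, n, n) for empirical-quantile validation.
    """

    mean: np.ndarray
    std: np.ndarray
    n_surrogates: int
    seed: int | None
    samples: np.ndarray | None = None


def _as_data(bold) -> np.ndarray:
    data = bold.data if isinstance(bold, BoldSeries) else np.asarray(bold, dtype=float)
    data = np.atleast_2d(data)
    if data.shape[0] < 2 or data.shape[1] < 3:
        raise ValueError("need at least 2 nodes and 3 time points")
    return data


def static_fc(bold) -> FCMatrix:
    """Pearson correlations of the entire BOLD-like time series."""
    data = _as_data(bold)
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance node(s): {bad.tolist()}")
    fc = np.corrcoef(data)
    np.fill_diagonal(fc, 1.0)
    return FCMatrix(values=fc, thresholded=False)


def ft_surrogate_signals(bold, n: int = 1, seed: int | None = None):
    """Yield ``n`` FT surrogates: per-node independent phase randomization.

    Each surrogate preserves every node's amplitude spectrum exactly (DC
    and Nyquist bins are kept real) while scrambling all cross-signal
    relationships.
    """
    data = _as_data(bold)
    nn, T = data.shape
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(data, axis=1)
    nf = spec.shape[1]
    lo, hi = 1, nf - 1 if T % 2 == 0 else nf
    for _ in range(n):
        phases = rng.uniform(0.0, 2.0 * np.pi, (nn, hi - lo))
        s = spec.copy()
        s[:, lo:hi] = spec[:, lo:hi] * np.exp(1j * phases)
        yield np.fft.irfft(s, n=T, axis=1)


def ft_surrogates(
    bold, n: int = 500, seed: int | None = None, keep_samples: bool = False
) -> SurrogateEnsemble:
    """Fit a per-edge Gaussian null from FT (phase-randomization) surrogates.

    Each surrogate randomizes the Fourier phases of every node
    independently (DC and Nyquist bins kept real), leaving each node's
    periodogram identical to the original.  Correlation matrices of the
    ``n`` surrogates give the null mean and standard deviation per edge.
    """
    if n < 2:
        raise ValueError("need at least 2 surrogates")
    data = _as_data(bold)
    nn = data.shape[0]

    acc = np.zeros((nn, nn))
    acc2 = np.zeros((nn, nn))
    kept = np.empty((n, nn, nn)) if keep_samples else None
    for k, surr in enumerate(ft_surrogate_signals(data, n=n, seed=seed)):
        r = np.corrcoef(surr)
        acc += r
        acc2 += r * r
        if kept is not None:
            kept[k] = r
    mean = acc / n
    var = np.maximum(acc2 / n - mean**2, 0.0) * n / (n - 1)
    return SurrogateEnsemble(
        mean=mean, std=np.sqrt(var), n_surrogates=n, seed=seed, samples=kept
    )


def threshold_fc(
    fc: FCMatrix,
    ens: SurrogateEnsemble,
    p: float = 0.05,
    correction: str = "bh_fdr",
    null: str = "gaussian",
) -> FCMatrix:
    """Keep edges whose correlation beats the surrogate null (right tail).

    One-sided p-values from the per-edge Gaussian null (or the empirical
    surrogate quantiles with ``null="empirical"``, for validation; the
    ensemble must then carry samples), corrected across the (n^2 - n)/2
    edges by Benjamini-Hochberg FDR (``correction="none"`` for
    uncorrected tests).  Surviving edges keep their positive correlation
    weight; everything else, including negative correlations, is zeroed.
    """
    if correction not in ("bh_fdr", "none"):
        raise ValueError("correction must be 'bh_fdr' or 'none'")
    if null not in ("gaussian", "empirical"):
        raise ValueError("null must be 'gaussian' or 'empirical'")
    n = fc.n
    if ens.mean.shape != (n, n):
        raise ValueError("surrogate ensemble does not match FC dimensions")
    iu = np.triu_indices(n, k=1)
    r = fc.values[iu]

    if null == "empirical":
        if ens.samples is None:
            raise ValueError("empirical null requires ft_surrogates(keep_samples=True)")
        exceed = (ens.samples[:, iu[0], iu[1]] >= r[None, :]).sum(axis=0)
        pvals = (1.0 + exceed) / (ens.n_surrogates + 1.0)
    else:
        mu = ens.mean[iu]
        sd = ens.std[iu]
        pvals = np.empty_like(r)
        ok = sd > 0
        pvals[ok] = stats.norm.sf((r[ok] - mu[ok]) / sd[ok])
        if np.any(~ok):
            logger.info(
                "%d edge(s) with degenerate (zero-sd) null; using point null", (~ok).sum()
            )
            pvals[~ok] = np.where(r[~ok] > mu[~ok], 0.0, 1.0)

    if correction == "bh_fdr":
        reject, p_adj, _, _ = multipletests(pvals, alpha=p, method="fdr_bh")
    else:
        reject, p_adj = pvals < p, pvals

    keep = reject & (r > 0)
    out = np.zeros((n, n))
    out[iu] = np.where(keep, r, 0.0)
    out = out + out.T

    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = keep
    mask = mask | mask.T
    praw = np.zeros((n, n))
    praw[iu] = pvals
    praw = praw + praw.T
    padj = np.zeros((n, n))
    padj[iu] = p_adj
    padj = padj + padj.T
    return FCMatrix(values=out, thresholded=True, mask=mask, p_raw=praw, p_fdr=padj)
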