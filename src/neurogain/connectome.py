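"""Structural connectivity: loading, validation, normalization, synthesis.

The coupling substrate of the network model is a weighted, undirected,
zero-diagonal region-by-region matrix ``M`` with entries in [0, 1] (e.g. a
90-region AAL human connectome).  Before simulation each row is divided by
the node's in-strength so that the long-range input to every column is a
convex combination of the other columns' outputs -- a local homeostatic
normalization that equalizes excitatory input while preserving topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StructuralConnectome",
    "load_connectome",
    "normalize_in_strength",
    "generate_synthetic_connectome",
]


class ConnectomeError(ValueError):
    """Raised when a matrix fails structural-connectome validation."""


@dataclass
class StructuralConnectome:
    """Weighted undirected structural connectivity matrix.

    Parameters
    ----------
    weights
        Region-by-region nonnegative coupling matrix, zero diagonal.
        Raw (unnormalized) matrices are symmetric with entries in [0, 1];
        in-strength normalization rescales rows (breaking symmetry of the
        values but not of the zero pattern).
    labels
        Region identifiers, one per row.
    normalized
        True if rows have been divided by their in-strength.
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ConnectomeError(
                f"connectome matrix must be square, got shape {self.weights.shape}"
            )
        if not self.labels:
            self.labels = [f"region_{i}" for i in range(self.n)]
        if len(self.labels) != self.n:
            raise ConnectomeError(
                f"{len(self.labels)} labels for {self.n} regions"
            )
        self._validate()

    @property
    def n(self) -> int:
        """Number of regions."""
        return self.weights.shape[0]

    def _validate(self) -> None:
        w = self.weights
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("connectome contains non-finite entries")
        if np.any(w < 0):
            raise ConnectomeError("connectome contains negative weights")
        if np.any(np.diag(w) != 0):
            raise ConnectomeError("connectome diagonal must be zero")
        if not self.normalized:
            if np.any(w > 1):
                raise ConnectomeError("raw connectome weights must lie in [0, 1]")
            if not np.allclose(w, w.T):
                raise ConnectomeError("raw connectome must be symmetric")


def load_connectome(
    path: str | Path,
    format: str | None = None,
    labels_path: str | Path | None = None,
) -> StructuralConnectome:
    """Load a raw structural connectome from a dense matrix file.

    Supported formats: ``csv``, ``tsv`` (optional single header row,
    autodetected) and ``npy``.  The matrix must be square, symmetric,
    nonnegative with zero diagonal; a sidecar text file with one region
    label per line may be supplied.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".npy": "npy"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "npy":
        w = np.load(path)
    else:
        delim = "\t" if format == "tsv" else ","
        try:
            w = np.loadtxt(path, delimiter=delim)
        except ValueError:
            # first row is probably a header of region names
            w = np.loadtxt(path, delimiter=delim, skiprows=1)
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"matrix in {path} is not square: {w.shape}")

    labels: list[str] = []
    if labels_path is not None:
        labels = Path(labels_path).read_text().split()
    return StructuralConnectome(weights=w, labels=labels, normalized=False)


def normalize_in_strength(sc: StructuralConnectome) -> StructuralConnectome:
    """Divide each row by the node's in-strength so rows sum to one.

    The normalized coupling is ``M~_ij = M_ij / sum_{j != i} M_ij``; the
    zero pattern is preserved exactly.  Rows with zero in-strength
    (isolated nodes) are left all-zero and logged.  Already-normalized
    input is returned unchanged (the operation is idempotent).
    """
    if sc.normalized:
        return sc
    w = sc.weights
    strength = w.sum(axis=1)
    if np.all(strength == 0):
        raise ConnectomeError("all-zero connectome: no coupling possible")
    isolated = strength == 0
    if np.any(isolated):
        logger.warning(
            "%d isolated node(s) left with zero coupling row: %s",
            isolated.sum(),
            [sc.labels[i] for i in np.flatnonzero(isolated)],
        )
    norm = np.where(isolated, 1.0, strength)
    return replace(sc, weights=w / norm[:, None], normalized=True)


def _planted_partition(n: int, n_modules: int) -> np.ndarray:
    """Assign n nodes to n_modules contiguous, near-equal blocks."""
    sizes = np.full(n_modules, n // n_modules)
    sizes[: n % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def generate_synthetic_connectome(
    n: int = 90,
    n_modules: int = 4,
    p_intra: float = 0.6,
    p_inter: float = 0.05,
    weight_dist: str = "uniform",
    seed: int | None = None,
    max_retries: int = 50,
) -> StructuralConnectome:
    """Generate a modular weighted connectome as a stand-in for empirical data.

    Edges are drawn independently with probability ``p_intra`` inside the
    planted modules and ``p_inter`` between them; weights come from
    ``uniform`` ([0.3, 1]) or ``lognormal`` (rescaled to max 1)
    distributions.  The graph is redrawn (and finally bridged) until it has
    a single connected component.  Seed-deterministic.
    """
    if n < 2:
        raise ConnectomeError("need at least 2 nodes")
    if not (0 <= p_inter <= p_intra <= 1):
        raise ConnectomeError("require 0 <= p_inter <= p_intra <= 1")
    if weight_dist not in ("uniform", "lognormal"):
        raise ConnectomeError(f"unknown weight_dist {weight_dist!r}")

    rng = np.random.default_rng(seed)
    modules = _planted_partition(n, n_modules)

    for attempt in range(max_retries):
        same = modules[:, None] == modules[None, :]
        p = np.where(same, p_intra, p_inter)
        mask = np.triu(rng.random((n, n)) < p, k=1)
        if weight_dist == "uniform":
            w = rng.uniform(0.3, 1.0, (n, n))
        else:
            w = rng.lognormal(mean=-1.0, sigma=0.8, size=(n, n))
            w = np.clip(w / w.max(), 1e-6, 1.0)
        adj = np.where(mask, w, 0.0)
        adj = adj + adj.T

        g = nx.from_numpy_array(adj)
        comps = list(nx.connected_components(g))
        if len(comps) == 1:
            sc = StructuralConnectome(weights=adj, normalized=False)
            sc.planted_modules = modules  # type: ignore[attr-defined]
            return sc
        if attempt == max_retries - 2:
            # final attempt: bridge components with single random edges
            comps = [sorted(c) for c in comps]
            for a, b in zip(comps[:-1], comps[1:]):
                i = int(rng.choice(a))
                j = int(rng.choice(b))
                adj[i, j] = adj[j, i] = rng.uniform(0.3, 1.0)
            if nx.is_connected(nx.from_numpy_array(adj)):
                sc = StructuralConnectome(weights=adj, normalized=False)
                sc.planted_modules = modules  # type: ignore[attr-defined]
                return sc
    raise ConnectomeError(
        f"could not generate a connected graph after {max_retries} attempts "
        f"(n={n}, p_intra={p_intra}, p_inter={p_inter})"
    )
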