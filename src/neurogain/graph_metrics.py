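"""Weighted integration/segregation metrics on thresholded FC graphs.

Integration: global efficiency (mean inverse shortest path length on
lengths 1/weight) and the participation coefficient (spread of node
strength across modules).  Segregation: weighted transitivity (collectively
normalized triangle density with geometric-mean triangle intensities) and
Newman modularity, maximized by Louvain with a consensus-clustering wrapper
(repeat Louvain, build the pairwise agreement matrix, threshold it and
iterate until every run returns the same partition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .functional_connectivity import FCMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModulePartition",
    "GraphSummary",
    "global_efficiency",
    "transitivity",
    "consensus_partition",
    "modularity",
    "participation",
    "graph_summary",
]


@dataclass
class ModulePartition:
    """Node-to-module assignment with contiguous integer labels."""

    labels: np.ndarray
    agreement: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        # relabel to contiguous 0..k-1 preserving first-appearance order
        _, self.labels = np.unique(self.labels, return_inverse=True)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class GraphSummary:
    """Scalar integration/segregation summary of one functional graph."""

    E_w: float
    Q_w: float
    T_w: float
    PC_w_mean: float
    n_modules: int


def _weights(fc) -> np.ndarray:
    w = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    w = np.array(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    np.fill_diagonal(w, 0.0)
    return w


def global_efficiency(fc) -> float:
    """Mean inverse shortest path length; disconnected pairs contribute 0.

    Edge lengths are 1/weight, the convention of correlation-weighted
    brain graphs (stronger edges are shorter).
    """
    w = _weights(fc)
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    np.fill_diagonal(d, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def transitivity(fc) -> float:
    """Weighted transitivity: 2 sum_i t_i / sum_i k_i (k_i - 1).

    ``t_i`` is half the sum over neighbor pairs of the geometric mean of
    the three triangle weights; ``k_i`` is the binary degree.  Returns 0
    (logged) when no node has two neighbors.
    """
    w = _weights(fc)
    k = (w > 0).sum(axis=1)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        logger.info("transitivity undefined (no connected triples); returning 0")
        return 0.0
    w3 = np.cbrt(w)
    t = np.diagonal(w3 @ w3 @ w3) / 2.0  # 2 t_i = (W^(1/3))^3_ii
    return float(2.0 * t.sum() / denom)


def modularity(fc, part: ModulePartition) -> float:
    """Newman weighted modularity of a given partition.

    ``Q = (1/l) sum_ij [w_ij - k_i k_j / l] delta(m_i, m_j)`` with ``l``
    the total weight counting both orientations and ``k`` the node
    strengths.  An empty graph returns 0 with a warning.
    """
    w = _weights(fc)
    if part.labels.shape[0] != w.shape[0]:
        raise ValueError("partition does not cover all nodes")
    l_w = w.sum()
    if l_w == 0:
        logger.warning("modularity of an empty graph; returning 0")
        return 0.0
    k = w.sum(axis=1)
    same = part.labels[:, None] == part.labels[None, :]
    return float(((w - np.outer(k, k) / l_w) * same).sum() / l_w)


def participation(fc, part: ModulePartition) -> tuple[np.ndarray, float]:
    """Weighted participation coefficient per node and its mean.

    ``PC_i = 1 - sum_m (k_i(m)/k_i)^2``; isolated nodes get 0 and are
    included in the mean.
    """
    w = _weights(fc)
    labels = part.labels
    if labels.shape[0] != w.shape[0]:
        raise ValueError("partition does not cover all nodes")
    k = w.sum(axis=1)
    n_mod = part.n_modules
    km = np.zeros((w.shape[0], n_mod))
    for m in range(n_mod):
        km[:, m] = w[:, labels == m].sum(axis=1)
    pc = np.zeros(w.shape[0])
    nz = k > 0
    pc[nz] = 1.0 - ((km[nz] / k[nz, None]) ** 2).sum(axis=1)
    return pc, float(pc.mean())


def _louvain_once(g: nx.Graph, resolution: float, seed: int) -> np.ndarray:
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for m, nodes in enumerate(comms):
        for i in nodes:
            labels[i] = m
    return labels


def _canonical(labels: np.ndarray) -> tuple:
    """Relabel modules by first appearance so label permutations compare equal."""
    seen: dict[int, int] = {}
    return tuple(seen.setdefault(int(l), len(seen)) for l in labels)


def _agreement(partitions: list[np.ndarray]) -> np.ndarray:
    n = partitions[0].shape[0]
    g = np.zeros((n, n))
    for lab in partitions:
        g += lab[:, None] == lab[None, :]
    g /= len(partitions)
    np.fill_diagonal(g, 0.0)
    return g


def consensus_partition(
    fc,
    runs: int = 200,
    resolution: float = 1.0,
    agree_threshold: float = 0.5,
    seed: int | None = None,
    max_iter: int = 50,
) -> ModulePartition:
    """Consensus clustering over repeated Louvain runs.

    Louvain (randomized tie-breaking under ``seed``) is run ``runs`` times;
    if the partitions disagree, the pairwise agreement matrix is
    thresholded at ``agree_threshold`` and Louvain is re-run on it,
    iterating until all runs coincide.  Seed-deterministic; raises after
    ``max_iter`` consensus rounds without convergence.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    w = _weights(fc)
    rng = np.random.default_rng(seed)

    current = w
    agreement = None
    for _ in range(max_iter):
        g = nx.from_numpy_array(current)
        parts = [
            _louvain_once(g, resolution, int(rng.integers(0, 2**31 - 1)))
            for _ in range(runs)
        ]
        canon = {_canonical(p) for p in parts}
        if len(canon) == 1:
            return ModulePartition(labels=parts[0], agreement=agreement)
        agreement = _agreement(parts)
        current = np.where(agreement >= agree_threshold, agreement, 0.0)
    raise RuntimeError(
        f"consensus clustering did not converge in {max_iter} rounds "
        f"(n={w.shape[0]}, runs={runs})"
    )


def graph_summary(
    fc,
    runs: int = 200,
    resolution: float = 1.0,
    seed: int | None = None,
) -> GraphSummary:
    """Compute E_w, Q_w, T_w and mean PC_w for a thresholded FC graph."""
    part = consensus_partition(fc, runs=runs, resolution=resolution, seed=seed)
    _, pc_mean = participation(fc, part)
    return GraphSummary(
        E_w=global_efficiency(fc),
        Q_w=modularity(fc, part),
        T_w=transitivity(fc),
        PC_w_mean=pc_mean,
        n_modules=part.n_modules,
    )
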