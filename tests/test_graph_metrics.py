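"""Graph-metric checks against exhaustive brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest

from neurogain.graph_metrics import (
    ModulePartition,
    consensus_partition,
    global_efficiency,
    graph_summary,
    modularity,
    participation,
    transitivity,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)
# ---------------------------------------------------------------------------


def efficiency_oracle(w):
    """Floyd-Warshall on 1/weight lengths with explicit loops."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1)) if n > 1 else 0.0


def transitivity_oracle(w):
    """Exhaustive sum over ordered triples."""
    n = w.shape[0]
    num = 0.0
    for i in range(n):
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) == 3:
                    num += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
    den = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        den += k * (k - 1)
    return num / den if den > 0 else 0.0


def modularity_oracle(w, labels):
    l_w = w.sum()
    if l_w == 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / l_w
    return q / l_w


def participation_oracle(w, labels):
    n = w.shape[0]
    pcs = np.zeros(n)
    for i in range(n):
        k = w[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for m in set(labels):
            km = sum(w[i, j] for j in range(n) if labels[j] == m)
            acc += (km / k) ** 2
        pcs[i] = 1.0 - acc
    return pcs


def all_partitions(n):
    """Every set partition of range(n) as a label array (Bell-number many)."""
    if n == 1:
        yield [0]
        return
    for rest in all_partitions(n - 1):
        k = max(rest) + 1
        for m in range(k + 1):
            yield rest + [m]


def random_graph(rng, n, density=0.6):
    w = np.triu((rng.random((n, n)) < density) * rng.uniform(0.05, 1.0, (n, n)), k=1)
    w = w + w.T
    return w


# ---------------------------------------------------------------------------
# analytic special cases
# ---------------------------------------------------------------------------


class TestSpecialCases:
    def test_complete_unit_graph_efficiency_one(self):
        w = 1.0 - np.eye(5)
        assert global_efficiency(w) == pytest.approx(1.0)

    def test_empty_graph_efficiency_zero(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_path_graph_efficiency(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert global_efficiency(w) == pytest.approx(5.0 / 6.0)

    def test_triangle_transitivity_one(self):
        w = 1.0 - np.eye(3)
        assert transitivity(w) == pytest.approx(1.0)

    def test_star_transitivity_zero(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        assert transitivity(w) == 0.0

    def test_weighted_triangle_geometric_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.125
        assert transitivity(w) == pytest.approx(transitivity_oracle(w), abs=1e-12)
        assert transitivity(w) == pytest.approx(0.5)  # cbrt(0.125) = 0.5 per triangle

    def test_two_dyads_modularity_half(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        part = ModulePartition(np.array([0, 0, 1, 1]))
        assert modularity(w, part) == pytest.approx(0.5)

    def test_single_edge_hand_value(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        part = ModulePartition(np.array([0, 0]))
        # Eq by hand: l=2, within terms (1 - 1/2)*2 off-diag + (0 - 1/2)*2 diag = 0
        assert modularity(w, part) == pytest.approx(0.0, abs=1e-12)

    def test_participation_own_module_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        pc, _ = participation(w, ModulePartition(np.array([0, 0, 1])))
        assert pc[0] == 0.0

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_participation_equal_split_closed_form(self, m):
        """A hub spread equally over m modules has PC = 1 - 1/m."""
        n = m + 1
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        labels = np.concatenate([[0], np.arange(m)])
        pc, _ = participation(w, ModulePartition(labels))
        assert pc[0] == pytest.approx(1.0 - 1.0 / m)


# ---------------------------------------------------------------------------
# randomized oracle equivalence
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_random_graphs_match_oracles(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(8):
            w = random_graph(rng, n)
            labels = rng.integers(0, max(2, n // 2), n)
            part = ModulePartition(labels)
            assert global_efficiency(w) == pytest.approx(efficiency_oracle(w), abs=1e-9)
            assert transitivity(w) == pytest.approx(transitivity_oracle(w), abs=1e-9)
            assert modularity(w, part) == pytest.approx(modularity_oracle(w, part.labels), abs=1e-9)
            np.testing.assert_allclose(
                participation(w, part)[0], participation_oracle(w, part.labels), atol=1e-9
            )

    def test_louvain_bounded_by_exhaustive_optimum(self):
        """On small graphs the consensus Q never exceeds the exhaustive best."""
        rng = np.random.default_rng(7)
        for n in (5, 6, 7):
            w = random_graph(rng, n, density=0.5)
            if not w.any():
                continue
            best = max(
                modularity_oracle(w, labels) for labels in all_partitions(n)
            )
            part = consensus_partition(w, runs=40, seed=1)
            assert modularity(w, part) <= best + 1e-9

    def test_consensus_finds_exhaustive_optimum_on_planted_graph(self):
        w = np.full((8, 8), 0.05)
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        best = max(modularity_oracle(w, labels) for labels in all_partitions(8))
        part = consensus_partition(w, runs=40, seed=3)
        assert modularity(w, part) == pytest.approx(best, abs=1e-9)


# ---------------------------------------------------------------------------
# consensus clustering behaviour
# ---------------------------------------------------------------------------


class TestConsensus:
    def test_two_cliques_recovered(self):
        w = np.zeros((8, 8))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        part = consensus_partition(w, runs=20, seed=0)
        assert part.n_modules == 2
        assert len(set(part.labels[:4])) == 1
        assert len(set(part.labels[4:])) == 1

    def test_planted_weighted_modules_recovered(self):
        rng = np.random.default_rng(2)
        n = 12
        w = np.full((n, n), 0.05)
        w[:6, :6] = rng.uniform(0.8, 1.0, (6, 6))
        w[6:, 6:] = rng.uniform(0.8, 1.0, (6, 6))
        w = np.triu(w, 1)
        w = w + w.T
        part = consensus_partition(w, runs=50, seed=5)
        planted = np.array([0] * 6 + [1] * 6)
        # agreement up to relabeling
        assert len(set(zip(part.labels, planted))) == 2

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        w = random_graph(rng, 10, density=0.4)
        a = consensus_partition(w, runs=30, seed=42)
        b = consensus_partition(w, runs=30, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_unambiguous_structure_converges_first_round(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0.0)
        part = consensus_partition(w, runs=10, seed=0)
        assert part.agreement is None  # no consensus round was needed


class TestInvariances:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        w = random_graph(rng, 8)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        assert global_efficiency(w) == pytest.approx(global_efficiency(wp), abs=1e-12)
        assert transitivity(w) == pytest.approx(transitivity(wp), abs=1e-12)

    def test_efficiency_monotone_in_edge_weight(self):
        rng = np.random.default_rng(10)
        w = random_graph(rng, 6)
        i, j = 0, 1
        base = global_efficiency(w)
        w2 = w.copy()
        w2[i, j] = w2[j, i] = min(1.0, max(w[i, j] + 0.3, 0.3))
        assert global_efficiency(w2) >= base - 1e-12

    def test_negative_weights_rejected(self):
        w = np.array([[0.0, -0.2], [-0.2, 0.0]])
        with pytest.raises(ValueError):
            global_efficiency(w)


def test_graph_summary_bundles_metrics():
    w = np.zeros((8, 8))
    w[:4, :4] = 0.9
    w[4:, 4:] = 0.9
    np.fill_diagonal(w, 0.0)
    gs = graph_summary(w, runs=20, seed=0)
    assert 0.0 <= gs.E_w <= 1.0
    assert gs.Q_w == pytest.approx(0.5, abs=1e-9)
    assert gs.n_modules == 2
    assert 0.0 <= gs.PC_w_mean < 1.0
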