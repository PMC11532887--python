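import math

import numpy as np
import pytest

from symnet import (
    CommunityPartition,
    IsingSimulationSpec,
    PlantedStructure,
    compare_partitions,
    compute_centrality,
    core_symptom_cluster,
    estimate_ising,
    make_planted_network,
    modularity,
    simulate_ising,
    walktrap,
)

from conftest import catalog, network_from_weights


def two_cliques(bridge=0.0):
    w = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i < j:
                    w[i, j] = w[j, i] = 1.0
    if bridge:
        w[2, 3] = w[3, 2] = bridge
    return network_from_weights(w)


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1:]
        yield [[first]] + smaller


def naive_modularity(weights, labels):
    """Double-loop modularity on absolute weights; independent oracle."""
    a = np.abs(weights)
    m = a.sum() / 2.0
    if m == 0:
        return 0.0
    s = a.sum(axis=1)
    q = 0.0
    p = len(labels)
    for i in range(p):
        for j in range(p):
            if labels[i] == labels[j]:
                q += a[i, j] - s[i] * s[j] / (2 * m)
    return q / (2 * m)


def max_modularity_exhaustive(weights):
    p = weights.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(p))):
        labels = np.empty(p, dtype=int)
        for k, block in enumerate(part):
            labels[list(block)] = k
        best = max(best, naive_modularity(weights, labels))
    return best


def random_two_block_graphs(rng, count, p_lo=5, p_hi=9):
    """Weighted graphs with a planted two-block structure."""
    out = []
    for _ in range(count):
        p = int(rng.integers(p_lo, p_hi))
        split = p // 2
        w = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                same = (i < split) == (j < split)
                if same and rng.random() < 0.9:
                    w[i, j] = w[j, i] = rng.uniform(0.8, 1.5)
                elif not same and rng.random() < 0.25:
                    w[i, j] = w[j, i] = rng.uniform(0.1, 0.5)
        if np.abs(w).sum() > 0:
            out.append(w)
    return out


def ari_closed_form(la, lb):
    """Adjusted Rand index from the contingency table, direct formula."""
    from collections import Counter

    n = len(la)
    cont = Counter(zip(la, lb))
    a = Counter(la)
    b = Counter(lb)
    c2 = lambda x: x * (x - 1) / 2
    sum_ij = sum(c2(v) for v in cont.values())
    sum_a = sum(c2(v) for v in a.values())
    sum_b = sum(c2(v) for v in b.values())
    expected = sum_a * sum_b / c2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return (sum_ij - expected) / (max_index - expected)


class TestWalktrap:
    def test_bridged_cliques_split(self):
        part = walktrap(two_cliques(bridge=0.1))
        labels = [part.assignment[f"S{i + 1}"] for i in range(6)]
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]
        # and the chosen cut attains the exhaustive-search optimum
        net = two_cliques(bridge=0.1)
        assert part.modularity == pytest.approx(
            max_modularity_exhaustive(net.weights), abs=1e-9
        )

    def test_disconnected_cliques(self):
        part = walktrap(two_cliques(bridge=0.0))
        assert part.n_clusters == 2
        assert part.modularity == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        w = np.ones((5, 5)) - np.eye(5)
        part = walktrap(network_from_weights(w))
        assert part.n_clusters == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_isolated_nodes_singletons(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        part = walktrap(network_from_weights(w))
        assert part.assignment["S1"] == part.assignment["S2"]
        assert part.assignment["S3"] != part.assignment["S4"]

    def test_near_optimal_on_random_graphs(self, rng):
        # random two-block graphs; on unstructured dense graphs no greedy
        # agglomeration (including the reference implementation) attains a
        # uniform 0.9 gap bound
        for w in random_two_block_graphs(rng, 10):
            part = walktrap(network_from_weights(w))
            assert part.modularity >= 0.9 * max_modularity_exhaustive(w) - 1e-9

    def test_not_worse_than_igraph_reference(self, rng):
        igraph = pytest.importorskip("igraph")
        for w in random_two_block_graphs(rng, 8):
            part = walktrap(network_from_weights(w))
            g = igraph.Graph.Weighted_Adjacency(
                w.tolist(), mode="undirected", attr="weight"
            )
            cl = g.community_walktrap(weights="weight", steps=4).as_clustering()
            q_ref = g.modularity(cl.membership, weights="weight")
            assert part.modularity >= q_ref - 1e-9

    def test_permutation_equivariance(self, rng):
        net = two_cliques(bridge=0.2)
        part = walktrap(net)
        perm = rng.permutation(6)
        net_p = network_from_weights(net.weights[np.ix_(perm, perm)])
        part_p = walktrap(net_p)
        # same grouping of original nodes under the relabeling
        for i in range(6):
            for j in range(6):
                same = part.assignment[f"S{perm[i] + 1}"] == part.assignment[f"S{perm[j] + 1}"]
                same_p = part_p.assignment[f"S{i + 1}"] == part_p.assignment[f"S{j + 1}"]
                assert same == same_p

    def test_pipeline_community_recovery(self):
        hits = 0
        for seed in range(3):
            ps = PlantedStructure(
                assignment=(0,) * 5 + (1,) * 5, within_range=(1.0, 1.5)
            )
            truth = make_planted_network(10, ps, seed=300 + seed, thresholds=-2.5)
            data = simulate_ising(
                IsingSimulationSpec(
                    truth.thresholds, truth.weights, n_cases=3000, seed=400 + seed
                )
            )
            est = estimate_ising(data, n_lambda=50)
            part = walktrap(est)
            la = [part.assignment[c] for c in est.catalog.codes]
            hits += ari_closed_form(la, list(ps.assignment)) >= 0.8
        assert hits == 3


class TestModularity:
    def test_single_cluster_zero(self, rng):
        w = np.zeros((5, 5))
        for i in range(5):
            for j in range(i + 1, 5):
                if rng.random() < 0.6:
                    w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
        net = network_from_weights(w)
        assignment = {c: 1 for c in net.catalog.codes}
        assert modularity(net, assignment) == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_half(self):
        net = two_cliques(bridge=0.0)
        assignment = {f"S{i + 1}": 1 if i < 3 else 2 for i in range(6)}
        assert modularity(net, assignment) == pytest.approx(0.5)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(10):
            p = int(rng.integers(4, 9))
            w = np.zeros((p, p))
            for i in range(p):
                for j in range(i + 1, p):
                    if rng.random() < 0.5:
                        w[i, j] = w[j, i] = rng.uniform(0.1, 2.0) * rng.choice([-1, 1])
            if np.abs(w).sum() == 0:
                continue
            net = network_from_weights(w)
            labels = rng.integers(1, 4, p)
            assignment = {f"S{i + 1}": int(labels[i]) for i in range(p)}
            # contiguity not required by modularity itself
            assert modularity(net, assignment) == pytest.approx(
                naive_modularity(w, labels), abs=1e-12
            )

    def test_empty_network_warns(self):
        net = network_from_weights(np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="no edges"):
            assert modularity(net, {c: 1 for c in net.catalog.codes}) == 0.0


class TestCoreSymptomCluster:
    def test_core_cluster_contains_core_symptom(self):
        net = two_cliques(bridge=0.1)
        part = walktrap(net)
        cent = compute_centrality(net)
        cluster = core_symptom_cluster(part, cent)
        from symnet import core_symptom

        assert part.assignment[core_symptom(cent)] == cluster

    def test_singleton_core(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.2
        w[0, 3] = w[3, 0] = 0.2
        net = network_from_weights(w)
        # force a partition where the hub is alone
        part = CommunityPartition(
            assignment={"S1": 1, "S2": 2, "S3": 2, "S4": 2}, modularity=0.0
        )
        cent = compute_centrality(net)
        assert core_symptom_cluster(part, cent) == 1


class TestComparePartitions:
    def _part(self, labels):
        return CommunityPartition(
            assignment={f"S{i + 1}": l for i, l in enumerate(labels)}, modularity=0.0
        )

    def test_identical_partitions(self):
        a = self._part([1, 1, 2, 2, 3])
        tab, ari = compare_partitions(a, self._part([1, 1, 2, 2, 3]))
        assert ari == pytest.approx(1.0)

    def test_singletons_vs_lump(self):
        a = self._part([1, 2, 3, 4])
        b = self._part([1, 1, 1, 1])
        _, ari = compare_partitions(a, b)
        assert ari == pytest.approx(0.0)

    def test_matches_closed_form(self, rng):
        for _ in range(10):
            la = [int(x) for x in rng.integers(1, 4, 8)]
            lb = [int(x) for x in rng.integers(1, 4, 8)]
            la = list(np.unique(la, return_inverse=True)[1] + 1)
            lb = list(np.unique(lb, return_inverse=True)[1] + 1)
            _, ari = compare_partitions(self._part(la), self._part(lb))
            assert ari == pytest.approx(ari_closed_form(la, lb), abs=1e-12)

    def test_no_shared_nodes_errors(self):
        a = CommunityPartition(assignment={"A": 1}, modularity=0.0)
        b = CommunityPartition(assignment={"B": 1}, modularity=0.0)
        with pytest.raises(ValueError, match="share"):
            compare_partitions(a, b)

    def test_crosstab_counts(self):
        a = self._part([1, 1, 2, 2])
        b = self._part([1, 2, 2, 2])
        tab, _ = compare_partitions(a, b)
        assert tab.loc[1, 1] == 1 and tab.loc[1, 2] == 1 and tab.loc[2, 2] == 2
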