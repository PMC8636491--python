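from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from abdyn.correlation import GCCMatrix
from abdyn.network import (
    CommunityPartition, build_graph, community_repartition_difference,
    contact_persistence, girvan_newman_communities,
    shortest_path_betweenness,
)
from abdyn.synthetic import make_ca_topology, sample_contact_trajectory
from abdyn.trajectory_io import Trajectory


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent oracle: enumerate all simple paths per node pair, keep the
    minimum-weight ones, split the pair's unit among them."""
    bc = {tuple(sorted(e)): 0.0 for e in g.edges()}
    nodes = sorted(g.nodes())
    for s, t in combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        costs = [
            sum(g[u][v].get("weight", 1.0) for u, v in zip(p, p[1:]))
            for p in paths
        ]
        best = min(costs)
        winners = [
            p for p, c in zip(paths, costs) if np.isclose(c, best, rtol=1e-9)
        ]
        for p in winners:
            for u, v in zip(p, p[1:]):
                bc[tuple(sorted((u, v)))] += 1.0 / len(winners)
    return bc


class TestContactPersistence:
    def test_always_in_contact(self):
        traj, _ = sample_contact_trajectory(4, {(0, 2): 1.0}, 5, seed=0)
        pers = contact_persistence(traj, 0.45)
        assert pers[(0, 2)] == 1.0

    def test_half_time_below_threshold(self):
        traj, _ = sample_contact_trajectory(4, {(0, 2): 0.5}, 4, seed=0)
        pers = contact_persistence(traj, 0.45)
        assert pers[(0, 2)] == 0.5  # excluded later by the 0.75 criterion
        g = build_graph(pers, GCCMatrix(np.full((4, 4), 0.5)))
        assert not g.has_edge(0, 2)

    def test_sequence_neighbours_excluded(self):
        top = make_ca_topology(3)
        coords = np.zeros((2, 3, 3))
        coords[:, 1, 0] = 0.2  # residues 1-2 and 2-3 touch permanently
        coords[:, 2, 0] = 0.4
        traj = Trajectory(top, coords)
        pers = contact_persistence(traj, 0.45)
        assert (0, 1) not in pers and (1, 2) not in pers
        assert pers[(0, 2)] == 1.0  # |i-j| = 2 is allowed

    def test_no_heavy_atoms_error(self):
        from abdyn.trajectory_io import AtomRecord, Topology

        top = Topology([AtomRecord("H1", "H", 1, "GLY", "A")])
        traj = Trajectory(top, np.zeros((1, 1, 3)))
        with pytest.raises(ValueError, match="heavy"):
            contact_persistence(traj)


class TestBuildGraph:
    def _gcc(self, n, value):
        m = np.full((n, n), value, dtype=float)
        np.fill_diagonal(m, 1.0)
        return GCCMatrix(m)

    def test_weight_closed_forms(self):
        pers = {(0, 1): 1.0, (0, 2): 0.8}
        gcc = self._gcc(3, 0.5)
        gcc.values[0, 1] = gcc.values[1, 0] = 1.0
        gcc.values[0, 2] = gcc.values[2, 0] = np.exp(-1.0)
        g = build_graph(pers, gcc)
        assert g[0][1]["weight"] == pytest.approx(0.0)
        assert g[0][2]["weight"] == pytest.approx(1.0)

    def test_persistence_threshold_inclusive(self):
        pers = {(0, 1): 0.75, (0, 2): 0.74}
        g = build_graph(pers, self._gcc(3, 0.5))
        assert g.has_edge(0, 1)       # "at least 75%" keeps 0.75
        assert not g.has_edge(0, 2)   # 0.74 dropped

    def test_zero_gcc_edge_dropped_with_note(self):
        pers = {(0, 1): 1.0}
        gcc = self._gcc(2, 0.0)
        g = build_graph(pers, gcc)
        assert not g.has_edge(0, 1)
        assert (0, 1) in g.graph["dropped_zero_gcc"]


class TestBetweenness:
    def test_path_graph(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        bc = shortest_path_betweenness(g)
        assert bc[("A", "B")] == pytest.approx(2.0)
        assert bc[("B", "C")] == pytest.approx(2.0)

    def test_triangle(self):
        g = nx.Graph()
        for u, v in [(0, 1), (1, 2), (0, 2)]:
            g.add_edge(u, v, weight=1.0)
        bc = shortest_path_betweenness(g)
        assert all(v == pytest.approx(1.0) for v in bc.values())

    def test_square_tie_splitting(self):
        g = nx.Graph()
        for u, v in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            g.add_edge(u, v, weight=1.0)
        bc = shortest_path_betweenness(g)
        # adjacent pair: 1; each diagonal pair splits over two paths: +1/2
        assert all(v == pytest.approx(2.0) for v in bc.values())

    def test_disconnected_pairs_contribute_nothing(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        bc = shortest_path_betweenness(g)
        assert bc[(0, 1)] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        g = nx.gnp_random_graph(n, 0.5, seed=seed)
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
        mine = shortest_path_betweenness(g)
        oracle = brute_force_betweenness(g)
        for e in oracle:
            assert mine[e] == pytest.approx(oracle[e], abs=1e-9), (e, seed)

    def test_sum_identity_on_small_graph(self):
        # sum of edge betweenness = sum over connected pairs of the mean
        # number of edges on their shortest paths
        g = nx.Graph()
        for u, v in [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)]:
            g.add_edge(u, v, weight=1.0)
        bc = shortest_path_betweenness(g)
        oracle = brute_force_betweenness(g)
        assert sum(bc.values()) == pytest.approx(sum(oracle.values()), abs=1e-9)


def _two_clique_bridge():
    g = nx.Graph()
    blocks = ([0, 1, 2, 3], [4, 5, 6, 7])
    for block in blocks:
        for i, j in combinations(block, 2):
            g.add_edge(i, j, weight=-np.log(0.9), gcc=0.9, persistence=1.0)
    g.add_edge(0, 4, weight=-np.log(0.9), gcc=0.9, persistence=1.0)
    return g, blocks


class TestGirvanNewman:
    def test_two_cliques_split_at_bridge(self):
        g, blocks = _two_clique_bridge()
        bc = shortest_path_betweenness(g)
        assert max(bc, key=bc.get) == (0, 4)  # bridge carries all 16 cross pairs
        part = girvan_newman_communities(g)
        labels = {tuple(sorted(n for n in g if part.membership[n] == c))
                  for c in set(part.membership.values())}
        assert labels == {tuple(blocks[0]), tuple(blocks[1])}

    def test_single_clique_stays_whole(self):
        g = nx.Graph()
        for i, j in combinations(range(5), 2):
            g.add_edge(i, j, weight=0.1, gcc=0.9)
        part = girvan_newman_communities(g)
        assert len(set(part.membership.values())) == 1

    def test_edgeless_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        part = girvan_newman_communities(g)
        assert sorted(part.membership.values()) == [0, 1, 2, 3]

    def test_deterministic(self):
        g, _ = _two_clique_bridge()
        p1 = girvan_newman_communities(g)
        p2 = girvan_newman_communities(g)
        assert p1.membership == p2.membership


class TestCRD:
    def test_identical_partitions_zero(self):
        p = {0: 0, 1: 0, 2: 1}
        assert community_repartition_difference(p, dict(p)) == 0.0

    def test_three_node_example(self):
        # {AB}{C} vs {A}{BC}: pairs AB and BC disagree, AC agrees -> 2/3
        p1 = {"A": 0, "B": 0, "C": 1}
        p2 = {"A": 0, "B": 1, "C": 1}
        assert community_repartition_difference(p1, p2) == pytest.approx(2 / 3)

    def test_singletons_vs_monolith(self):
        m = 6
        p1 = {i: i for i in range(m)}
        p2 = {i: 0 for i in range(m)}
        assert community_repartition_difference(p1, p2) == 1.0

    def test_node_set_mismatch(self):
        with pytest.raises(ValueError):
            community_repartition_difference({0: 0}, {1: 0})

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        nodes = range(8)
        parts = [
            {n: int(rng.integers(0, 3)) for n in nodes} for _ in range(3)
        ]
        a, b, c = parts
        d = community_repartition_difference
        assert d(a, b) == d(b, a)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12
        assert 0.0 <= d(a, b) <= 1.0


def test_planted_two_block_network_recovery():
    """End-to-end: planted contacts + high in-block GCC recover the planted
    bipartition via Girvan-Newman."""
    n = 8
    blocks = ([0, 1, 2, 3], [4, 5, 6, 7])
    gcc = np.full((n, n), 0.1)
    pers = {}
    for block in blocks:
        for i, j in combinations(block, 2):
            pers[(i, j)] = 1.0
            gcc[i, j] = gcc[j, i] = 0.9
    pers[(0, 4)] = 1.0
    gcc[0, 4] = gcc[4, 0] = 0.9
    np.fill_diagonal(gcc, 1.0)
    g = build_graph(pers, GCCMatrix(gcc))
    part = girvan_newman_communities(g)
    found = {
        tuple(sorted(k for k in range(n) if part.membership[k] == c))
        for c in set(part.membership.values())
    }
    assert found == {tuple(blocks[0]), tuple(blocks[1])}
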