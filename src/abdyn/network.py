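"""Residue communication networks from contact persistence and correlation.

Nodes are residues (centered on C-alpha); two residues are connected if any
of their heavy atoms are within 0.45 nm in at least 75% of the analysed
frames.  Retained edges are weighted by the information-theoretic distance
w_ij = -log(GCC_ij), so strongly correlated residues are "close".

Edge betweenness is computed from all-pairs shortest paths (Floyd-Warshall
with path counting): each unordered node pair contributes one unit, split
equally among its equal-cost shortest paths.  Communities come from the
Girvan-Newman procedure — iterative removal of the highest-betweenness edge —
returning the partition along the removal sequence that maximizes weighted
modularity (with GCC as the affinity weight, since modularity expects
similarity, not distance).

Covalent sequence neighbours (|i - j| <= 1 within a chain) are excluded from
contacts: a peptide bond carries no communication signal of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .correlation import GCCMatrix
from .trajectory_io import Trajectory

DISTANCE_CUTOFF = 0.45  # nm, heavy-atom contact
PERSISTENCE_MIN = 0.75  # fraction of frames
_TIE_RTOL = 1e-9


@dataclass
class CommunityPartition:
    membership: dict  # node -> community id (contiguous from 0)
    modularity: float

    def as_labels(self, nodes: list) -> np.ndarray:
        return np.array([self.membership[n] for n in nodes], dtype=int)


def contact_persistence(
    traj: Trajectory,
    distance_cutoff: float = DISTANCE_CUTOFF,
    frames: np.ndarray | None = None,
    exclude_neighbours: int = 1,
) -> dict[tuple[int, int], float]:
    """Fraction of frames in which each residue pair is in heavy-atom contact.

    A pair is in contact in a frame iff the minimum distance between any
    heavy atoms of the two residues is <= the cutoff.  Pairs of sequence
    neighbours (|i - j| <= exclude_neighbours within one chain) are skipped.
    Returns only pairs with non-zero persistence, keyed by residue indices
    (0-based topology order, i < j).
    """
    top = traj.topology
    heavy = top.heavy_indices()
    if heavy.size == 0:
        raise ValueError("topology contains no heavy atoms")
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)

    res_of_heavy = top.atom_residue_indices()[heavy]
    n_res = top.n_residues
    counts = np.zeros((n_res, n_res), dtype=int)
    for f in frames:
        coords = traj.coords[f][heavy]
        close = cdist(coords, coords) <= distance_cutoff
        pair_contact = np.zeros((n_res, n_res), dtype=bool)
        ii, jj = np.nonzero(close)
        pair_contact[res_of_heavy[ii], res_of_heavy[jj]] = True
        counts += pair_contact

    out: dict[tuple[int, int], float] = {}
    keys = top.residues
    for i in range(n_res):
        for j in range(i + 1, n_res):
            ci, ni, _ = keys[i]
            cj, nj, _ = keys[j]
            if ci == cj and abs(ni - nj) <= exclude_neighbours:
                continue
            if counts[i, j]:
                out[(i, j)] = counts[i, j] / len(frames)
    return out


def build_graph(
    persistence: dict[tuple[int, int], float],
    gcc: GCCMatrix,
    persistence_min: float = PERSISTENCE_MIN,
    residue_keys: list | None = None,
) -> nx.Graph:
    """Persistence-filtered residue graph weighted by -log(GCC).

    Edges require persistence >= persistence_min (inclusive, "at least 75%").
    A retained pair with GCC = 0 has infinite distance and is dropped with a
    warning attribute; GCC = 1 gives weight 0.
    """
    g = nx.Graph()
    n_res = gcc.values.shape[0]
    for i in range(n_res):
        attrs = {}
        if residue_keys is not None:
            attrs = {"chain": residue_keys[i][0], "residue": residue_keys[i][1]}
        g.add_node(i, **attrs)
    dropped = []
    for (i, j), p in sorted(persistence.items()):
        if p < persistence_min:
            continue
        gij = float(gcc.values[i, j])
        if gij <= 0.0:
            dropped.append((i, j))
            continue
        g.add_edge(i, j, weight=float(-np.log(gij)), gcc=gij, persistence=float(p))
    g.graph["dropped_zero_gcc"] = dropped
    return g


def _floyd_warshall_counts(
    nodes: list, g: nx.Graph,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest path lengths (Floyd-Warshall) and path counts.

    Distances come from the Floyd-Warshall recursion; the number of distinct
    shortest paths is then counted exactly per source by dynamic programming
    over nodes in increasing distance order (correct for positive weights).
    """
    n = len(nodes)
    index = {v: k for k, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for u, v, data in g.edges(data=True):
        i, j = index[u], index[v]
        w = float(data.get("weight", 1.0))
        dist[i, j] = dist[j, i] = min(w, dist[i, j])
        adj[i].append((j, w))
        adj[j].append((i, w))
    for k in range(n):
        via = dist[:, k, None] + dist[None, k, :]
        np.minimum(dist, via, out=dist)

    cnt = np.zeros((n, n))
    for s in range(n):
        cnt[s, s] = 1.0
        order = np.argsort(dist[s], kind="stable")
        for u in order:
            if not np.isfinite(dist[s, u]) or cnt[s, u] == 0:
                continue
            for v, w in adj[u]:
                if np.isclose(dist[s, u] + w, dist[s, v],
                              rtol=_TIE_RTOL, atol=1e-12) and w > 0:
                    cnt[s, v] += cnt[s, u]
    return dist, cnt


def shortest_path_betweenness(g: nx.Graph) -> dict[tuple, float]:
    """Edge betweenness from all-pairs weighted shortest paths.

    Each unordered connected node pair contributes one unit, split equally
    among its equal-cost shortest paths; an edge's betweenness is the sum of
    the fractions of shortest paths that cross it.  Unreachable pairs
    contribute nothing.
    """
    nodes = sorted(g.nodes())
    index = {v: k for k, v in enumerate(nodes)}
    dist, cnt = _floyd_warshall_counts(nodes, g)
    n = len(nodes)
    bc = {tuple(sorted((u, v))): 0.0 for u, v in g.edges()}
    edges = [
        (index[u], index[v], float(d.get("weight", 1.0)), tuple(sorted((u, v))))
        for u, v, d in g.edges(data=True)
    ]
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or cnt[s, t] == 0:
                continue
            for iu, iv, w, key in edges:
                through = 0.0
                if np.isclose(dist[s, iu] + w + dist[iv, t], dist[s, t],
                              rtol=_TIE_RTOL, atol=1e-12):
                    through += cnt[s, iu] * cnt[iv, t]
                if np.isclose(dist[s, iv] + w + dist[iu, t], dist[s, t],
                              rtol=_TIE_RTOL, atol=1e-12):
                    through += cnt[s, iv] * cnt[iu, t]
                if through:
                    bc[key] += through / cnt[s, t]
    return bc


def _components_partition(g: nx.Graph) -> dict:
    membership = {}
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for cid, comp in enumerate(comps):
        for node in comp:
            membership[node] = cid
    return membership


def _weighted_modularity(g_orig: nx.Graph, membership: dict) -> float:
    """Modularity with GCC affinity weights (similarity, not distance)."""
    if g_orig.number_of_edges() == 0:
        return 0.0
    comms: dict[int, set] = {}
    for node, cid in membership.items():
        comms.setdefault(cid, set()).add(node)
    return nx.community.modularity(g_orig, comms.values(), weight="gcc")


def girvan_newman_communities(g: nx.Graph) -> CommunityPartition:
    """Girvan-Newman community detection on the weighted residue graph.

    Repeatedly removes the edge of maximum betweenness (ties broken by the
    lexicographically smallest sorted node pair) and returns the partition
    along the removal sequence with maximal weighted modularity.  Isolated
    nodes and the edgeless graph yield singleton communities.
    """
    if g.number_of_nodes() == 0:
        return CommunityPartition({}, 0.0)
    work = g.copy()
    best_membership = _components_partition(work)
    best_q = _weighted_modularity(g, best_membership)
    n_comps = max(best_membership.values()) + 1
    while work.number_of_edges() > 0:
        bc = shortest_path_betweenness(work)
        max_val = max(bc.values())
        candidates = sorted(
            k for k, v in bc.items()
            if np.isclose(v, max_val, rtol=_TIE_RTOL, atol=1e-12)
        )
        work.remove_edge(*candidates[0])
        membership = _components_partition(work)
        k = max(membership.values()) + 1
        if k > n_comps:
            n_comps = k
            q = _weighted_modularity(g, membership)
            if q > best_q + 1e-12:
                best_q = q
                best_membership = membership
    return CommunityPartition(best_membership, float(best_q))


def community_repartition_difference(
    p1: CommunityPartition | dict, p2: CommunityPartition | dict,
) -> float:
    """Rand distance between two partitions of the same node set.

    The fraction of unordered node pairs whose co-membership status
    (same community vs different) disagrees between the partitions; 0 for
    identical partitions, 1 when all pairs disagree.
    """
    m1 = p1.membership if isinstance(p1, CommunityPartition) else p1
    m2 = p2.membership if isinstance(p2, CommunityPartition) else p2
    if set(m1) != set(m2):
        raise ValueError("partitions must cover the same node set")
    nodes = sorted(m1)
    if len(nodes) < 2:
        return 0.0
    disagree = 0
    total = 0
    for a, b in combinations(nodes, 2):
        total += 1
        if (m1[a] == m1[b]) != (m2[a] == m2[b]):
            disagree += 1
    return disagree / total
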