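"""Weighted modularity and Louvain community detection.

The partition quality is Newman–Girvan modularity with a resolution
parameter gamma:

    Q = sum_c [ S_in(c) / 2m  -  gamma * (S_tot(c) / 2m)^2 ]

where ``S_in(c)`` is twice the weight inside community c (self-loops
counted twice), ``S_tot(c)`` the total weighted degree of its nodes and
``2m`` the total weighted degree of the graph.  Louvain greedily
maximises Q by alternating a local node-moving phase with graph
aggregation until no pass improves Q.

Determinism: the node visit order of each local-moving sweep is a
seeded shuffle, and ties in the move gain keep the current community
when it participates in the tie, otherwise take the community with the
lowest canonical index.  Identical (graph, gamma, seed) therefore
always yield the identical partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import AnalysisError, ValidationError
from .synchrony import FunctionalGraph

_TOL = 1e-12


@dataclass(frozen=True)
class Partition:
    """Node-to-community map plus the modularity it achieves."""

    membership: dict
    q: float
    gamma: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list:
        groups: dict[int, list] = {}
        for node, c in self.membership.items():
            groups.setdefault(c, []).append(node)
        return [sorted(groups[c]) for c in sorted(groups)]


def _as_nx(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, FunctionalGraph) else graph


def modularity(graph, membership: Mapping, gamma: float = 1.0) -> float:
    """Evaluate Q for an explicit partition of a weighted graph."""
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    g = _as_nx(graph)
    missing = [n for n in g.nodes if n not in membership]
    if missing:
        raise ValidationError(f"partition misses nodes: {missing[:5]}")
    degree = dict(g.degree(weight="weight"))  # self-loops count twice
    m2 = sum(degree.values())
    if m2 == 0:
        raise AnalysisError("modularity undefined on a graph with no edges")
    s_in: dict = {}
    s_tot: dict = {}
    for node, deg in degree.items():
        c = membership[node]
        s_tot[c] = s_tot.get(c, 0.0) + deg
        s_in.setdefault(c, 0.0)
    for u, v, w in g.edges(data="weight", default=1.0):
        if membership[u] == membership[v]:
            s_in[membership[u]] += 2 * w
    return float(
        sum(s_in[c] / m2 - gamma * (s_tot[c] / m2) ** 2 for c in s_tot)
    )


def _local_moving(adj, loops, degree, m2, gamma, rng):
    """One local-moving phase; returns (community map, n_moves)."""
    nodes = list(range(len(adj)))
    comm = {u: u for u in nodes}
    ctot = {u: degree[u] for u in nodes}
    total_moves = 0
    moved = True
    while moved:
        moved = False
        order = rng.permutation(len(nodes))
        for u in order:
            u = int(u)
            cu = comm[u]
            # weight from u to each neighbouring community
            nw: dict[int, float] = {}
            for v, w in adj[u].items():
                nw[comm[v]] = nw.get(comm[v], 0.0) + w
            ctot[cu] -= degree[u]
            m = m2 / 2.0
            best_c, best_gain = cu, nw.get(cu, 0.0) / m - gamma * degree[u] * ctot[cu] / (2 * m * m)
            for c, w_uc in sorted(nw.items()):
                if c == cu:
                    continue
                gain = w_uc / m - gamma * degree[u] * ctot[c] / (2 * m * m)
                if gain > best_gain + _TOL or (
                    gain > best_gain - _TOL and best_c != cu and c < best_c
                ):
                    best_c, best_gain = c, gain
            ctot[best_c] = ctot.get(best_c, 0.0) + degree[u]
            if best_c != cu:
                comm[u] = best_c
                moved = True
                total_moves += 1
    return comm, total_moves


def _aggregate(adj, loops, comm):
    """Collapse communities into super-nodes with self-loops."""
    labels = sorted(set(comm.values()))
    relabel = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    new_adj: list[dict] = [dict() for _ in range(k)]
    new_loops = [0.0] * k
    for u, neigh in enumerate(adj):
        cu = relabel[comm[u]]
        new_loops[cu] += loops[u]
        for v, w in neigh.items():
            if v <= u:
                continue  # count each undirected edge once
            cv = relabel[comm[v]]
            if cu == cv:
                new_loops[cu] += w
            else:
                new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
                new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
    return new_adj, new_loops, relabel


def louvain(graph, gamma: float = 1.0, seed: int = 0, n_restarts: int = 10) -> Partition:
    """Louvain community detection on a weighted undirected graph.

    Runs ``n_restarts`` independent passes of the local-moving +
    aggregation procedure (visit orders shuffled by sub-streams of
    ``seed``) and keeps the partition with the highest modularity, so
    the result is deterministic given (graph, gamma, seed).  Raises
    :class:`AnalysisError` on an edgeless graph (every node would be
    its own community and Q is undefined there).
    """
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    g = _as_nx(graph)
    if g.number_of_nodes() == 0:
        raise AnalysisError("empty graph")
    if g.number_of_edges() == 0:
        raise AnalysisError("graph has no edges; modularity undefined")
    best = None
    for child in np.random.SeedSequence(entropy=int(seed)).spawn(n_restarts):
        part = _louvain_once(g, gamma, np.random.default_rng(child), seed)
        if best is None or part.q > best.q + _TOL:
            best = part
    return best


def _louvain_once(g: nx.Graph, gamma: float, rng, seed: int) -> Partition:
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj: list[dict] = [dict() for _ in nodes]
    loops = [0.0] * len(nodes)
    for u, v, w in g.edges(data="weight", default=1.0):
        iu, iv = index[u], index[v]
        if iu == iv:
            loops[iu] += w
        else:
            adj[iu][iv] = adj[iu].get(iv, 0.0) + w
            adj[iv][iu] = adj[iv].get(iu, 0.0) + w

    # membership of original nodes in terms of current-level super-nodes
    node_level = {i: i for i in range(len(nodes))}
    prev_q = -np.inf
    while True:
        degree = [sum(a.values()) + 2 * lo for a, lo in zip(adj, loops)]
        m2 = sum(degree)
        comm, n_moves = _local_moving(adj, loops, degree, m2, gamma, rng)
        adj, loops, relabel = _aggregate(adj, loops, comm)
        node_level = {n: relabel[comm[c]] for n, c in node_level.items()}
        q = _q_from_membership(adj, loops, gamma)
        if q < prev_q - 1e-9:  # Q must never decrease across passes
            raise AssertionError(f"modularity decreased across passes: {prev_q} -> {q}")
        if n_moves == 0 or q <= prev_q + _TOL:
            break
        prev_q = q

    # canonical labels 0..K-1 by first appearance in sorted node order
    seen: dict[int, int] = {}
    membership = {}
    for n in nodes:
        c = node_level[index[n]]
        if c not in seen:
            seen[c] = len(seen)
        membership[n] = seen[c]
    q_final = modularity(g, membership, gamma)
    return Partition(membership=membership, q=q_final, gamma=gamma, seed=seed)


def _q_from_membership(adj, loops, gamma):
    """Q of the current aggregated graph with singleton communities."""
    degree = [sum(a.values()) + 2 * lo for a, lo in zip(adj, loops)]
    m2 = sum(degree)
    return sum(2 * lo / m2 - gamma * (d / m2) ** 2 for lo, d in zip(loops, degree))
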