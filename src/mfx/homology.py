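"""Homology graph construction and Markov Clustering (MCL).

Nodes are namespaced sequence labels; an edge joins two sequences when at
least one directional similarity hit between them passes both a stringency
threshold on the e-value and a minimum alignment length.  The edge weight is
the maximum bitscore over passing hits in either direction (bitscores are
database-size independent, unlike e-values).

Clustering is a from-scratch dense-matrix MCL: the weighted adjacency matrix
with self-loops (loop weight = maximum incident edge weight; 1.0 on isolated
nodes, a standard regularization that prevents immediate attractor loss) is
column-normalized into a column-stochastic flow matrix, then expansion
(matrix power) and inflation (elementwise power followed by renormalization,
with pruning of tiny entries) alternate until the flow stabilizes.  Clusters
are read off the attractor structure of the limit matrix.  Each connected
component is iterated independently, which is exact — flow never crosses
components — and keeps the dense matrices small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .seqio import SimilarityHit

logger = logging.getLogger(__name__)

_SUPPORT_EPS = 1e-8


class HomologyGraph:
    """Weighted undirected graph over sequence identifiers.

    No self-edges; positive weights; symmetric by construction.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-edge on {a!r} not allowed")
        if weight <= 0:
            raise ValueError("edge weight must be positive")
        if self._g.has_edge(a, b):
            weight = max(weight, self._g[a][b]["weight"])
        self._g.add_edge(a, b, weight=weight)

    def weight(self, a: str, b: str) -> float:
        return self._g[a][b]["weight"]

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        return {tuple(sorted((a, b))): d["weight"] for a, b, d in self._g.edges(data=True)}

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(node))

    def nx_graph(self) -> nx.Graph:
        return self._g


@dataclass
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    prune_below: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


def build_homology_graph(
    hits: Iterable[SimilarityHit],
    evalue_max: float = 1e-20,
    min_align_len: int = 50,
    known_ids: set[str] | None = None,
) -> HomologyGraph:
    """Build the homology graph from similarity hits above a stringent threshold.

    An edge (a, b) exists iff a != b and at least one directional hit passes
    both ``evalue <= evalue_max`` and ``align_len >= min_align_len``; its
    weight is the maximum bitscore over passing hits in either direction.
    Hits naming unknown sequences (when ``known_ids`` is given) are logged
    and skipped.  Known ids are added as nodes even if they gain no edge.
    """
    graph = HomologyGraph()
    if known_ids:
        for node in known_ids:
            graph.add_node(node)
    for hit in hits:
        if known_ids is not None and (
            hit.query_id not in known_ids or hit.subject_id not in known_ids
        ):
            logger.info("skipping hit with unknown id: %s -> %s", hit.query_id, hit.subject_id)
            continue
        if hit.query_id == hit.subject_id:
            continue
        if hit.evalue > evalue_max or hit.align_len < min_align_len:
            continue
        graph.add_edge(hit.query_id, hit.subject_id, hit.bitscore)
    return graph


def connected_components(graph: HomologyGraph) -> list[set[str]]:
    """Connected components, sorted by their smallest member for determinism."""
    comps = [set(c) for c in nx.connected_components(graph.nx_graph())]
    return sorted(comps, key=lambda c: min(c))


def mcl_cluster(graph: HomologyGraph, params: MclParams | None = None) -> list[set[str]]:
    """Cluster the homology graph with Markov Clustering.

    Every node is assigned to exactly one cluster; where the limit matrix
    leaves a node supported by several attractors, the node follows the
    lexicographically smallest attractor.  On non-convergence within
    ``max_iterations`` the current clustering is returned with a warning.
    Output is deterministic: clusters sorted by their smallest member.
    """
    params = params or MclParams()
    clusters: list[set[str]] = []
    for comp in connected_components(graph):
        clusters.extend(_mcl_component(sorted(comp), graph, params))
    return sorted(clusters, key=lambda c: min(c))


def _mcl_component(nodes: list[str], graph: HomologyGraph, p: MclParams) -> list[set[str]]:
    n = len(nodes)
    if n == 1:
        return [{nodes[0]}]
    index = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for a in nodes:
        for b in graph.neighbors(a):
            if b in index:
                A[index[a], index[b]] = graph.weight(a, b)
    # self-loops: max incident weight (1.0 would only occur on isolated nodes,
    # which are handled above as singleton components)
    for i in range(n):
        inc = A[i].max()
        A[i, i] = inc if inc > 0 else 1.0
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(p.max_iterations):
        new = np.linalg.matrix_power(M, p.expansion)
        new = new**p.inflation
        new[new < p.prune_below] = 0.0
        colsums = new.sum(axis=0, keepdims=True)
        dead = colsums[0] == 0
        if dead.any():  # fully pruned column: park the walker on itself
            new[np.where(dead)[0], np.where(dead)[0]] = 1.0
            colsums = new.sum(axis=0, keepdims=True)
        new /= colsums
        if np.abs(new - M).max() < p.convergence_tol:
            M = new
            converged = True
            break
        M = new
    if not converged:
        logger.warning("MCL did not converge within %d iterations", p.max_iterations)
    return _read_clusters(M, nodes)


def _read_clusters(M: np.ndarray, nodes: list[str]) -> list[set[str]]:
    n = len(nodes)
    attractors = [i for i in range(n) if M[i, i] > _SUPPORT_EPS]
    owner: dict[int, int] = {}
    for j in range(n):
        supporters = [i for i in attractors if M[i, j] > _SUPPORT_EPS]
        if supporters:
            # resolve overlaps to the lexicographically smallest attractor label
            owner[j] = min(supporters, key=lambda i: nodes[i])
        else:
            owner[j] = int(np.argmax(M[:, j]))
    # attractors of one attractor system share rows, so chasing the owner of
    # the owner collapses the system onto its smallest attractor
    def resolve(j: int) -> int:
        seen = set()
        while owner[j] != j and j not in seen:
            seen.add(j)
            j = owner[j]
        return j

    groups: dict[int, set[str]] = {}
    for j in range(n):
        groups.setdefault(resolve(j), set()).add(nodes[j])
    return sorted(groups.values(), key=lambda c: min(c))
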