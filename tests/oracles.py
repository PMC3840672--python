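"""Independent oracle implementations used to cross-check the package.

Each oracle is deliberately coded apart from the implementation it checks:
the ORF oracle scans codon lists with groupby; the MCL oracle iterates the
whole-graph matrix without per-component decomposition; the tree oracle
enumerates bipartition leaf-sets by brute-force DFS over an edge-list tree
representation, with its own exhaustive topology generator.
"""

from __future__ import annotations

import itertools
import random

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# ORF oracle: brute-force 6-frame scan
# ---------------------------------------------------------------------------

def longest_orf_oracle(seq: str) -> tuple[int, int, int]:
    """Longest stop-free codon run across six frames; (frame, fwd_start, fwd_end)."""
    seq = seq.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int, int, int]] = []
    for frame_idx, frame in enumerate((1, 2, 3, -1, -2, -3)):
        s = seq if frame > 0 else revcomp(seq)
        off = abs(frame) - 1
        codons = [s[i : i + 3] for i in range(off, n - 2, 3)]
        pos = off
        for is_stop, grp in itertools.groupby(codons, key=lambda c: c in STOPS):
            length = 3 * len(list(grp))
            if not is_stop:
                start, end = pos, pos + length
                if frame < 0:
                    start, end = n - end, n - start
                candidates.append((-length, frame_idx, start, frame, end))
            pos += length
    if not candidates:
        return (1, 0, 0)
    neg_len, _, start, frame, end = min(candidates)
    return (frame, start, end)


# ---------------------------------------------------------------------------
# MCL oracle: whole-graph dense iteration
# ---------------------------------------------------------------------------

def mcl_oracle(
    nodes: list[str],
    edges: dict[tuple[str, str], float],
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iterations: int = 100,
    tol: float = 1e-6,
) -> list[set[str]]:
    """Reference MCL on the full adjacency matrix at once."""
    nodes = sorted(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    T = np.zeros((n, n))
    for (a, b), w in edges.items():
        T[pos[a], pos[b]] = max(T[pos[a], pos[b]], w)
        T[pos[b], pos[a]] = max(T[pos[b], pos[a]], w)
    for i in range(n):
        m = T[i].max()
        T[i, i] = m if m > 0 else 1.0
    T = T / T.sum(axis=0)
    for _ in range(max_iterations):
        expanded = np.linalg.matrix_power(T, expansion)
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune_below] = 0.0
        sums = inflated.sum(axis=0)
        for j in np.where(sums == 0)[0]:
            inflated[j, j] = 1.0
        inflated = inflated / inflated.sum(axis=0)
        if np.max(np.abs(inflated - T)) < tol:
            T = inflated
            break
        T = inflated
    eps = 1e-8
    attractors = [i for i in range(n) if T[i, i] > eps]
    owner_of: dict[int, int] = {}
    for j in range(n):
        owners = [i for i in attractors if T[i, j] > eps]
        owner_of[j] = min(owners, key=lambda i: nodes[i]) if owners else int(T[:, j].argmax())
    def chase(j: int) -> int:
        seen = set()
        while owner_of[j] != j and j not in seen:
            seen.add(j)
            j = owner_of[j]
        return j
    groups: dict[int, set[str]] = {}
    for j in range(n):
        groups.setdefault(chase(j), set()).add(nodes[j])
    return sorted(groups.values(), key=min)


def random_weighted_graph(seed: int, max_nodes: int = 8):
    """Seeded random weighted graph as (nodes, edges) for oracle comparison."""
    rng = random.Random(seed)
    n = rng.randint(2, max_nodes)
    nodes = [f"n{i}" for i in range(n)]
    edges: dict[tuple[str, str], float] = {}
    p = rng.uniform(0.2, 0.8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(nodes[i], nodes[j])] = round(rng.uniform(0.5, 10.0), 3)
    return nodes, edges


# ---------------------------------------------------------------------------
# tree oracle: edge-list trees, brute-force bipartition enumeration
# ---------------------------------------------------------------------------

class EdgeTree:
    """Unrooted tree as an edge list; leaves carry labels."""

    def __init__(self, edges: list[tuple[int, int]], leaf_labels: dict[int, str]):
        self.edges = list(edges)
        self.leaf_labels = dict(leaf_labels)
        self.adj: dict[int, set[int]] = {}
        for a, b in self.edges:
            self.adj.setdefault(a, set()).add(b)
            self.adj.setdefault(b, set()).add(a)

    def side_leaves(self, a: int, b: int) -> set[str]:
        """Leaf labels on the a-side of edge (a, b)."""
        seen = {b, a}
        stack = [a]
        labels = set()
        while stack:
            v = stack.pop()
            if v in self.leaf_labels:
                labels.add(self.leaf_labels[v])
            for w in self.adj.get(v, ()):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return labels

    def candidate_leaf_sets(self) -> set[frozenset[str]]:
        """All branch-induced bipartition sides plus the whole leaf set."""
        whole = frozenset(self.leaf_labels.values())
        out = {whole}
        for a, b in self.edges:
            side = frozenset(self.side_leaves(a, b))
            out.add(side)
            out.add(whole - side)
        out.discard(frozenset())
        return out

    def to_newick(self) -> str:
        internals = [v for v in self.adj if v not in self.leaf_labels]
        if not internals:  # two-leaf tree: a single edge
            a, b = sorted(self.leaf_labels)
            return f"({self.leaf_labels[a]},{self.leaf_labels[b]});"
        # root at the neighbor of the smallest-id leaf (an internal node)
        leaf0 = min(self.leaf_labels)
        root = next(iter(self.adj[leaf0]))

        def render(v: int, parent: int) -> str:
            if v in self.leaf_labels:
                return self.leaf_labels[v]
            kids = [render(w, v) for w in sorted(self.adj[v]) if w != parent]
            return "(" + ",".join(kids) + ")"

        kids = [render(w, root) for w in sorted(self.adj[root], key=lambda w: w != leaf0)]
        return "(" + ",".join(kids) + ");"


def taxon_unique(labels: frozenset[str]) -> bool:
    taxa = [x.split("@", 1)[0] for x in labels]
    return len(taxa) == len(set(taxa))


def max_taxon_unique_size(tree: EdgeTree) -> int:
    """Size of the largest taxon-unique candidate subtree (brute force)."""
    sizes = [len(c) for c in tree.candidate_leaf_sets() if taxon_unique(c)]
    return max(sizes) if sizes else 0


def all_topologies(n_leaves: int) -> list[EdgeTree]:
    """All unrooted binary topologies on n labeled leaves, by leaf insertion.

    Leaves are nodes 0..n-1; internal nodes get ids from 1000 upward.
    """
    base = EdgeTree([(0, 1)], {0: "L0", 1: "L1"})
    trees = [base]
    next_internal = 1000
    for leaf in range(2, n_leaves):
        grown = []
        for t in trees:
            for a, b in t.edges:
                w = next_internal + len(grown)  # unique internal id per variant
                edges = [e for e in t.edges if e != (a, b)]
                edges += [(a, w), (w, b), (w, leaf)]
                labels = dict(t.leaf_labels)
                labels[leaf] = f"L{leaf}"
                grown.append(EdgeTree(edges, labels))
        trees = grown
        next_internal += 10000
    return trees


def assign_taxa(tree: EdgeTree, taxa: tuple[int, ...]) -> EdgeTree:
    """Relabel leaves Li -> 'x<taxon>@<i>' for a given taxon assignment."""
    labels = {
        node: f"x{taxa[int(lbl[1:])]}@{lbl[1:]}" for node, lbl in tree.leaf_labels.items()
    }
    return EdgeTree(tree.edges, labels)


def random_labeled_tree(n_leaves: int, n_taxa: int, rng: random.Random) -> EdgeTree:
    """One random topology with a random taxon assignment."""
    edges = [(0, 1)]
    leaf_labels = {0: "L0", 1: "L1"}
    next_internal = 1000
    for leaf in range(2, n_leaves):
        a, b = rng.choice(edges)
        w = next_internal
        next_internal += 1
        edges = [e for e in edges if e != (a, b)] + [(a, w), (w, b), (w, leaf)]
        leaf_labels[leaf] = f"L{leaf}"
    taxa = tuple(rng.randrange(n_taxa) for _ in range(n_leaves))
    return assign_taxa(EdgeTree(edges, leaf_labels), taxa)
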