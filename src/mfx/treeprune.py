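"""Gene-tree handling: Newick parsing, support filtering, and decomposition
of each gene tree into maximally inclusive subtrees with at most one
sequence per taxon (putative ortholog sets).

Trees are treated as unrooted: candidate subtrees are the two leaf-sets
induced by deleting each branch, plus the entire leaf set.  The greedy
decomposition repeatedly extracts the largest taxon-unique candidate, deletes
its leaves, suppresses the degree-2 nodes this creates, and continues on the
residual forest until no leaves remain.  Ties between equally large
candidates break by number of distinct taxa, then by the lexicographically
smallest sorted label list, so extraction order is fully deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy
import networkx as nx

from .refine import Cluster
from .seqio import GeneSequence, taxon_of

logger = logging.getLogger(__name__)


@dataclass
class GeneTree:
    """A leaf-labeled gene tree with optional internal-node support values."""

    tree: dendropy.Tree
    tree_id: str = ""

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


@dataclass
class OrthologSet:
    tree_id: str
    leaf_labels: frozenset[str]
    rank: int

    def __post_init__(self) -> None:
        if not self.leaf_labels:
            raise ValueError("empty ortholog set")
        taxa = [taxon_of(label) for label in self.leaf_labels]
        if len(taxa) != len(set(taxa)):
            raise ValueError("ortholog set holds two sequences of one taxon")


def parse_newick(text: str, tree_id: str = "") -> GeneTree:
    """Parse a Newick string; numeric internal-node labels are support values."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    return GeneTree(tree=tree, tree_id=tree_id)


def write_newick(gt: GeneTree) -> str:
    """Serialize a GeneTree back to Newick (topology, labels, supports, lengths)."""
    return gt.tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def _internal_supports(gt: GeneTree) -> list[float]:
    supports = []
    for node in gt.tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            supports.append(float(node.label))
        except ValueError:
            continue
    return supports


def mean_support(gt: GeneTree) -> float:
    """Arithmetic mean over internal nodes that carry a numeric support value."""
    supports = _internal_supports(gt)
    if not supports:
        raise ValueError(f"unsupported tree {gt.tree_id!r}: no support values")
    return sum(supports) / len(supports)


def filter_trees_by_support(
    trees: list[GeneTree], min_mean_support: float
) -> tuple[list[GeneTree], list[GeneTree]]:
    """Keep trees with mean bootstrap support >= threshold.

    Trees without any support values are excluded with a warning (never
    silently kept).  Returns (kept, excluded).
    """
    kept, excluded = [], []
    for gt in trees:
        try:
            m = mean_support(gt)
        except ValueError:
            logger.warning("tree %s has no support values; excluded", gt.tree_id)
            excluded.append(gt)
            continue
        (kept if m >= min_mean_support else excluded).append(gt)
    logger.info(
        "support filter >= %.1f: kept %d of %d trees",
        min_mean_support,
        len(kept),
        len(kept) + len(excluded),
    )
    return kept, excluded


# ---------------------------------------------------------------------------
# ortholog decomposition
# ---------------------------------------------------------------------------

def _tree_to_graph(gt: GeneTree) -> nx.Graph:
    g = nx.Graph()
    ids = itertools.count()
    node_of = {}
    for node in gt.tree.preorder_node_iter():
        if node.is_leaf():
            name = ("leaf", node.taxon.label)
        else:
            name = ("internal", next(ids))
        node_of[node] = name
        g.add_node(name)
        if node.parent_node is not None:
            g.add_edge(node_of[node.parent_node], name)
    return g


def _leaves(g: nx.Graph, nodes=None) -> set[str]:
    pool = g.nodes if nodes is None else nodes
    return {n[1] for n in pool if n[0] == "leaf"}


def _taxon_unique(labels: set[str]) -> bool:
    taxa = {taxon_of(label) for label in labels}
    return len(taxa) == len(labels)


def _candidates(g: nx.Graph) -> list[frozenset[str]]:
    """Branch-induced leaf bipartition sides plus the whole leaf set, per component."""
    cands: set[frozenset[str]] = set()
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        all_leaves = frozenset(_leaves(g, comp))
        if all_leaves:
            cands.add(all_leaves)
        for a, b in sub.edges:
            h = sub.copy()
            h.remove_edge(a, b)
            side = nx.node_connected_component(h, a)
            side_leaves = frozenset(_leaves(g, side))
            other = all_leaves - side_leaves
            if side_leaves:
                cands.add(side_leaves)
            if other:
                cands.add(other)
    return list(cands)


def _selection_key(labels: frozenset[str]) -> tuple[int, int, tuple[str, ...]]:
    taxa = {taxon_of(label) for label in labels}
    # max leaves, then max taxa; sorted labels negated by ordering trick below
    return (len(labels), len(taxa), tuple(sorted(labels)))


def _cleanup(g: nx.Graph) -> None:
    """Drop dangling unlabeled nodes and suppress degree-2 unlabeled nodes."""
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if node[0] == "leaf":
                continue
            deg = g.degree(node)
            if deg <= 1:
                g.remove_node(node)
                changed = True
            elif deg == 2:
                a, b = list(g.neighbors(node))
                g.remove_node(node)
                g.add_edge(a, b)
                changed = True


def prune_orthologs(gt: GeneTree) -> list[OrthologSet]:
    """Decompose a gene tree into maximally inclusive taxon-unique subtrees.

    Output sets are pairwise disjoint, cover every leaf, and each holds at
    most one sequence per taxon.  The first extracted set has maximum
    cardinality among all branch-induced taxon-unique candidate subtrees.
    """
    g = _tree_to_graph(gt)
    sets: list[OrthologSet] = []
    rank = 0
    while _leaves(g):
        candidates = [c for c in _candidates(g) if _taxon_unique(c)]
        # singletons are always taxon-unique, so candidates is never empty
        best = max(
            candidates,
            key=lambda c: (len(c), len({taxon_of(x) for x in c})),
        )
        # among equally sized/taxon-rich candidates take the lexicographically
        # smallest sorted label list
        top = [
            c
            for c in candidates
            if len(c) == len(best)
            and len({taxon_of(x) for x in c}) == len({taxon_of(x) for x in best})
        ]
        best = min(top, key=lambda c: tuple(sorted(c)))
        sets.append(OrthologSet(tree_id=gt.tree_id, leaf_labels=best, rank=rank))
        rank += 1
        for label in best:
            g.remove_node(("leaf", label))
        _cleanup(g)
    return sets


def ortholog_sets_to_clusters(
    sets: list[OrthologSet], sequences: dict[str, GeneSequence]
) -> list[Cluster]:
    """Re-enter pruned subtrees as clusters (source=treeprune) for realignment."""
    clusters = []
    for oset in sets:
        members = [sequences[label] for label in sorted(oset.leaf_labels)]
        clusters.append(
            Cluster(
                cluster_id=f"{oset.tree_id}_o{oset.rank}",
                members=members,
                source="treeprune",
            )
        )
    return clusters
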