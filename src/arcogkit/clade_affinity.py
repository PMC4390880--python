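"""Per-gene-tree quantification of a focal clade's phylogenetic position.

Each gene tree is midpoint-rooted, the node(s) representing the focal
("target") clade's position are located by three criteria — the node covers
>= 0.75 of the target clade's weight, covers >= 0.75 of at least one other
clade's weight, and no descendant node does both — and per-clade affinities
are computed at those nodes:

    W_i* = (weight of clade-i genomes under the node)
           / (weight of clade-i genomes in the whole tree)        i != target
    R_i* = W_i* / sum_k W_k*

With several qualifying nodes (deep paralogs) the W_i* are averaged across
nodes before normalization.  Topology support (class I / II / X) is decided
from the set of clades qualifying at the selected node(s) against a
configurable sister set and enclosing group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import yaml

from arcogkit.genome_weighting import GenomeWeightTable, clade_weight_totals
from arcogkit.tree_io import CladeMap, Node, RootedTree, genome_of

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------


def _leaf_distances(tree: RootedTree):
    """All pairwise leaf distances treating the tree as unrooted.

    Returns (best_pair, best_distance, parent_map_from_a) for the longest
    leaf-to-leaf path; ties broken by the lexicographically smallest sorted
    label pair.
    """
    adjacency: dict[int, list[tuple[Node, float]]] = {}
    for node in tree.preorder():
        adjacency.setdefault(id(node), [])
        for child in node.children:
            adjacency[id(node)].append((child, child.length))
            adjacency.setdefault(id(child), []).append((node, child.length))

    leaves = sorted(tree.leaves(), key=lambda n: n.label)
    best: Optional[tuple[float, tuple[str, str], Node, Node]] = None
    for a in leaves:
        dist = {id(a): 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            for nbr, length in adjacency[id(node)]:
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(node)] + length
                    stack.append(nbr)
        for b in leaves:
            if b.label <= a.label:
                continue
            d = dist[id(b)]
            key = (d, (a.label, b.label))
            if best is None or d > best[0] + _EPS or (
                abs(d - best[0]) <= _EPS and key[1] < best[1]
            ):
                best = (d, key[1], a, b)
    assert best is not None
    return best


def _path_between(tree: RootedTree, a: Node, b: Node) -> list[Node]:
    """Node path from a to b through the tree (undirected)."""
    ancestors_a = []
    node = a
    while node is not None:
        ancestors_a.append(node)
        node = node.parent
    ancestor_ids = {id(n): i for i, n in enumerate(ancestors_a)}
    path_b = []
    node = b
    while id(node) not in ancestor_ids:
        path_b.append(node)
        node = node.parent
    join = node
    return ancestors_a[: ancestor_ids[id(join)] + 1] + list(reversed(path_b))


def _invert(node: Node) -> Node:
    """Reverse parent pointers from ``node`` up to the old root, making
    ``node`` the root of its side; edge lengths travel with their edges."""
    prev = node
    parent = node.parent
    edge_len = node.length
    node.parent = None
    node.length = 0.0
    while parent is not None:
        next_parent = parent.parent
        next_len = parent.length
        parent.children.remove(prev)
        prev.add_child(parent)
        parent.length = edge_len
        edge_len = next_len
        prev = parent
        parent = next_parent
    return node


def _reroot_at_node(tree: RootedTree, node: Node) -> RootedTree:
    if node is tree.root:
        return tree
    new = RootedTree(_invert(node))
    new.suppress_unifurcations()
    return new


def _reroot_on_edge(
    tree: RootedTree, child: Node, dist_from_child: float
) -> RootedTree:
    parent = child.parent
    edge_len = child.length
    parent.remove_child(child)
    upper = _invert(parent)
    new_root = Node()
    child.length = dist_from_child
    new_root.add_child(child)
    upper.length = edge_len - dist_from_child
    new_root.add_child(upper)
    new = RootedTree(new_root)
    new.suppress_unifurcations()
    return new


def root_midpoint(tree: RootedTree) -> RootedTree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    The input is treated as unrooted regardless of its current root.  Ties in
    path length are broken by the lexicographically smallest leaf pair, which
    makes the operation deterministic and idempotent.
    """
    if tree.n_leaves < 3:
        raise ValueError("midpoint rooting requires at least 3 leaves")
    work = tree.copy()
    diameter, _pair, a, b = _leaf_distances(work)
    path = _path_between(work, a, b)
    half = diameter / 2.0

    cum = 0.0
    for u, v in zip(path, path[1:]):
        # edge length between adjacent path nodes (one is the other's parent)
        edge_len = v.length if v.parent is u else u.length
        if cum + edge_len >= half - _EPS:
            d_on_edge = half - cum
            child = v if v.parent is u else u  # rooted-tree child end of edge
            dist_from_child = (
                edge_len - d_on_edge if v.parent is u else d_on_edge
            )
            if dist_from_child <= _EPS and child.is_leaf is False:
                return _reroot_at_node(work, child)
            if dist_from_child >= edge_len - _EPS and not child.parent.is_leaf:
                return _reroot_at_node(work, child.parent)
            return _reroot_on_edge(work, child, dist_from_child)
        cum += edge_len
    raise AssertionError("midpoint not found on path")  # pragma: no cover


# ---------------------------------------------------------------------------
# Affinity-node selection
# ---------------------------------------------------------------------------


def _genomes_below_by_clade(
    tree: RootedTree, clades: CladeMap
) -> dict[int, dict[str, set[str]]]:
    """Per node: clade -> set of distinct genomes with >= 1 leaf below."""
    index: dict[int, dict[str, set[str]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            genome = genome_of(node.label)
            clade = clades.get(genome)
            index[id(node)] = {clade: {genome}} if clade is not None else {}
        else:
            merged: dict[str, set[str]] = {}
            for child in node.children:
                for clade, genomes in index[id(child)].items():
                    merged.setdefault(clade, set()).update(genomes)
            index[id(node)] = merged
    return index


def genome_coverage(
    node: Node,
    clade: str,
    weights: GenomeWeightTable,
    clades: CladeMap,
) -> float:
    """Fraction of the clade's total weight (per the weight table) carried by
    distinct genomes with at least one leaf below ``node``.  A genome counts
    once regardless of paralog copies."""
    totals = clade_weight_totals(weights, clades)
    if clade not in totals:
        raise ValueError(f"clade {clade!r} absent from the weight table")
    genomes: set[str] = set()
    stack = [node]
    while stack:
        current = stack.pop()
        if current.is_leaf:
            genome = genome_of(current.label)
            if clades.get(genome) == clade:
                genomes.add(genome)
        else:
            stack.extend(current.children)
    return sum(weights.get(g, 0.0) for g in genomes) / totals[clade]


def find_affinity_nodes(
    tree: RootedTree,
    target: str,
    weights: GenomeWeightTable,
    clades: CladeMap,
    threshold: float = 0.75,
) -> list[Node]:
    """All minimal nodes covering >= ``threshold`` of the target clade's
    weight together with >= ``threshold`` of at least one other clade.

    Returns an empty list ("unclassifiable") when no second clade reaches the
    threshold anywhere in the tree; raises if the target is absent.
    """
    totals = clade_weight_totals(weights, clades)
    if target not in totals:
        raise ValueError(f"target clade {target!r} absent from the weight table")
    index = _genomes_below_by_clade(tree, clades)
    if target not in index[id(tree.root)]:
        raise ValueError(f"target clade {target!r} has no leaves in the tree")

    def coverage(node: Node, clade: str) -> float:
        genomes = index[id(node)].get(clade, ())
        return sum(weights.get(g, 0.0) for g in genomes) / totals[clade]

    qualifies: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            qualifies[id(node)] = False
            continue
        ok = coverage(node, target) >= threshold and any(
            coverage(node, clade) >= threshold
            for clade in index[id(node)]
            if clade != target
        )
        qualifies[id(node)] = ok

    selected: list[Node] = []
    has_below: dict[int, bool] = {}
    for node in tree.postorder():
        below = any(
            qualifies[id(c)] or has_below[id(c)] for c in node.children
        )
        has_below[id(node)] = below
        if qualifies[id(node)] and not below:
            selected.append(node)
    order = {id(n): i for i, n in enumerate(tree.preorder())}
    selected.sort(key=lambda n: order[id(n)])
    return selected


# ---------------------------------------------------------------------------
# Affinity computation and topology classification
# ---------------------------------------------------------------------------


@dataclass
class AffinityResult:
    """Per-tree affinity of the target clade to every other clade present."""

    tree_id: str
    target: str
    n_nodes: int
    W: dict[str, float]  # mean sister representation per non-target clade
    R: dict[str, float]  # normalized affinity; sums to 1 when any W > 0
    node_coverages: list[dict[str, float]] = field(default_factory=list)
    topology_class: Optional[str] = None


@dataclass
class AffinitySummary:
    n_trees: int
    mean_affinity: dict[str, float]
    class_counts: dict[str, int]


@dataclass(frozen=True)
class TopologyConfig:
    """Names the focal clade, its candidate sister clades, and the enclosing
    group used to recognize a basal attachment."""

    target: str
    sister_set: frozenset
    group: frozenset  # clades of the enclosing group (target included or not)
    threshold: float = 0.75

    @classmethod
    def from_dict(cls, data: dict) -> "TopologyConfig":
        return cls(
            target=data["target"],
            sister_set=frozenset(data["sister_set"]),
            group=frozenset(data["group"]),
            threshold=float(data.get("threshold", 0.75)),
        )

    @classmethod
    def from_yaml(cls, path) -> "TopologyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def compute_affinity(
    tree: RootedTree,
    nodes: list[Node],
    target: str,
    weights: GenomeWeightTable,
    clades: CladeMap,
    tree_id: str = "",
) -> AffinityResult:
    """W_i* and R_i* at the selected nodes, averaged over nodes.

    W_i* denominators use only the clade weight present in the tree; the
    per-node coverages recorded for topology classification use the weight
    table's full clade totals, matching the selection criteria.
    """
    index = _genomes_below_by_clade(tree, clades)
    totals = clade_weight_totals(weights, clades)
    in_tree = {
        clade: sum(weights.get(g, 0.0) for g in genomes)
        for clade, genomes in index[id(tree.root)].items()
    }
    other = sorted(c for c in in_tree if c != target and in_tree[c] > 0)

    def node_weight(node: Node, clade: str) -> float:
        return sum(weights.get(g, 0.0) for g in index[id(node)].get(clade, ()))

    W = {clade: 0.0 for clade in other}
    coverages: list[dict[str, float]] = []
    for node in nodes:
        for clade in other:
            W[clade] += node_weight(node, clade) / in_tree[clade]
        coverages.append(
            {
                clade: node_weight(node, clade) / totals[clade]
                for clade in index[id(node)]
                if clade in totals
            }
        )
    if nodes:
        W = {clade: w / len(nodes) for clade, w in W.items()}
    total = sum(W.values())
    if total > 0:
        R = {clade: w / total for clade, w in W.items()}
    else:
        R = {clade: 0.0 for clade in W}
    return AffinityResult(
        tree_id=tree_id,
        target=target,
        n_nodes=len(nodes),
        W=W,
        R=R,
        node_coverages=coverages,
    )


def _classify_node(
    coverage: dict[str, float], config: TopologyConfig
) -> str:
    qualifying = {
        clade
        for clade, cov in coverage.items()
        if clade != config.target and cov >= config.threshold
    }
    if not qualifying:
        return "X"
    if qualifying <= config.sister_set:
        return "II"
    in_group = qualifying & (config.group - {config.target})
    if (
        qualifying == in_group
        and len(in_group) >= 2
        and (in_group - config.sister_set)
    ):
        return "I"
    return "X"


def classify_topology(result: AffinityResult, config: TopologyConfig) -> str:
    """Class II: every qualifying sister clade is in the sister set.  Class I:
    two or more enclosing-group clades qualify, at least one outside the
    sister set, and nothing outside the group does.  Anything else (including
    an empty node list) is X; multi-node ties also resolve to X."""
    if result.n_nodes == 0 or not result.node_coverages:
        return "X"
    votes = Counter(
        _classify_node(coverage, config) for coverage in result.node_coverages
    )
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "X"
    return top[0][0]


def analyze_tree(
    tree: RootedTree,
    target: str,
    weights: GenomeWeightTable,
    clades: CladeMap,
    config: Optional[TopologyConfig] = None,
    threshold: float = 0.75,
    tree_id: str = "",
    midpoint: bool = True,
) -> AffinityResult:
    """Convenience wrapper: root, select nodes, compute affinity, classify."""
    rooted = root_midpoint(tree) if midpoint else tree
    nodes = find_affinity_nodes(rooted, target, weights, clades, threshold)
    result = compute_affinity(
        rooted, nodes, target, weights, clades, tree_id=tree_id
    )
    if config is not None:
        result.topology_class = classify_topology(result, config)
    return result


def aggregate(results: list[AffinityResult]) -> AffinitySummary:
    """Mean R_i* per clade across trees (clades missing from a tree's vector
    contribute 0 for that tree) and topology-class tallies."""
    if not results:
        raise ValueError("no affinity results to aggregate")
    all_clades = sorted({c for r in results for c in r.R})
    mean = {
        clade: sum(r.R.get(clade, 0.0) for r in results) / len(results)
        for clade in all_clades
    }
    counts = Counter(
        r.topology_class for r in results if r.topology_class is not None
    )
    return AffinitySummary(
        n_trees=len(results),
        mean_affinity=mean,
        class_counts=dict(counts),
    )
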