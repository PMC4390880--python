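import numpy as np
import pytest

from arcogkit.clade_affinity import (
    AffinityResult,
    TopologyConfig,
    aggregate,
    analyze_tree,
    classify_topology,
    compute_affinity,
    find_affinity_nodes,
    genome_coverage,
    root_midpoint,
)
from arcogkit.genome_weighting import GenomeWeightTable
from arcogkit.tree_io import CladeMap, RootedTree, genome_of, parse_newick

from conftest import random_rooted_tree


def _weights(d):
    return GenomeWeightTable(root_weight=sum(d.values()), weights=dict(d))


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------


def leaf_depths(tree: RootedTree) -> dict[str, float]:
    depths = {}

    def walk(node, depth):
        if node.is_leaf:
            depths[node.label] = depth
        for child in node.children:
            walk(child, depth + child.length)

    walk(tree.root, 0.0)
    return depths


class TestRootMidpoint:
    def test_symmetric_quartet(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_midpoint(tree)
        depths = leaf_depths(rooted)
        assert all(d == pytest.approx(2.0) for d in depths.values())

    def test_long_branch_example(self):
        # A--(5)--x--(1)--B with C off x at 1; longest path A-B (tie with A-C
        # broken toward the lexicographically smaller pair) has length 6, so
        # the root sits 3 from A on A's branch.
        tree = parse_newick("(A:5,B:1,C:1);")
        rooted = root_midpoint(tree)
        depths = leaf_depths(rooted)
        assert depths["A"] == pytest.approx(3.0)
        assert depths["B"] == pytest.approx(3.0)
        assert len(rooted.root.children) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        tree = random_rooted_tree(rng, n_leaves=20)
        once = root_midpoint(tree)
        twice = root_midpoint(once)
        assert leaf_depths(once) == pytest.approx(leaf_depths(twice))
        assert max(leaf_depths(once).values()) == pytest.approx(
            _diameter(tree) / 2
        )

    def test_small_tree_rejected(self):
        with pytest.raises(ValueError, match="3 leaves"):
            root_midpoint(parse_newick("(A:1,B:1);"))

    @pytest.mark.parametrize("seed", range(5))
    def test_deepest_leaf_at_half_diameter(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_rooted_tree(rng, n_leaves=12)
        rooted = root_midpoint(tree)
        assert sorted(rooted.leaf_labels()) == sorted(tree.leaf_labels())
        assert rooted.total_length() == pytest.approx(tree.total_length(), rel=1e-9)
        assert max(leaf_depths(rooted).values()) == pytest.approx(
            _diameter(tree) / 2, rel=1e-9
        )


def _diameter(tree: RootedTree) -> float:
    """Brute-force longest leaf-to-leaf path via root-paths."""

    def path_to_root(leaf):
        out = []
        node = leaf
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    leaves = tree.leaves()
    best = 0.0
    for i, a in enumerate(leaves):
        pa = path_to_root(a)
        ids = {id(n): k for k, n in enumerate(pa)}
        for b in leaves[i + 1 :]:
            d = 0.0
            node = b
            while id(node) not in ids:
                d += node.length
                node = node.parent
            d += sum(n.length for n in pa[: ids[id(node)]])
            best = max(best, d)
    return best


# ---------------------------------------------------------------------------
# Coverage and node selection
# ---------------------------------------------------------------------------


@pytest.fixture
def three_clade_tree():
    tree = parse_newick("(((A1:1,A2:1):1,(B1:1,B2:1):1):1,(C1:1,C2:1):1);")
    clades = CladeMap(
        {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C", "C2": "C"}
    )
    weights = _weights({g: 1.0 for g in clades.entries})
    return tree, clades, weights


class TestGenomeCoverage:
    def test_root_covers_all(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        for clade in "ABC":
            assert genome_coverage(tree.root, clade, weights, clades) == 1.0

    def test_node_below_clade_zero(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        c_node = tree.root.children[1]
        assert genome_coverage(c_node, "A", weights, clades) == 0.0

    def test_weighted_fraction(self):
        tree = parse_newick("((A1:1,A2:1):1,A3:1);")
        clades = CladeMap({"A1": "A", "A2": "A", "A3": "A"})
        weights = _weights({"A1": 1.0, "A2": 1.0, "A3": 2.0})
        a3 = [l for l in tree.leaves() if l.label == "A3"][0]
        assert genome_coverage(a3, "A", weights, clades) == pytest.approx(0.5)

    def test_paralogs_counted_once(self):
        tree = parse_newick("((A1|x:1,A1|y:1):1,B1|x:1);")
        clades = CladeMap({"A1": "A", "B1": "B"})
        weights = _weights({"A1": 1.0, "B1": 1.0})
        node = tree.root.children[0]
        assert genome_coverage(node, "A", weights, clades) == pytest.approx(1.0)

    def test_absent_clade_rejected(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        with pytest.raises(ValueError, match="absent"):
            genome_coverage(tree.root, "Zeta", weights, clades)


class TestFindAffinityNodes:
    def test_single_node_ab_ancestor(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        nodes = find_affinity_nodes(tree, "A", weights, clades)
        assert len(nodes) == 1
        labels = {l.label for l in _leaves_below(nodes[0])}
        assert labels == {"A1", "A2", "B1", "B2"}

    def test_paralog_duplication_two_nodes(self):
        # two paralogous copies, each subtree with full A and B coverage
        tree = parse_newick(
            "(((A1|x:1,A2|x:1):1,(B1|x:1,B2|x:1):1):1,"
            "((A1|y:1,A2|y:1):1,(B1|y:1,B2|y:1):1):1);"
        )
        clades = CladeMap({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        weights = _weights({g: 1.0 for g in clades.entries})
        nodes = find_affinity_nodes(tree, "A", weights, clades)
        assert len(nodes) == 2

    def test_star_root_fallback(self):
        tree = parse_newick("(A1:1,B1:1,C1:1,D1:1);")
        clades = CladeMap({"A1": "A", "B1": "B", "C1": "C", "D1": "D"})
        weights = _weights({g: 1.0 for g in clades.entries})
        nodes = find_affinity_nodes(tree, "A", weights, clades)
        assert nodes == [tree.root]

    def test_target_absent_rejected(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        clades2 = CladeMap(dict(clades.entries, **{"Z9": "Z"}))
        weights2 = _weights(dict(weights.weights, Z9=1.0))
        with pytest.raises(ValueError, match="no leaves"):
            find_affinity_nodes(tree, "Z", weights2, clades2)

    def test_no_partner_clade_unclassifiable(self):
        # clade B has most of its weight outside the tree, so no node (not
        # even the root) reaches 0.75 coverage of a second clade
        tree = parse_newick("((A1:1,B1:1):1,A2:1);")
        clades = CladeMap(
            {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "B3": "B", "B4": "B"}
        )
        weights = _weights({g: 1.0 for g in clades.entries})
        nodes = find_affinity_nodes(tree, "A", weights, clades, threshold=0.75)
        assert nodes == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        tree, clades, weights = _random_clade_tree(seed, max_leaves=8)
        target = clades[genome_of(tree.leaves()[0].label)]
        got = find_affinity_nodes(tree, target, weights, clades)
        expected = brute_force_affinity_nodes(tree, target, weights, clades)
        assert {id(n) for n in got} == {id(n) for n in expected}


def _leaves_below(node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def _random_clade_tree(seed, max_leaves=8, n_clades=3):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_leaves + 1))
    labels = [f"g{i}" for i in range(n)]
    tree = random_rooted_tree(rng, n_leaves=n, labels=labels)
    clade_names = [chr(ord("A") + i) for i in range(n_clades)]
    assignment = {g: clade_names[int(rng.integers(n_clades))] for g in labels}
    # make sure every clade has at least one genome
    for i, clade in enumerate(clade_names):
        assignment[labels[i % n]] = clade
    clades = CladeMap(assignment)
    weights = _weights({g: float(rng.uniform(0.1, 3.0)) for g in labels})
    return tree, clades, weights


def brute_force_affinity_nodes(tree, target, weights, clades, threshold=0.75):
    """Independent oracle: test the three selection criteria on every node by
    direct enumeration."""

    def coverage(node, clade):
        genomes = {
            genome_of(l.label)
            for l in _leaves_below(node)
            if clades.get(genome_of(l.label)) == clade
        }
        total = sum(
            w for g, w in weights.weights.items() if clades.get(g) == clade
        )
        return sum(weights.weights[g] for g in genomes) / total

    def crit12(node):
        if node.is_leaf:
            return False
        if coverage(node, target) < threshold:
            return False
        others = {
            clades.get(genome_of(l.label))
            for l in _leaves_below(node)
        } - {target, None}
        return any(coverage(node, c) >= threshold for c in others)

    def descendants(node):
        out = []
        stack = list(node.children)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    return [
        node
        for node in tree.nodes()
        if crit12(node) and not any(crit12(d) for d in descendants(node))
    ]


# ---------------------------------------------------------------------------
# Affinity computation
# ---------------------------------------------------------------------------


class TestComputeAffinity:
    def test_sister_gets_all(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        nodes = find_affinity_nodes(tree, "A", weights, clades)
        result = compute_affinity(tree, nodes, "A", weights, clades)
        assert result.W["B"] == pytest.approx(1.0)
        assert result.W["C"] == pytest.approx(0.0)
        assert result.R["B"] == pytest.approx(1.0)
        assert result.R["C"] == pytest.approx(0.0)

    def test_root_node_uniform(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        result = compute_affinity(tree, [tree.root], "A", weights, clades)
        assert result.W["B"] == pytest.approx(1.0)
        assert result.W["C"] == pytest.approx(1.0)
        assert result.R["B"] == pytest.approx(0.5)
        assert result.R["C"] == pytest.approx(0.5)

    def test_two_node_averaging(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        ab = tree.root.children[0]  # W_B = 1 there
        a_only = ab.children[0]  # W_B = 0 there
        result = compute_affinity(tree, [ab, a_only], "A", weights, clades)
        assert result.W["B"] == pytest.approx(0.5)

    def test_normalization_sums_to_one(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        nodes = find_affinity_nodes(tree, "A", weights, clades)
        result = compute_affinity(tree, nodes, "A", weights, clades)
        assert sum(result.R.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_node_list_zero_vector(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        result = compute_affinity(tree, [], "A", weights, clades)
        assert all(v == 0.0 for v in result.R.values())


# ---------------------------------------------------------------------------
# Topology classification
# ---------------------------------------------------------------------------


@pytest.fixture
def topo_config():
    return TopologyConfig(
        target="T",
        sister_set=frozenset({"Mc", "Mb"}),
        group=frozenset({"T", "Mc", "Mb", "H", "Tp"}),
        threshold=0.75,
    )


def _result(coverages, n_nodes=None):
    return AffinityResult(
        tree_id="t",
        target="T",
        n_nodes=len(coverages) if n_nodes is None else n_nodes,
        W={},
        R={},
        node_coverages=coverages,
    )


class TestClassifyTopology:
    def test_sister_set_only_is_II(self, topo_config):
        result = _result([{"T": 1.0, "Mc": 0.9}])
        assert classify_topology(result, topo_config) == "II"

    def test_both_sisters_is_II(self, topo_config):
        result = _result([{"T": 1.0, "Mc": 0.9, "Mb": 0.8}])
        assert classify_topology(result, topo_config) == "II"

    def test_basal_to_group_is_I(self, topo_config):
        result = _result([{"T": 1.0, "Mc": 1.0, "Mb": 1.0, "H": 1.0, "Tp": 1.0}])
        assert classify_topology(result, topo_config) == "I"

    def test_two_group_clades_outside_sisters_is_I(self, topo_config):
        result = _result([{"T": 1.0, "H": 1.0, "Tp": 0.9}])
        assert classify_topology(result, topo_config) == "I"

    def test_non_group_neighbor_is_X(self, topo_config):
        result = _result([{"T": 1.0, "Cren": 0.9}])
        assert classify_topology(result, topo_config) == "X"

    def test_single_non_sister_group_clade_is_X(self, topo_config):
        result = _result([{"T": 1.0, "H": 0.9}])
        assert classify_topology(result, topo_config) == "X"

    def test_mixed_group_and_non_group_is_X(self, topo_config):
        result = _result([{"T": 1.0, "H": 1.0, "Tp": 1.0, "Cren": 0.9}])
        assert classify_topology(result, topo_config) == "X"

    def test_below_threshold_ignored(self, topo_config):
        result = _result([{"T": 1.0, "Mc": 0.9, "Cren": 0.5}])
        assert classify_topology(result, topo_config) == "II"

    def test_empty_nodes_is_X(self, topo_config):
        assert classify_topology(_result([], n_nodes=0), topo_config) == "X"

    def test_majority_vote(self, topo_config):
        result = _result(
            [{"T": 1.0, "Mc": 0.9}, {"T": 1.0, "Mc": 0.9}, {"T": 1.0, "Cren": 0.9}]
        )
        assert classify_topology(result, topo_config) == "II"

    def test_tie_is_X(self, topo_config):
        result = _result([{"T": 1.0, "Mc": 0.9}, {"T": 1.0, "Cren": 0.9}])
        assert classify_topology(result, topo_config) == "X"


class TestAggregate:
    def _res(self, R, cls):
        return AffinityResult(
            tree_id="t", target="T", n_nodes=1, W=dict(R), R=dict(R),
            node_coverages=[], topology_class=cls,
        )

    def test_single_tree(self):
        summary = aggregate([self._res({"B": 1.0, "C": 0.0}, "II")])
        assert summary.mean_affinity == {"B": 1.0, "C": 0.0}
        assert summary.class_counts == {"II": 1}

    def test_two_tree_mean(self):
        summary = aggregate(
            [self._res({"B": 1.0}, "II"), self._res({"B": 0.0, "C": 1.0}, "X")]
        )
        assert summary.mean_affinity["B"] == pytest.approx(0.5)
        assert summary.mean_affinity["C"] == pytest.approx(0.5)

    def test_counts_sum_to_trees(self):
        results = [self._res({"B": 1.0}, c) for c in ("I", "II", "X", "II")]
        summary = aggregate(results)
        assert sum(summary.class_counts.values()) == summary.n_trees == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_mean_affinities_sum_to_one(self):
        results = [
            self._res({"B": 0.7, "C": 0.3}, "X"),
            self._res({"B": 0.2, "C": 0.8}, "X"),
        ]
        summary = aggregate(results)
        assert sum(summary.mean_affinity.values()) == pytest.approx(1.0)


class TestAnalyzeTree:
    def test_end_to_end_three_clades(self, three_clade_tree):
        tree, clades, weights = three_clade_tree
        config = TopologyConfig(
            target="A", sister_set=frozenset({"B"}), group=frozenset({"A", "B"})
        )
        result = analyze_tree(tree, "A", weights, clades, config=config)
        assert result.topology_class == "II"
        assert result.R["B"] == pytest.approx(1.0)
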