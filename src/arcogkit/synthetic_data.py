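"""Synthetic fixtures for the whole pipeline: clade-structured species trees,
gene-tree sets with a planted topology mixture, and phyletic matrices with
planted exclusively-shared gene sets.

Everything is a pure function of (config, seed): the same config yields
bit-identical Newick strings and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from arcogkit.genome_weighting import GenomeWeightTable, distribute_weights
from arcogkit.tree_io import CladeMap, MembershipTable, Node, RootedTree

#: Reference 13-clade configuration (class-level archaeal lineages).
DEFAULT_CLADES = (
    "Thermococci",
    "Methanococci",
    "Methanobacteria",
    "Methanopyri",
    "Methanomicrobia",
    "Halobacteria",
    "Thermoplasmata",
    "Archaeoglobi",
    "Nanoarchaeota",
    "Crenarchaeota",
    "Thaumarchaeota",
    "Korarchaeota",
    "Aigarchaeota",
)

#: Clades on the "euryarchaeal" side of the basal split in the generated tree.
EURYARCHAEOTA_CLADES = frozenset(DEFAULT_CLADES[:8])


@dataclass
class SimulationConfig:
    seed: int = 0
    clade_names: Sequence[str] = DEFAULT_CLADES
    genomes_per_clade: int | Sequence[int] = 4
    branch_length_mean: float = 0.1
    #: extra length added to the two basal branches so the midpoint root stays
    #: on the backbone, away from the planted attachment of the target clade
    basal_stem: float = 2.0
    target: str = "Thermococci"
    sister_set: frozenset = frozenset({"Methanococci", "Methanobacteria"})
    #: where the target sits in the base species tree (kept out of sister_set
    #: so unperturbed trees do not trivially read as class II)
    target_neighbor: str = "Halobacteria"
    #: optional elongation of the target clade's stem (long-branch regime)
    target_stem_extra: float = 0.0
    n_gene_trees: int = 200
    p_topology_II: float = 0.0
    p_topology_I: float = 0.0
    n_spr: int = 3
    taxon_sampling: float = 1.0
    background_presence: float = 0.1
    n_background_clusters: int = 50
    #: planted exclusively-shared gene sets: (clade subset, cluster count)
    planted_exclusive: Sequence[tuple[tuple[str, ...], int]] = field(
        default_factory=lambda: (
            (("Thermococci", "Methanococci"), 5),
            (("Thermococci", "Methanococci", "Methanobacteria"), 3),
        )
    )

    def __post_init__(self):
        for name, p in (
            ("p_topology_II", self.p_topology_II),
            ("p_topology_I", self.p_topology_I),
            ("taxon_sampling", self.taxon_sampling),
            ("background_presence", self.background_presence),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_topology_II + self.p_topology_I > 1.0 + 1e-12:
            raise ValueError("p_topology_II + p_topology_I must be <= 1")

    def genome_counts(self) -> list[int]:
        if isinstance(self.genomes_per_clade, int):
            return [self.genomes_per_clade] * len(self.clade_names)
        counts = list(self.genomes_per_clade)
        if len(counts) != len(self.clade_names):
            raise ValueError("genomes_per_clade length != number of clades")
        return counts


def _join_random(
    subtrees: list[Node], rng: np.random.Generator, bl_mean: float
) -> Node:
    """Random sequential pairwise joins into a single binary subtree."""
    pool = list(subtrees)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        right = pool.pop(j)
        left = pool.pop(i)
        parent = Node()
        left.length += float(rng.exponential(bl_mean))
        right.length += float(rng.exponential(bl_mean))
        parent.add_child(left)
        parent.add_child(right)
        pool.append(parent)
    return pool[0]


def _clade_subtree(
    clade: str, n: int, rng: np.random.Generator, bl_mean: float
) -> Node:
    leaves = [
        Node(label=f"{clade}_{k + 1:02d}", length=float(rng.exponential(bl_mean)))
        for k in range(n)
    ]
    if n == 1:
        return leaves[0]
    return _join_random(leaves, rng, bl_mean)


def make_species_tree(
    config: SimulationConfig,
) -> tuple[RootedTree, CladeMap, GenomeWeightTable]:
    """Clade-monophyletic rooted species tree with a deep basal split, plus
    the matching clade map and genome weights (root weight = leaf count)."""
    names = list(config.clade_names)
    if len(names) < 2:
        raise ValueError("need at least 2 clades")
    if config.target not in names:
        raise ValueError(f"target clade {config.target!r} not in clade_names")
    rng = np.random.default_rng(config.seed)
    counts = config.genome_counts()
    bl = config.branch_length_mean

    subtree = {
        clade: _clade_subtree(clade, n, rng, bl)
        for clade, n in zip(names, counts)
    }
    eury = [c for c in names if c in EURYARCHAEOTA_CLADES]
    other = [c for c in names if c not in EURYARCHAEOTA_CLADES]
    if config.target in eury and config.target_neighbor in eury:
        # deterministic base position: target joined with a neutral neighbor
        pair = Node()
        t = subtree.pop(config.target)
        nb = subtree.pop(config.target_neighbor)
        t.length += float(rng.exponential(bl)) + config.target_stem_extra
        nb.length += float(rng.exponential(bl))
        pair.add_child(t)
        pair.add_child(nb)
        eury_pool = [pair] + [subtree[c] for c in eury
                              if c not in (config.target, config.target_neighbor)]
    else:
        eury_pool = [subtree[c] for c in eury]
    sides = []
    for pool in (eury_pool, [subtree[c] for c in other]):
        if pool:
            sides.append(_join_random(pool, rng, bl))
    root = Node()
    for side in sides:
        side.length += float(rng.exponential(bl)) + config.basal_stem
        root.add_child(side)
    tree = RootedTree(root)

    clade_map = CladeMap(
        {
            f"{clade}_{k + 1:02d}": clade
            for clade, n in zip(names, counts)
            for k in range(n)
        }
    )
    weights = distribute_weights(tree, root_weight=float(tree.n_leaves))
    return tree, clade_map, weights


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------


def _detach_clade(tree: RootedTree, clade_map: CladeMap, clade: str) -> Node:
    """Remove the (monophyletic) clade's subtree; returns the detached root
    with its stem length preserved."""
    genomes = clade_map.genomes_in(clade)
    present = genomes & set(tree.leaf_labels())
    node = tree.mrca(present)
    parent = node.parent
    if parent is None:
        raise ValueError(f"clade {clade!r} spans the whole tree")
    parent.remove_child(node)
    tree.suppress_unifurcations()
    return node


def _attach(tree: RootedTree, edge_child: Node, subtree: Node,
            fraction: float) -> None:
    """Insert ``subtree`` on the branch above ``edge_child`` at the given
    fraction of the branch length measured from the child end."""
    parent = edge_child.parent
    idx = parent.children.index(edge_child)
    length = edge_child.length
    joint = Node(length=length * (1.0 - fraction))
    parent.children[idx] = joint
    joint.parent = parent
    edge_child.length = length * fraction
    joint.add_child(edge_child)
    joint.add_child(subtree)


def _random_spr(tree: RootedTree, rng: np.random.Generator) -> None:
    """One random subtree-prune-regraft move (in place); no-op if no valid
    regraft edge exists."""
    candidates = [
        n for n in tree.preorder()
        if n is not tree.root and n.parent is not tree.root
    ]
    if not candidates:
        return
    prune = candidates[int(rng.integers(len(candidates)))]
    in_pruned = set(map(id, _subtree_nodes(prune)))
    parent = prune.parent
    parent.remove_child(prune)
    tree.suppress_unifurcations()
    edges = [
        n for n in tree.preorder()
        if n is not tree.root and id(n) not in in_pruned
    ]
    if not edges:
        parent.add_child(prune)  # pragma: no cover - degenerate
        return
    target_edge = edges[int(rng.integers(len(edges)))]
    _attach(tree, target_edge, prune, fraction=0.5)


def _subtree_nodes(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _subsample(tree: RootedTree, rng: np.random.Generator, p: float) -> bool:
    """Drop each leaf with probability 1-p; returns False if fewer than 3
    leaves survive (tree unusable)."""
    drop = [leaf for leaf in tree.leaves() if rng.random() > p]
    if tree.n_leaves - len(drop) < 3:
        return False
    for leaf in drop:
        parent = leaf.parent
        parent.remove_child(leaf)
        while parent is not None and not parent.children:
            grand = parent.parent
            if grand is None:
                return False
            grand.remove_child(parent)
            parent = grand
    tree.suppress_unifurcations()
    return True


@dataclass
class SimulatedGeneTree:
    tree_id: str
    tree: RootedTree
    true_class: str  # "I", "II", or "X"


def simulate_gene_trees(
    species_tree: RootedTree,
    clade_map: CladeMap,
    config: SimulationConfig,
) -> list[SimulatedGeneTree]:
    """Gene trees drawn as perturbations of the species tree.

    A fraction ~p_topology_II has the target clade regrafted as sister to the
    sister-set clades, ~p_topology_I has it regrafted basally to the
    euryarchaeal side, and the remainder is perturbed by ``n_spr`` random SPR
    moves.  Leaves are then subsampled and relabelled ``genome|gene``.
    """
    if config.target not in clade_map.clades:
        raise ValueError(f"target clade {config.target!r} not in clade map")
    rng = np.random.default_rng(config.seed + 1)
    probs = np.array(
        [
            config.p_topology_II,
            config.p_topology_I,
            max(1.0 - config.p_topology_II - config.p_topology_I, 0.0),
        ]
    )
    probs = probs / probs.sum()
    sisters = sorted(config.sister_set)
    out: list[SimulatedGeneTree] = []
    for k in range(config.n_gene_trees):
        tree_id = f"gt{k:04d}"
        true_class = str(rng.choice(["II", "I", "X"], p=probs))
        tree = species_tree.copy()
        if true_class == "II":
            # graft the target as sister to one clade of the sister set; a
            # single clade's subtree is monophyletic by construction, so the
            # planted neighborhood contains only sister-set genomes
            target_sub = _detach_clade(tree, clade_map, config.target)
            sister = sisters[int(rng.integers(len(sisters)))]
            anchor = tree.mrca(
                clade_map.genomes_in(sister) & set(tree.leaf_labels())
            )
            if anchor is tree.root:  # pragma: no cover - degenerate config
                anchor = tree.root.children[0]
            _attach(tree, anchor, target_sub, fraction=0.5)
        elif true_class == "I":
            target_sub = _detach_clade(tree, clade_map, config.target)
            eury_genomes = {
                g
                for g, c in clade_map.entries.items()
                if c in EURYARCHAEOTA_CLADES and c != config.target
            }
            anchor = tree.mrca(eury_genomes & set(tree.leaf_labels()))
            if anchor is tree.root:  # pragma: no cover - degenerate config
                anchor = tree.root.children[0]
            # attach low on the basal stem so midpoint rooting stays above
            _attach(tree, anchor, target_sub, fraction=0.1)
        else:
            for _ in range(config.n_spr):
                _random_spr(tree, rng)
        if config.taxon_sampling < 1.0:
            if not _subsample(tree, rng, config.taxon_sampling):
                continue
        for leaf in tree.leaves():
            leaf.label = f"{leaf.label}|{tree_id}"
        out.append(SimulatedGeneTree(tree_id, tree, str(true_class)))
    return out


# ---------------------------------------------------------------------------
# Phyletic matrices
# ---------------------------------------------------------------------------


def simulate_phyletic_matrix(
    clade_map: CladeMap, config: SimulationConfig
) -> tuple[MembershipTable, pd.DataFrame]:
    """Membership table with planted exclusively-shared clusters (single-copy,
    present in every genome of the designated clade subsets, absent elsewhere)
    plus background clusters present per-genome at ``background_presence``.

    Returns (table, truth) where truth lists planted cluster ids and their
    clade subsets.
    """
    rng = np.random.default_rng(config.seed + 2)
    genomes = sorted(clade_map.entries)
    records: list[tuple[str, str, str]] = []
    gene_counter = {g: 0 for g in genomes}

    def add(genome: str, cluster: str) -> None:
        gene_counter[genome] += 1
        records.append((genome, f"{genome}_g{gene_counter[genome]:04d}", cluster))

    truth_rows = []
    planted_idx = 0
    for clade_subset, n_clusters in config.planted_exclusive:
        subset = set(clade_subset)
        unknown = subset - clade_map.clades
        if unknown:
            raise ValueError(f"planted clade(s) not in clade map: {sorted(unknown)}")
        members = [g for g in genomes if clade_map[g] in subset]
        for _ in range(n_clusters):
            cluster = f"planted{planted_idx:04d}"
            planted_idx += 1
            for genome in members:
                add(genome, cluster)
            truth_rows.append((cluster, "+".join(sorted(subset))))
    for b in range(config.n_background_clusters):
        cluster = f"bg{b:04d}"
        for genome in genomes:
            if rng.random() < config.background_presence:
                add(genome, cluster)

    truth = pd.DataFrame(truth_rows, columns=["cluster_id", "clade_set"])
    return MembershipTable(records), truth
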