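"""Relative genome weights from a rooted species tree.

The weight W assigned to a node is distributed among its child subtrees
proportionally to (incoming branch length + subtree branch-length sum):

    W_i = W * (L_i + T_i) / sum_k (L_k + T_k)

computed in two passes: subtree lengths leaf-to-root, weights root-to-leaf.
Closely related genomes (short terminal branches under a shallow ancestor)
thereby share weight instead of each counting fully, which damps taxon
sampling bias in downstream clade statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from arcogkit.tree_io import CladeMap, Node, RootedTree

logger = logging.getLogger(__name__)

CONSERVATION_RTOL = 1e-9


@dataclass
class GenomeWeightTable:
    """Per-genome relative weights plus the node caches they derive from."""

    root_weight: float
    weights: dict[str, float]
    subtree_length: dict[int, float] = field(default_factory=dict, repr=False)
    incoming_length: dict[int, float] = field(default_factory=dict, repr=False)

    def __getitem__(self, genome: str) -> float:
        return self.weights[genome]

    def get(self, genome: str, default=None):
        return self.weights.get(genome, default)

    def __contains__(self, genome: str) -> bool:
        return genome in self.weights

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def total(self) -> float:
        return sum(self.weights.values())

    @classmethod
    def from_tsv(cls, path) -> "GenomeWeightTable":
        df = pd.read_csv(path, sep="\t", dtype={"genome_id": str}, comment="#")
        if not {"genome_id", "weight"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns genome_id, weight")
        weights = dict(zip(df["genome_id"], df["weight"].astype(float)))
        return cls(root_weight=sum(weights.values()), weights=weights)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            sorted(self.weights.items()), columns=["genome_id", "weight"]
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def subtree_lengths(tree: RootedTree) -> dict[int, float]:
    """T(node) = sum of all branch lengths strictly below the node, keyed by
    ``id(node)``; T(leaf) = 0."""
    T: dict[int, float] = {}
    for node in tree.postorder():
        T[id(node)] = sum(child.length + T[id(child)] for child in node.children)
    return T


def distribute_weights(
    tree: RootedTree, root_weight: Optional[float] = None
) -> GenomeWeightTable:
    """Distribute ``root_weight`` (default: leaf count) down the tree.

    At each internal node the node's weight splits among children by
    (L_i + T_i) proportions.  If all children have L + T = 0 (a zero-length
    subtree) the split is equal, which keeps every leaf weight positive and
    the total conserved.
    """
    if root_weight is None:
        root_weight = float(tree.n_leaves)
    if not root_weight > 0:
        raise ValueError(f"root_weight must be positive, got {root_weight}")

    T = subtree_lengths(tree)
    L = {
        id(node): (0.0 if node is tree.root else node.length)
        for node in tree.preorder()
    }

    node_weight: dict[int, float] = {id(tree.root): float(root_weight)}
    leaf_weights: dict[str, float] = {}
    for node in tree.preorder():
        w = node_weight[id(node)]
        if node.is_leaf:
            leaf_weights[node.label] = w
            continue
        shares = [child.length + T[id(child)] for child in node.children]
        denom = sum(shares)
        if denom > 0:
            for child, share in zip(node.children, shares):
                node_weight[id(child)] = w * share / denom
        else:
            for child in node.children:
                node_weight[id(child)] = w / len(node.children)

    table = GenomeWeightTable(
        root_weight=float(root_weight),
        weights=leaf_weights,
        subtree_length=T,
        incoming_length=L,
    )
    total = table.total
    if abs(total - root_weight) > CONSERVATION_RTOL * max(abs(root_weight), 1.0):
        raise AssertionError(
            f"weight conservation violated: sum={total!r} vs root={root_weight!r}"
        )
    return table


def clade_weight_totals(
    weights: GenomeWeightTable, clades: CladeMap
) -> dict[str, float]:
    """Sum of genome weights per clade; genomes without a clade assignment are
    excluded with a warning."""
    unmapped = sorted(set(weights.weights) - set(clades.entries))
    if unmapped:
        logger.warning(
            "%d weighted genome(s) have no clade assignment and are excluded "
            "from clade totals",
            len(unmapped),
        )
    totals: dict[str, float] = {}
    matched = 0
    for genome, w in weights.weights.items():
        clade = clades.get(genome)
        if clade is None:
            continue
        totals[clade] = totals.get(clade, 0.0) + w
        matched += 1
    if matched == 0:
        raise ValueError("no overlap between weight table and clade map")
    return totals
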