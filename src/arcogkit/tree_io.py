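"""Shared data model and I/O: rooted trees (Newick), clade maps and ortholog
membership tables (TSV), and protein alignments (aligned FASTA).

Gene-tree leaves are labelled ``genome_id|gene_id``; the prefix before the
first ``|`` keys into the clade map and weight table.  Leaves without a ``|``
are taken to be genome ids themselves (species-tree convention).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,'\"]")


class NewickParseError(ValueError):
    """Raised for malformed Newick input; message names the offending position."""


def genome_of(label: str) -> str:
    """Return the genome id encoded in a leaf label (prefix before first '|')."""
    return label.split("|", 1)[0]


# ---------------------------------------------------------------------------
# Tree data model
# ---------------------------------------------------------------------------


class Node:
    """A node of a rooted tree.

    ``length`` is the branch length to the parent (ignored for the root).
    Leaves carry a ``label``; internal labels are preserved but never used for
    clade assignment.
    """

    __slots__ = ("parent", "children", "length", "label")

    def __init__(
        self,
        label: Optional[str] = None,
        length: float = 0.0,
        children: Optional[list["Node"]] = None,
    ):
        self.label = label
        self.length = float(length)
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        for child in children or []:
            self.add_child(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} L={self.length:g}>"


class RootedTree:
    """Rooted tree with branch lengths; multifurcations permitted."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf)

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        labels: set[str] = set()
        seen: set[int] = set()
        for node in self.preorder():
            if id(node) in seen:
                raise ValueError("cycle detected in tree")
            seen.add(id(node))
            if node is not self.root and node.parent is None:
                raise ValueError("non-root node without parent")
            if not (node.length >= 0.0) or node.length != node.length:
                raise ValueError(f"invalid branch length {node.length!r}")
            if node.is_leaf:
                if node.label is None:
                    raise ValueError("unlabelled leaf")
                if node.label in labels:
                    raise ValueError(f"duplicate leaf label {node.label!r}")
                labels.add(node.label)

    def copy(self) -> "RootedTree":
        def _copy(node: Node) -> Node:
            clone = Node(label=node.label, length=node.length)
            for child in node.children:
                clone.add_child(_copy(child))
            return clone

        return RootedTree(_copy(self.root))

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given leaf labels."""
        wanted = set(labels)
        if not wanted:
            raise ValueError("mrca of empty label set")
        counts: dict[int, int] = {}
        node_by_id: dict[int, Node] = {}
        for node in self.postorder():
            node_by_id[id(node)] = node
            if node.is_leaf:
                counts[id(node)] = 1 if node.label in wanted else 0
            else:
                counts[id(node)] = sum(counts[id(c)] for c in node.children)
        total = counts[id(self.root)]
        if total < len(wanted):
            missing = wanted - set(self.leaf_labels())
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        for node in self.postorder():
            if counts[id(node)] == len(wanted):
                return node
        return self.root  # pragma: no cover - unreachable

    def suppress_unifurcations(self) -> None:
        """Splice out degree-2 internal nodes, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in self.nodes():
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    child.parent = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    child.length += node.length
                    child.parent = parent
                    parent.children[idx] = child
                changed = True
                break

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<RootedTree n_leaves={self.n_leaves}>"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Quoted labels are handled by the parser; underscores in unquoted labels
    are kept literal (genome ids routinely contain them).  Missing branch
    lengths default to 0.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def _convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length or 0.0)
        for dchild in dnode.child_nodes():
            node.add_child(_convert(dchild))
        return node

    return RootedTree(_convert(dtree.seed_node))


def _format_label(label: Optional[str]) -> str:
    if label is None:
        return ""
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: RootedTree) -> str:
    """Serialize a tree to Newick; branch lengths kept to >= 6 significant
    digits, zero lengths written explicitly."""

    def _serialize(node: Node) -> str:
        if node.is_leaf:
            body = _format_label(node.label)
        else:
            inner = ",".join(_serialize(c) for c in node.children)
            body = f"({inner}){_format_label(node.label)}"
        return f"{body}:{node.length:.8g}"

    return _serialize(tree.root) + ";"


def read_tree(path) -> RootedTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_tree(tree: RootedTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


@dataclass
class CladeMap:
    """genome_id -> clade_id assignment."""

    entries: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, genome: str) -> str:
        return self.entries[genome]

    def get(self, genome: str, default=None):
        return self.entries.get(genome, default)

    def __contains__(self, genome: str) -> bool:
        return genome in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def clades(self) -> set[str]:
        return set(self.entries.values())

    def genomes_in(self, clade: str) -> set[str]:
        return {g for g, c in self.entries.items() if c == clade}

    @classmethod
    def from_tsv(cls, path) -> "CladeMap":
        df = _read_tsv(path, ["genome_id", "clade_id"])
        dup = df["genome_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate genome_id rows in clade map: "
                f"{sorted(df.loc[dup, 'genome_id'].unique())}"
            )
        return cls(dict(zip(df["genome_id"], df["clade_id"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.entries.items()), columns=["genome_id", "clade_id"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MembershipTable:
    """(genome_id, gene_id, cluster_id) records; a genome may contribute
    several genes (paralogs) to one cluster, but a gene_id occurs at most once
    per genome."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        for genome, gene, _cluster in self.records:
            key = (genome, gene)
            if key in seen:
                raise ValueError(f"duplicate (genome, gene) row: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _, _ in self.records}

    @property
    def clusters(self) -> set[str]:
        return {c for _, _, c in self.records}

    @classmethod
    def from_tsv(cls, path) -> "MembershipTable":
        df = _read_tsv(path, ["genome_id", "gene_id", "cluster_id"])
        return cls(list(df.itertuples(index=False, name=None)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.records, columns=["genome_id", "gene_id", "cluster_id"]
        ).to_csv(path, sep="\t", index=False)


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df[columns]


def read_tables(membership_path, clade_path) -> tuple[MembershipTable, CladeMap]:
    """Read the membership and clade-map TSVs; genomes present in membership
    but absent from the clade map are reported as warnings (they are excluded
    from clade statistics downstream)."""
    membership = MembershipTable.from_tsv(membership_path)
    clades = CladeMap.from_tsv(clade_path)
    unmapped = sorted(membership.genomes - set(clades.entries))
    if unmapped:
        logger.warning(
            "%d genome(s) in membership table lack a clade assignment and are "
            "excluded from clade statistics: %s",
            len(unmapped),
            ", ".join(unmapped[:10]) + ("..." if len(unmapped) > 10 else ""),
        )
    return membership, clades


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """Protein multiple alignment: parallel lists of labels and equal-length
    gapped rows."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(widths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def take_columns(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        return Alignment(
            list(self.labels), ["".join(row[j] for j in idx) for row in self.rows]
        )

    def take_rows(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        return Alignment([self.labels[i] for i in idx], [self.rows[i] for i in idx])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not labels:
            raise ValueError(f"no sequences in {path}")
        return cls(labels, rows)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(row), id=label, description="")
            for label, row in zip(self.labels, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        for label, row in zip(self.labels, self.rows):
            buf.write(f">{label}\n{row}\n")
        return buf.getvalue()
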