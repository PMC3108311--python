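"""Rooted phylogenetic trees, community assignments, and per-branch tallies.

The tree model is a flat array representation (parent pointers + branch
lengths in postorder) chosen so that the per-branch descendant counts
needed by the UniFrac family can be accumulated in a single postorder
pass, and re-accumulated cheaply for thousands of label permutations.

Newick reading and writing are delegated to scikit-bio; the arrays here
are a view of the same rooted topology.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import skbio

__all__ = [
    "NewickError",
    "ValidationError",
    "PhyloTree",
    "CommunityAssignment",
    "BranchTallySet",
    "parse_newick",
    "write_newick",
    "leaf_root_distances",
    "branch_tallies",
    "read_community_table",
    "write_community_table",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a tree or assignment violates a structural invariant."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree with branch lengths, stored as parent-pointer arrays.

    Nodes are indexed ``0 .. n_nodes-1`` in postorder (children before
    parents, root last).  ``parent[v]`` is the parent index (``-1`` for the
    root) and ``length[v]`` is the length of the branch *above* node ``v``
    (undefined, stored as 0, for the root).  Every non-root node therefore
    corresponds to exactly one branch; the synthetic edge above the root is
    not counted as a branch.
    """

    parent: np.ndarray
    length: np.ndarray
    names: tuple
    _leaf_index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.intp)
        length = np.asarray(self.length, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "length", length)
        if parent.shape != length.shape or parent.ndim != 1:
            raise ValidationError("parent and length arrays must be 1-D and equal length")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1 or roots[0] != parent.size - 1:
            raise ValidationError("exactly one root required, stored last in postorder")
        if np.any(parent[:-1] <= np.arange(parent.size - 1)):
            raise ValidationError("nodes must be in postorder (every parent after its children)")
        if not np.all(np.isfinite(length[:-1])):
            raise ValidationError("branch lengths must be finite")
        leaf_index = {}
        for v in self.leaf_nodes():
            name = self.names[v]
            if name is None:
                raise ValidationError(f"leaf node {v} has no label")
            if name in leaf_index:
                raise ValidationError(f"duplicate leaf label {name!r}")
            leaf_index[name] = v
        object.__setattr__(self, "_leaf_index", leaf_index)

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_branches(self) -> int:
        """Number of branches (edges); the root's synthetic edge is excluded."""
        return self.n_nodes - 1

    def leaf_nodes(self) -> np.ndarray:
        """Indices of leaves (nodes that are nobody's parent)."""
        is_parent = np.zeros(self.n_nodes, dtype=bool)
        is_parent[self.parent[:-1]] = True
        return np.flatnonzero(~is_parent)

    @property
    def leaf_names(self) -> list:
        return [self.names[v] for v in self.leaf_nodes()]

    @property
    def n_leaves(self) -> int:
        return self.leaf_nodes().size

    def leaf_node(self, name: str) -> int:
        try:
            return self._leaf_index[name]
        except KeyError:
            raise ValidationError(f"unknown leaf label {name!r}") from None

    # -- measures ----------------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root depth 0)."""
        depth = np.zeros(self.n_nodes)
        # parents come after children in postorder, so walk from the root down
        for v in range(self.n_nodes - 2, -1, -1):
            depth[v] = depth[self.parent[v]] + self.length[v]
        return depth

    def clamp_negative_lengths(self) -> "PhyloTree":
        """Return a copy with negative branch lengths set to zero."""
        return PhyloTree(self.parent.copy(), np.maximum(self.length, 0.0), self.names)

    # -- conversion --------------------------------------------------------

    def to_skbio(self) -> skbio.TreeNode:
        nodes = [skbio.TreeNode(name=self.names[v]) for v in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            nodes[v].length = float(self.length[v])
            nodes[self.parent[v]].append(nodes[v])
        return nodes[self.root]

    @classmethod
    def from_skbio(cls, root: skbio.TreeNode, allow_negative: bool = False) -> "PhyloTree":
        order = list(root.postorder(include_self=True))
        index = {id(node): i for i, node in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.intp)
        length = np.zeros(n)
        names = []
        for i, node in enumerate(order):
            names.append(node.name)
            if node.parent is not None:
                parent[i] = index[id(node.parent)]
                if node.length is None:
                    raise ValidationError(
                        f"branch above node {node.name or '<unnamed>'} has no length"
                    )
                length[i] = float(node.length)
                if length[i] < 0 and not allow_negative:
                    raise ValidationError(
                        f"negative branch length {length[i]} above node "
                        f"{node.name or '<unnamed>'}; pass allow_negative=True to keep it"
                    )
        return cls(parent, length, tuple(names))

    def shear(self, leaf_names: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to the given leaves.

        Internal nodes left with a single child are collapsed and their
        branch lengths summed, so the result covers exactly the subtree
        spanned by the kept leaves (plus the original root).
        """
        keep = list(leaf_names)
        for name in keep:
            self.leaf_node(name)  # validates
        sheared = self.to_skbio().shear(keep)
        sheared.prune()
        # shear can leave the root with a stray length
        sheared.length = None
        return PhyloTree.from_skbio(sheared, allow_negative=True)


def parse_newick(text: str, allow_negative: bool = False) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are required on every non-root edge.  Negative lengths
    are rejected unless ``allow_negative`` is set (neighbor joining can
    legitimately produce them).
    """
    try:
        root = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise NewickError(f"malformed Newick string: {exc}") from exc
    return PhyloTree.from_skbio(root, allow_negative=allow_negative)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick with full-precision branch lengths."""

    def emit(v: int, children: list) -> str:
        name = tree.names[v] or ""
        if any(c in name for c in "(),:;[] \t'"):
            name = "'" + name.replace("'", "''") + "'"
        if children[v]:
            inner = ",".join(emit(c, children) for c in children[v])
            label = f"({inner}){name}"
        else:
            label = name
        if tree.parent[v] >= 0:
            label += ":" + repr(float(tree.length[v]))
        return label

    children: list = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes - 1):
        children[tree.parent[v]].append(v)
    return emit(tree.root, children) + ";"


def leaf_root_distances(tree: PhyloTree) -> dict:
    """Map each leaf label to its root-to-leaf path length d_j."""
    depth = tree.node_depths()
    return {tree.names[v]: depth[v] for v in tree.leaf_nodes()}


@dataclass(frozen=True)
class CommunityAssignment:
    """Per-leaf counts of individuals observed in communities A and B.

    ``counts`` maps a leaf label to ``(alpha_j, beta_j)`` — how many times
    that leaf's sequence was observed in community A and in community B.
    Counts carry multiplicity: a leaf may represent several identical
    individuals.
    """

    counts: Mapping[str, tuple]
    names: tuple = ("A", "B")

    def __post_init__(self):
        clean = {}
        for leaf, (a, b) in self.counts.items():
            a, b = int(a), int(b)
            if a < 0 or b < 0:
                raise ValidationError(f"negative count for leaf {leaf!r}")
            if a or b:
                clean[str(leaf)] = (a, b)
        object.__setattr__(self, "counts", clean)
        if len(self.names) != 2 or self.names[0] == self.names[1]:
            raise ValidationError("exactly two distinct community names required")

    @classmethod
    def from_counts(
        cls,
        a_counts: Mapping[str, int],
        b_counts: Mapping[str, int],
        names: tuple = ("A", "B"),
    ) -> "CommunityAssignment":
        leaves = set(a_counts) | set(b_counts)
        return cls(
            {leaf: (a_counts.get(leaf, 0), b_counts.get(leaf, 0)) for leaf in leaves},
            names=names,
        )

    @property
    def a_total(self) -> int:
        return sum(a for a, _ in self.counts.values())

    @property
    def b_total(self) -> int:
        return sum(b for _, b in self.counts.values())

    @property
    def n_occupied_leaves(self) -> int:
        """n': the number of distinct leaves carrying any individual."""
        return len(self.counts)

    def validate_for_comparison(self, tree: PhyloTree) -> None:
        if self.a_total < 1 or self.b_total < 1:
            raise ValidationError("each community must contain at least one individual")
        for leaf in self.counts:
            tree.leaf_node(leaf)


@dataclass(frozen=True)
class BranchTallySet:
    """Per-branch sufficient statistics for the UniFrac family.

    One record per branch i: length ``b_i`` and the numbers of individuals
    from each community descending through it (``A_i``, ``B_i``); plus the
    per-leaf records (root distance ``d_j``, counts ``alpha_j``/``beta_j``)
    that the weighted UniFrac denominator needs.
    """

    lengths: np.ndarray  # b_i
    a: np.ndarray  # A_i
    b: np.ndarray  # B_i
    a_total: int
    b_total: int
    leaf_depths: np.ndarray  # d_j over occupied leaves
    leaf_a: np.ndarray  # alpha_j
    leaf_b: np.ndarray  # beta_j

    @property
    def m_i(self) -> np.ndarray:
        return self.a + self.b

    @property
    def m(self) -> int:
        return self.a_total + self.b_total


def branch_tallies(
    tree: PhyloTree, assignment: CommunityAssignment, prune: bool = False
) -> BranchTallySet:
    """Accumulate per-branch descendant counts for a two-community assignment.

    Leaves of the tree absent from the assignment count as (0, 0); with
    ``prune`` they are removed first (collapsing the tree to the compared
    leaves), which changes branch lengths d_j but not the counts.
    """
    assignment.validate_for_comparison(tree)
    if prune:
        tree = tree.shear(list(assignment.counts))
    alpha = np.zeros(tree.n_nodes, dtype=np.int64)
    beta = np.zeros(tree.n_nodes, dtype=np.int64)
    for leaf, (a, b) in assignment.counts.items():
        v = tree.leaf_node(leaf)
        alpha[v] = a
        beta[v] = b
    # postorder accumulation: children precede parents
    for v in range(tree.n_nodes - 1):
        alpha[tree.parent[v]] += alpha[v]
        beta[tree.parent[v]] += beta[v]
    depth = tree.node_depths()
    occupied = np.array([tree.leaf_node(leaf) for leaf in assignment.counts], dtype=np.intp)
    leaf_a = np.array([assignment.counts[leaf][0] for leaf in assignment.counts])
    leaf_b = np.array([assignment.counts[leaf][1] for leaf in assignment.counts])
    return BranchTallySet(
        lengths=tree.length[:-1].copy(),
        a=alpha[:-1].copy(),
        b=beta[:-1].copy(),
        a_total=assignment.a_total,
        b_total=assignment.b_total,
        leaf_depths=depth[occupied],
        leaf_a=leaf_a,
        leaf_b=leaf_b,
    )


# -- community tables ------------------------------------------------------


def read_community_table(source) -> dict:
    """Read a community abundance table (TSV) into {community: {leaf: count}}.

    Two layouts are accepted:

    * long form with header ``leaf_id  community  count``;
    * wide form with header ``leaf_id  <name1>  <name2> ...`` where each
      remaining column holds the counts of one community.
    """
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype=str)
    if df.columns[0] != "leaf_id":
        raise ValidationError("community table must start with a 'leaf_id' column")
    communities: dict = {}
    if list(df.columns[1:3]) == ["community", "count"] and df.shape[1] == 3:
        for row in df.itertuples(index=False):
            leaf, comm, count = row
            communities.setdefault(comm, {})
            communities[comm][leaf] = communities[comm].get(leaf, 0) + _parse_count(count, leaf)
    else:
        for comm in df.columns[1:]:
            communities[comm] = {
                leaf: _parse_count(c, leaf)
                for leaf, c in zip(df["leaf_id"], df[comm])
                if _parse_count(c, leaf) > 0
            }
    if len(communities) < 2:
        raise ValidationError("community table must define at least two communities")
    return communities


def _parse_count(value, leaf) -> int:
    try:
        count = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-integer count {value!r} for leaf {leaf!r}") from None
    if count < 0:
        raise ValidationError(f"negative count for leaf {leaf!r}")
    return count


def write_community_table(communities: Mapping[str, Mapping[str, int]], path) -> None:
    """Write {community: {leaf: count}} as a wide-form TSV."""
    names = list(communities)
    leaves = sorted({leaf for c in communities.values() for leaf in c})
    with open(path, "w") as fh:
        fh.write("leaf_id\t" + "\t".join(names) + "\n")
        for leaf in leaves:
            row = [str(communities[c].get(leaf, 0)) for c in names]
            fh.write(leaf + "\t" + "\t".join(row) + "\n")
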