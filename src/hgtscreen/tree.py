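"""Light-weight phylogenetic trees: topology, Newick I/O, bipartitions, NJ.

Trees are stored rooted for traversal purposes; an "unrooted" tree is simply
one whose root has three children (the standard unrooted-binary convention).
Reversible-model likelihoods do not depend on root placement, so rerooting is
a purely structural operation here.
"""

from __future__ import annotations

import io
import itertools
from typing import Iterable, Iterator

import dendropy
import numpy as np
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor


class Node:
    __slots__ = ("name", "children", "parent", "length", "support")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support: int | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length:.4g}, deg={len(self.children)})"


class Tree:
    """A rooted container for (possibly unrooted-semantics) binary trees."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        return cls(_from_dendropy(dt.seed_node))

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def copy(self) -> "Tree":
        return Tree(_copy_node(self.root))

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> list[Node]:
        """Child nodes of internal edges (both endpoints internal)."""
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and n.parent is not None
        ]

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    # -- serialisation -----------------------------------------------------

    def to_newick(self, support: bool = False, precision: int = 10) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.{precision}g}"
            inner = ",".join(fmt(c) for c in n.children)
            lab = ""
            if support and n.support is not None:
                lab = str(int(n.support))
            if n.parent is None:
                return f"({inner}){lab}"
            return f"({inner}){lab}:{n.length:.{precision}g}"

        return fmt(self.root) + ";"

    def write(self, path, support: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(support=support) + "\n")

    # -- unrooted semantics ------------------------------------------------

    def unroot(self) -> "Tree":
        """Collapse a degree-2 root so the root has three children."""
        t = self.copy()
        while len(t.root.children) == 2:
            a, b = t.root.children
            keep, merge = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                break  # two-leaf tree; nothing to do
            keep.length += merge.length
            # make `keep` the new root, attach `merge` under it
            keep.parent = None
            merge.parent = keep
            keep.children.append(merge)
            merge.length = keep.length
            keep.length = 0.0
            t.root = keep
        return t

    def reroot_at(self, node: Node) -> None:
        """Make ``node`` (an internal node of this tree) the traversal root."""
        if node is self.root:
            return
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent
        # reverse parent-child along the path
        for child, parent in zip(reversed(path[:-1]), reversed(path[1:])):
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
            parent.length = child.length
        node.parent = None
        node.length = 0.0
        old_root = path[-1]
        if len(old_root.children) == 1 and not old_root.is_leaf:
            # suppress the unifurcation left at the old root
            only = old_root.children[0]
            grand = old_root.parent
            only.length += old_root.length
            only.parent = grand
            grand.children[grand.children.index(old_root)] = only
        self.root = node

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the canonical (lexic. smaller) side."""
        all_leaves = frozenset(self.leaf_names())
        splits = set()
        below: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in n.children))
                below[id(n)] = s
                if n.parent is not None and 1 < len(s) < len(all_leaves) - 1:
                    splits.add(_canon(s, all_leaves))
        return splits

    def is_monophyletic(self, group: Iterable[str]) -> bool:
        group = frozenset(group)
        names = frozenset(self.leaf_names())
        unknown = group - names
        if unknown:
            raise ValueError(f"unknown taxa: {sorted(unknown)}")
        if len(group) <= 1 or group == names:
            return True
        comp = names - group
        if len(comp) <= 1:
            return True
        return _canon(group, names) in self.bipartitions()


def _canon(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def _from_dendropy(dnode) -> Node:
    n = Node()
    if dnode.taxon is not None:
        n.name = dnode.taxon.label.replace(" ", "_")
    elif dnode.label is not None:
        try:
            n.support = int(float(dnode.label))
        except ValueError:
            n.name = dnode.label
    n.length = float(dnode.edge.length or 0.0)
    for c in dnode.child_nodes():
        n.add(_from_dendropy(c))
    return n


def _copy_node(src: Node) -> Node:
    n = Node(src.name, src.length)
    n.support = src.support
    for c in src.children:
        n.add(_copy_node(c))
    return n


# ---------------------------------------------------------------------------
# distances and neighbor joining


def poisson_distance_matrix(ids: list[str], rows: list[str], cap: float = 10.0):
    """Poisson-corrected protein distances d = -ln(1 - p) per pair.

    Pairs at or beyond p = 0.95 are capped at ``cap`` (saturation).  Columns
    where either sequence is a gap or 'X' are excluded pairwise.
    Returns an (n, n) ndarray.
    """
    import warnings

    n = len(ids)
    arr = np.array([list(r.upper()) for r in rows])
    valid = (arr != "-") & (arr != "X")
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        m = both.sum()
        p = float((arr[i][both] != arr[j][both]).sum() / m) if m else 0.0
        if p >= 0.95:
            warnings.warn(f"saturated pair ({ids[i]}, {ids[j]}); distance capped")
            d = cap
        else:
            d = -np.log(1.0 - p)
        D[i, j] = D[j, i] = d
    return D


def neighbor_joining(ids: list[str], D: np.ndarray) -> Tree:
    """NJ tree from a distance matrix; negative branch lengths clamped to 0."""
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    lower = [[float(D[i, j]) for j in range(i + 1)] for i in range(len(ids))]
    bio_dm = _BioDM(names=list(ids), matrix=lower)
    bio_tree = DistanceTreeConstructor().nj(bio_dm)
    buf = io.StringIO()
    from Bio import Phylo

    Phylo.write(bio_tree, buf, "newick")
    t = Tree.from_newick(buf.getvalue())
    for n in t.postorder():
        if not n.is_leaf:
            n.name = None  # drop Bio.Phylo "InnerN" labels
        if n.length < 0:
            n.length = 0.0
    return t.unroot()
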