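"""Phylogenetic tree container: Newick round-trip, bipartitions, rooting.

A tree is a recursive :class:`Clade` structure under a :class:`PhyloTree`
wrapper.  Unrooted trees are stored with a degree-3 "root surrogate" (the
standard unrooted representation); rooted trees have a degree-2 root.
Bootstrap supports are integer percentages attached to internal nodes and,
conceptually, to the bipartition the node's edge induces — rooting moves
nodes around but keeps supports on the same bipartitions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import numpy as np


class Clade:
    """One tree node: a leaf (named) or an internal node (optional support)."""

    __slots__ = ("name", "branch_length", "support", "children")

    def __init__(self, name: str | None = None,
                 branch_length: float | None = None,
                 support: int | None = None,
                 children: Iterable["Clade"] = ()):
        self.name = name
        self.branch_length = branch_length
        self.support = support
        self.children = list(children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Clade"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list["Clade"]:
        return [n for n in self.walk() if n.is_leaf]

    def copy(self) -> "Clade":
        return Clade(self.name, self.branch_length, self.support,
                     [c.copy() for c in self.children])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Clade({self.name!r}, bl={self.branch_length}, " \
               f"n_children={len(self.children)})"


class PhyloTree:
    """A rooted or unrooted tree over uniquely labelled leaves."""

    def __init__(self, root: Clade, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = [l.name for l in root.leaves()]
        if any(n is None for n in names):
            raise ValueError("unnamed leaf")
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")

    # -- basic accessors ----------------------------------------------------

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def sort(self) -> "PhyloTree":
        """Canonically order children (by smallest descendant leaf name)."""

        def key(c: Clade) -> str:
            return min(l.name for l in c.leaves())

        for node in self.root.walk():
            node.children.sort(key=key)
        return self

    # -- bipartitions -------------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial splits, each canonicalized to the side *not* containing
        the lexicographically smallest leaf."""
        return set(self.bipartition_supports().keys())

    def bipartition_supports(self) -> dict[frozenset, int | None]:
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        n = len(all_leaves)
        out: dict[frozenset, int | None] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(l.name for l in node.leaves())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                out[side] = node.support
        return out

    # -- path lengths -------------------------------------------------------

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """All-pairs leaf-to-leaf path lengths (labels sorted)."""
        labels = self.leaf_names()
        idx = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def down(node: Clade) -> dict[int, float]:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            merged: dict[int, float] = {}
            groups = []
            for child in node.children:
                sub = down(child)
                bl = child.branch_length or 0.0
                sub = {k: v + bl for k, v in sub.items()}
                groups.append(sub)
                merged.update(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            d[a, b] = d[b, a] = da + db
            return merged

        down(self.root)
        return labels, d

    # -- newick -------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                if not node.name:
                    raise ValueError("unnamed leaf")
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    label += str(int(node.support))
            if node.branch_length is not None:
                label += f":{node.branch_length:.6f}"
            return label

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={len(self.leaf_names())}, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# Newick file I/O (writer is ours; reading goes through dendropy)
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write Newick with 6-decimal branch lengths and integer support labels."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(source: str | Path) -> PhyloTree:
    """Read a Newick tree (file path or literal string)."""
    text = source if str(source).strip().endswith(";") else Path(source).read_text()
    dtree = dendropy.Tree.get(data=str(text), schema="newick",
                              preserve_underscores=True)

    def convert(dnode) -> Clade:
        if not dnode.child_nodes():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            return Clade(name=name, branch_length=dnode.edge.length)
        support = None
        if dnode.label is not None:
            try:
                support = int(float(dnode.label))
            except ValueError:
                pass
        return Clade(branch_length=dnode.edge.length, support=support,
                     children=[convert(c) for c in dnode.child_nodes()])

    root = convert(dtree.seed_node)
    return PhyloTree(root, rooted=len(root.children) == 2)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _adjacency(root: Clade):
    """Undirected view: node -> list of (neighbor, length, support).

    The support stored on a child node is treated as a property of the edge
    above it, so it survives re-orientation.
    """
    adj: dict[int, list] = {}
    nodes: dict[int, Clade] = {}

    def add(a: Clade, b: Clade, bl: float | None, sup: int | None) -> None:
        adj.setdefault(id(a), []).append((b, bl, sup))
        adj.setdefault(id(b), []).append((a, bl, sup))
        nodes[id(a)] = a
        nodes[id(b)] = b

    def visit(node: Clade) -> None:
        for child in node.children:
            add(node, child, child.branch_length, child.support)
            visit(child)

    nodes[id(root)] = root
    adj.setdefault(id(root), [])
    visit(root)
    return adj, nodes


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a degree-2 root into the standard degree-3 surrogate."""
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        return PhyloTree(root, rooted=False)
    a, b = root.children
    # absorb the rooted edge into one child; prefer an internal node as the
    # new surrogate so the result is degree-3
    keep, other = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        raise ValueError("cannot unroot a 2-leaf tree")
    merged_bl = (a.branch_length or 0.0) + (b.branch_length or 0.0)
    sup = keep.support if keep.support is not None else other.support
    other.branch_length = merged_bl
    other.support = sup
    new_root = Clade(children=keep.children + [other])
    return PhyloTree(new_root, rooted=False)


def root_with_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root at the midpoint of the outgroup's pendant edge.

    Supports are preserved on the bipartitions they annotated in the unrooted
    tree.
    """
    if outgroup_label not in tree.leaf_names():
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf")
    base = unroot(tree) if tree.rooted else tree.copy()
    adj, _ = _adjacency(base.root)
    leaf = next(l for l in base.root.leaves() if l.name == outgroup_label)
    (neighbor, bl, sup), = adj[id(leaf)]
    half = (bl or 0.0) / 2.0

    def orient(node: Clade, parent: Clade) -> Clade:
        out = Clade(name=node.name)
        for nb, ebl, esup in adj[id(node)]:
            if nb is parent:
                continue
            child = orient(nb, node)
            child.branch_length = ebl
            child.support = esup
            out.children.append(child)
        return out

    og = Clade(name=outgroup_label, branch_length=half)
    ingroup = orient(neighbor, leaf)
    ingroup.branch_length = half
    ingroup.support = sup
    return PhyloTree(Clade(children=[og, ingroup]), rooted=True).sort()


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    """True iff the unrooted topologies agree (identical leaf and split sets)."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return a.bipartitions() == b.bipartitions()


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson–Foulds distance (symmetric split difference)."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise ValueError("trees have different leaf sets")
    return len(a.bipartitions() ^ b.bipartitions())
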