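"""Rooted time trees and gene-family trees.

Two tree flavours are used throughout the package:

``DatedTree``
    A rooted, strictly bifurcating, ultrametric species phylogeny whose nodes
    carry absolute ages in millions of years before present (Mya).  Leaves sit
    at age 0 (extant-only sampling); every internal node is strictly older
    than its children.  Branch lengths in newick output encode time spans in
    Myr, so the tree round-trips through any standard newick reader.

``GeneTree``
    A rooted binary topology whose leaves are labelled with species-tree taxon
    names (labels may repeat: one leaf per gene copy).  No ages are attached;
    gene trees are placed in time by reconciliation, not by their branch
    lengths.  A gene tree may carry a set of bootstrap replicate topologies.

Newick parsing is delegated to :mod:`dendropy`; writing is done by a small
deterministic serializer so that identical trees always produce identical
bytes.
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Iterator, Optional, Sequence

import dendropy

__all__ = ["TreeNode", "DatedTree", "GeneTree", "robinson_foulds"]


class TreeNode:
    """A node in a rooted binary tree."""

    __slots__ = ("parent", "children", "label", "age", "id")

    def __init__(self, label: Optional[str] = None, age: Optional[float] = None):
        self.parent: Optional["TreeNode"] = None
        self.children: list["TreeNode"] = []
        self.label = label
        self.age = age
        self.id: Optional[str] = None

    # -- structure -------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        new = TreeNode(self.label, self.age)
        new.id = self.id
        for child in self.children:
            new.add_child(child.copy())
        return new


class _BaseTree:
    def __init__(self, root: TreeNode):
        self.root = root

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    @property
    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def _assign_ids(self) -> None:
        """Leaves take their label as id; internal nodes get 'n<k>' in postorder."""
        k = 0
        for node in self.postorder():
            if node.is_leaf:
                node.id = node.label
            else:
                node.id = f"n{k}"
                k += 1

    def node_by_id(self, node_id: str) -> TreeNode:
        for node in self.postorder():
            if node.id == node_id:
                return node
        raise KeyError(f"no node with id {node_id!r}")

    def mrca(self, labels: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the leaves carrying ``labels``."""
        want = set(labels)
        seen = {n.label for n in self.leaves}
        missing = want - seen
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        below: dict[int, set[str]] = {}
        best = None
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label}
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if best is None and want <= below[id(node)]:
                best = node
        assert best is not None
        return best


class DatedTree(_BaseTree):
    """Rooted ultrametric chronogram with node ages in Mya."""

    def __init__(self, root: TreeNode):
        super().__init__(root)
        self._assign_ids()

    # -- invariants ------------------------------------------------------
    def validate(self, tol: float = 1e-9) -> None:
        """Raise ``ValueError`` if any chronogram invariant is violated."""
        if self.root.parent is not None:
            raise ValueError("root must have no parent")
        for node in self.postorder():
            if node.is_leaf:
                if abs(node.age) > tol:
                    raise ValueError(f"leaf {node.label!r} not at age 0 (got {node.age})")
            else:
                if len(node.children) != 2:
                    raise ValueError("internal nodes must be binary")
                for child in node.children:
                    if child.parent is not node:
                        raise ValueError("broken parent link")
                    if not node.age > child.age:
                        raise ValueError(
                            f"node {node.id} (age {node.age}) not strictly older "
                            f"than child {child.id} (age {child.age})"
                        )

    @property
    def root_age(self) -> float:
        return float(self.root.age)

    @property
    def taxa(self) -> set[str]:
        return set(self.leaf_labels)

    def branches(self) -> list[TreeNode]:
        """Every branch, identified by its child node (root excluded)."""
        return [n for n in self.postorder() if n.parent is not None]

    def branches_alive_at(self, age: float) -> list[TreeNode]:
        """Branches whose time span strictly contains ``age``."""
        return [
            n for n in self.branches() if n.age < age < n.parent.age
        ]

    def copy(self) -> "DatedTree":
        return DatedTree(self.root.copy())

    # -- newick ----------------------------------------------------------
    def to_newick(self, decimals: int = 8) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return body
            length = node.parent.age - node.age
            return f"{body}:{length:.{decimals}f}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, rel_tol: float = 1e-6) -> "DatedTree":
        """Parse a newick chronogram; branch lengths are time spans in Myr.

        Leaf depths must agree (ultrametricity) within ``rel_tol`` of the
        root age; leaf ages are then snapped to exactly 0.
        """
        dtree = dendropy.Tree.get(data=text, schema="newick")
        root = _from_dendropy(dtree.seed_node)
        # depths from root
        depths: dict[TreeNode, float] = {root: 0.0}
        stack = [root]
        order = []
        while stack:
            node = stack.pop()
            order.append(node)
            for child in node.children:
                depths[child] = depths[node] + child.age  # age temporarily = edge length
                stack.append(child)
        height = max(depths[n] for n in order if n.is_leaf)
        if height <= 0:
            raise ValueError("tree has zero height; cannot be a chronogram")
        for node in order:
            if node.is_leaf:
                if abs(depths[node] - height) > rel_tol * height:
                    raise ValueError(
                        f"tree is not ultrametric: leaf {node.label!r} at depth "
                        f"{depths[node]} vs height {height}"
                    )
                node.age = 0.0
            else:
                node.age = height - depths[node]
        tree = cls(root)
        tree.validate(tol=rel_tol * height)
        return tree


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label.replace(" ", "_")
    elif dnode.label:
        label = dnode.label
    node = TreeNode(label=label)
    node.age = dnode.edge.length if dnode.edge.length is not None else 0.0
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild))
    return node


class GeneTree(_BaseTree):
    """Rooted binary gene-family tree; leaf labels are species taxon names."""

    def __init__(self, root: TreeNode, rooted: bool = True,
                 bootstraps: Optional[list["GeneTree"]] = None):
        super().__init__(root)
        self.rooted = rooted
        self.bootstraps = bootstraps or []
        self._assign_ids()

    def validate(self, species: Optional[DatedTree] = None) -> None:
        if not self.leaves:
            raise ValueError("gene tree must have at least one leaf")
        for node in self.postorder():
            if not node.is_leaf and len(node.children) != 2:
                raise ValueError("gene tree must be binary")
        if species is not None:
            unknown = set(self.leaf_labels) - species.taxa
            if unknown:
                raise ValueError(f"gene leaves not in species tree: {sorted(unknown)}")

    @property
    def leaf_multiset(self) -> Counter:
        return Counter(self.leaf_labels)

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), rooted=self.rooted,
                        bootstraps=[b.copy() for b in self.bootstraps])

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            return "(" + ",".join(fmt(c) for c in node.children) + ")"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "GeneTree":
        # leaf labels may repeat (paralogs), so parse them as plain labels
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  suppress_leaf_node_taxa=True)
        return cls(_from_dendropy(dtree.seed_node), rooted=rooted)

    @classmethod
    def from_multi_newick(cls, text: str, rooted: bool = True) -> "GeneTree":
        """Read a multi-tree newick: the first tree is the gene tree, any
        further trees become its bootstrap replicate set."""
        dtrees = dendropy.TreeList.get(data=text, schema="newick",
                                       suppress_internal_node_taxa=True,
                                       suppress_leaf_node_taxa=True)
        if not dtrees:
            raise ValueError("no trees in newick input")
        trees = [cls(_from_dendropy(t.seed_node), rooted=rooted) for t in dtrees]
        main = trees[0]
        main.bootstraps = trees[1:]
        return main

    # -- rerooting -------------------------------------------------------
    def all_rootings(self) -> list["GeneTree"]:
        """One rooted tree per edge of the unrooted topology.

        The first entry is the tree itself; rerooting on either edge incident
        to the current root reproduces it, so one of the two is skipped.
        """
        out = [self.copy()]
        if len(self.leaves) < 3:
            return out
        nodes = list(self.postorder())
        skip = set(self.root.children)  # rerooting on either edge duplicates the input
        for idx, node in enumerate(nodes):
            if node.parent is None or node in skip:
                continue
            out.append(self.rerooted_at(idx))
        return out

    def rerooted_at(self, node_index: int) -> "GeneTree":
        """Reroot on the edge above the node at postorder position ``node_index``."""
        clone = self.root.copy()
        nodes = list(TreeNode.postorder(clone))
        target = nodes[node_index]
        if target.parent is None:
            return GeneTree(clone, rooted=True)
        new_root = TreeNode()
        # detach target from its parent; hang the reversed remainder beside it
        parent = target.parent
        parent.children.remove(target)
        target.parent = None
        rest = _reverse_path(parent)
        new_root.add_child(target)
        new_root.add_child(rest)
        return GeneTree(new_root, rooted=True)


def _reverse_path(node: TreeNode) -> TreeNode:
    """Reverse parent pointers from ``node`` up to the old root, suppressing
    the unary node the old root becomes."""
    parent = node.parent
    node.parent = None
    if parent is not None:
        parent.children.remove(node)
        flipped = _reverse_path(parent)
        node.children.append(flipped)
        flipped.parent = node
    # suppress unary nodes created at the old root
    if len(node.children) == 1:
        only = node.children[0]
        only.parent = None
        return only
    return node


def robinson_foulds(a: GeneTree, b: GeneTree) -> int:
    """Unrooted Robinson–Foulds distance for trees with unique leaf labels."""

    def splits(tree: GeneTree) -> set[frozenset]:
        labels = set(tree.leaf_labels)
        if len(labels) != len(tree.leaf_labels):
            raise ValueError("RF distance requires unique leaf labels")
        out = set()
        for node in tree.postorder():
            if node.is_leaf or node.parent is None:
                continue
            below = frozenset(n.label for n in node.leaves())
            if 1 < len(below) < len(labels) - 1:
                out.add(frozenset((below, frozenset(labels - below))))
        return out

    sa, sb = splits(a), splits(b)
    return len(sa ^ sb)
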