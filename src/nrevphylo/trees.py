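"""Rooted phylogenetic trees with branch lengths.

A lightweight node/tree structure used by the likelihood engine, the
simulator, and the tree-search code.  Newick parsing and writing are
delegated to dendropy; this class exists so that inner loops (pruning,
branch-length optimization, NNI rearrangement) can manipulate a minimal,
copyable structure.

Branch lengths are in expected substitutions per site.  The root carries no
branch length (``length`` of the root is ignored and kept at 0).
"""

from __future__ import annotations

import io
from typing import Callable, Iterator

import dendropy

__all__ = ["TreeNode", "RootedTree", "TreeError"]


class TreeError(ValueError):
    pass


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or ''} {kind} len={self.length:g}>"


class RootedTree:
    """A rooted tree; the root normally has exactly two children."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.root.length = 0.0

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes; each owns the branch to its parent."""
        return [n for n in self.postorder() if n is not self.root]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    # -- copying / scaling -------------------------------------------------
    def copy(self) -> "RootedTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return RootedTree(clone(self.root))

    def scaled(self, factor: float) -> "RootedTree":
        out = self.copy()
        for node in out.branches():
            node.length *= factor
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise TreeError("duplicate leaf labels")
        if any(n is None for n in names):
            raise TreeError("unlabelled leaf")
        for node in self.branches():
            if node.length < 0:
                raise TreeError(f"negative branch length on {node.name or 'internal'}")

    # -- Newick via dendropy -----------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "RootedTree":
        def convert(dnode: dendropy.Node) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon is not None else None
            node = TreeNode(name, dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(tree.seed_node))

    def to_dendropy(self) -> dendropy.Tree:
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)

        def convert(node: TreeNode, dnode: dendropy.Node) -> None:
            dnode.edge.length = node.length
            if node.is_leaf:
                dnode.taxon = ns.require_taxon(label=node.name)
            for child in node.children:
                convert(child, dnode.new_child())

        convert(self.root, tree.seed_node)
        tree.seed_node.edge.length = None
        tree.is_rooted = True
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        ).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RootedTree {self.n_leaves()} leaves>"
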