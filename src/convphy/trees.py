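"""Rooted phylogenetic trees with branch lengths.

A thin mutable tree structure tailored to likelihood computation:
every node is addressable, branch lengths are in expected
substitutions per site, and the topology is kept strictly binary
(polytomies are rejected by default, or resolved with zero-length
branches on request).  Newick parsing is delegated to dendropy;
serialization is a direct recursive write.
"""

from __future__ import annotations

import io
from typing import Iterator, Optional, Sequence

import dendropy


class TreeError(ValueError):
    """Raised for malformed or unusable tree inputs."""


class Node:
    __slots__ = ("name", "length", "parent", "children", "label")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        # free-form annotation slot (e.g. foreground flag for codon models)
        self.label: Optional[str] = None

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

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name or '<internal>'}, t={self.length:g})"


class PhyloTree:
    """Rooted, binary, branch-length-annotated tree."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # ------------------------------------------------------------------ io

    @classmethod
    def from_newick(cls, text: str, resolve_polytomies: bool = False) -> "PhyloTree":
        """Parse a Newick string into a rooted tree.

        Duplicate leaf names and unbalanced parentheses raise
        :class:`TreeError` naming the offending token.  Polytomies are
        rejected unless ``resolve_polytomies`` is set, in which case they
        are resolved arbitrarily with zero-length branches.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"newick parse error: {exc}") from exc

        seen: set[str] = set()
        for leaf in dtree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon else None
            if not name:
                raise TreeError("leaf without a name in newick input")
            if name in seen:
                raise TreeError(f"duplicate leaf name: {name!r}")
            seen.add(name)

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon else None
            node = Node(name=name, length=dnode.edge.length or 0.0)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        tree = cls.__new__(cls)
        tree.root = root
        if resolve_polytomies:
            tree._resolve_polytomies()
        tree._validate()
        return tree

    def to_newick(self, precision: int = 6) -> str:
        out = io.StringIO()

        def write(node: Node) -> None:
            if node.is_leaf:
                out.write(node.name)
            else:
                out.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(child)
                out.write(")")
            if node.parent is not None:
                out.write(f":{node.length:.{precision}f}")

        write(self.root)
        out.write(";")
        return out.getvalue()

    # ------------------------------------------------------------ structure

    def _validate(self) -> None:
        names = [leaf.name for leaf in self.leaves()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf name: {dup[0]!r}")
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise TreeError(
                    f"polytomy (or unifurcation) at node with {len(node.children)} "
                    "children; resolve or re-root the input tree"
                )
            if node.length < 0 or node.length != node.length:
                raise TreeError(f"negative or non-finite branch length {node.length}")

    def _resolve_polytomies(self) -> None:
        for node in list(self.preorder()):
            while len(node.children) > 2:
                a = node.children.pop()
                b = node.children.pop()
                a.parent = b.parent = None
                merged = Node(length=0.0)
                merged.add_child(a)
                merged.add_child(b)
                node.add_child(merged)
            if len(node.children) == 1:
                only = node.children[0]
                if node.parent is None:
                    only.parent = None
                    self.root = only
                else:
                    parent = node.parent
                    parent.remove_child(node)
                    only.length += node.length
                    parent.add_child(only)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_leaf)

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise TreeError(f"leaf {name!r} not found in tree")

    def mrca(self, names: Sequence[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        paths = []
        for name in names:
            node = self.find_leaf(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        if anc is None:
            raise TreeError("no common ancestor found (disjoint inputs?)")
        return anc

    def is_monophyletic(self, names: Sequence[str]) -> bool:
        mrca = self.mrca(names)
        below = {leaf.name for leaf in _subtree_leaves(mrca)}
        return below == set(names)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(name=node.name, length=node.length)
            new.label = node.label
            for child in node.children:
                new.add_child(clone(child))
            return new

        tree = PhyloTree.__new__(PhyloTree)
        tree.root = clone(self.root)
        return tree

    # ------------------------------------------------------------- editing

    def prune_leaf(self, name: str) -> Node:
        """Remove a leaf, suppressing the resulting unifurcation.

        Returns the node that now subtends the merged branch where the
        leaf was attached (its former sibling).
        """
        leaf = self.find_leaf(name)
        parent = leaf.parent
        if parent is None:
            raise TreeError("cannot prune the root")
        parent.remove_child(leaf)
        sibling = parent.children[0]
        grand = parent.parent
        if grand is None:
            # parent was the root: sibling becomes the new root
            parent.remove_child(sibling)
            sibling.length = 0.0
            self.root = sibling
        else:
            grand.remove_child(parent)
            sibling.length += parent.length
            parent.remove_child(sibling)
            grand.add_child(sibling)
        return sibling

    def attach_on_branch(self, below: Node, subtree: Node,
                         stem_length: float = 0.1) -> Node:
        """Bisect the branch above ``below`` and attach ``subtree`` there."""
        parent = below.parent
        if parent is None:
            raise TreeError("cannot attach above the root")
        parent.remove_child(below)
        knee = Node(length=below.length / 2.0)
        below.length = below.length / 2.0
        parent.add_child(knee)
        knee.add_child(below)
        subtree.length = stem_length
        knee.add_child(subtree)
        return knee

    def scale(self, factor: float) -> "PhyloTree":
        for node in self.preorder():
            if node.parent is not None:
                node.length *= factor
        return self

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n.parent is not None)

    def height(self) -> float:
        """Maximum root-to-leaf path length."""

        def depth(node: Node) -> float:
            if node.is_leaf:
                return 0.0
            return max(c.length + depth(c) for c in node.children)

        return depth(self.root)


def _subtree_leaves(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def parse_newick(text: str, resolve_polytomies: bool = False) -> PhyloTree:
    """Parse a Newick string (convenience wrapper)."""
    return PhyloTree.from_newick(text, resolve_polytomies=resolve_polytomies)
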