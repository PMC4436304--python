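"""Phylogenetic tree container with Newick round-trip, bipartitions and
patristic distances.

Trees are stored rooted (unrooted trees carry a trifurcating root); branch
lengths are non-negative floats and internal nodes may carry an integer-like
bootstrap support in [0, 100], serialised as the Newick internal-node label.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["Node", "Tree", "read_newick", "write_newick"]


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]


class Tree:
    """A rooted or unrooted (trifurcating root) tree over labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.name for n in root.leaves()]
        if any(l is None or l == "" for l in labels):
            raise ValueError("all leaves must be labelled")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        for node in root.walk():
            if node.length is not None:
                if not np.isfinite(node.length):
                    raise ValueError("non-finite branch length")
                if node.length < 0:
                    raise ValueError(f"negative branch length {node.length}")

    # -- basic accessors -------------------------------------------------
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def find_leaf(self, name: str) -> Node:
        for n in self.root.leaves():
            if n.name == name:
                return n
        raise KeyError(name)

    def copy(self) -> "Tree":
        return Tree(parse_newick(self.to_newick()).root)

    # -- Newick ----------------------------------------------------------
    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_support and node.support is not None:
                    s += _fmt_num(node.support)
                elif node.name:
                    s += node.name
            if node.length is not None:
                s += f":{_fmt_num(node.length)}"
            return s

        return fmt(self.root) + ";"

    def canonical_newick(self, include_support: bool = True) -> str:
        """Newick with children sorted by smallest descendant label."""
        t = self.copy()

        def key(node: Node) -> str:
            return min(l.name for l in node.leaves()) if not node.is_leaf else node.name

        for node in t.root.walk():
            node.children.sort(key=key)
        return t.to_newick(include_support=include_support)

    # -- bipartitions ----------------------------------------------------
    def bipartitions(self, with_support: bool = False):
        """Non-trivial unrooted bipartitions.

        Each bipartition is canonicalised as the frozenset of the side NOT
        containing the lexicographically smallest leaf. Returns a set, or a
        dict bipartition -> support when ``with_support`` is true.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, float | None] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(l.name for l in node.leaves())
            if ref in side:
                side = all_leaves - side
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            prev = out.get(side)
            sup = node.support
            if prev is None or (sup is not None and (prev is None or sup > prev)):
                out[side] = sup
        return out if with_support else set(out)

    # -- distances -------------------------------------------------------
    def patristic_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf labels (sorted) and the matrix of path-length distances."""
        # root-to-node distances plus LCA via parent chains; trees are small
        depth: dict[int, float] = {}
        order: dict[int, Node] = {}
        for node in self.root.walk():
            order[id(node)] = node
            parent = node.parent
            d = depth[id(parent)] if parent is not None else 0.0
            depth[id(node)] = d + (node.length or 0.0)
        leaves = sorted(self.root.leaves(), key=lambda n: n.name)
        labels = [n.name for n in leaves]
        n = len(leaves)
        mat = np.zeros((n, n))

        def ancestors(node: Node) -> list[Node]:
            chain = []
            while node is not None:
                chain.append(node)
                node = node.parent
            return chain

        chains = [ancestors(l) for l in leaves]
        chain_sets = [{id(a) for a in c} for c in chains]
        for i in range(n):
            for j in range(i + 1, n):
                lca = next(a for a in chains[i] if id(a) in chain_sets[j])
                d = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * depth[id(lca)]
                mat[i, j] = mat[j, i] = d
        return labels, mat


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".10g")


# -- Newick parsing ------------------------------------------------------


class _NewickParser:
    def __init__(self, text: str):
        self.text = text.strip()
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> Node:
        node = self._node()
        if self.peek() != ";":
            raise ValueError(
                f"newick parse error at position {self.pos}: expected ';' "
                f"(unbalanced parentheses?)"
            )
        return node

    def _node(self) -> Node:
        node = Node()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add(self._node())
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise ValueError(
                    f"newick parse error at position {self.pos}: unbalanced parentheses"
                )
            label = self._label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            name = self._label()
            if not name:
                raise ValueError(f"newick parse error: empty leaf label at {self.pos}")
            node.name = name
        if self.peek() == ":":
            self.pos += 1
            node.length = self._number()
            if node.length < 0:
                raise ValueError(f"negative branch length {node.length}")
        return node

    def _label(self) -> str:
        start = self.pos
        while self.peek() not in ("", ":", ",", ")", ";", "("):
            self.pos += 1
        return self.text[start : self.pos].strip()

    def _number(self) -> float:
        start = self.pos
        while self.peek() not in ("", ",", ")", ";"):
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            return float(token)
        except ValueError as exc:
            raise ValueError(f"bad branch length {token!r}") from exc


def parse_newick(text: str) -> Tree:
    return Tree(_NewickParser(text).parse())


def read_newick(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
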