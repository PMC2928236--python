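"""Phylogenetic trees: a light mutable node tree plus Newick round-tripping.

Trees are stored as node objects with child lists; support values (bootstrap
percentages, decay indices) hang off internal nodes and serialize as internal
node labels, the most portable Newick dialect.  Branch lengths are carried
but ignored by every parsimony operation.  Unrooted trees are addressed
through their bipartitions (splits of the leaf set), canonicalized as the
side not containing the alphabetically first leaf.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterator

import dendropy


class NewickError(ValueError):
    pass


class Node:
    __slots__ = ("name", "children", "parent", "length", "support", "decay", "event")

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support = support
        self.decay = None
        self.event = None  # duplication / speciation tag where relevant

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        c = Node(self.name, self.length, self.support)
        c.decay, c.event = self.decay, self.event
        for ch in self.children:
            c.add(ch.copy())
        return c


class PhyloTree:
    """A rooted or unrooted tree over uniquely labelled leaves."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = [l.name for l in root.leaves()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")

    # -- basics ------------------------------------------------------------
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def is_binary(self) -> bool:
        """Every internal node has 2 children (unrooted trees may have a
        basal trifurcation at the stored root)."""
        for n in self.postorder():
            if n.is_leaf:
                continue
            k = len(n.children)
            if n is self.root:
                ok = k == 2 or (not self.rooted and k == 3)
            else:
                ok = k == 2
            if not ok:
                return False
        return True

    # -- splits ------------------------------------------------------------
    def _ref_leaf(self) -> str:
        return min(self.leaf_names())

    def bipartitions(self, with_support: bool = False):
        """Non-trivial splits of the leaf set (unrooted view).

        Returns a set of frozensets, or with ``with_support`` a dict mapping
        each split to the support stored on its node (``None`` if absent).
        Each split is represented by the side excluding the alphabetically
        first leaf.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = self._ref_leaf()
        out: dict[frozenset, float | None] = {}
        for n in self.postorder():
            if n is self.root or n.is_leaf:
                continue
            below = frozenset(l.name for l in n.leaves())
            side = below if ref not in below else all_leaves - below
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            if side in out and out[side] is not None:
                continue
            out[side] = n.support
        return out if with_support else set(out)

    def clades(self) -> dict[frozenset, Node]:
        """Rooted view: leaf set below each internal non-root node."""
        out = {}
        for n in self.postorder():
            if n.is_leaf or n is self.root:
                continue
            out[frozenset(l.name for l in n.leaves())] = n
        return out

    def has_bipartition(self, side: frozenset) -> bool:
        all_leaves = frozenset(self.leaf_names())
        ref = self._ref_leaf()
        canon = side if ref not in side else all_leaves - side
        return canon in self.bipartitions()

    # -- rooting -----------------------------------------------------------
    def unroot(self) -> "PhyloTree":
        """Collapse a degree-2 root into a basal trifurcation."""
        t = self.copy()
        t.rooted = False
        r = t.root
        if len(r.children) == 2:
            a, b = r.children
            keep, move = (a, b) if not a.is_leaf else (b, a)
            if not keep.is_leaf:
                r.children = list(keep.children) + [move]
                for c in r.children:
                    c.parent = r
                r.support = keep.support
        return t

    def root_on_edge(self, side: frozenset) -> "PhyloTree":
        """Return a rooted copy with the root placed on the edge whose split
        separates ``side`` from the rest of the leaves (``side`` may be a
        single leaf name, rooting on that terminal branch)."""
        t = self.copy()
        all_leaves = frozenset(t.leaf_names())
        if not side or side == all_leaves:
            raise ValueError("split side must be a proper non-empty leaf subset")
        target = None
        for n in t.postorder():
            if n is t.root:
                continue
            below = frozenset(l.name for l in n.leaves())
            if below == side or below == all_leaves - side:
                target = n
                break
        if target is None:
            raise ValueError(f"no edge matches split {sorted(side)}")
        path = []
        n = target
        while n is not None:
            path.append(n)
            n = n.parent

        def invert(i: int) -> Node:
            """Subtree hanging off path[i] as seen from path[i-1]."""
            node = path[i]
            rest = [c for c in node.children if c is not path[i - 1]]
            if i == len(path) - 1:
                if len(rest) == 1:  # old degree-2 root dissolves
                    rest[0].parent = None
                    return rest[0]
                node.children = []
                for c in rest:
                    node.add(c)
                return node
            node.children = []
            for c in rest:
                node.add(c)
            node.add(invert(i + 1))
            return node

        new_root = Node()
        sibling = invert(1) if len(path) > 1 else None
        new_root.add(target)
        new_root.add(sibling)
        return PhyloTree(new_root, rooted=True)


# ---------------------------------------------------------------------------
# Newick I/O

def _check_balanced(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(f"unbalanced ')' at character offset {i}")
    if depth != 0:
        raise NewickError(f"unbalanced '(' — {depth} unclosed at end of input")


def parse_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse one Newick tree; internal node labels are read as supports when
    numeric.  ``rooted=None`` infers rootedness from a ``[&R]`` tag, else
    the tree is treated as unrooted."""
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error classes vary
        raise NewickError(f"malformed Newick: {exc}") from exc
    if rooted is None:
        rooted = bool(dtree.is_rooted)

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            return Node(name=name, length=dnode.edge.length)
        n = Node(length=dnode.edge.length)
        label = dnode.label
        if label is not None:
            try:
                n.support = float(label)
            except ValueError:
                n.name = label
        for ch in dnode.child_nodes():
            n.add(convert(ch))
        return n

    return PhyloTree(convert(dtree.seed_node), rooted=rooted)


def _fmt(x: float) -> str:
    return f"{x:g}"


def to_newick(tree: PhyloTree, lengths: bool = False) -> str:
    def render(n: Node) -> str:
        if n.is_leaf:
            s = n.name or ""
        else:
            s = "(" + ",".join(render(c) for c in n.children) + ")"
            if n.support is not None:
                s += _fmt(n.support)
            elif n.name:
                s += n.name
        if lengths and n.length is not None:
            s += f":{_fmt(n.length)}"
        return s

    return render(tree.root) + ";"


def read_newick(path: str | Path, rooted: bool | None = None) -> PhyloTree:
    return parse_newick(Path(path).read_text(), rooted=rooted)


def write_newick(tree: PhyloTree, path: str | Path, lengths: bool = False) -> None:
    Path(path).write_text(to_newick(tree, lengths=lengths) + "\n")


# ---------------------------------------------------------------------------

def splits_conflict(a: frozenset, b: frozenset, leaves: frozenset) -> bool:
    """Four-intersection incompatibility test for two splits of ``leaves``."""
    a2, b2 = leaves - a, leaves - b
    return all((a & b, a & b2, a2 & b, a2 & b2))


def same_topology(t1: PhyloTree, t2: PhyloTree, rooted: bool = False) -> bool:
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        return False
    if rooted:
        return set(t1.clades()) == set(t2.clades())
    return t1.bipartitions() == t2.bipartitions()
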