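"""Parsimony ancestral-state reconstruction on rooted trees.

Implemented as a unit-cost Sankoff dynamic programme rather than the
two-pass Fitch bookkeeping: a downward pass gives, per node and state, the
minimal number of changes in that node's subtree; an upward pass gives the
cost of the rest of the tree.  Their sum identifies the MPR (most
parsimonious reconstruction) state set at every node, and two deterministic
top-down trace-backs yield the ACCTRAN (changes placed as close to the root
as possible: change whenever a change is cost-neutral) and DELTRAN (changes
delayed: keep the parental state whenever cost-neutral) optimizations.
Both attain the character's Fitch length by construction.

Missing leaves carry zero cost for every state and therefore never generate
changes on their terminal branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .tree import Node, PhyloTree

_INF = 10**9

#: a node is keyed by its leaf name (tips) or its subtended leaf set.
NodeKey = str | frozenset


def node_key(node: Node) -> NodeKey:
    if node.is_leaf:
        return node.name
    return frozenset(l.name for l in node.leaves())


@dataclass
class Change:
    """One state change on the branch above ``branch`` (a node key)."""

    branch: NodeKey
    from_state: str
    to_state: str

    def astuple(self) -> tuple:
        return (self.branch, self.from_state, self.to_state)


@dataclass
class CharacterReconstruction:
    """MPR sets and both optimizations for a single character."""

    char_index: int
    states: list[str]
    mpr: dict[NodeKey, frozenset]
    acctran_states: dict[NodeKey, str]
    deltran_states: dict[NodeKey, str]
    acctran_events: list[Change]
    deltran_events: list[Change]

    @property
    def equivocal_nodes(self) -> frozenset:
        return frozenset(k for k, s in self.mpr.items() if len(s) > 1)

    @property
    def length(self) -> int:
        """Fitch length of the character (= event count of each optimization)."""
        return len(self.acctran_events)


@dataclass
class AncestralReconstruction:
    """Per-character reconstructions over one rooted tree."""

    tree: PhyloTree
    chars: list[CharacterReconstruction]
    char_names: list[str]

    def char(self, name: str) -> CharacterReconstruction:
        return self.chars[self.char_names.index(name)]


def _check_tree_matrix(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    if not tree.rooted:
        raise ValueError(
            "reconstruction needs a rooted tree (optimization direction is "
            "undefined on an unrooted one)"
        )
    tn, mn = set(tree.leaf_names()), set(matrix.taxa)
    if tn != mn:
        raise ValueError(
            f"leaf/taxon mismatch: tree-only={sorted(tn - mn)}, "
            f"matrix-only={sorted(mn - tn)}"
        )


def _reconstruct_char(tree: PhyloTree, matrix: CharacterMatrix,
                      j: int) -> CharacterReconstruction:
    states = sorted({r[j] for r in matrix.rows} - {MISSING})
    keys = {id(n): node_key(n) for n in tree.postorder()}
    if not states:
        # all-missing column: every node equivocal by convention, no events
        empty = frozenset()
        return CharacterReconstruction(
            j, [], {keys[id(n)]: empty for n in tree.postorder()},
            {}, {}, [], [])
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    row_of = {t: i for i, t in enumerate(matrix.taxa)}

    down: dict[int, np.ndarray] = {}
    nodes = list(tree.postorder())
    for n in nodes:
        if n.is_leaf:
            c = matrix.rows[row_of[n.name]][j]
            if c == MISSING:
                down[id(n)] = np.zeros(k, dtype=np.int64)
            else:
                v = np.full(k, _INF, dtype=np.int64)
                v[sidx[c]] = 0
                down[id(n)] = v
        else:
            tot = np.zeros(k, dtype=np.int64)
            for ch in n.children:
                c = down[id(ch)]
                tot += np.minimum(c, c.min() + 1)
            down[id(n)] = tot

    root = tree.root
    best = int(down[id(root)].min())

    # upward pass: cost of everything outside each node's subtree
    up: dict[int, np.ndarray] = {id(root): np.zeros(k, dtype=np.int64)}
    for n in tree.root.preorder():
        if n.is_leaf:
            continue
        sib_cost = {}
        for ch in n.children:
            c = down[id(ch)]
            sib_cost[id(ch)] = np.minimum(c, c.min() + 1)
        total_sib = sum(sib_cost.values())
        for ch in n.children:
            r = up[id(n)] + total_sib - sib_cost[id(ch)]
            up[id(ch)] = np.minimum(r, r.min() + 1)

    mpr = {
        keys[id(n)]: frozenset(
            states[i] for i in range(k)
            if down[id(n)][i] + up[id(n)][i] == best
        )
        for n in nodes
    }

    def traceback(prefer_change: bool) -> tuple[dict, list[Change]]:
        assign: dict[int, int] = {}
        events: list[Change] = []
        assign[id(root)] = int(np.argmin(down[id(root)]))
        for n in root.preorder():
            if n is root:
                continue
            pi = assign[id(n.parent)]
            c = down[id(n)]
            keep = int(c[pi])
            masked = c.copy()
            masked[pi] = _INF
            ti = int(np.argmin(masked))
            change = int(masked[ti]) + 1
            if change < keep or (change == keep and prefer_change):
                assign[id(n)] = ti
                events.append(Change(keys[id(n)], states[pi], states[ti]))
            else:
                assign[id(n)] = pi
        return (
            {keys[i]: states[s] for i, s in assign.items()},
            events,
        )

    acc_states, acc_events = traceback(prefer_change=True)
    del_states, del_events = traceback(prefer_change=False)
    return CharacterReconstruction(
        j, states, mpr, acc_states, del_states, acc_events, del_events
    )


def ancestral_states(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    char_names: list[str] | None = None,
) -> AncestralReconstruction:
    """Reconstruct every character of ``matrix`` on a rooted ``tree``."""
    _check_tree_matrix(tree, matrix)
    chars = [_reconstruct_char(tree, matrix, j) for j in range(matrix.nchar)]
    if char_names is None:
        char_names = [str(j + 1) for j in range(matrix.nchar)]
    return AncestralReconstruction(tree, chars, list(char_names))


def list_synapomorphies(
    tree: PhyloTree, matrix: CharacterMatrix
) -> dict[NodeKey, list[tuple[int, str, str]]]:
    """Unambiguously optimized changes per branch.

    A change is reported for a branch only when ACCTRAN and DELTRAN place a
    change on that same branch with the same ancestral and derived states.
    Positions are 1-based; the branch is keyed by the node below it (leaf
    name or subtended leaf set).
    """
    rec = ancestral_states(tree, matrix)
    out: dict[NodeKey, list[tuple[int, str, str]]] = {}
    for cr in rec.chars:
        acc = {c.astuple() for c in cr.acctran_events}
        dele = {c.astuple() for c in cr.deltran_events}
        for branch, frm, to in sorted(acc & dele, key=lambda x: str(x[0])):
            out.setdefault(branch, []).append((cr.char_index + 1, frm, to))
    for v in out.values():
        v.sort()
    return out
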