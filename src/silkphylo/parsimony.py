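"""Maximum-parsimony machinery: Fitch length, tree search, consensus,
bootstrap, Bremer decay and homoplasy indices.

Unordered (Fitch) parsimony throughout, with gaps and ambiguity codes
treated as missing data.  Heuristic search follows the classic recipe of
random-order stepwise addition followed by branch swapping (NNI, SPR or
full tree-bisection-reconnection), with all randomness driven by an
explicit seed so every search is bit-reproducible.

Internally trees live as integer adjacency maps (leaves ``0..n-1`` indexing
the matrix taxa) and are scored against a :class:`~silkphylo._packed.PackedMatrix`;
public entry points speak :class:`~silkphylo.tree.PhyloTree`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from ._packed import PackedMatrix
from .matrix import MISSING, CharacterMatrix
from .tree import Node, PhyloTree

Adj = dict[int, list[int]]

EXHAUSTIVE_MAX_TAXA = 10


# ---------------------------------------------------------------------------
# adjacency-tree plumbing

def _edges(adj: Adj) -> list[tuple[int, int]]:
    out = []
    for u in sorted(adj):
        for v in adj[u]:
            if u < v:
                out.append((u, v))
    return out


def _copy(adj: Adj) -> Adj:
    return {k: list(v) for k, v in adj.items()}


def _dfs_topo(adj: Adj, root: int = 0) -> tuple[list[int], dict[int, int]]:
    parent = {root: -1}
    topo = []
    stack = [root]
    while stack:
        node = stack.pop()
        topo.append(node)
        for nb in adj[node]:
            if nb != parent[node]:
                parent[nb] = node
                stack.append(nb)
    return topo, parent


def _score(adj: Adj, packed: PackedMatrix) -> int:
    """Total Fitch steps of an unrooted tree (leaves are taxon indices)."""
    rows = packed.rows
    combine = packed.combine
    root = min(k for k, v in adj.items() if len(v) == 1)
    topo, parent = _dfs_topo(adj, root)
    masks: dict[int, int] = {}
    total = 0
    for node in reversed(topo):
        kids = [n for n in adj[node] if n != parent[node]]
        if not kids:
            masks[node] = rows[node]
            continue
        m = masks[kids[0]]
        for k in kids[1:]:
            m, s = combine(m, masks[k])
            total += s
        if node == root:  # DFS root is a leaf: final combine with its own row
            m, s = combine(m, rows[root])
            total += s
        masks[node] = m
    return total


def _splits(adj: Adj, n_leaves: int) -> frozenset[int]:
    """Non-trivial splits as taxon bitmasks of the side not containing leaf 0."""
    topo, parent = _dfs_topo(adj, 0)
    below: dict[int, int] = {}
    out = set()
    full = (1 << n_leaves) - 1
    for node in reversed(topo):
        kids = [n for n in adj[node] if n != parent[node]]
        if not kids:
            below[node] = 1 << node
        else:
            b = 0
            for k in kids:
                b |= below[k]
            below[node] = b
    for node in topo:
        if node == 0 or parent[node] == -1:
            continue
        side = below[node]
        k = side.bit_count()
        if 2 <= k <= n_leaves - 2:
            out.add(side if not side & 1 else full ^ side)
    return frozenset(out)


def _canonical_key(adj: Adj, n_leaves: int) -> frozenset[int]:
    return _splits(adj, n_leaves)


def _insert_leaf(adj: Adj, u: int, v: int, internal: int, leaf: int) -> None:
    adj[u].remove(v)
    adj[v].remove(u)
    adj[u].append(internal)
    adj[v].append(internal)
    adj[internal] = [u, v]
    if leaf >= 0:
        adj[internal].append(leaf)
        adj[leaf] = [internal]


def _remove_leaf(adj: Adj, u: int, v: int, internal: int, leaf: int) -> None:
    if leaf >= 0:
        del adj[leaf]
    del adj[internal]
    adj[u].remove(internal)
    adj[v].remove(internal)
    adj[u].append(v)
    adj[v].append(u)


def _star3(a: int, b: int, c: int, hub: int) -> Adj:
    return {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}


def adj_to_phylo(adj: Adj, taxa: Sequence[str]) -> PhyloTree:
    """Unrooted adjacency tree -> PhyloTree (rooted representationally at
    leaf 0's neighbour, giving the usual basal polytomy)."""
    if len(adj) == 2:  # two-leaf tree
        root = Node()
        for t in sorted(adj):
            root.add(Node(name=taxa[t]))
        return PhyloTree(root, rooted=False)
    start = adj[0][0]

    def build(node: int, par: int) -> Node:
        kids = [n for n in adj[node] if n != par]
        if not kids:
            return Node(name=taxa[node])
        n = Node()
        for k in sorted(kids, key=lambda x: (x >= len(taxa), x)):
            n.add(build(k, node))
        return n

    root = Node()
    root.add(Node(name=taxa[0]))
    for k in sorted((n for n in adj[start] if n != 0),
                    key=lambda x: (x >= len(taxa), x)):
        root.add(build(k, start))
    return PhyloTree(root, rooted=False)


def phylo_to_adj(tree: PhyloTree, taxa: Sequence[str]) -> Adj:
    """PhyloTree -> unrooted adjacency tree over taxon indices."""
    index = {t: i for i, t in enumerate(taxa)}
    names = tree.leaf_names()
    missing = set(names) - set(taxa)
    extra = set(taxa) - set(names)
    if missing or extra:
        raise ValueError(
            f"leaf/taxon mismatch: tree-only={sorted(missing)}, "
            f"matrix-only={sorted(extra)}"
        )
    adj: Adj = {}
    next_id = [len(taxa)]

    def nid(node: Node) -> int:
        if node.is_leaf:
            return index[node.name]
        next_id[0] += 1
        return next_id[0] - 1

    def walk(node: Node, my_id: int) -> None:
        adj.setdefault(my_id, [])
        for ch in node.children:
            cid = nid(ch)
            adj.setdefault(cid, [])
            adj[my_id].append(cid)
            adj[cid].append(my_id)
            walk(ch, cid)

    root_id = nid(tree.root)
    walk(tree.root, root_id)
    # suppress a degree-2 root left by a rooted representation
    if len(adj.get(root_id, [])) == 2:
        a, b = adj[root_id]
        adj[a].remove(root_id)
        adj[b].remove(root_id)
        adj[a].append(b)
        adj[b].append(a)
        del adj[root_id]
    return adj


def split_to_names(split: int, taxa: Sequence[str]) -> frozenset[str]:
    return frozenset(t for i, t in enumerate(taxa) if split >> i & 1)


def names_to_split(names: Iterable[str], taxa: Sequence[str]) -> int:
    index = {t: i for i, t in enumerate(taxa)}
    mask = 0
    for n in names:
        mask |= 1 << index[n]
    if mask & 1:
        mask ^= (1 << len(taxa)) - 1
    return mask


# ---------------------------------------------------------------------------
# public scoring

def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> tuple[int, list[int]]:
    """Fitch parsimony length of ``tree`` on ``matrix``.

    Returns ``(total steps, per-character steps)``.  Missing cells carry the
    full observed state set of their column.
    """
    adj = phylo_to_adj(tree, matrix.taxa)
    per_char: list[int] = []
    topo, parent = _dfs_topo(adj, 0)
    order = list(reversed(topo))
    kids = {
        node: [n for n in adj[node] if n != parent[node]] for node in adj
    }
    for j in range(matrix.nchar):
        obs = sorted({r[j] for r in matrix.rows} - {MISSING})
        bit = {s: 1 << i for i, s in enumerate(obs)}
        full = (1 << max(1, len(obs))) - 1
        steps = 0
        masks: dict[int, int] = {}
        for node in order:
            ks = kids[node]
            if not ks:
                c = matrix.rows[node][j]
                masks[node] = full if c == MISSING else bit[c]
                continue
            m = masks[ks[0]]
            for k in ks[1:]:
                i = m & masks[k]
                if i:
                    m = i
                else:
                    m |= masks[k]
                    steps += 1
            if node == 0:
                c = matrix.rows[0][j]
                lm = full if c == MISSING else bit[c]
                i = m & lm
                if i:
                    m = i
                else:
                    m |= lm
                    steps += 1
            masks[node] = m
        per_char.append(steps)
    return sum(per_char), per_char


# ---------------------------------------------------------------------------
# search results

@dataclass
class SearchResult:
    """Outcome of a parsimony tree search.

    All returned trees share the best Fitch length; they are canonically
    ordered (by their sorted split sets) so repeated runs under one seed
    produce identical output.
    """

    best_length: int
    trees: list[PhyloTree]
    settings: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _result(best: int, adjs: dict[frozenset, Adj], taxa: Sequence[str],
            settings: dict) -> SearchResult:
    ordered = sorted(adjs.items(), key=lambda kv: sorted(kv[0]))
    trees = [adj_to_phylo(a, taxa) for _, a in ordered]
    return SearchResult(best, trees, settings)


# ---------------------------------------------------------------------------
# exhaustive search

def _enumerate_topologies(n: int, visit: Callable[[Adj], None]) -> None:
    """Visit every unrooted binary topology on leaves 0..n-1 ((2n-5)!! trees).

    The adjacency passed to ``visit`` is reused; copy it if kept.
    """
    adj = _star3(0, 1, 2, n)

    def recurse(k: int) -> None:
        if k == n:
            visit(adj)
            return
        internal = n + k - 2
        for u, v in _edges(adj):
            _insert_leaf(adj, u, v, internal, k)
            recurse(k + 1)
            _remove_leaf(adj, u, v, internal, k)

    if n == 3:
        visit(adj)
    else:
        recurse(3)


def exhaustive_search(matrix: CharacterMatrix,
                      packed: PackedMatrix | None = None) -> SearchResult:
    """Evaluate all unrooted binary topologies (4-10 taxa) and return every
    most parsimonious tree."""
    n = matrix.ntax
    if n < 4:
        raise ValueError("exhaustive search needs at least 4 taxa")
    if n > EXHAUSTIVE_MAX_TAXA:
        raise ValueError(
            f"{n} taxa: (2n-5)!! topologies is prohibitive; use heuristic_search"
        )
    packed = packed or PackedMatrix(matrix)
    best = [None]
    kept: dict[frozenset, Adj] = {}
    count = [0]

    def visit(adj: Adj) -> None:
        count[0] += 1
        s = _score(adj, packed)
        if best[0] is None or s < best[0]:
            best[0] = s
            kept.clear()
        if s == best[0]:
            kept[_canonical_key(adj, n)] = _copy(adj)

    _enumerate_topologies(n, visit)
    return _result(best[0], kept, matrix.taxa,
                   {"method": "exhaustive", "topologies": count[0]})


# ---------------------------------------------------------------------------
# branch swapping

def _splice_out(adj: Adj, node: int) -> tuple[int, int] | None:
    """Remove a degree-2 node, reconnecting its two neighbours; returns the
    new edge, or None if the node was not degree 2."""
    if len(adj[node]) != 2:
        return None
    p, q = adj[node]
    adj[p].remove(node)
    adj[q].remove(node)
    adj[p].append(q)
    adj[q].append(p)
    del adj[node]
    return (p, q) if p < q else (q, p)


def _component(adj: Adj, start: int, banned: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for nb in adj[x]:
            if nb != banned and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _nni_neighbors(adj: Adj) -> Iterator[Adj]:
    """The two nearest-neighbour interchanges across each internal edge."""
    for u, v in _edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue
        a1, a2 = (x for x in adj[u] if x != v)
        b1, b2 = (x for x in adj[v] if x != u)
        for x, y in ((a2, b1), (a2, b2)):
            t = _copy(adj)
            t[u].remove(x)
            t[v].remove(y)
            t[u].append(y)
            t[v].append(x)
            t[x].remove(u)
            t[x].append(v)
            t[y].remove(v)
            t[y].append(u)
            yield t


def _bisection_neighbors(adj: Adj, tbr: bool) -> Iterator[Adj]:
    """SPR/TBR neighbourhoods by edge bisection and reconnection.

    Each edge is removed in turn; the freed attachment points are spliced
    out and the two fragments reconnected by subdividing one edge on each
    side.  TBR reconnects across all edge pairs; SPR keeps one side's
    original attachment point fixed.
    """
    for u, v in _edges(adj):
        side_u_full = _component(adj, u, v)
        base = _copy(adj)
        base[u].remove(v)
        base[v].remove(u)
        splice_u = _splice_out(base, u)  # None when u was a leaf
        splice_v = _splice_out(base, v)
        nodes_u = side_u_full - ({u} if splice_u else set())
        a_edges = [e for e in _edges(base) if e[0] in nodes_u]
        b_edges = [e for e in _edges(base) if e[0] not in nodes_u]
        single_u = len(nodes_u) == 1
        single_v = len(base) - len(nodes_u) == 1
        a_opts = [None] if single_u else a_edges
        b_opts = [None] if single_v else b_edges
        orig_a = None if single_u else splice_u
        orig_b = None if single_v else splice_v

        if tbr:
            pairs = [(a, b) for a in a_opts for b in b_opts]
        else:
            pairs = [(a, orig_b) for a in a_opts]
            pairs += [(orig_a, b) for b in b_opts]

        def rejoin(a_e, b_e) -> Adj:
            t = _copy(base)
            if a_e is None:
                pa = next(iter(nodes_u))
            else:
                _insert_leaf(t, a_e[0], a_e[1], u, -1)
                pa = u
            if b_e is None:
                pb = next(x for x in base if x not in nodes_u)
            else:
                _insert_leaf(t, b_e[0], b_e[1], v, -1)
                pb = v
            t[pa].append(pb)
            t[pb].append(pa)
            return t

        seen: set = set()
        for a_e, b_e in pairs:
            if (a_e, b_e) == (orig_a, orig_b):
                continue  # reassembles the original tree
            if (a_e, b_e) in seen:
                continue
            seen.add((a_e, b_e))
            yield rejoin(a_e, b_e)


def _neighbors(adj: Adj, swap: str) -> Iterator[Adj]:
    if swap == "NNI":
        return _nni_neighbors(adj)
    if swap in ("SPR", "TBR"):
        return _bisection_neighbors(adj, tbr=swap == "TBR")
    raise ValueError(f"unknown swap type {swap!r}")


# ---------------------------------------------------------------------------
# stepwise addition and heuristic search

def _stepwise_addition(packed: PackedMatrix, order: Sequence[int],
                       rng: np.random.Generator) -> Adj:
    n = len(order)
    adj = _star3(order[0], order[1], order[2], n)
    for k in range(3, n):
        leaf = order[k]
        internal = n + k - 2
        best_s = None
        best_edges = []
        for u, v in _edges(adj):
            _insert_leaf(adj, u, v, internal, leaf)
            s = _score(adj, packed)
            _remove_leaf(adj, u, v, internal, leaf)
            if best_s is None or s < best_s:
                best_s, best_edges = s, [(u, v)]
            elif s == best_s:
                best_edges.append((u, v))
        u, v = best_edges[rng.integers(len(best_edges))]
        _insert_leaf(adj, u, v, internal, leaf)
    return adj


def _random_topology(leaves: Sequence[int], rng: np.random.Generator,
                     id_start: int) -> Adj:
    """Uniform-ish random unrooted binary tree by random sequential insertion."""
    leaves = list(leaves)
    if len(leaves) == 1:
        return {leaves[0]: []}
    if len(leaves) == 2:
        a, b = leaves
        return {a: [b], b: [a]}
    adj = _star3(leaves[0], leaves[1], leaves[2], id_start)
    nid = id_start + 1
    for leaf in leaves[3:]:
        edges = _edges(adj)
        u, v = edges[rng.integers(len(edges))]
        _insert_leaf(adj, u, v, nid, leaf)
        nid += 1
    return adj


def _random_tree_with_split(n: int, require: int, rng: np.random.Generator) -> Adj:
    side_a = [i for i in range(n) if require >> i & 1]
    side_b = [i for i in range(n) if not require >> i & 1]
    ta = _random_topology(side_a, rng, n)
    tb = _random_topology(side_b, rng, n + len(side_a))
    joint = 2 * n

    def hook(t: Adj, side: list[int], new_id: int) -> tuple[Adj, int]:
        if len(side) == 1:
            return t, side[0]
        edges = _edges(t)
        u, v = edges[rng.integers(len(edges))]
        _insert_leaf(t, u, v, new_id, -1)
        return t, new_id

    ta, pa = hook(ta, side_a, joint)
    tb, pb = hook(tb, side_b, joint + 1)
    adj = {**ta, **tb}
    adj[pa].append(pb)
    adj[pb].append(pa)
    return adj


def heuristic_search(
    matrix: CharacterMatrix,
    n_addition_reps: int = 10,
    swap: str = "TBR",
    seed: int | None = None,
    *,
    forbid: frozenset | None = None,
    require: frozenset | None = None,
    maxtrees: int = 64,
    packed: PackedMatrix | None = None,
) -> SearchResult:
    """Random-addition + branch-swapping parsimony search.

    ``forbid`` / ``require`` constrain the searched tree space to trees
    lacking / containing a given split (a frozenset of taxon names), which
    is how Bremer decay and branch-support decompositions are computed.
    Deterministic for a fixed seed.
    """
    n = matrix.ntax
    if n < 4:
        raise ValueError("search needs at least 4 taxa")
    if swap not in ("NNI", "SPR", "TBR"):
        raise ValueError(f"unknown swap type {swap!r}")
    if seed is None:
        raise ValueError("heuristic_search requires an explicit seed")
    rng = np.random.default_rng(seed)
    packed = packed or PackedMatrix(matrix)
    fb = names_to_split(forbid, matrix.taxa) if forbid else None
    rq = names_to_split(require, matrix.taxa) if require else None

    def ok(splits: frozenset[int]) -> bool:
        if fb is not None and fb in splits:
            return False
        if rq is not None and rq not in splits:
            return False
        return True

    best_s: int | None = None
    best: dict[frozenset, Adj] = {}

    for _ in range(max(1, n_addition_reps)):
        order = list(rng.permutation(n))
        if rq is not None:
            cur = _random_tree_with_split(n, rq, rng)
        else:
            cur = _stepwise_addition(packed, order, rng)
            if fb is not None and fb in _splits(cur, n):
                # nudge off the forbidden split with one accepted neighbour
                for nb in _neighbors(cur, swap):
                    if ok(_splits(nb, n)):
                        cur = nb
                        break
                else:
                    continue
        cur_s = _score(cur, packed)
        improved = True
        while improved:
            improved = False
            for nb in _neighbors(cur, swap):
                if (fb is not None or rq is not None) and not ok(_splits(nb, n)):
                    continue
                s = _score(nb, packed)
                if s < cur_s:
                    cur, cur_s = nb, s
                    improved = True
                    break
        if best_s is None or cur_s < best_s:
            best_s = cur_s
            best = {}
        if cur_s == best_s:
            best[_canonical_key(cur, n)] = cur

    # closure: gather equally short neighbours of the best trees
    queue = list(best.values())
    while queue and len(best) < maxtrees:
        t = queue.pop()
        for nb in _neighbors(t, swap):
            if (fb is not None or rq is not None) and not ok(_splits(nb, n)):
                continue
            s = _score(nb, packed)
            if s < best_s:
                best_s = s
                best = {_canonical_key(nb, n): nb}
                queue = [nb]
                break
            if s == best_s:
                key = _canonical_key(nb, n)
                if key not in best and len(best) < maxtrees:
                    best[key] = nb
                    queue.append(nb)

    settings = {
        "method": "heuristic", "swap": swap, "seed": seed,
        "n_addition_reps": n_addition_reps, "maxtrees": maxtrees,
    }
    if forbid:
        settings["forbid"] = sorted(forbid)
    if require:
        settings["require"] = sorted(require)
    return _result(best_s, best, matrix.taxa, settings)


def search_best(
    matrix: CharacterMatrix,
    seed: int = 0,
    *,
    forbid: frozenset | None = None,
    require: frozenset | None = None,
    n_addition_reps: int = 10,
    swap: str = "TBR",
    packed: PackedMatrix | None = None,
) -> SearchResult:
    """Exhaustive search (with optional split constraints) when the taxon
    count allows it, heuristic constrained search otherwise."""
    n = matrix.ntax
    if n <= EXHAUSTIVE_MAX_TAXA and forbid is None and require is None:
        return exhaustive_search(matrix, packed=packed)
    if n <= EXHAUSTIVE_MAX_TAXA:
        packed = packed or PackedMatrix(matrix)
        fb = names_to_split(forbid, matrix.taxa) if forbid else None
        rq = names_to_split(require, matrix.taxa) if require else None
        best = [None]
        kept: dict[frozenset, Adj] = {}

        def visit(adj: Adj) -> None:
            sp = _splits(adj, n)
            if fb is not None and fb in sp:
                return
            if rq is not None and rq not in sp:
                return
            s = _score(adj, packed)
            if best[0] is None or s < best[0]:
                best[0] = s
                kept.clear()
            if s == best[0]:
                kept[frozenset(sp)] = _copy(adj)

        _enumerate_topologies(n, visit)
        if best[0] is None:
            raise ValueError("no topology satisfies the constraints")
        return _result(best[0], kept, matrix.taxa, {"method": "exhaustive-filtered"})
    return heuristic_search(
        matrix, n_addition_reps=n_addition_reps, swap=swap, seed=seed,
        forbid=forbid, require=require, packed=packed,
    )


# ---------------------------------------------------------------------------
# consensus

def _consensus_from_splits(splits: dict[frozenset, float],
                           leaf_names: list[str]) -> PhyloTree:
    """Assemble a (possibly multifurcating) tree from a compatible split set.

    Splits are canonicalized as the side excluding the alphabetically first
    leaf, so they form a laminar family and nest directly into clades of a
    tree hung off that reference leaf.
    """
    ref = min(leaf_names)
    others = [l for l in leaf_names if l != ref]
    root = Node()
    root.add(Node(name=ref))
    made: list[tuple[frozenset, Node]] = []
    for side in sorted(splits, key=lambda s: (-len(s), sorted(s))):
        parent, best = root, None
        for s, nd in made:
            if side < s and (best is None or len(s) < best):
                best, parent = len(s), nd
        node = Node(support=splits[side])
        parent.add(node)
        made.append((side, node))
    for l in others:
        parent, best = root, None
        for s, nd in made:
            if l in s and (best is None or len(s) < best):
                best, parent = len(s), nd
        parent.add(Node(name=l))
    return PhyloTree(root, rooted=False)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Splits present in every tree (input trees must share one leaf set)."""
    if not trees:
        raise ValueError("no trees")
    leaf_sets = {frozenset(t.leaf_names()) for t in trees}
    if len(leaf_sets) > 1:
        raise ValueError("trees have differing leaf sets")
    common = set(trees[0].bipartitions())
    for t in trees[1:]:
        common &= t.bipartitions()
    return _consensus_from_splits({s: 100.0 for s in common},
                                  sorted(leaf_sets.pop()))


def majority_consensus(trees: Sequence[PhyloTree], cutoff: float = 0.5) -> PhyloTree:
    """Splits occurring in more than ``cutoff`` of the trees (cutoff >= 0.5
    guarantees pairwise compatibility); node supports hold the percentage."""
    if not trees:
        raise ValueError("no trees")
    if cutoff < 0.5:
        raise ValueError("cutoff below 0.5 does not guarantee a compatible set")
    leaf_sets = {frozenset(t.leaf_names()) for t in trees}
    if len(leaf_sets) > 1:
        raise ValueError("trees have differing leaf sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    keep = {
        s: 100.0 * c / len(trees)
        for s, c in counts.items() if c / len(trees) > cutoff
    }
    return _consensus_from_splits(keep, sorted(leaf_sets.pop()))


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap(
    matrix: CharacterMatrix,
    reps: int = 1000,
    addition_reps_per_rep: int = 3,
    seed: int | None = None,
    swap: str = "TBR",
) -> dict[frozenset, float]:
    """Nonparametric bootstrap support (%) per split.

    Characters are resampled with replacement to the original width; each
    pseudo-replicate gets its own heuristic search.  A replicate counts once
    per split; when it yields several equally short trees the split's
    contribution is averaged over them.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    n = matrix.ntax
    acc: dict[int, float] = {}
    for _ in range(reps):
        idx = rng.integers(0, matrix.nchar, matrix.nchar)
        packed = PackedMatrix(matrix, columns=idx)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = heuristic_search(
            matrix, n_addition_reps=addition_reps_per_rep, swap=swap,
            seed=sub_seed, packed=packed,
        )
        split_sets = [
            _splits(phylo_to_adj(t, matrix.taxa), n) for t in res.trees
        ]
        pool = set().union(*split_sets)
        for s in pool:
            frac = sum(s in ss for ss in split_sets) / len(split_sets)
            acc[s] = acc.get(s, 0.0) + frac
    return {
        split_to_names(s, matrix.taxa): 100.0 * v / reps for s, v in acc.items()
    }


# ---------------------------------------------------------------------------
# Bremer decay

def decay_index(
    matrix: CharacterMatrix,
    result: SearchResult | None = None,
    seed: int = 0,
    n_addition_reps: int = 10,
    swap: str = "TBR",
) -> dict[frozenset, int]:
    """Bremer decay per split of the MPT strict consensus.

    decay = (best length among trees lacking the split) - (best length).
    Computed by filtered exhaustive search for <=10 taxa, reverse-constraint
    heuristic search otherwise.
    """
    if result is None:
        result = search_best(matrix, seed=seed, n_addition_reps=n_addition_reps,
                             swap=swap)
    cons = strict_consensus(result.trees)
    out: dict[frozenset, int] = {}
    for split in sorted(cons.bipartitions(), key=sorted):
        anti = search_best(
            matrix, seed=seed, forbid=split,
            n_addition_reps=n_addition_reps, swap=swap,
        )
        out[split] = anti.best_length - result.best_length
    return out


# ---------------------------------------------------------------------------
# homoplasy indices

def _column_counts(matrix: CharacterMatrix, j: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in matrix.rows:
        c = r[j]
        if c != MISSING:
            counts[c] = counts.get(c, 0) + 1
    return counts


def is_parsimony_informative(matrix: CharacterMatrix, j: int) -> bool:
    counts = _column_counts(matrix, j)
    return sum(1 for v in counts.values() if v >= 2) >= 2


def ci_ri(matrix: CharacterMatrix, tree: PhyloTree) -> dict[str, float]:
    """Consistency and retention indices of ``tree`` on ``matrix``.

    CI = sum(m_i)/sum(s_i) with m_i the minimum conceivable steps (observed
    states - 1) and s_i the realized Fitch steps; RI rescales by the maximum
    steps g_i a star tree could need.  ``ci_excluding_uninformative``
    restricts the sums to parsimony-informative characters.
    """
    total, per_char = fitch_length(tree, matrix)
    m = g = s = 0
    mi = gi = si = 0
    for j in range(matrix.nchar):
        counts = _column_counts(matrix, j)
        mj = max(0, len(counts) - 1)
        gj = sum(counts.values()) - max(counts.values(), default=0)
        sj = per_char[j]
        m, g, s = m + mj, g + gj, s + sj
        if is_parsimony_informative(matrix, j):
            mi, gi, si = mi + mj, gi + gj, si + sj
    ci = 1.0 if s == 0 else m / s
    ri = 1.0 if g == m else (g - s) / (g - m)
    ci_ex = 1.0 if si == 0 else mi / si
    return {"CI": ci, "RI": ri, "CI_excluding_uninformative": ci_ex}
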