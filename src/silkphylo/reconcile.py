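"""Gene-tree/species-tree reconciliation and duplication/loss rooting.

A rooted gene tree is embedded into a rooted species tree by the LCA
(last-common-ancestor) map: each gene leaf goes to its species, each gene
node to the species-tree LCA of its children's images.  A gene node is a
duplication when its image coincides with a child's image; losses are
counted edge by edge from the path lengths the embedding implies.  The
weighted score c_dup * D + c_loss * L (defaults 1.5 and 1.0) ranks candidate
rootings of an unrooted gene family tree: every branch is tried as the root
and all co-optimal rootings are reported, never silently tie-broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqs import LeafSpeciesMap
from .tree import Node, PhyloTree

DEFAULT_DUP_COST = 1.5
DEFAULT_LOSS_COST = 1.0


def weighted_score(
    n_dup: int, n_loss: int,
    c_dup: float = DEFAULT_DUP_COST, c_loss: float = DEFAULT_LOSS_COST,
) -> float:
    """Weighted duplication/loss cost ``c_dup * D + c_loss * L``."""
    if n_dup < 0 or n_loss < 0:
        raise ValueError("duplication and loss counts must be non-negative")
    return c_dup * n_dup + c_loss * n_loss


@dataclass
class ReconciliationResult:
    """LCA embedding of a gene tree into a species tree.

    ``duplications`` holds the gene nodes inferred to be duplications, each
    as the set of gene leaves below it; ``mapping`` records each gene
    node's species-tree image (a species leaf name or set of names).
    """

    n_duplications: int
    n_losses: int
    c_dup: float = DEFAULT_DUP_COST
    c_loss: float = DEFAULT_LOSS_COST
    duplications: set[frozenset] = field(default_factory=set)
    mapping: dict = field(default_factory=dict)

    @property
    def score(self) -> float:
        return weighted_score(self.n_duplications, self.n_losses,
                              self.c_dup, self.c_loss)


def _check_binary_rooted(tree: PhyloTree, what: str) -> None:
    if not tree.rooted:
        raise ValueError(f"{what} must be rooted")
    for n in tree.postorder():
        if n.children and len(n.children) != 2:
            raise ValueError(
                f"{what} must be binary (node with {len(n.children)} children; "
                "polytomies are not resolved)"
            )


def prune_to_species(species_tree: PhyloTree, keep: set[str]) -> PhyloTree:
    """Restrict a rooted species tree to ``keep``, suppressing the unary
    nodes the removal leaves behind."""
    missing = keep - set(species_tree.leaf_names())
    if missing:
        raise ValueError(f"species absent from species tree: {sorted(missing)}")

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            return Node(name=node.name) if node.name in keep else None
        kids = [b for b in (build(c) for c in node.children) if b is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        n = Node(name=node.name)
        for k in kids:
            n.add(k)
        return n

    root = build(species_tree.root)
    if root is None:
        raise ValueError("pruning removed every species")
    return PhyloTree(root, rooted=True)


def reconcile(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    leaf_map: LeafSpeciesMap,
    c_dup: float = DEFAULT_DUP_COST,
    c_loss: float = DEFAULT_LOSS_COST,
    prune: bool = True,
) -> ReconciliationResult:
    """LCA-reconcile a rooted binary gene tree into a rooted binary species
    tree.

    With ``prune`` (default) the species tree is first restricted to the
    species actually present in the gene tree, so species never sampled for
    the family do not inflate the loss count.
    """
    _check_binary_rooted(gene_tree, "gene tree")
    _check_binary_rooted(species_tree, "species tree")
    unmapped = [l for l in gene_tree.leaf_names() if l not in leaf_map]
    if unmapped:
        raise ValueError(f"gene leaves without species assignment: {sorted(unmapped)}")
    present = {leaf_map[l] for l in gene_tree.leaf_names()}
    stree = prune_to_species(species_tree, present) if prune else species_tree
    if len(stree.leaf_names()) == 1:
        # single-species family: every internal gene node is a duplication
        only = stree.leaf_names()[0]
        dups = {
            frozenset(l.name for l in n.leaves())
            for n in gene_tree.postorder() if n.children
        }
        mapping = {
            (n.name if n.is_leaf else frozenset(l.name for l in n.leaves())): only
            for n in gene_tree.postorder()
        }
        return ReconciliationResult(len(dups), 0, c_dup, c_loss, dups, mapping)

    # species-tree indexing for LCA queries
    sparent: dict[int, Node | None] = {id(stree.root): None}
    sdepth: dict[int, int] = {id(stree.root): 0}
    for n in stree.root.preorder():
        for c in n.children:
            sparent[id(c)] = n
            sdepth[id(c)] = sdepth[id(n)] + 1
    sleaf = {l.name: l for l in stree.leaves()}

    def lca(a: Node, b: Node) -> Node:
        while a is not b:
            if sdepth[id(a)] < sdepth[id(b)]:
                b = sparent[id(b)]
            else:
                a = sparent[id(a)]
        return a

    image: dict[int, Node] = {}
    is_dup: dict[int, bool] = {}
    for g in gene_tree.postorder():
        if g.is_leaf:
            image[id(g)] = sleaf[leaf_map[g.name]]
            continue
        a, b = (image[id(c)] for c in g.children)
        m = lca(a, b)
        image[id(g)] = m
        is_dup[id(g)] = m is a or m is b

    losses = 0
    for g in gene_tree.postorder():
        if g.parent is None:
            continue
        u = g.parent
        k = sdepth[id(image[id(g)])] - sdepth[id(image[id(u)])]
        losses += k if is_dup[id(u)] else k - 1

    dups = {
        frozenset(l.name for l in n.leaves())
        for n in gene_tree.postorder() if n.children and is_dup[id(n)]
    }

    def skey(s: Node):
        return s.name if s.is_leaf else frozenset(l.name for l in s.leaves())

    mapping = {
        (g.name if g.is_leaf else frozenset(l.name for l in g.leaves())):
            skey(image[id(g)])
        for g in gene_tree.postorder()
    }
    return ReconciliationResult(
        len(dups), losses, c_dup, c_loss, dups, mapping
    )


def root_search(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    leaf_map: LeafSpeciesMap,
    c_dup: float = DEFAULT_DUP_COST,
    c_loss: float = DEFAULT_LOSS_COST,
    prune: bool = True,
) -> list[tuple[frozenset, ReconciliationResult]]:
    """Try every branch of an unrooted gene tree as the root and rank the
    rootings by weighted duplication/loss score.

    Returns all ``2n - 3`` candidate root branches (each as the leaf set of
    one side) with their reconciliations, best first; co-optimal rootings
    are adjacent at the head of the list.
    """
    if gene_tree.rooted:
        gene_tree = gene_tree.unroot()
    if gene_tree.n_leaves < 3:
        raise ValueError("root search needs an unrooted tree with >=3 leaves")
    candidates: list[frozenset] = []
    seen = set()
    all_leaves = frozenset(gene_tree.leaf_names())
    for n in gene_tree.postorder():
        if n is gene_tree.root:
            continue
        side = frozenset(l.name for l in n.leaves())
        canon = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
        if canon in seen:
            continue
        seen.add(canon)
        candidates.append(side)
    ranked = []
    for side in candidates:
        rooted = gene_tree.root_on_edge(side)
        res = reconcile(rooted, species_tree, leaf_map,
                        c_dup=c_dup, c_loss=c_loss, prune=prune)
        ranked.append((side, res))
    ranked.sort(key=lambda pr: (pr[1].score, tuple(sorted(pr[0]))))
    return ranked
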