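"""LCA reconciliation, weighted D/L scoring, and root search."""

import itertools

import pytest

from silkphylo.reconcile import (prune_to_species, reconcile, root_search,
                                 weighted_score)
from silkphylo.seqs import LeafSpeciesMap
from silkphylo.simulate import simulate_gene_family, simulate_species_tree
from silkphylo.tree import Node, PhyloTree, parse_newick


class TestWeightedScore:
    @pytest.mark.parametrize("d,l,score", [(11, 39, 55.5), (10, 28, 43.0),
                                           (0, 0, 0.0), (12, 42, 60.0)])
    def test_default_costs(self, d, l, score):
        assert weighted_score(d, l) == score

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            weighted_score(-1, 0)

    def test_result_matches_reconciliation_score_identity(self):
        sp = parse_newick("(A,B);", rooted=True)
        g = parse_newick("((a1,b1),(a2,b2));", rooted=True)
        lm = LeafSpeciesMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = reconcile(g, sp, lm)
        assert res.score == weighted_score(res.n_duplications, res.n_losses)


SP3 = parse_newick("((A,B),C);", rooted=True)
LM = LeafSpeciesMap({f"{s.lower()}{i}": s
                     for s in "ABC" for i in (1, 2)})


class TestReconcile:
    def test_congruent_one_copy_family_costs_nothing(self):
        g = parse_newick("((a1,b1),c1);", rooted=True)
        res = reconcile(g, SP3, LM)
        assert (res.n_duplications, res.n_losses, res.score) == (0, 0, 0.0)

    def test_root_duplication_of_two_species(self):
        sp = parse_newick("(A,B);", rooted=True)
        g = parse_newick("((a1,b1),(a2,b2));", rooted=True)
        res = reconcile(g, sp, LM)
        assert (res.n_duplications, res.n_losses, res.score) == (1, 0, 1.5)
        assert res.duplications == {frozenset({"a1", "a2", "b1", "b2"})}

    def test_within_species_duplication(self):
        sp = parse_newick("(A,B);", rooted=True)
        g = parse_newick("((a1,a2),b1);", rooted=True)
        res = reconcile(g, sp, LM)
        assert (res.n_duplications, res.n_losses, res.score) == (1, 0, 1.5)

    def test_loss_on_unsampled_lineage(self):
        g = parse_newick("(a1,c1);", rooted=True)
        res = reconcile(g, SP3, LM, prune=False)
        assert (res.n_duplications, res.n_losses, res.score) == (0, 1, 1.0)

    def test_pruning_removes_phantom_losses(self):
        g = parse_newick("(a1,c1);", rooted=True)
        res = reconcile(g, SP3, LM, prune=True)
        assert (res.n_duplications, res.n_losses) == (0, 0)

    def test_unmapped_leaf_and_polytomy_rejected(self):
        g = parse_newick("((a1,b1),zz);", rooted=True)
        with pytest.raises(ValueError, match="zz"):
            reconcile(g, SP3, LM)
        poly = parse_newick("(a1,b1,c1);", rooted=True)
        with pytest.raises(ValueError, match="binary"):
            reconcile(poly, SP3, LM)

    def test_prune_keeps_structure(self):
        sp = parse_newick("(((A,B),C),(D,E));", rooted=True)
        pruned = prune_to_species(sp, {"A", "C", "D"})
        assert set(pruned.leaf_names()) == {"A", "C", "D"}
        assert pruned.clades().keys() == {frozenset({"A", "C"})}


def all_rooted_topologies(leaves):
    """Every rooted binary topology over the given leaf labels ((2n-3)!!
    of them; the first leaf is pinned to the left of the root, so each
    unordered root split appears once)."""
    if len(leaves) == 1:
        yield Node(name=leaves[0])
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(len(rest)):
        for extra in itertools.combinations(rest, k):
            left = [first, *extra]
            right = [x for x in rest if x not in extra]
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    root = Node()
                    root.add(lt.copy())
                    root.add(rt.copy())
                    yield root


def brute_force_min_cost(gene, stree, leaf_map):
    """Minimal (L, D) over all valid embeddings of the gene tree.

    Enumerates every mapping M with M(leaf) fixed and M(parent) an ancestor
    of (or equal to) the species-LCA of the children's images, computing
    duplications and path-length losses per mapping.
    """
    sparent = {id(stree.root): None}
    sdepth = {id(stree.root): 0}
    for n in stree.root.preorder():
        for c in n.children:
            sparent[id(c)] = n
            sdepth[id(c)] = sdepth[id(n)] + 1
    sleaf = {l.name: l for l in stree.leaves()}

    def lca(a, b):
        while a is not b:
            if sdepth[id(a)] < sdepth[id(b)]:
                b = sparent[id(b)]
            else:
                a = sparent[id(a)]
        return a

    def ancestors(s):
        while s is not None:
            yield s
            s = sparent[id(s)]

    gnodes = list(gene.postorder())
    min_l, min_d = [None], [None]

    def is_dup(mapping, g):
        """Speciation only when the image is exactly the children's LCA and
        strictly above both child images; anything else duplicates."""
        m1, m2 = (mapping[id(c)] for c in g.children)
        s = mapping[id(g)]
        return not (s is lca(m1, m2) and s is not m1 and s is not m2)

    def assign(i, mapping):
        if i == len(gnodes):
            dups = sum(is_dup(mapping, g) for g in gnodes if g.children)
            losses = 0
            for g in gnodes:
                if g.parent is None:
                    continue
                u = g.parent
                k = sdepth[id(mapping[id(g)])] - sdepth[id(mapping[id(u)])]
                losses += k if is_dup(mapping, u) else k - 1
            if min_l[0] is None or losses < min_l[0]:
                min_l[0] = losses
            if min_d[0] is None or dups < min_d[0]:
                min_d[0] = dups
            return
        g = gnodes[i]
        if g.is_leaf:
            mapping[id(g)] = sleaf[leaf_map[g.name]]
            assign(i + 1, mapping)
            return
        base = lca(*(mapping[id(c)] for c in g.children))
        for s in ancestors(base):
            mapping[id(g)] = s
            assign(i + 1, mapping)
        del mapping[id(g)]

    assign(0, {})
    return min_l[0], min_d[0]


class TestBruteForceOracle:
    @pytest.mark.parametrize("genes,species_nwk,mapping", [
        (["a1", "b1", "c1", "a2"], "((A,B),C);",
         {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}),
        (["a1", "b1", "c1", "d1"], "((A,B),(C,D));",
         {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}),
        (["a1", "a2", "b1", "c1", "d1"], "(((A,B),C),D);",
         {"a1": "A", "a2": "A", "b1": "B", "c1": "C", "d1": "D"}),
    ])
    def test_lca_losses_match_minimum_over_embeddings(self, genes,
                                                      species_nwk, mapping):
        stree = parse_newick(species_nwk, rooted=True)
        lm = LeafSpeciesMap(mapping)
        for root in all_rooted_topologies(genes):
            gt = PhyloTree(root, rooted=True)
            res = reconcile(gt, stree, lm, prune=False)
            min_l, min_d = brute_force_min_cost(gt, stree, lm)
            assert res.n_losses == min_l
            assert res.n_duplications == min_d


class TestRootSearch:
    def test_congruent_family_roots_at_species_root(self):
        g = parse_newick("((a1,b1),c1);")
        ranked = root_search(g, SP3, LM)
        assert len(ranked) == 2 * 3 - 3
        side, best = ranked[0]
        assert best.score == 0.0
        assert side in (frozenset({"a1", "b1"}), frozenset({"c1"}))

    def test_deep_duplication_rooting_recovered(self):
        sp = parse_newick("((A,B),C);", rooted=True)
        g = parse_newick("(((a1,b1),c1),((a2,b2),c2));")
        ranked = root_search(g, sp, LM)
        side, best = ranked[0]
        assert best.score == 1.5 and best.n_duplications == 1
        assert side in (frozenset({"a1", "b1", "c1"}),
                        frozenset({"a2", "b2", "c2"}))

    def test_simulated_families_root_with_true_duplication_count(self):
        ok = 0
        sp = simulate_species_tree(6, 40)
        for s in range(20):
            gt, truth = simulate_gene_family(sp, 0.6, 0.0, 500 + s)
            ranked = root_search(gt.unroot(), sp,
                                 LeafSpeciesMap(truth.leaf_map))
            if ranked[0][1].n_duplications == truth.n_duplications:
                ok += 1
        assert ok >= 18
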