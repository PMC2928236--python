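"""Fitch length, tree search, consensus, bootstrap, decay, CI/RI."""

import itertools

import numpy as np
import pytest

from silkphylo.matrix import CharacterMatrix
from silkphylo.parsimony import (EXHAUSTIVE_MAX_TAXA, bootstrap, ci_ri,
                                 decay_index, exhaustive_search, fitch_length,
                                 heuristic_search, majority_consensus,
                                 strict_consensus)
from silkphylo.parsimony import _enumerate_topologies
from silkphylo.tree import parse_newick, same_topology, to_newick

from conftest import random_matrix


def brute_force_fitch(tree, matrix):
    """Minimum changes over all internal labelings (observed states only)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    row = {t: r for t, r in zip(matrix.taxa, matrix.rows)}
    total = 0
    for j in range(matrix.nchar):
        obs = sorted({r[j] for r in matrix.rows} - {"?"})
        if not obs:
            continue
        best = None
        for lab in itertools.product(obs, repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, lab)}
            cost = 0
            for n in nodes:
                if n.parent is None:
                    continue
                ps = assign[id(n.parent)]
                if n.is_leaf:
                    c = row[n.name][j]
                    cost += c != "?" and c != ps
                else:
                    cost += assign[id(n)] != ps
            if best is None or cost < best:
                best = cost
        total += best
    return total


class TestFitch:
    def test_single_origin_is_one_step(self, quartet_tree):
        m = CharacterMatrix(list("ABCD"), ["0", "0", "1", "1"], "standard")
        assert fitch_length(quartet_tree, m) == (1, [1])

    def test_split_origin_is_two_steps(self):
        t = parse_newick("((A,C),(B,D));")
        m = CharacterMatrix(list("ABCD"), ["0", "0", "1", "1"], "standard")
        assert fitch_length(t, m)[0] == 2

    def test_constant_and_missing_characters(self, quartet_tree):
        m = CharacterMatrix(list("ABCD"), ["00", "00", "01", "?1"], "standard")
        assert fitch_length(quartet_tree, m) == (1, [0, 1])

    def test_leaf_taxon_mismatch_lists_difference(self, quartet_tree):
        m = CharacterMatrix(list("ABCE"), ["0", "0", "1", "1"], "standard")
        with pytest.raises(ValueError, match="E.*|D.*"):
            fitch_length(quartet_tree, m)

    def test_matches_brute_force_on_random_characters(self):
        rng = np.random.default_rng(11)
        trees = [
            parse_newick("((A,B),(C,(D,E)));"),
            parse_newick("(((A,C),E),(B,D));"),
        ]
        for _ in range(25):
            m = random_matrix(rng, list("ABCDE"), 6, "012", missing_p=0.15)
            for t in trees:
                assert fitch_length(t, m)[0] == brute_force_fitch(t, m)


class TestExhaustive:
    def test_topology_counts(self):
        for n, expected in ((4, 3), (5, 15), (6, 105)):
            count = []
            _enumerate_topologies(n, lambda a: count.append(1))
            assert len(count) == expected

    def test_refuses_large_problems(self):
        m = random_matrix(np.random.default_rng(0),
                          [f"t{i}" for i in range(EXHAUSTIVE_MAX_TAXA + 1)], 4)
        with pytest.raises(ValueError, match="heuristic"):
            exhaustive_search(m)

    def test_homoplasy_free_matrix_recovers_generating_tree(self, six_taxa):
        # characters = clades of ((t0,t1),((t2,t3),(t4,t5)))
        m = CharacterMatrix(
            six_taxa, ["1000", "1000", "0110", "0110", "0011", "0011"],
            "standard")
        res = exhaustive_search(m)
        gen = parse_newick("((t0,t1),((t2,t3),(t4,t5)));")
        assert res.n_trees == 1
        assert same_topology(res.trees[0], gen)


class TestHeuristic:
    def test_attains_exhaustive_optimum(self):
        rng = np.random.default_rng(21)
        taxa = [f"t{i}" for i in range(8)]
        for trial in range(5):
            m = random_matrix(rng, taxa, 15, "0123")
            ex = exhaustive_search(m)
            h = heuristic_search(m, n_addition_reps=10, swap="TBR", seed=trial)
            assert h.best_length == ex.best_length

    def test_deterministic_under_seed(self, six_taxa):
        m = random_matrix(np.random.default_rng(3), six_taxa, 10, "012")
        a = heuristic_search(m, 5, "TBR", seed=9)
        b = heuristic_search(m, 5, "TBR", seed=9)
        assert a.best_length == b.best_length
        assert [to_newick(t) for t in a.trees] == [to_newick(t) for t in b.trees]

    def test_unknown_swap_rejected(self, six_taxa):
        m = random_matrix(np.random.default_rng(3), six_taxa, 4)
        with pytest.raises(ValueError, match="swap"):
            heuristic_search(m, 2, "FOO", seed=1)

    def test_seed_is_mandatory(self, six_taxa):
        m = random_matrix(np.random.default_rng(3), six_taxa, 4)
        with pytest.raises(ValueError, match="seed"):
            heuristic_search(m, 2, "TBR", seed=None)

    @pytest.mark.parametrize("swap", ["NNI", "SPR", "TBR"])
    def test_all_swap_types_run(self, six_taxa, swap):
        m = random_matrix(np.random.default_rng(4), six_taxa, 8, "012")
        res = heuristic_search(m, 3, swap, seed=2)
        assert res.best_length >= 0 and res.n_trees >= 1


class TestConsensus:
    def test_consensus_of_one_tree_is_that_tree(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        assert same_topology(strict_consensus([t]), t)

    def test_disagreement_collapses_to_polytomy(self):
        t1 = parse_newick("((A,B),(C,(D,E)));")
        t2 = parse_newick("((A,B),(D,(C,E)));")
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == {frozenset({"C", "D", "E"})}

    def test_majority_keeps_what_strict_drops(self):
        trees = [parse_newick(s) for s in (
            "((A,B),(C,(D,E)));", "((A,B),(C,(D,E)));", "((A,B),(D,(C,E)));",
        )]
        strict = strict_consensus(trees).bipartitions()
        major = majority_consensus(trees).bipartitions()
        assert frozenset({"D", "E"}) not in strict
        assert frozenset({"D", "E"}) in major

    def test_differing_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="leaf"):
            strict_consensus([parse_newick("((A,B),(C,D));"),
                              parse_newick("((A,B),(C,E));")])


class TestBootstrap:
    def test_supports_bounded_and_deterministic(self, six_taxa):
        m = random_matrix(np.random.default_rng(8), six_taxa, 12, "012")
        a = bootstrap(m, reps=25, addition_reps_per_rep=2, seed=4)
        b = bootstrap(m, reps=25, addition_reps_per_rep=2, seed=4)
        assert a == b
        assert all(0.0 <= v <= 100.0 for v in a.values())

    def test_overwhelming_signal_gets_full_support(self, six_taxa):
        rows = ["1" * 12, "1" * 12] + ["0" * 12] * 4
        m = CharacterMatrix(six_taxa, rows, "standard")
        sup = bootstrap(m, reps=50, addition_reps_per_rep=2, seed=1)
        assert sup[frozenset({"t2", "t3", "t4", "t5"})] >= 99.0

    def test_rep_count_validated(self, six_taxa):
        m = random_matrix(np.random.default_rng(8), six_taxa, 6)
        with pytest.raises(ValueError):
            bootstrap(m, reps=0, seed=1)


class TestDecay:
    def test_uncontradicted_characters_set_the_decay(self, six_taxa):
        m = CharacterMatrix(six_taxa, ["111", "111"] + ["000"] * 4, "standard")
        res = exhaustive_search(m)
        d = decay_index(m, res)
        assert d[frozenset({"t2", "t3", "t4", "t5"})] == 3

    def test_every_consensus_split_decays_at_least_one(self, six_taxa):
        m = random_matrix(np.random.default_rng(12), six_taxa, 14, "012")
        res = exhaustive_search(m)
        d = decay_index(m, res)
        assert all(v >= 1 for v in d.values())


class TestCiRi:
    def test_homoplasy_free_scores_one(self, six_taxa):
        m = CharacterMatrix(
            six_taxa, ["1000", "1000", "0110", "0110", "0011", "0011"],
            "standard")
        tree = exhaustive_search(m).trees[0]
        out = ci_ri(m, tree)
        assert out["CI"] == 1.0 and out["RI"] == 1.0

    def test_two_step_binary_character_contributes_half(self):
        t = parse_newick("((A,C),(B,D));")
        m = CharacterMatrix(list("ABCD"), ["0", "0", "1", "1"], "standard")
        out = ci_ri(m, t)
        assert out["CI"] == 0.5

    def test_ci_never_exceeds_one(self, six_taxa):
        rng = np.random.default_rng(13)
        for trial in range(5):
            m = random_matrix(rng, six_taxa, 10, "012")
            tree = exhaustive_search(m).trees[0]
            assert ci_ri(m, tree)["CI"] <= 1.0 + 1e-12
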