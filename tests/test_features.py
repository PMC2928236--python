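"""Motif grammar, hydropathy, identity/conservation, terminus pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silkphylo.features import (MOTIF_NAMES, MotifConfig, conservation,
                                hydropathy, identity_stats, length_stats,
                                pair_termini, scan_motifs)
from silkphylo.matrix import CharacterMatrix
from silkphylo.seqs import DomainSequence


def prot(seq, **kw):
    kw.setdefault("id", "x")
    return DomainSequence(kw.pop("id"), seq, molecule="protein", **kw)


class TestMotifScan:
    @pytest.mark.parametrize("seq,motif,present", [
        ("AAAA", "polyA", 1),       # at the >=4 threshold
        ("AAA", "polyA", 0),        # below it
        ("GAGA", "GA", 1),          # two couplets
        ("GAS", "GA", 0),
        ("GSGS", "GS", 1),
        ("GSGA", "GS", 0),
        ("GGAGGQ", "GGX", 1),       # two tandem GGX units
        ("GGA", "GGX", 0),
        ("GPGGYGPGQQ", "GPGX", 1),  # two contiguous GPG+X{1..3} units
        ("GPGGY", "GPGX", 0),
    ])
    def test_threshold_truth_table(self, seq, motif, present):
        assert scan_motifs(prot(seq)).present[motif] == present

    def test_couplet_intervals_are_leftmost_one_based(self):
        p = scan_motifs(prot("GAGASSGSGS"))
        assert p.intervals["GA"] == (1, 4)
        assert p.intervals["GS"] == (7, 10)

    def test_missing_symbols_break_runs(self):
        assert scan_motifs(prot("AA?AA")).present["polyA"] == 0
        assert scan_motifs(prot("AAXAA")).present["polyA"] == 0

    def test_nucleotide_input_rejected(self):
        dna = DomainSequence("d", "ACGTACGT", molecule="nucleotide")
        with pytest.raises(ValueError, match="protein"):
            scan_motifs(dna)

    def test_config_thresholds_are_live(self):
        cfg = MotifConfig(polyA_min=6)
        assert scan_motifs(prot("AAAAA"), cfg).present["polyA"] == 0
        assert scan_motifs(prot("AAAAAA"), cfg).present["polyA"] == 1
        with pytest.raises(ValueError):
            MotifConfig(polyA_min=0)
        with pytest.raises(ValueError):
            MotifConfig(gpgx_x_set=frozenset())

    @given(st.text(alphabet="GASPQY", min_size=0, max_size=30),
           st.text(alphabet="GASPQY", min_size=0, max_size=30))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_presence_monotone_under_concatenation(self, s, t):
        if not s:
            return
        base = scan_motifs(prot(s)).present
        ext = scan_motifs(prot(s + t)).present
        for m in MOTIF_NAMES:
            assert ext[m] >= base[m]


class TestHydropathy:
    def test_constant_window_gives_scale_value(self):
        h = hydropathy(prot("IIIII"), 5)
        assert h.values == [4.5]  # Kyte-Doolittle isoleucine

    def test_mixed_window_is_arithmetic_mean(self):
        h = hydropathy(prot("AG"), 1)
        # A = 1.8, G = -0.4
        assert h.values == pytest.approx([1.8, -0.4])
        h3 = hydropathy(prot("AAGG"), 2 + 1)
        assert h3.values[0] == pytest.approx((1.8 + 1.8 - 0.4) / 3)

    def test_windows_touching_missing_are_omitted(self):
        h = hydropathy(prot("AAA?AAA"), 3)
        assert h.positions == [2, 6]

    @pytest.mark.parametrize("window", [2, 4, 99])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            hydropathy(prot("MKTAYIAK"), window)

    def test_reversal_symmetry(self):
        s = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        f = hydropathy(prot(s), 7)
        r = hydropathy(prot(s[::-1]), 7)
        assert np.allclose(f.values, r.values[::-1])


class TestIdentity:
    def test_identical_pair_is_100(self):
        m = CharacterMatrix(["a", "b"], ["MKTA", "MKTA"], "protein")
        assert identity_stats(m)["mean"] == 100.0

    def test_disjoint_pair_is_0(self):
        m = CharacterMatrix(["a", "b"], ["AAAA", "TTTT"], "protein")
        assert identity_stats(m)["mean"] == 0.0

    def test_missing_columns_excluded_from_denominator(self):
        m = CharacterMatrix(["a", "b"], ["AA??", "AATT"], "protein")
        assert identity_stats(m)["mean"] == 100.0

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACDG?"), size=12)) for _ in range(5)]
        m = CharacterMatrix(list("abcde"), rows, "protein")
        out = identity_stats(m)
        pid = out["matrix"]
        assert np.allclose(pid, pid.T)
        assert np.allclose(np.diag(pid), 100.0)
        assert 0.0 <= out["mean"] <= 100.0
        assert 0.0 <= out["median"] <= 100.0

    def test_single_sequence_rejected(self):
        m = CharacterMatrix(["a"], ["MKTA"], "protein")
        with pytest.raises(ValueError):
            identity_stats(m)


class TestConservation:
    def test_universal_and_majority_positions(self):
        m = CharacterMatrix(["a", "b", "c", "d"],
                            ["MATG", "MATG", "MTTA", "MGTA"], "protein")
        out = conservation(m)
        assert out["universal"] == [1, 3]
        assert 1 in out["majority"] and 2 in out["majority"]

    def test_majority_threshold_is_inclusive(self):
        m = CharacterMatrix(["a", "b", "c", "d"],
                            ["A", "A", "T", "G"], "protein")
        assert conservation(m, 0.5)["majority"] == [1]

    def test_all_missing_column_is_neither(self):
        m = CharacterMatrix(["a", "b"], ["A?", "A?"], "protein")
        out = conservation(m)
        assert out["universal"] == [1] and out["majority"] == [1]


class TestLengthStats:
    def test_range_and_count(self):
        recs = [prot("A" * n, id=f"r{n}", region="N") for n in (151, 160, 162)]
        assert length_stats(recs, "N") == {"min": 151, "max": 162, "n": 3}

    def test_missing_symbols_not_counted(self):
        rec = prot("A" * 155 + "?" * 5, id="r")
        assert length_stats([rec]) == {"min": 155, "max": 155, "n": 1}

    def test_empty_filter_rejected(self):
        with pytest.raises(ValueError):
            length_stats([prot("AA", id="r", region="N")], "C")


class TestPairTermini:
    FLANK = "QTWEVLEHKRMFDNIQTWEVLEHKRMFDNIQTWEVLEHKR"  # 40 aa

    def _n(self, ident, sp, flank=None):
        return prot("M" * 50 + (flank or self.FLANK), id=ident, species=sp)

    def _c(self, ident, sp, flank=None):
        return prot((flank or self.FLANK) + "W" * 40, id=ident, species=sp)

    def test_same_species_identical_flanks_pair(self):
        pairs = pair_termini([self._n("n1", "sp1")], [self._c("c1", "sp1")])
        assert [(p.n_id, p.c_id, p.ambiguous) for p in pairs] == \
            [("n1", "c1", False)]
        assert pairs[0].overlap >= 40

    def test_cross_species_never_pairs(self):
        assert pair_termini([self._n("n1", "sp1")],
                            [self._c("c1", "sp2")]) == []

    def test_near_identical_candidates_flagged_ambiguous(self):
        mutated = self.FLANK[:-1] + "K"
        pairs = pair_termini(
            [self._n("n1", "sp1")],
            [self._c("c1", "sp1"), self._c("c2", "sp1", mutated)],
        )
        assert len(pairs) == 2
        assert all(p.ambiguous for p in pairs)

    def test_divergent_flank_stays_unpaired(self):
        rng = np.random.default_rng(2)
        decoy = "".join(
            c if rng.random() < 0.7 else "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            for c in self.FLANK
        )
        pairs = pair_termini([self._n("n1", "sp1")],
                             [self._c("c1", "sp1", decoy)])
        assert pairs == []

    def test_output_invariant_to_input_order(self):
        ns = [self._n("n1", "sp1"), self._n("n2", "sp2", self.FLANK[::-1])]
        cs = [self._c("c1", "sp1"), self._c("c2", "sp2", self.FLANK[::-1])]
        a = pair_termini(ns, cs)
        b = pair_termini(ns[::-1], cs[::-1])
        assert [(p.n_id, p.c_id) for p in a] == [(p.n_id, p.c_id) for p in b]
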