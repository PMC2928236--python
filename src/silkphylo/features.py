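"""Sequence-level characterization of spidroin domains.

Covers the five structural motif classes of silk repeat biology — poly-alanine
runs (beta-sheet, tensile strength), glycine-alanine and glycine-serine
couplets (beta-sheet), GPGX_n units (beta-turn spirals, extensibility) and
tandem GGX (3_10 helix) — plus Kyte–Doolittle hydropathy profiles,
alignment identity/conservation summaries, and the repeat-flank rule used
to decide which N- and C-terminal cDNAs belong to the same protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
import logging

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .matrix import MISSING, CharacterMatrix
from .seqs import MISSING_SYMBOLS, DomainSequence

log = logging.getLogger(__name__)

MOTIF_NAMES = ("polyA", "GA", "GS", "GPGX", "GGX")

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifConfig:
    """Thresholds of the motif grammar.

    Defaults encode the usual coding rules: a poly-alanine run needs at
    least four contiguous A's; couplet motifs need at least two consecutive
    GA (or GS) couplets; GPGX_n needs at least two contiguous units of GPG
    followed by 1..gpgx_max_x residues from ``gpgx_x_set``; GGX needs at
    least two tandem GGX units.  The X subset for GPGX is configurable
    because published silk motifs vary in which residues fill it.
    """

    polyA_min: int = 4
    couplet_min: int = 2
    gpgx_min_units: int = 2
    gpgx_x_set: frozenset = frozenset("GQYSA")
    gpgx_max_x: int = 3
    ggx_min_units: int = 2

    def __post_init__(self) -> None:
        for name in ("polyA_min", "couplet_min", "gpgx_min_units",
                     "gpgx_max_x", "ggx_min_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.gpgx_x_set:
            raise ValueError("gpgx_x_set must be non-empty")


@dataclass
class MotifProfile:
    """Presence flags (0/1) and leftmost 1-based match intervals per motif."""

    sequence_id: str
    present: dict[str, int]
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def as_row(self) -> list[int]:
        return [self.present[m] for m in MOTIF_NAMES]


def _motif_patterns(cfg: MotifConfig) -> dict[str, re.Pattern]:
    x = "".join(sorted(cfg.gpgx_x_set))
    return {
        "polyA": re.compile("A{%d,}" % cfg.polyA_min),
        "GA": re.compile("(?:GA){%d,}" % cfg.couplet_min),
        "GS": re.compile("(?:GS){%d,}" % cfg.couplet_min),
        "GPGX": re.compile(
            "(?:GPG[%s]{1,%d}){%d,}" % (x, cfg.gpgx_max_x, cfg.gpgx_min_units)
        ),
        "GGX": re.compile("(?:GG[%s]){%d,}" % (_STANDARD_AA, cfg.ggx_min_units)),
    }


def scan_motifs(seq: DomainSequence, cfg: MotifConfig | None = None) -> MotifProfile:
    """Score one protein sequence for the five structural motifs.

    Missing symbols break every run.  Overlapping parses are resolved
    left-greedy by the regex engine, so the reported interval is the
    leftmost qualifying match.
    """
    cfg = cfg or MotifConfig()
    if seq.alphabet == "nucleotide":
        raise ValueError(
            f"record {seq.identifier!r} looks like nucleotide; motif scanning "
            "needs protein input"
        )
    # missing symbols (and the X placeholder) must not bridge runs
    text = "".join(
        c if c in _STANDARD_AA else "*" for c in seq.residues.upper()
    )
    present: dict[str, int] = {}
    intervals: dict[str, tuple[int, int]] = {}
    for name, pat in _motif_patterns(cfg).items():
        m = pat.search(text)
        present[name] = int(m is not None)
        if m:
            intervals[name] = (m.start() + 1, m.end())
    return MotifProfile(seq.identifier, present, intervals)


# ---------------------------------------------------------------------------
# hydropathy

@dataclass
class HydropathyProfile:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    ``values[i]`` is the mean over the window centred on 1-based position
    ``positions[i]``; windows touching a missing symbol are omitted, which
    renders as a break in the plotted line over gapped regions.
    """

    window: int
    positions: list[int]
    values: list[float]


def hydropathy(seq: DomainSequence, window: int = 11) -> HydropathyProfile:
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq.residues):
        raise ValueError(
            f"window {window} exceeds sequence length {len(seq.residues)}"
        )
    if seq.alphabet == "nucleotide":
        raise ValueError("hydropathy is defined for protein sequences")
    res = seq.residues.upper()
    vals = np.array(
        [KYTE_DOOLITTLE.get(c, np.nan) for c in res], dtype=float
    )
    half = window // 2
    positions, values = [], []
    for center in range(half, len(res) - half):
        win = vals[center - half: center + half + 1]
        if np.isnan(win).any():
            continue
        positions.append(center + 1)
        values.append(float(win.mean()))
    return HydropathyProfile(window, positions, values)


# ---------------------------------------------------------------------------
# alignment statistics

def identity_stats(matrix: CharacterMatrix) -> dict:
    """Pairwise percent identity over an alignment.

    Identity for a pair counts matches over the columns where both
    sequences are non-missing, so identical partial sequences score 100%.
    Returns the full symmetric matrix plus the mean and median over all
    unordered pairs.
    """
    n = matrix.ntax
    if n < 2:
        raise ValueError("identity needs at least 2 sequences")
    pid = np.full((n, n), 100.0)
    pair_vals = []
    for i, j in combinations(range(n), 2):
        ri, rj = matrix.rows[i], matrix.rows[j]
        both = [(a, b) for a, b in zip(ri, rj) if a != MISSING and b != MISSING]
        if not both:
            val = float("nan")
        else:
            val = 100.0 * sum(a == b for a, b in both) / len(both)
        pid[i, j] = pid[j, i] = val
        pair_vals.append(val)
    arr = np.array(pair_vals)
    return {
        "matrix": pid,
        "taxa": list(matrix.taxa),
        "mean": float(np.nanmean(arr)),
        "median": float(np.nanmedian(arr)),
    }


def conservation(matrix: CharacterMatrix, majority_fraction: float = 0.5) -> dict:
    """Universally conserved and majority-conserved alignment columns.

    A column is universal when every sequence holds the same non-missing
    residue; it is a majority column when one residue occurs in at least
    ``majority_fraction`` of the sequences.  Positions are 1-based.
    """
    if matrix.ntax == 0 or matrix.nchar == 0:
        raise ValueError("empty alignment")
    universal, majority = [], []
    n = matrix.ntax
    for j in range(matrix.nchar):
        col = matrix.column(j)
        counts: dict[str, int] = {}
        for c in col:
            if c != MISSING:
                counts[c] = counts.get(c, 0) + 1
        if counts:
            top = max(counts.values())
            if top == n and len(counts) == 1:
                universal.append(j + 1)
            if top / n >= majority_fraction:
                majority.append(j + 1)
    return {
        "universal": universal,
        "majority": majority,
        "fraction_majority": len(majority) / matrix.nchar,
    }


def length_stats(
    records: list[DomainSequence],
    region: str | None = None,
) -> dict:
    """Min/max/count of non-missing residue lengths, optionally filtered by
    region (complete N-termini run ~151-162 aa, C-termini ~87-107 aa)."""
    kept = [r for r in records if region is None or r.region == region]
    if not kept:
        raise ValueError(f"no records left after filtering (region={region!r})")
    lengths = [r.ungapped_length() for r in kept]
    return {"min": min(lengths), "max": max(lengths), "n": len(kept)}


# ---------------------------------------------------------------------------
# N <-> C terminus pairing via repeat flanks

@dataclass
class TerminusPair:
    n_id: str
    c_id: str
    identity: float  # fraction over the compared overlap
    overlap: int
    ambiguous: bool = False


def _best_local_identity(a: str, b: str, min_overlap: int) -> tuple[float, int]:
    """Best ungapped sliding-window identity between two fragments.

    Slides one fragment across the other; for each offset with at least
    ``min_overlap`` aligned residues, identity = matches / overlap over the
    columns where both symbols are non-missing.
    """
    best = (0.0, 0)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    miss = np.frombuffer("".join(MISSING_SYMBOLS).encode(), dtype=np.uint8)
    ok_a = ~np.isin(av, miss)
    ok_b = ~np.isin(bv, miss)
    la, lb = len(av), len(bv)
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        sa, sb = max(0, off), max(0, -off)
        ln = min(la - sa, lb - sb)
        if ln < min_overlap:
            continue
        both = ok_a[sa:sa + ln] & ok_b[sb:sb + ln]
        comp = int(both.sum())
        if comp < min_overlap:
            continue
        m = int(((av[sa:sa + ln] == bv[sb:sb + ln]) & both).sum())
        ident = m / comp
        if (ident, comp) > best:
            best = (ident, comp)
    return best


def pair_termini(
    n_records: list[DomainSequence],
    c_records: list[DomainSequence],
    min_identity: float = 0.95,
    min_overlap: int = 30,
) -> list[TerminusPair]:
    """Assign C-terminal to N-terminal cDNAs of the same species whose
    attached repeat fragments are nearly identical.

    Every qualifying candidate is reported; when one N sequence matches
    several C sequences (or vice versa) all pairs are flagged ambiguous
    rather than silently resolved.  Records lacking a repeat fragment are
    skipped with a warning.  Output order is independent of input order.
    """

    def usable(records: list[DomainSequence]) -> list[DomainSequence]:
        kept = []
        for r in records:
            if not r.residues or r.residues.upper().strip("".join(MISSING_SYMBOLS)) == "":
                log.warning("record %s has no repeat fragment; skipped", r.identifier)
                continue
            kept.append(r)
        return sorted(kept, key=lambda r: r.identifier)

    pairs: list[TerminusPair] = []
    for nrec in usable(n_records):
        for crec in usable(c_records):
            if nrec.species is None or nrec.species != crec.species:
                continue
            ident, overlap = _best_local_identity(
                nrec.residues.upper(), crec.residues.upper(), min_overlap
            )
            if overlap >= min_overlap and ident >= min_identity:
                pairs.append(TerminusPair(nrec.identifier, crec.identifier,
                                          ident, overlap))
    n_counts: dict[str, int] = {}
    c_counts: dict[str, int] = {}
    for p in pairs:
        n_counts[p.n_id] = n_counts.get(p.n_id, 0) + 1
        c_counts[p.c_id] = c_counts.get(p.c_id, 0) + 1
    for p in pairs:
        p.ambiguous = n_counts[p.n_id] > 1 or c_counts[p.c_id] > 1
    return pairs
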