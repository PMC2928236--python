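"""Sequence records for spidroin terminal domains and repeat exemplars.

Spidroin (spider fibroin) genes encode a long repetitive core flanked by
non-repetitive N- and C-terminal domains.  Each record here is one such
region from one paralog (MaSp1, TuSp1, Flag, ...) of one species, which is
the unit every downstream analysis operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

log = logging.getLogger(__name__)

#: symbols treated as missing data in every alphabet (gaps are missing).
MISSING_SYMBOLS = frozenset("?-.")

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_ALPHABET = frozenset("ACGTU")

REGIONS = ("N", "C", "repeat", "full")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line/record."""


@dataclass(frozen=True)
class DomainSequence:
    """One sequence region tagged with species, paralog and role.

    ``region`` is one of ``N`` / ``C`` / ``repeat`` / ``full``.  ``residues``
    may contain missing symbols (``?``, ``-``); alphabet is inferred lazily.
    """

    identifier: str
    residues: str
    species: str | None = None
    paralog: str | None = None
    region: str | None = None
    molecule: str | None = None  # "protein" / "nucleotide"; inferred if unset

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.identifier!r}: empty residues")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(
                f"record {self.identifier!r}: region {self.region!r} not in {REGIONS}"
            )
        if self.molecule not in (None, "protein", "nucleotide"):
            raise ValueError(
                f"record {self.identifier!r}: molecule {self.molecule!r}"
            )

    @property
    def alphabet(self) -> str:
        """``protein`` or ``nucleotide``: the explicit ``molecule`` tag if
        set, else inferred from the symbols.

        Inference calls a sequence nucleotide only when it is composed of
        {A,C,G,T,U,N} *and* contains T or U — silk proteins are G/A/S-rich,
        so an all-ACG fragment (e.g. a poly-alanine run) stays protein
        unless tagged otherwise.
        """
        if self.molecule is not None:
            return self.molecule
        observed = {c for c in self.residues.upper() if c not in MISSING_SYMBOLS}
        if (observed and observed <= (NUCLEOTIDE_ALPHABET | {"N"})
                and observed & {"T", "U"}):
            return "nucleotide"
        return "protein"

    def ungapped_length(self) -> int:
        """Residue count excluding missing symbols (and protein 'X')."""
        missing = MISSING_SYMBOLS | ({"X"} if self.alphabet == "protein" else {"N"})
        return sum(1 for c in self.residues.upper() if c not in missing)

    def __len__(self) -> int:
        return len(self.residues)


def _parse_header(header: str) -> dict:
    """Split ``id|species|paralog|region`` headers; plain headers keep only id."""
    if "|" in header:
        parts = header.split("|")
        if len(parts) != 4:
            raise ParseError(
                f"header {header!r}: expected 'id|species|paralog|region' "
                f"(4 fields), got {len(parts)}"
            )
        ident, species, paralog, region = (p.strip() for p in parts)
        return {
            "identifier": ident,
            "species": species or None,
            "paralog": paralog or None,
            "region": region or None,
        }
    return {"identifier": header.strip(), "species": None, "paralog": None, "region": None}


def read_fasta(path: str | Path) -> list[DomainSequence]:
    """Read a FASTA file into :class:`DomainSequence` records.

    Headers of the form ``id|species|paralog|region`` are split into the
    record's metadata; any other header becomes the identifier verbatim.
    Duplicate identifiers and malformed files raise :class:`ParseError`.
    An empty file returns an empty list with a logged warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        log.warning("FASTA file %s is empty", path)
        return []
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        lineno = next(
            i for i, ln in enumerate(text.splitlines(), 1) if ln.strip()
        )
        raise ParseError(f"{path}: line {lineno}: expected '>' header, got {first!r}")
    records: list[DomainSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(rec.description)
        if not str(rec.seq):
            raise ParseError(f"{path}: record {meta['identifier']!r} has no sequence")
        if meta["identifier"] in seen:
            raise ParseError(f"{path}: duplicate identifier {meta['identifier']!r}")
        seen.add(meta["identifier"])
        records.append(DomainSequence(residues=str(rec.seq).upper(), **meta))
    return records


def write_fasta(records: Iterable[DomainSequence], path: str | Path) -> None:
    """Write records with ``id|species|paralog|region`` headers (blank fields kept)."""
    with open(path, "w") as fh:
        for r in records:
            if r.species or r.paralog or r.region:
                header = "|".join(
                    [r.identifier, r.species or "", r.paralog or "", r.region or ""]
                )
            else:
                header = r.identifier
            fh.write(f">{header}\n{r.residues}\n")


@dataclass
class LeafSpeciesMap:
    """Total mapping from gene-tree leaf labels to species labels.

    The study encodes species inside sequence names ("L.h. MaSp1"); the
    reconciliation step needs the mapping explicit, hence this sidecar.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, leaf: str) -> str:
        try:
            return self.entries[leaf]
        except KeyError:
            raise KeyError(f"gene leaf {leaf!r} has no species assignment") from None

    def __contains__(self, leaf: str) -> bool:
        return leaf in self.entries

    def species(self) -> set[str]:
        return set(self.entries.values())

    @classmethod
    def from_records(cls, records: Iterable[DomainSequence]) -> "LeafSpeciesMap":
        entries = {}
        for r in records:
            if r.species is None:
                raise ValueError(f"record {r.identifier!r} has no species label")
            entries[r.identifier] = r.species
        return cls(entries)


def read_leaf_map(path: str | Path) -> LeafSpeciesMap:
    """Read a two-column TSV (gene leaf label, species label)."""
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        leaf, sp = parts[0].strip(), parts[1].strip()
        if leaf in entries:
            raise ParseError(f"{path}: line {lineno}: duplicate leaf {leaf!r}")
        entries[leaf] = sp
    return LeafSpeciesMap(entries)


def write_leaf_map(mapping: LeafSpeciesMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for leaf, sp in mapping.entries.items():
            fh.write(f"{leaf}\t{sp}\n")
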