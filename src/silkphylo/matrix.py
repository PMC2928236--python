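"""Aligned character matrices with missing-data semantics and named partitions.

The parsimony analyses treat alignment gaps as missing data, so every reader
normalizes gap/ambiguity symbols to the canonical missing symbol ``?`` at
load time.  A matrix may carry named contiguous column blocks (the N- and
C-terminal partitions of a concatenated alignment); combined-versus-separate
support analyses address characters through those blocks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqs import MISSING_SYMBOLS, NUCLEOTIDE_ALPHABET, DomainSequence, ParseError

MISSING = "?"

_ALLOWED = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789") | set(MISSING_SYMBOLS)


def _infer_datatype(symbols: set[str]) -> str:
    """``nucleotide`` / ``protein`` / ``standard`` from observed symbols."""
    obs = {s for s in symbols if s not in MISSING_SYMBOLS}
    if obs and obs <= set("01"):
        return "standard"
    if obs and obs <= (NUCLEOTIDE_ALPHABET | {"N"}):
        return "nucleotide"
    return "protein"


def _normalize_row(row: str, datatype: str) -> str:
    missing = set(MISSING_SYMBOLS)
    if datatype == "protein":
        missing.add("X")
    elif datatype == "nucleotide":
        missing.add("N")
    return "".join(MISSING if c in missing else c for c in row)


@dataclass
class CharacterMatrix:
    """Taxa × characters table of state symbols.

    ``rows[i]`` is the normalized state string for ``taxa[i]``; missing cells
    hold ``?``.  ``partitions`` maps block name to a 0-based half-open column
    interval; blocks are disjoint, contiguous and cover the matrix when set.
    Reported positions are 1-based.
    """

    taxa: list[str]
    rows: list[str]
    datatype: str = "protein"
    partitions: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxa: {dup}")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            for t, r in zip(self.taxa, self.rows):
                if len(r) != len(self.rows[0]):
                    raise ValueError(
                        f"ragged matrix: row {t!r} has {len(r)} columns, "
                        f"expected {len(self.rows[0])}"
                    )
        if self.partitions is not None:
            spans = sorted(self.partitions.values())
            covered = 0
            for a, b in spans:
                if a != covered:
                    raise ValueError("partition blocks must be contiguous and disjoint")
                covered = b
            if covered != self.nchar:
                raise ValueError("partition blocks must cover the matrix")

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def is_missing(self, i: int, j: int) -> bool:
        return self.rows[i][j] == MISSING

    def partition_of_column(self, j: int) -> str | None:
        if self.partitions is None:
            return None
        for name, (a, b) in self.partitions.items():
            if a <= j < b:
                return name
        return None

    def block(self, name: str) -> "CharacterMatrix":
        """Extract one named partition as a stand-alone matrix."""
        a, b = self.partitions[name]
        return CharacterMatrix(
            list(self.taxa), [r[a:b] for r in self.rows], self.datatype,
            partitions={name: (0, b - a)},
        )

    def take_columns(self, idx: Sequence[int]) -> "CharacterMatrix":
        """Column subset/resample; partitions are dropped (column order is free)."""
        return CharacterMatrix(
            list(self.taxa), ["".join(r[j] for j in idx) for r in self.rows],
            self.datatype,
        )

    @classmethod
    def from_records(cls, records: Iterable[DomainSequence]) -> "CharacterMatrix":
        records = list(records)
        if not records:
            raise ValueError("no records")
        symbols = {c for r in records for c in r.residues.upper()}
        datatype = _infer_datatype(symbols)
        return cls(
            [r.identifier for r in records],
            [_normalize_row(r.residues.upper(), datatype) for r in records],
            datatype,
        )


# ---------------------------------------------------------------------------
# readers / writers

def read_phylip(path: str | Path) -> CharacterMatrix:
    """Relaxed sequential PHYLIP: header ``ntax nchar``, then ``name  states``.

    Names are whitespace-delimited (no 10-column padding); state strings may
    be split across whitespace but not across lines.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    m = re.match(r"\s*(\d+)\s+(\d+)\s*$", lines[0])
    if not m:
        raise ParseError(f"{path}: line 1: expected 'ntax nchar' header")
    ntax, nchar = int(m.group(1)), int(m.group(2))
    taxa, rows = [], []
    for ln in lines[1 : 1 + ntax]:
        parts = ln.split()
        name, states = parts[0], "".join(parts[1:]).upper()
        bad = set(states) - _ALLOWED
        if bad:
            raise ParseError(f"{path}: row {name!r}: unknown symbol(s) {sorted(bad)}")
        if len(states) != nchar:
            raise ParseError(
                f"{path}: row {name!r}: {len(states)} characters, expected {nchar}"
            )
        taxa.append(name)
        rows.append(states)
    if len(taxa) != ntax:
        raise ParseError(f"{path}: expected {ntax} rows, found {len(taxa)}")
    datatype = _infer_datatype({c for r in rows for c in r})
    return CharacterMatrix(taxa, [_normalize_row(r, datatype) for r in rows], datatype)


def read_nexus(path: str | Path) -> CharacterMatrix:
    """Simple NEXUS: one DATA or CHARACTERS block with DIMENSIONS and MATRIX."""
    path = Path(path)
    text = path.read_text()
    block = re.search(
        r"begin\s+(?:data|characters)\s*;(.*?)end\s*;", text, re.I | re.S
    )
    if not block:
        raise ParseError(f"{path}: no DATA/CHARACTERS block found")
    body = block.group(1)
    dims = re.search(r"dimensions\s+([^;]*);", body, re.I)
    ntax = nchar = None
    if dims:
        mt = re.search(r"ntax\s*=\s*(\d+)", dims.group(1), re.I)
        mc = re.search(r"nchar\s*=\s*(\d+)", dims.group(1), re.I)
        ntax = int(mt.group(1)) if mt else None
        nchar = int(mc.group(1)) if mc else None
    fmt = re.search(r"format\s+([^;]*);", body, re.I)
    datatype = None
    if fmt:
        md = re.search(r"datatype\s*=\s*(\w+)", fmt.group(1), re.I)
        if md:
            dt = md.group(1).lower()
            datatype = {"dna": "nucleotide", "rna": "nucleotide"}.get(dt, dt)
    mat = re.search(r"matrix(.*?);", body, re.I | re.S)
    if not mat:
        raise ParseError(f"{path}: no MATRIX command in block")
    taxa, rows = [], []
    for ln in mat.group(1).splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("["):
            continue
        parts = ln.split()
        name, states = parts[0].strip("'\""), "".join(parts[1:]).upper()
        bad = set(states) - _ALLOWED
        if bad:
            raise ParseError(f"{path}: row {name!r}: unknown symbol(s) {sorted(bad)}")
        taxa.append(name)
        rows.append(states)
    if not taxa:
        raise ParseError(f"{path}: MATRIX command holds no rows")
    if nchar is not None:
        for t, r in zip(taxa, rows):
            if len(r) != nchar:
                raise ParseError(
                    f"{path}: row {t!r}: {len(r)} characters, expected {nchar}"
                )
    if ntax is not None and len(taxa) != ntax:
        raise ParseError(f"{path}: expected {ntax} taxa, found {len(taxa)}")
    if datatype is None:
        datatype = _infer_datatype({c for r in rows for c in r})
    return CharacterMatrix(taxa, [_normalize_row(r, datatype) for r in rows], datatype)


def read_matrix(path: str | Path, format: str | None = None) -> CharacterMatrix:
    """Dispatch on ``format`` (``phylip`` / ``nexus``) or file extension."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "nexus" if suffix in {".nex", ".nexus", ".nxs"} else "phylip"
    if format == "phylip":
        return read_phylip(path)
    if format == "nexus":
        return read_nexus(path)
    raise ValueError(f"unknown matrix format {format!r}")


def write_phylip(matrix: CharacterMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{matrix.ntax} {matrix.nchar}\n")
        for t, r in zip(matrix.taxa, matrix.rows):
            fh.write(f"{t}  {r}\n")


def write_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    dt = {"nucleotide": "dna"}.get(matrix.datatype, matrix.datatype)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin data;\n")
        fh.write(f"  dimensions ntax={matrix.ntax} nchar={matrix.nchar};\n")
        fh.write(f"  format datatype={dt} missing=? gap=-;\n  matrix\n")
        for t, r in zip(matrix.taxa, matrix.rows):
            fh.write(f"    {t}  {r}\n")
        fh.write("  ;\nend;\n")


# ---------------------------------------------------------------------------

def concat_partitions(
    matrices: Sequence[CharacterMatrix],
    fill_missing: bool = False,
    names: Sequence[str] | None = None,
) -> CharacterMatrix:
    """Concatenate aligned blocks into one partitioned matrix.

    Combined columns are numbered 1-based with the first block first (an N
    block of width 168 and a C block of width 109 give combined positions
    1-168 and 169-277).  A taxon absent from a block gets an all-missing row
    there when ``fill_missing`` is set, and is an error otherwise.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    if names is None:
        names = []
        for i, m in enumerate(matrices):
            if m.partitions is not None and len(m.partitions) == 1:
                names.append(next(iter(m.partitions)))
            else:
                names.append(f"p{i + 1}")
    if len(set(names)) != len(names):
        names = [f"p{i + 1}" for i in range(len(matrices))]
    taxa: list[str] = []
    for m in matrices:
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    common = set.intersection(*(set(m.taxa) for m in matrices))
    if not common:
        raise ValueError("blocks share no taxa")
    rows = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, m in zip(names, matrices):
        for t in taxa:
            if t in m.taxa:
                rows[t].append(m.row(t))
            elif fill_missing:
                rows[t].append(MISSING * m.nchar)
            else:
                raise ValueError(
                    f"taxon {t!r} absent from block {name!r} (fill_missing is off)"
                )
        partitions[name] = (offset, offset + m.nchar)
        offset += m.nchar
    return CharacterMatrix(
        taxa, ["".join(rows[t]) for t in taxa], matrices[0].datatype, partitions
    )
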