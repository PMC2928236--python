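"""Bit-packed Fitch scoring engine.

Each character occupies a fixed-width field of one big Python integer: one
bit per observed state plus a high guard bit.  A taxon row packs all of its
character state sets into a single integer, so the Fitch preliminary pass
for an entire matrix at one internal node is a handful of bitwise big-int
operations, and the step count falls out of a popcount.  Zero fields after
an intersection are detected with the subtract-borrow trick: for a field
with its guard bit forced on, subtracting 1 from the field's low bit clears
the guard iff the field's state bits were all zero.

Missing cells carry the full observed state set of their column and so never
contribute steps, which is the gaps-as-missing convention of the analyses.
"""

from __future__ import annotations

from typing import Sequence

from .matrix import MISSING, CharacterMatrix


class PackedMatrix:
    """Matrix rows packed for fast Fitch scoring.

    ``columns`` selects (and may repeat) matrix columns, which is how
    bootstrap pseudo-replicates are built without touching the engine.
    """

    __slots__ = (
        "taxa", "n_chars", "width", "rows", "guards", "low_ones", "state_mask",
        "column_states",
    )

    def __init__(self, matrix: CharacterMatrix, columns: Sequence[int] | None = None):
        if columns is None:
            columns = range(matrix.nchar)
        cols = list(columns)
        self.taxa = list(matrix.taxa)
        self.n_chars = len(cols)
        # per selected column: sorted observed states -> bit index
        self.column_states: list[dict[str, int]] = []
        maxk = 1
        for j in cols:
            obs = sorted({r[j] for r in matrix.rows} - {MISSING})
            self.column_states.append({s: i for i, s in enumerate(obs)})
            maxk = max(maxk, len(obs))
        w = maxk + 1  # +1 guard bit
        self.width = w
        guards = 0
        low_ones = 0
        state_mask = 0
        for f in range(self.n_chars):
            base = f * w
            guards |= 1 << (base + w - 1)
            low_ones |= 1 << base
            k = max(1, len(self.column_states[f]))
            state_mask |= ((1 << k) - 1) << base
        self.guards = guards
        self.low_ones = low_ones
        self.state_mask = state_mask
        self.rows = []
        for r in matrix.rows:
            packed = 0
            for f, j in enumerate(cols):
                states = self.column_states[f]
                base = f * w
                c = r[j]
                if c == MISSING or not states:
                    bits = (1 << max(1, len(states))) - 1  # full set
                else:
                    bits = 1 << states[c]
                packed |= bits << base
            self.rows.append(packed)

    def combine(self, a: int, b: int) -> tuple[int, int]:
        """Fitch preliminary-set combination of two child masks.

        Returns ``(mask, steps)`` where ``steps`` counts characters whose
        child sets were disjoint (union events).
        """
        inter = a & b
        nz_guards = ((inter | self.guards) - self.low_ones) & self.guards
        steps = (self.guards ^ nz_guards).bit_count()
        # expand each surviving guard bit over its field's state bits
        nz_fields = (nz_guards >> (self.width - 1)) * ((1 << (self.width - 1)) - 1)
        mask = (inter & nz_fields) | ((a | b) & ~nz_fields)
        return mask, steps
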