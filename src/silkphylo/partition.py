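"""Combined-versus-separate analysis: partitioned branch support, hidden
branch support, the partition-homogeneity (ILD) test, and detection of
well-supported conflict between trees.

Branch support (BS) here is the Bremer decay of a node on the combined
matrix.  Partitioned branch support (PBS) decomposes it: for each data
partition, the difference between that partition's mean length on the
shortest combined-data trees *lacking* the node and its mean length on the
combined MPTs.  Because every tied tree has the same total length, the PBS
values of a node sum exactly to its BS (the Baker–DeSalle identity), which
the test suite uses as the primary correctness oracle.  Hidden branch
support compares PBS with the decay the partition gives the node on its
own (negative when the partition's own shortest trees contradict the node):
PHBS_j = PBS_j - separateBS_j, and HBS = sum_j PHBS_j measures support that
only emerges in combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._packed import PackedMatrix
from .matrix import MISSING, CharacterMatrix
from .parsimony import (
    SearchResult,
    _score,
    phylo_to_adj,
    search_best,
    strict_consensus,
)
from .tree import PhyloTree, splits_conflict


@dataclass
class NodeSupport:
    """Support decomposition at one combined-tree node."""

    split: frozenset
    bs: float
    pbs: dict[str, float]
    separate_bs: dict[str, float] = field(default_factory=dict)
    phbs: dict[str, float] = field(default_factory=dict)

    @property
    def hbs(self) -> float:
        return sum(self.phbs.values())


@dataclass
class SupportDecomposition:
    partitions: list[str]
    nodes: list[NodeSupport]

    def totals(self) -> dict:
        out: dict = {
            "BS": sum(n.bs for n in self.nodes),
            "PBS": {p: sum(n.pbs[p] for n in self.nodes) for p in self.partitions},
        }
        if self.nodes and self.nodes[0].phbs:
            out["PHBS"] = {
                p: sum(n.phbs[p] for n in self.nodes) for p in self.partitions
            }
            out["HBS"] = sum(n.hbs for n in self.nodes)
        return out


def _require_partitions(matrix: CharacterMatrix) -> list[str]:
    if matrix.partitions is None or len(matrix.partitions) < 2:
        raise ValueError("a partitioned matrix with >=2 blocks is required")
    return list(matrix.partitions)


def _partition_packed(matrix: CharacterMatrix) -> dict[str, PackedMatrix]:
    return {
        name: PackedMatrix(matrix, columns=range(a, b))
        for name, (a, b) in matrix.partitions.items()
    }


def _mean_partition_lengths(
    trees: list[PhyloTree], taxa: list[str], packs: dict[str, PackedMatrix]
) -> dict[str, float]:
    adjs = [phylo_to_adj(t, taxa) for t in trees]
    return {
        name: float(np.mean([_score(a, pk) for a in adjs]))
        for name, pk in packs.items()
    }


def pbs(
    matrix: CharacterMatrix,
    combined: SearchResult | None = None,
    seed: int = 0,
    n_addition_reps: int = 10,
    swap: str = "TBR",
) -> SupportDecomposition:
    """Partitioned branch support for every node of the combined strict
    consensus; anti-constraint tie sets are averaged, so values may be
    fractional."""
    parts = _require_partitions(matrix)
    if combined is None:
        combined = search_best(matrix, seed=seed,
                               n_addition_reps=n_addition_reps, swap=swap)
    packs = _partition_packed(matrix)
    mpt_means = _mean_partition_lengths(combined.trees, matrix.taxa, packs)
    nodes = []
    for split in sorted(strict_consensus(combined.trees).bipartitions(), key=sorted):
        anti = search_best(matrix, seed=seed, forbid=split,
                           n_addition_reps=n_addition_reps, swap=swap)
        anti_means = _mean_partition_lengths(anti.trees, matrix.taxa, packs)
        nodes.append(NodeSupport(
            split=split,
            bs=float(anti.best_length - combined.best_length),
            pbs={p: anti_means[p] - mpt_means[p] for p in parts},
        ))
    return SupportDecomposition(parts, nodes)


def _signed_separate_bs(
    block: CharacterMatrix, split: frozenset, best: int,
    seed: int, n_addition_reps: int, swap: str,
) -> float:
    req = search_best(block, seed=seed, require=split,
                      n_addition_reps=n_addition_reps, swap=swap)
    if req.best_length > best:
        # the node contradicts this partition's shortest trees
        return -float(req.best_length - best)
    anti = search_best(block, seed=seed, forbid=split,
                       n_addition_reps=n_addition_reps, swap=swap)
    return float(anti.best_length - best)


def hbs(
    matrix: CharacterMatrix,
    combined: SearchResult | None = None,
    seed: int = 0,
    n_addition_reps: int = 10,
    swap: str = "TBR",
) -> SupportDecomposition:
    """Full decomposition: BS, PBS, separate-analysis BS, PHBS and HBS."""
    parts = _require_partitions(matrix)
    decomp = pbs(matrix, combined=combined, seed=seed,
                 n_addition_reps=n_addition_reps, swap=swap)
    blocks = {p: matrix.block(p) for p in parts}
    separate_best = {
        p: search_best(blocks[p], seed=seed,
                       n_addition_reps=n_addition_reps, swap=swap).best_length
        for p in parts
    }
    for node in decomp.nodes:
        for p in parts:
            node.separate_bs[p] = _signed_separate_bs(
                blocks[p], node.split, separate_best[p],
                seed, n_addition_reps, swap,
            )
            node.phbs[p] = node.pbs[p] - node.separate_bs[p]
    return decomp


# ---------------------------------------------------------------------------
# partition homogeneity (incongruence length difference) test

def _variable_columns(matrix: CharacterMatrix) -> list[int]:
    out = []
    for j in range(matrix.nchar):
        if len({r[j] for r in matrix.rows} - {MISSING}) > 1:
            out.append(j)
    return out


def _best_length(matrix: CharacterMatrix, columns, seed: int,
                 n_addition_reps: int) -> int:
    sub = matrix.take_columns(list(columns))
    return search_best(sub, seed=seed, n_addition_reps=n_addition_reps).best_length


def pht(
    matrix: CharacterMatrix,
    n_perm: int = 1000,
    addition_reps: int = 10,
    seed: int | None = None,
) -> dict:
    """Partition-homogeneity (ILD) permutation test.

    Invariant characters are removed first; the incongruence statistic
    D = combined length - sum of separate partition lengths is compared to
    a null built by randomly reassigning the variable characters to blocks
    of the original sizes.  p uses the add-one estimator with the >=
    orientation (greater incongruence is more extreme).
    """
    parts = _require_partitions(matrix)
    if seed is None:
        raise ValueError("pht requires an explicit seed")
    rng = np.random.default_rng(seed)
    variable = _variable_columns(matrix)
    cols_by_part = {
        p: [j for j in variable if matrix.partition_of_column(j) == p]
        for p in parts
    }
    widths = [len(cols_by_part[p]) for p in parts]
    for p, w in zip(parts, widths):
        if w == 0:
            raise ValueError(f"partition {p!r} has no variable characters")

    def d_stat(assignment: list[list[int]]) -> int:
        combined = [j for block in assignment for j in block]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        total = _best_length(matrix, combined, sub_seed, addition_reps)
        sep = sum(
            _best_length(matrix, block, sub_seed, addition_reps)
            for block in assignment
        )
        return total - sep

    observed = d_stat([cols_by_part[p] for p in parts])
    exceed = 0
    for _ in range(n_perm):
        perm = list(rng.permutation(variable))
        blocks, at = [], 0
        for w in widths:
            blocks.append(perm[at:at + w])
            at += w
        if d_stat(blocks) >= observed:
            exceed += 1
    return {
        "D": observed,
        "p": (1 + exceed) / (1 + n_perm),
        "n_perm": n_perm,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# supported conflict between trees

def supported_conflicts(
    tree_a: PhyloTree,
    tree_b: PhyloTree,
    threshold: float = 70.0,
) -> list[tuple[frozenset, float, frozenset, float]]:
    """Pairs of incompatible splits both supported at or above ``threshold``
    (bootstrap percentages stored on the trees' internal nodes)."""
    la, lb = frozenset(tree_a.leaf_names()), frozenset(tree_b.leaf_names())
    if la != lb:
        raise ValueError(
            f"leaf-set mismatch: only-in-A={sorted(la - lb)}, "
            f"only-in-B={sorted(lb - la)}"
        )
    sa = {
        s: sup for s, sup in tree_a.bipartitions(with_support=True).items()
        if sup is not None and sup >= threshold
    }
    sb = {
        s: sup for s, sup in tree_b.bipartitions(with_support=True).items()
        if sup is not None and sup >= threshold
    }
    out = []
    for a, sup_a in sorted(sa.items(), key=lambda kv: sorted(kv[0])):
        for b, sup_b in sorted(sb.items(), key=lambda kv: sorted(kv[0])):
            if splits_conflict(a, b, la):
                out.append((a, sup_a, b, sup_b))
    return out
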