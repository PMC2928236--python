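"""Synthetic data with the statistical structure of a spidroin terminal-domain
study, with full ground truth for recovery tests.

The generator emulates the study conditions: a gene family of roughly 25
terminal-domain pairs spread over ~15 species via duplication/loss on a
species tree; aligned N- and C-terminal domain blocks with lengths of
151-162 and 87-107 residues and deeper divergence (lower identity) in the C
block; exemplar repeats assembled from the silk motif grammar (poly-A,
GA/GS couplets, GPGX units, tandem GGX) whose true motif states evolve by a
two-state gain/loss process; and paired N/C partial transcripts sharing a
near-identical repeat flank.  Sequences are generated already aligned (no
indels): in the real pipeline alignments are inputs, so synthetic matrices
enter at the same stage.  Every generator is deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import MOTIF_NAMES, MotifConfig, scan_motifs
from .matrix import CharacterMatrix, write_phylip
from .seqs import DomainSequence, LeafSpeciesMap, write_fasta, write_leaf_map
from .tree import Node, PhyloTree, to_newick, write_newick

_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues that cannot create or extend any motif unit
_SPACER_AA = "TLEVKFDNIRHWMC"

#: grammar units realizing each motif; spacers keep units from interacting
MOTIF_UNITS = {
    "polyA": "AAAAA",
    "GA": "GAGAGA",
    "GS": "GSGSGS",
    "GPGX": "GPGGYGPGQQ",
    "GGX": "GGAGGQGGY",
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Substitution intensities are expected substitutions per site per unit
    branch length; the N block is slower than the C block so N-terminal
    identity exceeds C-terminal identity, and the defaults put mean
    N-terminal pairwise identity in the mid-30s% on the default tree depth.
    """

    seed: int
    n_species: int = 15
    dup_rate: float = 0.5
    loss_rate: float = 0.2
    n_length_range: tuple[int, int] = (151, 162)
    c_length_range: tuple[int, int] = (87, 107)
    n_intensity: float = 0.95
    c_intensity: float = 1.5
    motif_gain_rate: float = 0.4
    motif_loss_rate: float = 0.4
    root_motif_p: float = 0.5
    flank_length: int = 40
    decoy_identity: float = 0.7
    min_tips: int = 4
    max_attempts: int = 50

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("dup_rate", "loss_rate", "n_intensity", "c_intensity",
                     "motif_gain_rate", "motif_loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rng_ in (self.n_length_range, self.c_length_range):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValueError(f"bad length range {rng_}")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    species_newick: str
    gene_newick: str
    n_duplications: int
    n_losses: int
    leaf_map: dict[str, str]
    motif_states: dict[str, dict[str, int]] = field(default_factory=dict)
    pairings: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# species tree

def simulate_species_tree(n_species: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) rooted ultrametric tree, depth scaled to 1."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    root = Node()
    a, b = Node(), Node()
    root.add(a)
    root.add(b)
    birth = {id(a): 0.0, id(b): 0.0}
    active = [a, b]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.length = t - birth[id(parent)]
        c1, c2 = Node(), Node()
        parent.add(c1)
        parent.add(c2)
        birth[id(c1)] = birth[id(c2)] = t
        active.extend([c1, c2])
    depth = t + rng.exponential(1.0 / len(active))
    for leaf in active:
        leaf.length = depth - birth[id(leaf)]
    for n in root.postorder():
        if n.length is not None:
            n.length /= depth
    # stable species names in traversal order
    for i, leaf in enumerate(root.leaves()):
        leaf.name = f"S{i + 1:02d}"
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# gene family by birth-death along the species tree

def simulate_gene_family(
    species_tree: PhyloTree,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    root_duplications: int = 0,
    min_tips: int = 4,
    max_attempts: int = 50,
) -> tuple[PhyloTree, GroundTruth]:
    """Evolve gene lineages along the species tree by duplication and loss.

    Internal nodes of the returned gene tree carry ``event`` labels
    (``duplication`` / ``speciation``); a duplication both of whose copies
    die leaves no trace, so the recorded duplication count is the number of
    duplication nodes surviving in the tree — the quantity reconciliation
    should recover (exactly so when ``loss_rate`` is 0).
    ``root_duplications`` forces that many duplications at the root (so one
    forced duplication with no loss yields two complete copies of the
    species tree).
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    stime: dict[int, float] = {id(species_tree.root): 0.0}
    for n in species_tree.root.preorder():
        for c in n.children:
            stime[id(c)] = stime[id(n)] + (c.length or 0.0)
    total_rate = dup_rate + loss_rate
    losses = [0]

    def lineage(sp: Node, t: float) -> Node | None:
        """Fate of a gene lineage on the branch above ``sp`` at time ``t``."""
        t_end = stime[id(sp)]
        while True:
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if t + dt >= t_end:
                break
            t = t + dt
            if rng.random() < (loss_rate / total_rate if total_rate else 0):
                losses[0] += 1
                return None
            left = lineage(sp, t)
            right = lineage(sp, t)
            if left is None and right is None:
                return None
            if left is None or right is None:
                return left if right is None else right
            node = Node()
            node.event = "duplication"
            node.length = t  # temporary: absolute time, rescaled below
            node.add(left)
            node.add(right)
            return node
        if sp.is_leaf:
            tip = Node(name=sp.name)
            tip.length = t_end
            return tip
        kids = [lineage(c, t_end) for c in sp.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = Node()
        node.event = "speciation"
        node.length = t_end
        node.add(kids[0])
        node.add(kids[1])
        return node

    for attempt in range(max_attempts):
        losses[0] = 0
        roots = [lineage(species_tree.root, 0.0)
                 for _ in range(root_duplications + 1)]
        roots = [r for r in roots if r is not None]
        if not roots:
            continue
        top = roots[0]
        for extra in roots[1:]:
            join = Node()
            join.event = "duplication"
            join.length = 0.0
            join.add(top)
            join.add(extra)
            top = join
        if len(top.leaves()) < min_tips or not top.children:
            continue
        # absolute times -> branch lengths; name tips per-species
        def finalize(n: Node, t0: float) -> None:
            t = n.length if n.length is not None else t0
            for c in n.children:
                finalize(c, t)
            n.length = max(0.0, t - t0)

        finalize(top, 0.0)
        counters: dict[str, int] = {}
        leaf_map: dict[str, str] = {}
        for leaf in top.leaves():
            sp = leaf.name
            counters[sp] = counters.get(sp, 0) + 1
            leaf.name = f"{sp}_g{counters[sp]}"
            leaf_map[leaf.name] = sp
        gene_tree = PhyloTree(top, rooted=True)
        n_dup = sum(1 for n in top.postorder() if n.event == "duplication")
        truth = GroundTruth(
            species_newick=to_newick(species_tree, lengths=True),
            gene_newick=to_newick(gene_tree, lengths=True),
            n_duplications=n_dup,
            n_losses=losses[0],
            leaf_map=leaf_map,
        )
        return gene_tree, truth
    raise RuntimeError(
        f"no surviving gene family with >={min_tips} tips in "
        f"{max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# aligned domain matrices

def _evolve_sites(parent: np.ndarray, intensity: float, length: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Symmetric jump process: Poisson(intensity * branch) substitution
    events per site, each replacing the residue with a uniform different
    one."""
    child = parent.copy()
    hits = rng.poisson(intensity * length, size=parent.size)
    for i in np.nonzero(hits)[0]:
        for _ in range(hits[i]):
            new = rng.integers(19)
            child[i] = new if new < child[i] else new + 1
    return child


def simulate_domains(
    gene_tree: PhyloTree,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[CharacterMatrix, dict[str, list[DomainSequence]]]:
    """Evolve aligned N- and C-terminal blocks along the gene tree.

    Returns the partitioned matrix (N block first) and the per-region
    records.  No indels are generated; both blocks are rectangular.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_len = int(rng.integers(config.n_length_range[0],
                             config.n_length_range[1] + 1))
    c_len = int(rng.integers(config.c_length_range[0],
                             config.c_length_range[1] + 1))
    if n_len < 1 or c_len < 1:
        raise ValueError("zero-length domain")
    root_n = rng.integers(0, 20, size=n_len)
    root_c = rng.integers(0, 20, size=c_len)
    seqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def walk(node: Node, sn: np.ndarray, sc: np.ndarray) -> None:
        for ch in node.children:
            ln = ch.length or 0.0
            cn = _evolve_sites(sn, config.n_intensity, ln, rng)
            cc = _evolve_sites(sc, config.c_intensity, ln, rng)
            if ch.is_leaf:
                seqs[ch.name] = (cn, cc)
            else:
                walk(ch, cn, cc)

    root = gene_tree.root
    if root.is_leaf:
        raise ValueError("degenerate gene tree")
    walk(root, root_n, root_c)
    taxa = [l.name for l in gene_tree.leaves()]
    rows = []
    records: dict[str, list[DomainSequence]] = {"N": [], "C": []}
    for t in taxa:
        sn, sc = seqs[t]
        n_str = "".join(_AA[i] for i in sn)
        c_str = "".join(_AA[i] for i in sc)
        rows.append(n_str + c_str)
        sp = t.rsplit("_g", 1)[0]
        records["N"].append(DomainSequence(f"{t}_N", n_str, species=sp,
                                           paralog=t, region="N",
                                           molecule="protein"))
        records["C"].append(DomainSequence(f"{t}_C", c_str, species=sp,
                                           paralog=t, region="C",
                                           molecule="protein"))
    matrix = CharacterMatrix(
        taxa, rows, "protein",
        partitions={"N": (0, n_len), "C": (n_len, n_len + c_len)},
    )
    return matrix, records


# ---------------------------------------------------------------------------
# repeats from the motif grammar

def _spacer(rng: np.random.Generator, lo: int = 3, hi: int = 6) -> str:
    ln = int(rng.integers(lo, hi + 1))
    return "".join(_SPACER_AA[i] for i in rng.integers(0, len(_SPACER_AA), ln))


def build_exemplar(states: dict[str, int], rng: np.random.Generator,
                   cfg: MotifConfig | None = None) -> str:
    """Construct a repeat whose motif scan equals ``states`` exactly."""
    cfg = cfg or MotifConfig()
    parts = [_spacer(rng)]
    for m in MOTIF_NAMES:
        if states.get(m, 0):
            parts.append(MOTIF_UNITS[m])
            parts.append(_spacer(rng))
    # pad to a repeat-like length with inert residues
    while sum(len(p) for p in parts) < 30:
        parts.append(_spacer(rng))
    seq = "".join(parts)
    probe = DomainSequence("probe", seq, region="repeat", molecule="protein")
    got = scan_motifs(probe, cfg).present
    want = {m: int(states.get(m, 0)) for m in MOTIF_NAMES}
    if got != want:
        raise AssertionError(
            f"grammar construction violated its own coding: {got} != {want}"
        )
    return seq


def simulate_repeats(
    gene_tree: PhyloTree,
    config: SimulationConfig,
    seed: int | None = None,
    cfg: MotifConfig | None = None,
) -> tuple[list[DomainSequence], dict[str, dict[str, int]]]:
    """Evolve motif presence by a two-state Markov process and emit one
    exemplar repeat per tip realizing its true state vector."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g, l = config.motif_gain_rate, config.motif_loss_rate
    if g == 0 and l == 0 and config.root_motif_p not in (0.0, 1.0):
        pass  # states simply inherit the root draw

    def transition(state: int, ln: float) -> int:
        tot = g + l
        if tot == 0 or ln == 0:
            return state
        decay = 1.0 - np.exp(-tot * ln)
        p_gain = (g / tot) * decay
        p_loss = (l / tot) * decay
        r = rng.random()
        if state == 0:
            return 1 if r < p_gain else 0
        return 0 if r < p_loss else 1

    states: dict[str, dict[str, int]] = {}

    def walk(node: Node, vec: dict[str, int]) -> None:
        for ch in node.children:
            child_vec = {
                m: transition(vec[m], ch.length or 0.0) for m in MOTIF_NAMES
            }
            if ch.is_leaf:
                states[ch.name] = child_vec
            else:
                walk(ch, child_vec)

    root_vec = {
        m: int(rng.random() < config.root_motif_p) for m in MOTIF_NAMES
    }
    walk(gene_tree.root, root_vec)
    records = []
    for t in sorted(states):
        seq = build_exemplar(states[t], rng, cfg)
        records.append(DomainSequence(
            f"{t}_rep", seq, species=t, paralog=t, region="repeat",
            molecule="protein",
        ))
    return records, states


def simulate_single_gain_history(
    tree: PhyloTree, seed: int
) -> tuple[CharacterMatrix, frozenset | str]:
    """One irreversible motif gain on a uniformly chosen branch.

    The gain branch is drawn from branches that are neither the root nor a
    child of the root, so the root state is unambiguously 0 and parsimony
    can localize the gain exactly; the motif is present in precisely the
    subtended clade.  Returns the binary one-character matrix and the gain
    branch's key (subtended leaf set, or leaf name for a terminal branch).
    """
    rng = np.random.default_rng(seed)
    candidates = [
        n for n in tree.postorder()
        if n is not tree.root and n.parent is not tree.root
    ]
    if not candidates:
        raise ValueError("tree too small for a nested gain branch")
    node = candidates[int(rng.integers(len(candidates)))]
    clade = {l.name for l in node.leaves()}
    taxa = tree.leaf_names()
    matrix = CharacterMatrix(
        taxa, ["1" if t in clade else "0" for t in taxa], "standard"
    )
    key = node.name if node.is_leaf else frozenset(clade)
    return matrix, key


# ---------------------------------------------------------------------------
# paired partial transcripts

def _mutate(seq: str, keep_p: float, rng: np.random.Generator) -> str:
    out = []
    for c in seq:
        if rng.random() < keep_p:
            out.append(c)
        else:
            new = _AA[int(rng.integers(19))]
            out.append(new if new != c else _AA[19])
    return "".join(out)


def make_paired_transcripts(
    gene_tree: PhyloTree,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[DomainSequence], list[DomainSequence], list[tuple[str, str]]]:
    """Per tip, one N and one C partial transcript sharing an identical
    repeat flank; flanks of other paralogs from the same species are decoys
    mutated down to ``config.decoy_identity``."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tips = [l.name for l in gene_tree.leaves()]
    by_species: dict[str, list[str]] = {}
    for t in tips:
        by_species.setdefault(t.rsplit("_g", 1)[0], []).append(t)
    n_records, c_records, pairing = [], [], []
    for sp in sorted(by_species):
        base = "".join(_AA[i] for i in rng.integers(0, 20, config.flank_length))
        for i, t in enumerate(sorted(by_species[sp])):
            flank = base if i == 0 else _mutate(base, config.decoy_identity, rng)
            ndom = "".join(_AA[i] for i in rng.integers(0, 20, 60))
            cdom = "".join(_AA[i] for i in rng.integers(0, 20, 50))
            n_records.append(DomainSequence(
                f"{t}_N", ndom + flank, species=sp, paralog=t, region="N",
                molecule="protein"))
            c_records.append(DomainSequence(
                f"{t}_C", flank + cdom, species=sp, paralog=t, region="C",
                molecule="protein"))
            pairing.append((f"{t}_N", f"{t}_C"))
    return n_records, c_records, pairing


# ---------------------------------------------------------------------------
# one-call dataset

def simulate_dataset(config: SimulationConfig, out_dir: str | Path | None = None):
    """Generate the full synthetic study: species tree, gene family, domain
    matrix, repeats, paired transcripts and a truth record.

    With ``out_dir`` set, writes species.nwk, gene_tree.nwk, leafmap.tsv,
    domains.phy, repeats.fasta, transcripts_N.fasta, transcripts_C.fasta
    and truth.json.
    """
    rng = np.random.default_rng(config.seed)
    s_seed, g_seed, d_seed, r_seed, p_seed = (
        int(x) for x in rng.integers(0, 2**31 - 1, 5)
    )
    species = simulate_species_tree(config.n_species, s_seed)
    gene_tree, truth = simulate_gene_family(
        species, config.dup_rate, config.loss_rate, g_seed,
        min_tips=config.min_tips, max_attempts=config.max_attempts,
    )
    matrix, domain_records = simulate_domains(gene_tree, config, d_seed)
    repeats, motif_states = simulate_repeats(gene_tree, config, r_seed)
    n_rec, c_rec, pairing = make_paired_transcripts(gene_tree, config, p_seed)
    truth.motif_states = motif_states
    truth.pairings = pairing
    data = {
        "species_tree": species,
        "gene_tree": gene_tree,
        "leaf_map": LeafSpeciesMap(truth.leaf_map),
        "matrix": matrix,
        "domain_records": domain_records,
        "repeats": repeats,
        "transcripts_N": n_rec,
        "transcripts_C": c_rec,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_newick(species, out / "species.nwk", lengths=True)
        write_newick(gene_tree, out / "gene_tree.nwk", lengths=True)
        write_leaf_map(data["leaf_map"], out / "leafmap.tsv")
        write_phylip(matrix, out / "domains.phy")
        (out / "partitions.json").write_text(json.dumps(matrix.partitions))
        write_fasta(repeats, out / "repeats.fasta")
        write_fasta(n_rec, out / "transcripts_N.fasta")
        write_fasta(c_rec, out / "transcripts_C.fasta")
        (out / "truth.json").write_text(json.dumps(asdict(truth), indent=1))
    return data
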