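"""Evolution of silk structural motifs on a fixed rooted tree.

Exemplar repeat sequences (one repeat unit per spidroin) are scored for the
five structural motifs, assembled into a 0/1 character matrix, and the
motifs' gains and losses are reconstructed by parsimony on a user-supplied
rooted tree (typically the combined N+C terminal-domain tree).  Motifs are
treated as unordered reversible binary characters; taxa with no exemplar
enter as full-ambiguity rows.  Nodes whose most-parsimonious state set is
{0,1} are flagged equivocal, and whenever ACCTRAN and DELTRAN disagree the
summary marks the motif as having other equally parsimonious
reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import MOTIF_NAMES, MotifConfig, scan_motifs
from .matrix import MISSING, CharacterMatrix
from .reconstruct import AncestralReconstruction
from .reconstruct import ancestral_states as _reconstruct
from .seqs import DomainSequence
from .tree import PhyloTree


@dataclass
class MotifMatrix:
    """Taxa x 5 binary presence matrix with exemplar provenance."""

    matrix: CharacterMatrix
    provenance: dict[str, str]  # taxon -> exemplar record id

    @property
    def taxa(self) -> list[str]:
        return self.matrix.taxa


def build_motif_matrix(
    exemplars: list[DomainSequence],
    cfg: MotifConfig | None = None,
    taxa: list[str] | None = None,
) -> MotifMatrix:
    """Score one exemplar repeat per taxon into a binary motif matrix.

    The exemplar's ``species`` label (falling back to its identifier) names
    the taxon.  When ``taxa`` is given, taxa without an exemplar receive an
    all-``?`` row.  Two exemplars for one taxon is an error.
    """
    cfg = cfg or MotifConfig()
    rows: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for rec in exemplars:
        taxon = rec.species or rec.identifier
        if taxon in rows:
            raise ValueError(f"duplicate exemplar for taxon {taxon!r}")
        profile = scan_motifs(rec, cfg)
        rows[taxon] = "".join(str(profile.present[m]) for m in MOTIF_NAMES)
        provenance[taxon] = rec.identifier
    if taxa is None:
        taxa = list(rows)
    for t in taxa:
        rows.setdefault(t, MISSING * len(MOTIF_NAMES))
    matrix = CharacterMatrix(list(taxa), [rows[t] for t in taxa], "standard")
    return MotifMatrix(matrix, provenance)


def ancestral_states(
    tree: PhyloTree, motifs: MotifMatrix | CharacterMatrix
) -> AncestralReconstruction:
    """Parsimony reconstruction of every motif on a rooted tree."""
    matrix = motifs.matrix if isinstance(motifs, MotifMatrix) else motifs
    names = list(MOTIF_NAMES)[: matrix.nchar] if matrix.nchar == len(MOTIF_NAMES) \
        else [str(j + 1) for j in range(matrix.nchar)]
    return _reconstruct(tree, matrix, char_names=names)


def dollo_reconstruction(
    tree: PhyloTree, motifs: MotifMatrix | CharacterMatrix
) -> dict[str, dict]:
    """Dollo parsimony: one gain per motif, losses counted thereafter.

    Offered as an alternative to the default freely reversible coding for
    users who consider motif re-gain implausible.  The gain sits on the
    stem of the smallest clade containing every presence; losses are the
    maximal all-absent subtrees inside it (subtrees of only missing data
    are treated as uninformative, not as losses).
    """
    matrix = motifs.matrix if isinstance(motifs, MotifMatrix) else motifs
    if not tree.rooted:
        raise ValueError("Dollo reconstruction needs a rooted tree")
    names = list(MOTIF_NAMES)[: matrix.nchar] if matrix.nchar == len(MOTIF_NAMES) \
        else [str(j + 1) for j in range(matrix.nchar)]
    row = {t: r for t, r in zip(matrix.taxa, matrix.rows)}
    out: dict[str, dict] = {}
    for j, name in enumerate(names):
        def state(leaf):
            return row[leaf.name][j]

        present = [l for l in tree.leaves() if state(l) == "1"]
        if not present:
            out[name] = {"gain_branch": None, "gains": 0, "losses": 0,
                         "loss_branches": []}
            continue
        # smallest clade containing every presence
        node = present[0]
        wanted = {l.name for l in present}
        while not wanted <= {l.name for l in node.leaves()}:
            node = node.parent
        loss_branches = []

        def walk(n):
            states = {state(l) for l in n.leaves()}
            if states <= {"0"}:
                key = n.name if n.is_leaf else frozenset(
                    l.name for l in n.leaves())
                loss_branches.append(key)
                return
            for c in n.children:
                walk(c)

        for c in node.children:
            walk(c)
        gain_key = node.name if node.is_leaf else frozenset(
            l.name for l in node.leaves())
        out[name] = {
            "gain_branch": gain_key, "gains": 1,
            "losses": len(loss_branches), "loss_branches": loss_branches,
        }
    return out


def count_events(rec: AncestralReconstruction) -> dict[str, dict]:
    """Gains (0 -> 1), losses (1 -> 0) and equivocal nodes per motif.

    Counts are reported separately for ACCTRAN and DELTRAN; when the two
    optimizations place events differently the motif is flagged as having
    other equally parsimonious reconstructions.
    """
    out: dict[str, dict] = {}
    for name, cr in zip(rec.char_names, rec.chars):
        per_opt = {}
        for opt, events in (("ACCTRAN", cr.acctran_events),
                            ("DELTRAN", cr.deltran_events)):
            gains = [e.branch for e in events
                     if e.from_state == "0" and e.to_state == "1"]
            losses = [e.branch for e in events
                      if e.from_state == "1" and e.to_state == "0"]
            per_opt[opt] = {
                "gains": len(gains), "losses": len(losses),
                "gain_branches": gains, "loss_branches": losses,
            }
        acc = {e.astuple() for e in cr.acctran_events}
        dl = {e.astuple() for e in cr.deltran_events}
        out[name] = {
            **per_opt,
            "equivocal_nodes": len(cr.equivocal_nodes),
            "other_equally_parsimonious": acc != dl,
            "length": cr.length,
        }
    return out
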