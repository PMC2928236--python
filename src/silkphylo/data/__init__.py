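"""Bundled example inputs."""

from importlib import resources

from ..tree import PhyloTree, parse_newick


def load_synthetic_species_tree() -> PhyloTree:
    """Rooted species tree over the 15 study species.

    This is a *synthetic stand-in*: the study's composite species phylogeny
    is published as a figure, so this fixture reassembles only the coarse,
    text-stated lineage structure (Mygalomorphae basal; then Haplogynae,
    the RTA clade, Deinopoidea and Araneoidea, the last holding the
    Theridiidae / Nephilidae / Araneidae genera).  Within-family placements
    are plausible but not authoritative; treat it as an example input.
    """
    text = (
        resources.files(__package__)
        .joinpath("species_tree_synthetic.nwk")
        .read_text()
    )
    return parse_newick(text, rooted=True)
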