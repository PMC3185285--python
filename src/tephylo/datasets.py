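"""Bundled study fixtures: the 12-species *Drosophila* phylogeny (branch
lengths in substitutions per site) and the gene panels used in the analysis.
"""

from __future__ import annotations

from importlib import resources

from .phylo import Phylogeny, parse_newick

__all__ = [
    "study_tree_newick",
    "study_tree",
    "PIRNA_GENES",
    "CONTROL_GENES_12SP",
    "CONTROL_GENES_SUBGROUP",
    "SUBGROUP_5SP",
]

#: Components of the piRNA biogenesis machinery / nuage.
PIRNA_GENES: tuple = (
    "ago3", "armitage", "aubergine", "cutoff", "krimper", "maelstrom",
    "piwi", "spn-E", "squash", "vasa", "zucchini",
)

#: Control genes matched to the piRNA set by omega distribution (12 species).
CONTROL_GENES_12SP: tuple = (
    "CG8222", "CG7876", "CG2595", "CG31605", "CG31287", "CG33934",
    "CG6898", "CG15013", "CG4815", "CG11405", "CG4259",
)

#: Control genes matched on the *D. melanogaster* subgroup phylogeny.
CONTROL_GENES_SUBGROUP: tuple = (
    "CG8348", "CG10372", "CG8222", "CG6898", "CG2595", "CG33934",
    "CG4815", "CG31605", "CG30169", "CG4259", "CG31287",
)

#: The five-species *D. melanogaster* subgroup.
SUBGROUP_5SP: tuple = ("dmel", "dsim", "dsec", "dyak", "dere")


def study_tree_newick() -> str:
    """The 12-species study phylogeny as a Newick string (verbatim)."""
    ref = resources.files("tephylo").joinpath("data/drosophila_12sp.nwk")
    return ref.read_text().strip()


def study_tree() -> Phylogeny:
    """The 12-species study phylogeny (root is a trifurcation)."""
    return parse_newick(study_tree_newick())
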