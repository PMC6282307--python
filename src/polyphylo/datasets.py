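"""Bundled desk-scale example system for demos and validation.

An 8-taxon system modeled on the biology the pipeline targets: five
diploid lineages (an outgroup plus four ingroup diploids, two of which
— ``PAT`` and ``SEM`` — are the candidate hybridization parents) and a
clade of three allopolyploid taxa that arose by a single hybridization
between the pendant edges of ``PAT`` and ``SEM``. Branch lengths are in
arbitrary time units and drive the duplication-loss simulator.
"""

from __future__ import annotations

from .trees import PhyloTree, SpeciesNetwork, parse_enewick, parse_newick

#: Taxa of the allopolyploid clade, shaped ((AFR,IND),KOT).
POLYPLOID_TAXA = ("AFR", "IND", "KOT")

#: Diploids whose pendant edges may parent a hybridization.
CANDIDATE_PARENTS = ("PAT", "SEM")

#: Scan label of the generating one-event hypothesis.
TRUE_HYPOTHESIS_LABEL = "N1:PATxSEM"

_NETWORK = (
    "(((((PAT:0.3,((AFR:0.4,IND:0.4):0.3,KOT:0.7)#H1:0.3):0.3,"
    "(SEM:0.3,#H1:0.3):0.3):0.4,EVE:1.0):0.4,AME:1.4):0.4,OUT:1.8);"
)

_BACKBONE_T1 = "(((((((AFR,IND),KOT),PAT),SEM),EVE),AME),OUT);"
_BACKBONE_T2 = "(((((((AFR,IND),KOT),SEM),PAT),EVE),AME),OUT);"


def example_network() -> SpeciesNetwork:
    """The generating 1-hybridization network, with branch lengths."""
    return parse_enewick(_NETWORK)


def example_backbones() -> tuple[PhyloTree, PhyloTree]:
    """T1/T2 no-hybridization backbones (polyploid clade sister to each parent)."""
    return parse_newick(_BACKBONE_T1), parse_newick(_BACKBONE_T2)
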