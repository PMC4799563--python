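"""Built-in study trees for the three simulated divergence regimes.

The simulation study behind this package uses three mammalian trees with
small, moderate and large divergence: 12 primates (total branch length
0.384), 15 mammals (1.539) and 9 fast-evolving mammals (2.279), with branch
lengths in expected substitutions per neutral site.  The published record of
those trees is a summary (leaf count, total length, external/internal
branch-length means), so the trees embedded here are representative
reconstructions: fixed topologies whose external and internal branch lengths
are spread around the published means and scaled so the totals match the
published values exactly.  Segment-level statistics of the neutral
indel process depend on the total rate and the number of leaves rather than
on fine topology, which is what makes these stand-ins usable as study
conditions.
"""

from __future__ import annotations

from .phylo import PhyloTree, tree_from_newick

PRIMATES12_NEWICK = (
    "(((((((P01:0.0207,P02:0.0298):0.0018,P03:0.0435):0.0463,P04:0.0147):0.0116,"
    "P05:0.0196):0.0231,(P06:0.0205,P07:0.0062):0.0029):0.0043,"
    "((P08:0.0124,P09:0.0319):0.0122,P10:0.0201):0.0071):0.0086,"
    "(P11:0.0287,P12:0.0158):0.0022);"
)
"""12 leaves, total branch length 0.384 (small divergence)."""

MAMMALS15_NEWICK = (
    "((((((M01:0.0079,M02:0.0840):0.0266,M03:0.0943):0.0550,"
    "(M04:0.0294,M05:0.1117):0.0297):0.0044,((M06:0.0703,M07:0.0792):0.0177,"
    "(M08:0.0949,M09:0.1034):0.0116):0.0259):0.0386,"
    "(((M10:0.0706,M11:0.1899):0.0407,M12:0.0624):0.0066,M13:0.0364):0.0426):0.0172,"
    "(M14:0.1127,M15:0.0536):0.0217);"
)
"""15 leaves, total branch length 1.539 (moderate divergence)."""

FAST9_NEWICK = (
    "((((F01:0.1938,F02:0.1472):0.0228,(F03:0.3347,F04:0.2771):0.0245):0.0296,"
    "(F05:0.2192,(F06:0.1293,F07:0.2425):0.0490):0.0479):0.0426,"
    "(F08:0.3082,F09:0.2026):0.0080);"
)
"""9 leaves, total branch length 2.279 (large divergence)."""


def primates12() -> PhyloTree:
    """The 12-leaf small-divergence study tree (total length 0.384)."""
    return tree_from_newick(PRIMATES12_NEWICK)


def mammals15() -> PhyloTree:
    """The 15-leaf moderate-divergence study tree (total length 1.539)."""
    return tree_from_newick(MAMMALS15_NEWICK)


def fast9() -> PhyloTree:
    """The 9-leaf large-divergence study tree (total length 2.279)."""
    return tree_from_newick(FAST9_NEWICK)


STUDY_TREES = {
    "primates12": primates12,
    "mammals15": mammals15,
    "fast9": fast9,
}
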