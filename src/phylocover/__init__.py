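"""Labellable phylogenetic networks and their expanding set covers.

A rooted phylogenetic network is *labellable* when its internal vertices can
be deterministically numbered by a greedy extension of the classical tree
labelling; labellable networks are in bijection with *expanding covers* of
finite sets, so a whole network can be stored, compared and manipulated as a
set of integer sets.  This package implements the labelling algorithm, the
bijection in both directions, the non-degeneracy order condition, the usual
class predicates (tree-child, tree-sibling, orchard, tree-based, normal),
and the derived-network quotient that projects any network onto the
labellable class.
"""

from .network import (PhyloNetwork, NetworkError, NetworkSyntaxError,
                      InvariantError, VertexRole, Degeneracy,
                      parse_network, write_network)
from .ordering import (set_precedes, is_labellable, labellable_witness,
                       NotLabellableError, VertexLabelling, label_network)
from .covers import (Cover, CoverError, LabellingOrder, cover_of,
                     implied_leaf_count, is_expanding, expanding_violation,
                     labelling_order, order_condition_violations,
                     network_from_cover, parse_cover, write_cover)
from .classes import (ClassReport, SizeLimitError, is_tree_child,
                      is_tree_sibling, visible_vertices, find_cherries,
                      find_reticulated_cherries, is_orchard_binary,
                      is_tree_based, is_normal, classify)
from .quotient import QuotientTrace, quotient_step, derived_network, normalise
from .synth import GenConfig, random_expanding_cover, random_network, fixtures

__version__ = "0.1.0"

__all__ = [
    "PhyloNetwork", "NetworkError", "NetworkSyntaxError", "InvariantError",
    "VertexRole", "Degeneracy", "parse_network", "write_network",
    "set_precedes", "is_labellable", "labellable_witness",
    "NotLabellableError", "VertexLabelling", "label_network",
    "Cover", "CoverError", "LabellingOrder", "cover_of",
    "implied_leaf_count", "is_expanding", "expanding_violation",
    "labelling_order", "order_condition_violations", "network_from_cover",
    "parse_cover", "write_cover",
    "ClassReport", "SizeLimitError", "is_tree_child", "is_tree_sibling",
    "visible_vertices", "find_cherries", "find_reticulated_cherries",
    "is_orchard_binary", "is_tree_based", "is_normal", "classify",
    "QuotientTrace", "quotient_step", "derived_network", "normalise",
    "GenConfig", "random_expanding_cover", "random_network", "fixtures",
]
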