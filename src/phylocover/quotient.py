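"""Quotients onto the labellable class, and normalisation.

Merging all vertices that share a children set (leaves exempt: their
children sets are empty, and collapsing the leaf set would destroy the
labelling) yields a smaller network; iterating to a fixpoint gives the
*derived network* ``D(N)``, which is labellable, and the map is idempotent —
a canonical projection of all networks onto the labellable class.

Normalisation ``N(N)`` restricts to the visible vertices, takes the Hasse
diagram (transitive reduction) of their reachability order, and suppresses
degree-two vertices, yielding a normal network.  Normal networks are already
labellable, so ``D(N(N)) = N(N)``; the two projections differ in general
(``N(D(N)) != N(N)`` is possible).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .classes import visible_vertices
from .network import PhyloNetwork, Vertex
from .ordering import is_labellable

__all__ = ["QuotientTrace", "quotient_step", "derived_network", "normalise"]


@dataclass
class QuotientTrace:
    """Record of the quotient iteration from ``N`` to its fixpoint.

    ``steps`` holds every network in the sequence, the input first and the
    derived network last; ``class_map`` sends each original vertex to the
    vertex of the final network it merged into.
    """

    steps: list[PhyloNetwork]
    class_map: dict[Vertex, Vertex]


def quotient_step(net: PhyloNetwork
                  ) -> tuple[PhyloNetwork, dict[Vertex, Vertex]]:
    """One application of the children-set quotient.

    Non-leaf vertices ``x ~ y`` iff ``c_N(x) = c_N(y)``; leaves are kept as
    singleton classes.  The quotient vertex set is the set of classes, with
    an edge between classes whenever any pair of members carries an edge
    (multi-edges collapse).  Returns the quotient network and the map from
    original vertices to class identifiers.

    Leaf set and labels, single-rootedness and acyclicity are preserved
    (asserted via revalidation on construction).
    """
    by_children: dict[frozenset, list[Vertex]] = {}
    for v in net.non_leaf_vertices():
        by_children.setdefault(frozenset(net.children(v)), []).append(v)
    class_of: dict[Vertex, Vertex] = {}
    for members in by_children.values():
        cid = frozenset(members)
        for v in members:
            class_of[v] = cid
    for leaf in net.leaves():
        class_of[leaf] = frozenset([leaf])
    edges = {(class_of[u], class_of[v]) for u, v in net.edges()}
    leaf_label = {class_of[v]: l for v, l in net.leaf_label.items()}
    return PhyloNetwork(edges, leaf_label), class_of


def derived_network(net: PhyloNetwork
                    ) -> tuple[PhyloNetwork, QuotientTrace]:
    """Iterate :func:`quotient_step` to its fixpoint ``D(N)``.

    The vertex count strictly decreases at every non-final step, the result
    is labellable, and the map is idempotent: ``D(D(N)) = D(N)`` and
    ``D(N) = N`` exactly when ``N`` is labellable.
    """
    steps = [net]
    total_map: dict[Vertex, Vertex] = {v: v for v in net.vertices()}
    current = net
    while not is_labellable(current):
        nxt, class_of = quotient_step(current)
        assert len(nxt) < len(current)
        total_map = {v: class_of[c] for v, c in total_map.items()}
        steps.append(nxt)
        current = nxt
    return current, QuotientTrace(steps=steps, class_map=total_map)


def normalise(net: PhyloNetwork) -> PhyloNetwork:
    """The normalisation ``N(N)``: visible vertices, Hasse diagram,
    degree-two suppression.

    The visible vertices are ordered by reachability in ``N``; the Hasse
    diagram of that partial order is its transitive reduction.  Internal
    vertices of in- and out-degree 1 are then suppressed (a root of
    out-degree 1 has total degree 1 and is kept).  The result is a normal
    network and the map is idempotent.
    """
    vis = visible_vertices(net)
    g = net.digraph()
    order = nx.DiGraph()
    order.add_nodes_from(vis)
    vis_list = sorted(vis, key=repr)
    reach = {v: nx.descendants(g, v) for v in vis_list}
    for u in vis_list:
        for v in vis_list:
            if u != v and v in reach[u]:
                order.add_edge(u, v)
    hasse = nx.transitive_reduction(order)

    # suppress internal degree-(1,1) vertices, collapsing any multi-edge
    changed = True
    while changed:
        changed = False
        for v in list(hasse.nodes()):
            if v in net.leaves():
                continue
            if hasse.in_degree(v) == 1 and hasse.out_degree(v) == 1:
                (p,) = hasse.predecessors(v)
                (c,) = hasse.successors(v)
                hasse.remove_node(v)
                hasse.add_edge(p, c)
                changed = True

    leaf_label = {v: l for v, l in net.leaf_label.items() if v in hasse}
    return PhyloNetwork(hasse.edges(), leaf_label)
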