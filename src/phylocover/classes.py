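"""Membership predicates for the familiar network classes.

Implements tree-child, tree-sibling, normal, orchard (binary) and tree-based
recognition, together with the visibility computation they lean on, and an
aggregating :func:`classify` that produces a :class:`ClassReport`.

Tree-based recognition is exact by brute force over the spanning-tree parent
choice of each reticulation (the oracle, correct by definition); on binary
networks the same question reduces to a 2-SAT instance which is solved in
polynomial time and cross-checked against the brute force.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .network import PhyloNetwork, Vertex
from .ordering import is_labellable, labellable_witness

__all__ = [
    "ClassReport",
    "SizeLimitError",
    "is_tree_child",
    "is_tree_sibling",
    "visible_vertices",
    "find_cherries",
    "find_reticulated_cherries",
    "is_orchard_binary",
    "is_tree_based",
    "is_normal",
    "classify",
]


class SizeLimitError(RuntimeError):
    """Exact search would exceed the configured size limit."""


def is_tree_child(net: PhyloNetwork) -> bool:
    """True iff every non-leaf vertex has at least one child of in-degree 1
    (a tree vertex).  Equivalent to every vertex being visible."""
    return _tree_child_witness(net) is None


def _tree_child_witness(net: PhyloNetwork) -> Optional[Vertex]:
    for v in net.non_leaf_vertices():
        if not any(net.in_degree(c) == 1 for c in net.children(v)):
            return v
    return None


def is_tree_sibling(net: PhyloNetwork) -> bool:
    """True iff every reticulation shares a parent with some tree vertex."""
    return _tree_sibling_witness(net) is None


def _tree_sibling_witness(net: PhyloNetwork) -> Optional[Vertex]:
    for r in net.reticulations():
        siblings = {c for p in net.parents(r) for c in net.children(p)} - {r}
        if not any(net.in_degree(s) == 1 for s in siblings):
            return r
    return None


def visible_vertices(net: PhyloNetwork) -> set[Vertex]:
    """Vertices ``v`` for which some leaf is disconnected from the root when
    ``v`` is removed, i.e. every root-to-that-leaf path passes through ``v``.

    The root and every leaf are always visible.
    """
    g = net.digraph()
    root = net.root
    leaves = net.leaves()
    visible = {root} | leaves
    for v in net.internal_vertices():
        h = nx.restricted_view(g, [v], [])
        reachable = {root} | nx.descendants(h, root)
        if any(leaf not in reachable for leaf in leaves):
            visible.add(v)
    return visible


def find_cherries(net: PhyloNetwork) -> list[tuple[int, int]]:
    """Unordered sibling leaf pairs, as sorted ``(label, label)`` tuples."""
    cherries = set()
    for v in net.non_leaf_vertices():
        leaf_kids = sorted(net.leaf_label[c] for c in net.children(v)
                           if net.is_leaf(c))
        for a, b in itertools.combinations(leaf_kids, 2):
            cherries.add((a, b))
    return sorted(cherries)


def find_reticulated_cherries(net: PhyloNetwork) -> list[tuple[int, int]]:
    """Ordered pairs ``(x, y)`` of leaf labels where the parent of ``x`` is a
    reticulation sharing a parent with ``y`` (``p(y) ∈ p(p(x))``)."""
    pairs = set()
    for x in net.leaves():
        (px,) = net.parents(x)
        if net.in_degree(px) <= 1:
            continue
        for y in net.leaves():
            if y == x:
                continue
            (py,) = net.parents(y)
            if py in net.parents(px):
                pairs.add((net.leaf_label[x], net.leaf_label[y]))
    return sorted(pairs)


def _suppress_if_degree_two(g: nx.DiGraph, v: Vertex) -> None:
    """Suppress v when it is internal with in-degree 1 and out-degree 1."""
    if v not in g:
        return
    if g.in_degree(v) == 1 and g.out_degree(v) == 1:
        (p,) = g.predecessors(v)
        (c,) = g.successors(v)
        g.remove_node(v)
        g.add_edge(p, c)


def is_orchard_binary(net: PhyloNetwork) -> bool:
    """Orchard recognition for binary non-degenerate networks.

    Repeatedly applies cherry reductions (delete the larger leaf of a sibling
    leaf pair and suppress its degree-two parent) and reticulated-cherry
    reductions (delete the edge from the shared parent to the reticulate
    parent of ``x`` and suppress resulting degree-two vertices), always
    taking the lexicographically smallest applicable leaf pair, cherries
    before reticulated cherries.  True iff the network reduces to a single
    leaf with no reticulations.  The fixed order is safe because binary
    cherry-picking reductions are order independent.

    Raises
    ------
    ValueError
        If the network is not binary or not non-degenerate.
    """
    if not net.is_binary():
        raise ValueError("orchard recognition implemented for binary "
                         "networks only")
    if not net.is_nondegenerate():
        raise ValueError("orchard recognition requires a non-degenerate "
                         "network")
    g = net.digraph()
    label = dict(net.leaf_label)

    def leaf_of(lbl: int) -> Vertex:
        return next(v for v, l in label.items() if l == lbl)

    while True:
        leaves = [v for v in g if g.out_degree(v) == 0]
        retics = [v for v in g if g.in_degree(v) > 1]
        if len(leaves) == 1 and not retics:
            return True
        cherries = []
        ret_cherries = []
        for v in leaves:
            (pv,) = g.predecessors(v)
            for w in leaves:
                if w is v:
                    continue
                (pw,) = g.predecessors(w)
                if pv == pw and label[v] < label[w]:
                    cherries.append((label[v], label[w]))
                if g.in_degree(pv) > 1 and pw in g.predecessors(pv):
                    ret_cherries.append((label[v], label[w]))
        if cherries:
            a, b = min(cherries)
            y = leaf_of(b)
            (p,) = g.predecessors(y)
            g.remove_node(y)
            del label[y]
            _suppress_if_degree_two(g, p)
        elif ret_cherries:
            a, b = min(ret_cherries)
            x, y = leaf_of(a), leaf_of(b)
            (r,) = g.predecessors(x)
            (q,) = g.predecessors(y)
            g.remove_edge(q, r)
            _suppress_if_degree_two(g, r)
            _suppress_if_degree_two(g, q)
        else:
            return False


def _orchard_backtracking(net: PhyloNetwork) -> bool:
    """Reference orchard recognition trying every reduction order.

    Exponential; used as an independent cross-check on small instances.
    """

    def step(g: nx.DiGraph, label: dict) -> bool:
        leaves = [v for v in g if g.out_degree(v) == 0]
        retics = [v for v in g if g.in_degree(v) > 1]
        if len(leaves) == 1 and not retics:
            return True
        moves = []
        for v in leaves:
            (pv,) = g.predecessors(v)
            for w in leaves:
                if w is v:
                    continue
                (pw,) = g.predecessors(w)
                if pv == pw and label[v] < label[w]:
                    moves.append(("cherry", v, w))
                if g.in_degree(pv) > 1 and pw in g.predecessors(pv):
                    moves.append(("ret", v, w))
        for kind, x, y in moves:
            h = g.copy()
            lab = dict(label)
            if kind == "cherry":
                (p,) = h.predecessors(y)
                h.remove_node(y)
                del lab[y]
                _suppress_if_degree_two(h, p)
            else:
                (r,) = h.predecessors(x)
                (q,) = h.predecessors(y)
                h.remove_edge(q, r)
                _suppress_if_degree_two(h, r)
                _suppress_if_degree_two(h, q)
            if step(h, lab):
                return True
        return False

    return step(net.digraph(), dict(net.leaf_label))


def is_tree_based(net: PhyloNetwork, max_choices: int = 2 ** 20) -> bool:
    """True iff the network admits a spanning tree whose leaves are exactly
    the network's leaves.

    Every non-root vertex keeps exactly one in-edge (only reticulations have
    a choice); the assignment is admissible when every non-leaf vertex
    retains at least one out-edge.  The search enumerates the product of
    reticulation parent choices and is exact.  On binary networks the result
    is additionally computed by a polynomial 2-SAT reduction and the two
    answers are asserted equal.

    Raises
    ------
    SizeLimitError
        If the choice product exceeds ``max_choices``.
    """
    result = _tree_based_bruteforce(net, max_choices)
    if net.is_binary() and net.is_nondegenerate():
        assert result == _tree_based_binary_2sat(net), \
            "2-SAT and brute-force tree-based recognition disagree"
    return result


def _tree_based_bruteforce(net: PhyloNetwork, max_choices: int) -> bool:
    retics = sorted(net.reticulations(), key=repr)
    parent_lists = [sorted(net.parents(r), key=repr) for r in retics]
    total = 1
    for pl in parent_lists:
        total *= len(pl)
        if total > max_choices:
            raise SizeLimitError(
                f"tree-based search needs > {max_choices} assignments")
    # vertices needing a kept child: those whose children are all reticulate
    needy = {}
    for v in net.non_leaf_vertices():
        ret_kids = [c for c in net.children(v) if net.in_degree(c) > 1]
        if len(ret_kids) == len(net.children(v)):
            needy[v] = ret_kids
    if not needy:
        return True
    for choice in itertools.product(*parent_lists):
        chosen = dict(zip(retics, choice))
        if all(any(chosen[c] == v for c in kids)
               for v, kids in needy.items()):
            return True
    return False


def _tree_based_binary_2sat(net: PhyloNetwork) -> bool:
    """Polynomial tree-based recognition for binary networks via 2-SAT.

    Each reticulation ``r`` with parents ``(a, b)`` gets a boolean ``x_r``
    (true: keep the edge from ``a``).  A vertex whose children are all
    reticulate contributes a clause requiring one child to keep its edge; in
    a binary network each clause has at most two literals.
    """
    retics = sorted(net.reticulations(), key=repr)
    parent_pair = {r: tuple(sorted(net.parents(r), key=repr)) for r in retics}
    index = {r: i for i, r in enumerate(retics)}

    def lit(r: Vertex, parent: Vertex) -> int:
        # positive literal i+1 means x_r true (keep edge from first parent)
        i = index[r] + 1
        return i if parent == parent_pair[r][0] else -i

    clauses: list[tuple[int, ...]] = []
    for v in net.non_leaf_vertices():
        kids = net.children(v)
        if all(net.in_degree(c) > 1 for c in kids):
            clauses.append(tuple(lit(c, v) for c in kids))
    # implication graph over literals
    g = nx.DiGraph()
    for i in range(1, len(retics) + 1):
        g.add_node(i)
        g.add_node(-i)
    for clause in clauses:
        if len(clause) == 1:
            (a,) = clause
            g.add_edge(-a, a)
        else:
            a, b = clause[0], clause[1]
            g.add_edge(-a, b)
            g.add_edge(-b, a)
    comp = {}
    for k, scc in enumerate(nx.strongly_connected_components(g)):
        for node in scc:
            comp[node] = k
    return all(comp[i] != comp[-i] for i in range(1, len(retics) + 1))


def _shortcut_edges(net: PhyloNetwork) -> list[tuple[Vertex, Vertex]]:
    g = net.digraph()
    shortcuts = []
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        if nx.has_path(g, u, v):
            shortcuts.append((u, v))
        g.add_edge(u, v)
    return shortcuts


def is_normal(net: PhyloNetwork) -> bool:
    """True iff the network is tree-child and has no shortcut edge (an edge
    ``(u, v)`` alongside another directed path from ``u`` to ``v``)."""
    return is_tree_child(net) and not _shortcut_edges(net)


@dataclass
class ClassReport:
    """Aggregated class memberships with witnesses for each failure.

    Predicates whose preconditions do not apply (orchard on a non-binary or
    degenerate network; tree-based/normal on a degenerate network) are
    ``None`` (absent), never ``False``.
    """

    labellable: bool
    tree_child: bool
    tree_sibling: bool
    binary: bool
    nondegenerate: bool
    orchard: Optional[bool] = None
    tree_based: Optional[bool] = None
    normal: Optional[bool] = None
    witnesses: list[tuple[str, tuple]] = field(default_factory=list)

    def to_json(self) -> str:
        data = {k: getattr(self, k)
                for k in ("labellable", "tree_child", "tree_sibling",
                          "binary", "nondegenerate", "orchard",
                          "tree_based", "normal")}
        data["witnesses"] = [[kind, [repr(v) for v in vs]]
                             for kind, vs in self.witnesses]
        return json.dumps(data, indent=2)


def classify(net: PhyloNetwork) -> ClassReport:
    """Run all applicable predicates and collect witnesses for failures."""
    witnesses: list[tuple[str, tuple]] = []

    lw = labellable_witness(net)
    if lw is not None:
        witnesses.append(("equal_children_sets", lw))
    tcw = _tree_child_witness(net)
    if tcw is not None:
        witnesses.append(("no_tree_vertex_child", (tcw,)))
    tsw = _tree_sibling_witness(net)
    if tsw is not None:
        witnesses.append(("no_tree_vertex_sibling", (tsw,)))
    degen = tuple(sorted(net.degenerate_vertices(), key=repr))
    if degen:
        witnesses.append(("degenerate_vertices", degen))

    binary = net.is_binary()
    nondegen = not degen
    report = ClassReport(
        labellable=lw is None,
        tree_child=tcw is None,
        tree_sibling=tsw is None,
        binary=binary,
        nondegenerate=nondegen,
        witnesses=witnesses,
    )
    if binary and nondegen:
        report.orchard = is_orchard_binary(net)
        if not report.orchard:
            witnesses.append(("no_cherry_or_reticulated_cherry", ()))
    if nondegen:
        try:
            report.tree_based = is_tree_based(net)
        except SizeLimitError:
            report.tree_based = None
        report.normal = is_normal(net)
        if report.normal is False:
            shortcuts = _shortcut_edges(net)
            if shortcuts:
                witnesses.append(("shortcut_edge", tuple(shortcuts[0])))
    return report
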