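"""Seeded generators of random covers and networks, plus named fixtures.

Every generator is fully determined by its seed.  Expanding covers are
sampled constructively from the two defining conditions (the distribution is
valid but unspecified -- uniform sampling of expanding covers is open).
Class-constrained networks are produced either by constructions that
guarantee membership (binary orchard networks grow by reverse cherry and
reticulated-cherry expansions) or by adding reticulation edges to a random
tree and rejecting candidates that the corresponding predicate refutes, so
generation and validation always agree.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .classes import (is_normal, is_orchard_binary, is_tree_child,
                      is_tree_sibling)
from .covers import Cover, is_expanding, labelling_order, \
    network_from_cover, order_condition_violations
from .network import PhyloNetwork
from .ordering import is_labellable

__all__ = ["GenConfig", "random_expanding_cover", "random_network",
           "fixtures"]

CLASS_FILTERS = ("labellable", "nondegenerate", "tree_child", "tree_sibling",
                 "orchard_binary", "normal", "unrestricted")


@dataclass
class GenConfig:
    """Generator configuration; ``seed`` fully determines the output.

    ``m`` is the cover ground-set size; ``m - n`` bounds the number of extra
    (reticulate or degenerate) labels beyond the leaves.  ``gadget_p`` is the
    probability that an unrestricted network gets a planted pair of parents
    with identical children sets, making it unlabellable.
    """

    n: int = 5
    m: int = 9
    seed: int = 0
    class_filter: str = "unrestricted"
    gadget_p: float = 0.3

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need n >= 1")
        if self.m < self.n:
            raise ValueError("need m >= n")
        if self.class_filter not in CLASS_FILTERS:
            raise ValueError(f"unknown class_filter {self.class_filter!r}")


def random_expanding_cover(cfg: GenConfig,
                           rng: Optional[np.random.Generator] = None
                           ) -> Cover:
    """Sample an expanding cover of ``[m]`` with ``m - n + 1`` sets.

    Sets are built in a sequence ``C_1..C_K`` with ``C_i ⊆ [n+i-1]``, leaf
    elements drawn without replacement and internal labels with, so both
    expanding conditions hold by construction; leftovers (unused leaves and
    internal labels, always including ``m``) form the final set.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n, cfg.m
    big = m - n + 1
    for _attempt in range(200):
        leaves_left = list(range(1, n + 1))
        internal_unused: set[int] = set()
        internal_all: list[int] = []
        sets: list[frozenset[int]] = []
        ok = True
        for i in range(1, big):
            usable = leaves_left + internal_all
            size = max(1, min(int(rng.geometric(0.45)), 4, len(usable)))
            chosen = None
            for _retry in range(30):
                pick = rng.choice(len(usable), size=size, replace=False)
                cand = frozenset(usable[j] for j in pick)
                if cand not in sets:
                    chosen = cand
                    break
            if chosen is None:
                ok = False
                break
            sets.append(chosen)
            leaves_left = [x for x in leaves_left if x not in chosen]
            internal_unused -= chosen
            new_label = n + i
            internal_all.append(new_label)
            internal_unused.add(new_label)
        if not ok:
            continue
        final = frozenset(leaves_left) | frozenset(internal_unused)
        if not final or final in sets:
            continue
        sets.append(final)
        cover = Cover.from_sets(sets)
        assert is_expanding(cover)
        return cover
    raise RuntimeError(f"could not sample an expanding cover for {cfg}")


# ---------------------------------------------------------------------------
# random networks
# ---------------------------------------------------------------------------

def _random_tree(n: int, rng: np.random.Generator,
                 binary: bool = False) -> PhyloNetwork:
    """Random rooted tree on leaves 1..n by coalescing subtree roots."""
    counter = itertools.count()
    roots: list = list(range(1, n + 1))
    edges = []
    while len(roots) > 1:
        k = 2 if (binary or len(roots) == 2) else int(
            rng.choice([2, 2, 2, 3], ))
        k = min(k, len(roots))
        pick = sorted(rng.choice(len(roots), size=k, replace=False),
                      reverse=True)
        parent = f"t{next(counter)}"
        for j in pick:
            edges.append((parent, roots.pop(j)))
        roots.append(parent)
    if n == 1:
        edges.append((f"t{next(counter)}", 1))
    return PhyloNetwork(edges, {i: i for i in range(1, n + 1)})


def _add_reticulation(net: PhyloNetwork, rng: np.random.Generator
                      ) -> Optional[PhyloNetwork]:
    """Subdivide two distinct edges and join the subdivision points.

    Returns ``None`` when the sampled pair would create a cycle or a
    parallel edge.
    """
    edges = sorted(net.edges(), key=repr)
    if len(edges) < 2:
        return None
    i, j = rng.choice(len(edges), size=2, replace=False)
    (u1, v1), (u2, v2) = edges[i], edges[j]
    g = net.digraph()
    # adding s1 -> s2 inside edge (u2, v2) must not let v2 reach u1
    if u1 == u2 or nx.has_path(g, v2, u1):
        return None
    counter = itertools.count()
    existing = net.vertices()
    def fresh():
        while True:
            name = f"r{next(counter)}"
            if name not in existing:
                return name
    s1, s2 = fresh(), fresh()
    g.remove_edge(u1, v1)
    g.remove_edge(u2, v2)
    g.add_edges_from([(u1, s1), (s1, v1), (u2, s2), (s2, v2), (s1, s2)])
    try:
        return PhyloNetwork(g.edges(), net.leaf_label)
    except Exception:
        return None


def _grow_orchard_binary(n: int, reticulations: int,
                         rng: np.random.Generator) -> PhyloNetwork:
    """Binary orchard network by reverse reductions from a cherry.

    Cherry expansion replaces a leaf by a cherry; reticulated-cherry
    expansion subdivides the pendant edges of two leaves and joins the
    subdivision points, making the first one a reticulation.  Membership in
    the orchard class is guaranteed by construction.
    """
    if n < 2:
        raise ValueError("binary networks need n >= 2")
    counter = itertools.count()
    edges = [("rho", 1), ("rho", 2)]
    leaves = [1, 2]
    next_leaf = 3
    moves = ["cherry"] * (n - 2) + ["ret"] * reticulations
    rng.shuffle(moves)
    g_edges = edges
    for move in moves:
        g = nx.DiGraph(g_edges)
        if move == "cherry":
            x = leaves[int(rng.integers(len(leaves)))]
            (p,) = g.predecessors(x)
            v = f"c{next(counter)}"
            g.remove_edge(p, x)
            g.add_edges_from([(p, v), (v, x), (v, next_leaf)])
            leaves.append(next_leaf)
            next_leaf += 1
        else:
            if len(leaves) < 2:
                continue
            i, j = rng.choice(len(leaves), size=2, replace=False)
            x, y = leaves[i], leaves[j]
            (px,) = g.predecessors(x)
            (py,) = g.predecessors(y)
            r = f"c{next(counter)}"
            q = f"c{next(counter)}"
            g.remove_edge(px, x)
            g.remove_edge(py, y)
            g.add_edges_from([(px, r), (r, x), (py, q), (q, y), (q, r)])
        g_edges = list(g.edges())
    labels = {leaf: k + 1 for k, leaf in enumerate(sorted(leaves))}
    g = nx.relabel_nodes(nx.DiGraph(g_edges),
                         {leaf: f"L{labels[leaf]}" for leaf in leaves})
    return PhyloNetwork(g.edges(),
                        {f"L{l}": l for l in labels.values()})


def _plant_gadget(net: PhyloNetwork, rng: np.random.Generator
                  ) -> PhyloNetwork:
    """Attach two parents with identical children sets below a random
    non-leaf vertex, making the network unlabellable."""
    hosts = sorted(net.non_leaf_vertices(), key=repr)
    host = hosts[int(rng.integers(len(hosts)))]
    n = net.n
    g = net.digraph()
    g.add_edges_from([
        (host, "_gu"), (host, "_gv"),
        ("_gu", "_gr1"), ("_gu", "_gr2"),
        ("_gv", "_gr1"), ("_gv", "_gr2"),
        ("_gr1", "_gl1"), ("_gr2", "_gl2"),
    ])
    labels = dict(net.leaf_label)
    labels["_gl1"] = n + 1
    labels["_gl2"] = n + 2
    return PhyloNetwork(g.edges(), labels)


def random_network(cfg: GenConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> PhyloNetwork:
    """Sample a network of the class named by ``cfg.class_filter``.

    ``labellable`` reconstructs from a random expanding cover;
    ``nondegenerate`` additionally rejects covers violating the order
    condition; ``orchard_binary`` grows by reverse reductions; the
    remaining constrained classes add ``m - n`` reticulation edges to a
    random tree, rejecting any addition the class predicate refutes;
    ``unrestricted`` plants an unlabellable gadget with probability
    ``gadget_p``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = cfg.m - cfg.n
    if cfg.class_filter == "labellable":
        return network_from_cover(random_expanding_cover(cfg, rng))
    if cfg.class_filter == "nondegenerate":
        for _ in range(500):
            cover = random_expanding_cover(cfg, rng)
            with warnings.catch_warnings():
                # root out-degree 1 is screened out below, no need to warn
                warnings.simplefilter("ignore")
                violations = order_condition_violations(cover)
                root_set = labelling_order(cover).sequence[-1]
            if not violations and len(root_set) > 1:
                return network_from_cover(cover)
        raise RuntimeError("no non-degenerate cover found; widen config")
    if cfg.class_filter == "orchard_binary":
        net = _grow_orchard_binary(cfg.n, k, rng)
        assert is_orchard_binary(net)
        return net
    if cfg.class_filter in ("tree_child", "tree_sibling", "normal"):
        predicate = {"tree_child": is_tree_child,
                     "tree_sibling": is_tree_sibling,
                     "normal": is_normal}[cfg.class_filter]
        net = _random_tree(cfg.n, rng)
        added = 0
        for _ in range(60 * max(k, 1)):
            if added >= k:
                break
            candidate = _add_reticulation(net, rng)
            if candidate is not None and predicate(candidate):
                net = candidate
                added += 1
        assert predicate(net)
        return net
    if cfg.class_filter == "unrestricted":
        net = network_from_cover(random_expanding_cover(cfg, rng))
        if rng.random() < cfg.gadget_p:
            net = _plant_gadget(net, rng)
        return net
    raise ValueError(cfg.class_filter)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixtures() -> dict:
    """Named, version-stable worked instances.

    - ``ex45_cover``: the 8-set expanding cover of [12] whose reconstruction
      has 5 leaves and reticulations at labels 6 and 8; its order-condition
      check flags exactly label 11.
    - ``fig3_cover``: the 7-set cover of [11] of a degenerate labelled
      network.
    - ``fig2_gadget``: the smallest completed network containing two parents
      with identical (all-reticulate) children sets; not labellable.
    - ``zigzag_network``: a hand-built binary, non-degenerate network that is
      labellable but not tree-based (its zig-zag of three reticulations
      forces conflicting spanning-tree choices).
    - ``min_reticulation``: 3-leaf binary network with one reticulation.
    """
    ex45 = Cover.from_sets([
        {2}, {5}, {1, 6}, {4, 8}, {3, 6, 9}, {10}, {7, 11}, {8, 12}])
    fig3 = Cover.from_sets([
        {1}, {3}, {2, 7}, {4, 7}, {5, 8, 9}, {6, 8}, {10, 11}])
    gadget = PhyloNetwork(
        [("rho", "u"), ("rho", "v"),
         ("u", "r1"), ("u", "r2"), ("v", "r1"), ("v", "r2"),
         ("r1", "l1"), ("r2", "l2")],
        {"l1": 1, "l2": 2})
    zigzag = PhyloNetwork(
        [("rho", "y1"), ("rho", "y2"),
         ("y1", "y3"), ("y1", "q1"), ("y3", "t1"), ("y3", "q1"),
         ("y2", "y4"), ("y2", "q3"), ("y4", "t2"), ("y4", "q3"),
         ("q1", "r1"), ("q3", "r3"),
         ("t1", "r1"), ("t1", "r2"), ("t2", "r2"), ("t2", "r3"),
         ("r1", "l1"), ("r2", "l2"), ("r3", "l3")],
        {"l1": 1, "l2": 2, "l3": 3})
    min_ret = PhyloNetwork(
        [("r", "a"), ("r", "b"), ("a", 1), ("a", "x"),
         ("b", "x"), ("b", 2), ("x", 3)],
        {1: 1, 2: 2, 3: 3})
    return {
        "ex45_cover": ex45,
        "fig3_cover": fig3,
        "fig2_gadget": gadget,
        "zigzag_network": zigzag,
        "min_reticulation": min_ret,
    }
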