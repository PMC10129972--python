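"""The lexicographic order on integer sets and the internal-vertex labelling.

The labelling algorithm extends the classical internal-vertex labelling of
phylogenetic trees to networks.  Starting from leaves labelled ``1..n`` it
repeatedly picks, among the unlabelled non-root vertices whose children are
all labelled, the one whose children-label set is minimal in the order ``≺``
and assigns it the next integer.  The root is never labelled, so the non-root
internal vertices end up labelled ``n+1 .. n + #non-leaf vertices - 1``.

A network is *labellable* when this procedure is well defined, which happens
exactly when no two non-leaf vertices share the same children set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Optional

from .network import PhyloNetwork, Vertex

__all__ = [
    "set_precedes",
    "min_set",
    "is_labellable",
    "labellable_witness",
    "NotLabellableError",
    "VertexLabelling",
    "label_network",
]


def set_precedes(a: AbstractSet[int], b: AbstractSet[int]) -> bool:
    """Strict lexicographic partial order ``A ≺ B`` on non-empty sets.

    ``A ≺ B`` iff ``A ⊆ B`` (strictly, since the relation is irreflexive) or
    ``min(A \\ B) < min(B \\ A)``.  Exactly one of ``A ≺ B``, ``B ≺ A``
    holds for distinct non-empty sets, so the relation is a tournament;
    it is not transitive on arbitrary families (``{2} ≺ {1,2} ≺ {1,4} ≺
    {2}``), which is why minima are taken with :func:`min_set` rather than
    by sorting.  Restricted to pairwise-disjoint sets it reduces to
    comparison of minima and is a genuine total order.
    """
    a, b = frozenset(a), frozenset(b)
    if not a or not b:
        raise ValueError("sets compared by ≺ must be non-empty")
    if a == b:
        return False
    if a <= b:
        return True
    if b <= a:
        return False
    return min(a - b) < min(b - a)


def min_set(sets) -> frozenset:
    """The ≺-minimal member of a family of pairwise-distinct sets.

    ≺ is total on distinct sets but not transitive in general (three sets
    can form a cycle, e.g. ``{4} ≺ {2,4} ≺ {3} ≺ {4}``), so "minimal" means
    the *undominated* element: the set preceded by no other member, which is
    unique whenever it exists (totality forbids two).  A family caught in a
    cycle has no undominated element; the deadlock is broken canonically by
    taking the smallest set in the lexicographic order on sorted tuples.
    Any fixed deterministic choice here preserves the network/cover
    bijection, because the greedy cover ordering and the vertex-labelling
    loop are presented with identical families at every step; the
    undominated rule is what reproduces the worked orderings, and the
    fallback only decides cases the defining relation leaves open.
    """
    family = [frozenset(s) for s in sets]
    if not family:
        raise ValueError("empty family")
    undominated = [s for s in family
                   if not any(set_precedes(t, s) for t in family if t != s)]
    if undominated:
        assert len(undominated) == 1
        return undominated[0]
    return min(family, key=lambda s: tuple(sorted(s)))


def labellable_witness(net: PhyloNetwork
                       ) -> Optional[tuple[Vertex, Vertex]]:
    """A pair of distinct non-leaf vertices with equal children sets, if any.

    Returns ``None`` when the children-set map on non-leaf vertices is
    one-to-one, i.e. when the network is labellable.
    """
    seen: dict[frozenset, Vertex] = {}
    for v in sorted(net.non_leaf_vertices(), key=repr):
        key = frozenset(net.children(v))
        if key in seen:
            return (seen[key], v)
        seen[key] = v
    return None


def is_labellable(net: PhyloNetwork) -> bool:
    """True iff distinct non-leaf vertices always have distinct children
    sets, the combinatorial characterisation of labellability."""
    return labellable_witness(net) is None


class NotLabellableError(ValueError):
    """The network has two non-leaf vertices with the same children set."""

    def __init__(self, witness: tuple[Vertex, Vertex]):
        self.witness = witness
        super().__init__(
            f"network is not labellable: vertices {witness[0]!r} and "
            f"{witness[1]!r} have the same children set")


@dataclass(frozen=True)
class VertexLabelling:
    """Injective labelling of all non-root vertices.

    ``mapping`` sends leaves to their leaf labels ``1..n`` and non-root
    internal vertices to ``n+1..m``; the root is absent.  ``m`` equals
    ``n + #non-leaf vertices - 1``.
    """

    mapping: dict[Vertex, int]
    n: int

    @property
    def m(self) -> int:
        return max(self.mapping.values()) if self.mapping else 0

    def label(self, v: Vertex) -> int:
        return self.mapping[v]

    def vertex(self, label: int) -> Vertex:
        for v, l in self.mapping.items():
            if l == label:
                return v
        raise KeyError(label)


def label_network(net: PhyloNetwork) -> VertexLabelling:
    """Deterministically label the non-root internal vertices.

    At each step the candidates are the unlabelled non-root vertices whose
    children are all labelled; the candidate with ≺-minimal children-label
    set receives the next integer.  Candidate children sets are always
    pairwise distinct on a labellable network (asserted at runtime), so no
    tie-breaking is ever needed and the result is independent of internal
    vertex identifiers.

    Raises
    ------
    NotLabellableError
        If two non-leaf vertices share a children set (checked up front, so
        error reporting does not depend on input order).
    """
    w = labellable_witness(net)
    if w is not None:
        raise NotLabellableError(w)
    labels: dict[Vertex, int] = dict(net.leaf_label)
    next_label = net.n + 1
    unlabelled = net.non_leaf_vertices() - {net.root}
    while unlabelled:
        candidates = [v for v in unlabelled
                      if all(c in labels for c in net.children(v))]
        # Lemma-style guarantee: an acyclic network always has a candidate.
        assert candidates, "no vertex with fully labelled children"
        child_sets = {v: frozenset(labels[c] for c in net.children(v))
                      for v in candidates}
        assert len(set(child_sets.values())) == len(candidates)
        minimal = min_set(child_sets.values())
        (chosen,) = [v for v in candidates if child_sets[v] == minimal]
        labels[chosen] = next_label
        next_label += 1
        unlabelled.discard(chosen)
    return VertexLabelling(mapping=labels, n=net.n)
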