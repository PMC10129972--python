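"""Covers of [m]: the set-theoretic side of the network encoding.

A *cover* of ``[m] = {1..m}`` is a set of distinct non-empty integer subsets
whose union is ``[m]``.  The cover associated with a labellable network is
the set of sibling-label sets ``{labels of c_N(v) : v non-leaf}``; repeated
labels mark reticulations.  Covers that satisfy the two *expanding*
conditions (leaf labels unrepeated; at least ``i`` member sets inside
``[n+i-1]`` for every ``i``) are exactly the covers of labellable networks,
and the reconstruction here realises the bijection in both directions.

The *order condition* refines this to non-degenerate networks: in the
labelling order, a singleton ``C_i`` must have its induced label ``n+i``
repeated in the cover (in-degree > 1), while a larger ``C_i`` must not.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .network import PhyloNetwork
from .ordering import label_network, min_set

__all__ = [
    "Cover",
    "CoverError",
    "LabellingOrder",
    "cover_of",
    "implied_leaf_count",
    "is_expanding",
    "expanding_violation",
    "labelling_order",
    "order_condition_violations",
    "network_from_cover",
    "parse_cover",
    "write_cover",
]


class CoverError(ValueError):
    """Malformed cover (empty set, duplicate set, gap in the ground set)."""


@dataclass(frozen=True)
class Cover:
    """A cover of ``[m]``: distinct non-empty subsets with union ``{1..m}``."""

    sets: frozenset[frozenset[int]]
    m: int

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[int]]) -> "Cover":
        fam = []
        for s in sets:
            fs = frozenset(int(x) for x in s)
            if not fs:
                raise CoverError("empty set in cover")
            if any(x < 1 for x in fs):
                raise CoverError(f"non-positive element in {sorted(fs)}")
            if fs in fam:
                raise CoverError(f"duplicate set {sorted(fs)}")
            fam.append(fs)
        if not fam:
            raise CoverError("cover has no sets")
        union = frozenset().union(*fam)
        m = max(union)
        if union != frozenset(range(1, m + 1)):
            missing = sorted(set(range(1, m + 1)) - union)
            raise CoverError(f"union is not [{m}]: missing {missing}")
        return cls(sets=frozenset(fam), m=m)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, s) -> bool:
        return frozenset(s) in self.sets

    def multiplicity(self, x: int) -> int:
        """Number of member sets containing ``x`` (the in-degree of the
        vertex labelled ``x`` in the reconstructed network)."""
        return sum(1 for s in self.sets if x in s)

    def sorted_sets(self) -> list[list[int]]:
        return sorted((sorted(s) for s in self.sets), key=lambda s: (s[0], s))

    def __repr__(self) -> str:
        body = ", ".join("{" + ",".join(map(str, s)) + "}"
                         for s in self.sorted_sets())
        return f"Cover([{self.m}]: {body})"


def implied_leaf_count(cover: Cover) -> int:
    """Leaf count ``n = m - |C| + 1`` of any network with this cover.

    Raises :class:`CoverError` if the result is < 1, in which case the cover
    cannot come from a network.
    """
    n = cover.m - len(cover) + 1
    if n < 1:
        raise CoverError(
            f"m - |C| + 1 = {n} < 1: cover cannot come from a network")
    return n


def expanding_violation(cover: Cover) -> Optional[str]:
    """First violated expanding condition, or ``None`` if the cover is
    expanding.

    Condition (1): each element of ``{1..n}`` occurs in exactly one set.
    Condition (2): for each ``i = 1..|C|``, at least ``i`` member sets are
    subsets of ``[n+i-1]``.
    """
    n = implied_leaf_count(cover)
    for x in range(1, n + 1):
        mult = cover.multiplicity(x)
        if mult != 1:
            return (f"condition (1): leaf element {x} occurs {mult} times")
    maxima = sorted(max(s) for s in cover.sets)
    for i in range(1, len(cover) + 1):
        threshold = n + i - 1
        count = sum(1 for mx in maxima if mx <= threshold)
        if count < i:
            return (f"condition (2): only {count} subsets of [{threshold}], "
                    f"need at least {i}")
    return None


def is_expanding(cover: Cover) -> bool:
    """True iff the cover satisfies both expanding conditions."""
    return expanding_violation(cover) is None


@dataclass(frozen=True)
class LabellingOrder:
    """The greedy sequence ``C_1..C_|C|``; ``C_i`` induces label ``n+i``."""

    sequence: tuple[frozenset[int], ...]
    n: int

    def label_of(self, s) -> int:
        return self.n + self.sequence.index(frozenset(s)) + 1

    def __iter__(self):
        return iter(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def labelling_order(cover: Cover) -> LabellingOrder:
    """Order the cover greedily: ``C_i`` is the ≺-minimal remaining set
    contained in ``[n+i-1]``.  Total on expanding covers."""
    violation = expanding_violation(cover)
    if violation is not None:
        raise CoverError(f"cover is not expanding: {violation}")
    n = implied_leaf_count(cover)
    remaining = set(cover.sets)
    seq: list[frozenset[int]] = []
    for i in range(1, len(cover) + 1):
        threshold = n + i - 1
        eligible = [s for s in remaining if max(s) <= threshold]
        assert eligible, "expanding property violated mid-ordering"
        chosen = min_set(eligible)
        seq.append(chosen)
        remaining.discard(chosen)
    return LabellingOrder(sequence=tuple(seq), n=n)


def order_condition_violations(cover: Cover) -> list[int]:
    """Labels whose multiplicity contradicts the non-degeneracy condition.

    For each ``C_i`` in the labelling order with induced label ``n+i <= m``:
    a singleton ``C_i`` must have ``n+i`` appearing more than once in the
    cover, a larger ``C_i`` at most once.  The final set's label ``m+1``
    belongs to the unlabelled root and is exempt.  A singleton final set
    (root out-degree 1) triggers a warning, not a violation, since degeneracy
    is defined for internal vertices only.

    An empty result means the reconstructed network is non-degenerate.
    """
    order = labelling_order(cover)
    n = order.n
    violations: list[int] = []
    for i, ci in enumerate(order, start=1):
        label = n + i
        if label > cover.m:
            if len(ci) == 1:
                warnings.warn(
                    "final labelling-order set is a singleton: the "
                    "reconstructed root has out-degree 1", stacklevel=2)
            continue
        mult = cover.multiplicity(label)
        if len(ci) == 1 and mult <= 1:
            violations.append(label)
        elif len(ci) > 1 and mult > 1:
            violations.append(label)
    return violations


def cover_of(net: PhyloNetwork) -> Cover:
    """The cover associated with a labellable network: the sets of sibling
    labels ``{labels of c_N(v)}`` over non-leaf vertices ``v``."""
    labelling = label_network(net)
    sets = []
    for v in net.non_leaf_vertices():
        sets.append(frozenset(labelling.label(c) for c in net.children(v)))
    return Cover.from_sets(sets)


def network_from_cover(cover: Cover) -> PhyloNetwork:
    """Reconstruct the unique labellable network with the given cover.

    Starts from isolated leaf vertices ``1..n``; for each ``C_i`` in the
    labelling order a new vertex labelled ``n+i`` is added with an edge to
    each member of ``C_i``.  Labels repeated across sets become
    reticulations; the vertex added last is the root (its label ``m+1``
    never occurs in the cover).  Vertex identifiers in the result are the
    label integers themselves, with ``m+1`` for the root.
    """
    order = labelling_order(cover)
    n = order.n
    edges: list[tuple[int, int]] = []
    for i, ci in enumerate(order, start=1):
        parent = n + i
        for x in sorted(ci):
            edges.append((parent, x))
    leaf_label = {i: i for i in range(1, n + 1)}
    return PhyloNetwork(edges, leaf_label)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def parse_cover(text: str, format: str = "auto") -> Cover:
    """Parse a cover from JSON (``{"m": int, "sets": [[...], ...]}`` or a
    bare list of lists) or line-oriented text (comma-separated integers per
    line).  Duplicate sets, empty sets and ground-set gaps are errors."""
    stripped = text.strip()
    if format == "auto":
        format = "json" if stripped[:1] in "{[" else "lines"
    if format == "json":
        data = json.loads(stripped)
        if isinstance(data, dict):
            sets = data["sets"]
            declared_m = data.get("m")
        else:
            sets, declared_m = data, None
        cover = Cover.from_sets(sets)
        if declared_m is not None and declared_m != cover.m:
            raise CoverError(
                f"declared m={declared_m} but ground set is [{cover.m}]")
        return cover
    if format == "lines":
        sets = []
        for lineno, raw in enumerate(stripped.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                sets.append([int(tok) for tok in line.replace(",", " ").split()])
            except ValueError:
                raise CoverError(
                    f"line {lineno}: non-integer token in {line!r}") from None
        return Cover.from_sets(sets)
    raise ValueError(f"unknown cover format {format!r}")


def write_cover(cover: Cover, format: str = "json") -> str:
    """Serialise a cover; round trip through :func:`parse_cover` is the
    identity on the set of sets."""
    if format == "json":
        return json.dumps({"m": cover.m, "sets": cover.sorted_sets()})
    if format == "lines":
        return "\n".join(",".join(map(str, s))
                         for s in cover.sorted_sets()) + "\n"
    raise ValueError(f"unknown cover format {format!r}")
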