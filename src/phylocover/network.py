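"""Rooted phylogenetic networks: data model, validation and file I/O.

A rooted phylogenetic network on ``n`` leaves is a directed acyclic graph
with a single root (the unique vertex of in-degree 0) whose out-degree-0
vertices -- the leaves -- each have in-degree 1 and are bijectively labelled
by the integers ``1..n``.  Internal vertices of in-degree greater than 1 are
reticulations; edges point away from the root (down the page, towards the
leaves).

Vertex identifiers are opaque hashables.  Every algorithm in this package is
invariant under renaming of internal identifiers; only leaf labels carry
meaning.
"""

from __future__ import annotations

import enum
import itertools
from typing import Hashable, Iterable, Mapping

import networkx as nx

Vertex = Hashable

__all__ = [
    "PhyloNetwork",
    "NetworkError",
    "NetworkSyntaxError",
    "InvariantError",
    "VertexRole",
    "Degeneracy",
    "parse_network",
    "write_network",
    "parse_enewick",
    "write_enewick",
    "parse_edgelist",
    "write_edgelist",
]


class NetworkError(ValueError):
    """Base class for malformed-network errors."""


class NetworkSyntaxError(NetworkError):
    """Raised when input text cannot be parsed in the named dialect."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class InvariantError(NetworkError):
    """Raised when a digraph violates the phylogenetic-network invariants.

    Carries the offending vertices in :attr:`witnesses`.
    """

    def __init__(self, message: str, witnesses: tuple = ()):
        self.witnesses = witnesses
        super().__init__(message)


class VertexRole(enum.Enum):
    ROOT = "root"
    LEAF = "leaf"
    TREE_VERTEX = "tree_vertex"
    RETICULATION = "reticulation"


class Degeneracy(enum.Enum):
    NONDEGENERATE = "nondegenerate"
    DEGENERATE_TREE = "degenerate_tree"
    DEGENERATE_RETICULATION = "degenerate_reticulation"


class PhyloNetwork:
    """A validated rooted phylogenetic network.

    Parameters
    ----------
    edges:
        Iterable of ``(parent, child)`` pairs.  Parallel edges are forbidden:
        child/parent sets are genuine sets, so a reticulation cannot receive
        two edges from the same parent.
    leaf_label:
        Mapping from each out-degree-0 vertex to its integer label; must be a
        bijection onto ``{1..n}``.

    Raises
    ------
    InvariantError
        If the digraph has a cycle, zero or several roots, an unlabelled or
        mislabelled leaf, a labelled non-leaf, a leaf of in-degree != 1, a
        parallel edge, or an unreachable vertex.
    """

    def __init__(self, edges: Iterable[tuple[Vertex, Vertex]],
                 leaf_label: Mapping[Vertex, int]):
        edges = list(edges)
        seen = set()
        for e in edges:
            if e in seen:
                raise InvariantError(f"parallel edge {e!r}", (e,))
            seen.add(e)
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if g.number_of_nodes() == 0:
            raise InvariantError("empty network")
        for u, v in edges:
            if u == v:
                raise InvariantError(f"self-loop at {u!r}", (u,))
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise InvariantError("directed cycle", tuple(u for u, _ in cyc))
        roots = [v for v in g if g.in_degree(v) == 0]
        if len(roots) != 1:
            raise InvariantError(
                f"expected exactly one root, found {len(roots)}", tuple(roots))
        self._root = roots[0]
        leaves = {v for v in g if g.out_degree(v) == 0}
        labelled = set(leaf_label)
        if labelled != leaves:
            bad = tuple(labelled ^ leaves)
            raise InvariantError(
                "leaf_label domain must be exactly the out-degree-0 vertices",
                bad)
        n = len(leaves)
        values = sorted(leaf_label.values())
        if values != list(range(1, n + 1)):
            raise InvariantError(
                f"leaf labels must be a bijection onto 1..{n}, got {values}",
                tuple(leaves))
        for v in leaves:
            if g.in_degree(v) != 1:
                raise InvariantError(
                    f"leaf {leaf_label[v]} has in-degree {g.in_degree(v)}",
                    (v,))
        reachable = {self._root} | nx.descendants(g, self._root)
        if reachable != set(g):
            bad = tuple(set(g) - reachable)
            raise InvariantError("vertices unreachable from the root", bad)
        self._graph = g
        self._leaf_label = dict(leaf_label)
        self._label_leaf = {l: v for v, l in leaf_label.items()}

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self) -> Vertex:
        return self._root

    @property
    def n(self) -> int:
        """Leaf count."""
        return len(self._leaf_label)

    @property
    def leaf_label(self) -> dict[Vertex, int]:
        return dict(self._leaf_label)

    def leaf_with_label(self, label: int) -> Vertex:
        return self._label_leaf[label]

    def vertices(self) -> set[Vertex]:
        return set(self._graph)

    def edges(self) -> set[tuple[Vertex, Vertex]]:
        return set(self._graph.edges())

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __contains__(self, v: Vertex) -> bool:
        return v in self._graph

    def digraph(self) -> nx.DiGraph:
        """A copy of the underlying digraph."""
        return self._graph.copy()

    def _check_vertex(self, v: Vertex) -> None:
        if v not in self._graph:
            raise KeyError(f"unknown vertex {v!r}")

    def children(self, v: Vertex) -> set[Vertex]:
        """The children set c_N(v)."""
        self._check_vertex(v)
        return set(self._graph.successors(v))

    def parents(self, v: Vertex) -> set[Vertex]:
        """The parent set p_N(v)."""
        self._check_vertex(v)
        return set(self._graph.predecessors(v))

    def in_degree(self, v: Vertex) -> int:
        self._check_vertex(v)
        return self._graph.in_degree(v)

    def out_degree(self, v: Vertex) -> int:
        self._check_vertex(v)
        return self._graph.out_degree(v)

    def is_leaf(self, v: Vertex) -> bool:
        self._check_vertex(v)
        return self._graph.out_degree(v) == 0

    def leaves(self) -> set[Vertex]:
        return set(self._leaf_label)

    def internal_vertices(self) -> set[Vertex]:
        """Vertices that are neither the root nor a leaf."""
        return self.vertices() - self.leaves() - {self._root}

    def non_leaf_vertices(self) -> set[Vertex]:
        return self.vertices() - self.leaves()

    def reticulations(self) -> set[Vertex]:
        return {v for v in self._graph if self._graph.in_degree(v) > 1}

    # -- classification ----------------------------------------------------

    def classify_vertex(self, v: Vertex) -> tuple[VertexRole, Degeneracy]:
        """Role (root / leaf / tree vertex / reticulation) and degeneracy.

        A non-root internal vertex is degenerate if its in- and out-degree
        are both 1 (degenerate tree vertex) or both greater than 1
        (degenerate reticulation).  The root is exempt from the degeneracy
        classification.
        """
        self._check_vertex(v)
        ind = self._graph.in_degree(v)
        outd = self._graph.out_degree(v)
        if ind == 0:
            role = VertexRole.ROOT
        elif outd == 0:
            role = VertexRole.LEAF
        elif ind > 1:
            role = VertexRole.RETICULATION
        else:
            role = VertexRole.TREE_VERTEX
        degen = Degeneracy.NONDEGENERATE
        if role in (VertexRole.TREE_VERTEX, VertexRole.RETICULATION):
            if ind == 1 and outd == 1:
                degen = Degeneracy.DEGENERATE_TREE
            elif ind > 1 and outd > 1:
                degen = Degeneracy.DEGENERATE_RETICULATION
        return role, degen

    def degenerate_vertices(self) -> set[Vertex]:
        return {v for v in self._graph
                if self.classify_vertex(v)[1] is not Degeneracy.NONDEGENERATE}

    def is_nondegenerate(self) -> bool:
        return not self.degenerate_vertices()

    def is_binary(self) -> bool:
        """True iff the root has out-degree 2 and every internal vertex has
        total degree 3 (in/out degrees (1,2) or (2,1))."""
        if self._graph.out_degree(self._root) != 2:
            return False
        for v in self.internal_vertices():
            dio = (self._graph.in_degree(v), self._graph.out_degree(v))
            if dio not in ((1, 2), (2, 1)):
                return False
        return True

    def is_tree(self) -> bool:
        return all(self._graph.in_degree(v) <= 1 for v in self._graph)

    # -- comparison --------------------------------------------------------

    def isomorphic_to(self, other: "PhyloNetwork") -> bool:
        """Leaf-label-preserving digraph isomorphism."""
        if self.n != other.n or len(self) != len(other):
            return False
        g1 = self._graph.copy()
        g2 = other._graph.copy()
        nx.set_node_attributes(g1, {v: self._leaf_label.get(v)
                                    for v in g1}, "label")
        nx.set_node_attributes(g2, {v: other._leaf_label.get(v)
                                    for v in g2}, "label")
        matcher = nx.algorithms.isomorphism.DiGraphMatcher(
            g1, g2,
            node_match=lambda a, b: a["label"] == b["label"])
        return matcher.is_isomorphic()

    def relabelled(self, mapping: Mapping[Vertex, Vertex]) -> "PhyloNetwork":
        """Copy with vertex identifiers renamed by ``mapping`` (total map)."""
        edges = [(mapping[u], mapping[v]) for u, v in self._graph.edges()]
        labels = {mapping[v]: l for v, l in self._leaf_label.items()}
        return PhyloNetwork(edges, labels)

    def __repr__(self) -> str:
        return (f"<PhyloNetwork n={self.n} vertices={len(self)} "
                f"reticulations={len(self.reticulations())}>")


# ---------------------------------------------------------------------------
# extended Newick
# ---------------------------------------------------------------------------

def parse_enewick(text: str) -> PhyloNetwork:
    """Parse an extended-Newick string into a network.

    Hybrid vertices tagged ``#H<k>`` (also ``#LGT``/``#R`` tags) occurring
    several times are merged into a single reticulation; the children given
    at each occurrence are united.  Leaf names must be the decimal integers
    ``1..n``; internal names are ignored.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NetworkSyntaxError("eNewick must end with ';'", len(s))
    s = s[:-1]
    pos = 0
    counter = itertools.count()
    edges: list[tuple[str, str]] = []
    names: dict[str, str] = {}       # vertex id -> bare name (may be '')
    hybrids: dict[str, str] = {}     # hybrid tag -> vertex id

    def error(msg: str) -> NetworkSyntaxError:
        return NetworkSyntaxError(msg, pos)

    def read_name() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),;":
            pos += 1
        return s[start:pos].strip()

    def subtree() -> str:
        # returns vertex id of the parsed subtree root
        nonlocal pos
        children: list[str] = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children.append(subtree())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(subtree())
            if pos >= len(s) or s[pos] != ")":
                raise error("expected ')'")
            pos += 1
        name = read_name()
        if ":" in name:  # branch lengths are accepted and discarded
            name = name.split(":", 1)[0].strip()
        tag = None
        if "#" in name:
            name, tag = name.split("#", 1)
            name = name.strip()
            tag = tag.strip()
            if not tag:
                raise error("empty hybrid tag")
        if tag is not None:
            vid = hybrids.setdefault(tag, f"_h_{tag}")
        else:
            vid = f"_v{next(counter)}"
        if name:
            prev = names.get(vid, "")
            if prev and prev != name:
                raise error(f"hybrid tag #{tag} used with names "
                            f"{prev!r} and {name!r}")
            names[vid] = name
        else:
            names.setdefault(vid, "")
        for c in children:
            if (vid, c) in set(edges):
                raise error(f"parallel edge to {names.get(c) or c!r}")
            edges.append((vid, c))
        return vid

    root = subtree()
    if pos != len(s):
        raise error("trailing characters after newick expression")

    g = nx.DiGraph(edges)
    g.add_node(root)
    leaf_label: dict[str, int] = {}
    for v in g:
        if g.out_degree(v) == 0:
            nm = names.get(v, "")
            if not nm:
                raise NetworkSyntaxError(f"unlabelled leaf (vertex {v!r})")
            try:
                leaf_label[v] = int(nm)
            except ValueError:
                raise NetworkSyntaxError(
                    f"leaf name {nm!r} is not a decimal integer") from None
    return PhyloNetwork(g.edges(), leaf_label)


def write_enewick(net: PhyloNetwork) -> str:
    """Serialise to extended Newick.

    Each reticulation is emitted once with its children and tagged ``#H<k>``;
    later occurrences are bare ``#H<k>`` references.  Children are ordered by
    a bottom-up structural signature (leaf labels at the leaves, sorted child
    signatures above) and hybrid tags are numbered by first encounter in the
    resulting traversal, so the output is invariant under renaming of
    internal vertex identifiers.
    """
    g = net.digraph()
    sig: dict[Vertex, tuple] = {}
    for v in reversed(list(nx.topological_sort(g))):
        if net.is_leaf(v):
            sig[v] = ("L", net.leaf_label[v])
        else:
            kids = sorted(sig[c] for c in g.successors(v))
            sig[v] = ("I", g.in_degree(v) > 1, tuple(kids))

    hybrid_tag: dict[Vertex, int] = {}
    counter = itertools.count(1)

    def render(v: Vertex) -> str:
        if net.is_leaf(v):
            return str(net.leaf_label[v])
        if g.in_degree(v) > 1:
            if v in hybrid_tag:
                return f"#H{hybrid_tag[v]}"
            hybrid_tag[v] = next(counter)
        kids = sorted(g.successors(v), key=lambda c: sig[c])
        inner = "(" + ",".join(render(c) for c in kids) + ")"
        if v in hybrid_tag:
            return inner + f"#H{hybrid_tag[v]}"
        return inner

    return render(net.root) + ";"


# ---------------------------------------------------------------------------
# edge-list TSV
# ---------------------------------------------------------------------------

def parse_edgelist(text: str) -> PhyloNetwork:
    """Parse a two-column ``parent<TAB>child`` edge list.

    A header line ``parent<TAB>child`` is optional.  Vertices of out-degree 0
    are the leaves and their names must be the integers ``1..n``.
    """
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.replace("\t", " ").split()]
        if len(parts) != 2:
            raise NetworkSyntaxError(
                f"line {lineno}: expected two columns, got {len(parts)}")
        if lineno == 1 and [p.lower() for p in parts] == ["parent", "child"]:
            continue
        edges.append((parts[0], parts[1]))
    if not edges:
        raise NetworkSyntaxError("empty edge list")
    g = nx.DiGraph(edges)
    if g.number_of_edges() != len(edges):
        raise NetworkSyntaxError("duplicate (parallel) edge in edge list")
    leaf_label = {}
    for v in g:
        if g.out_degree(v) == 0:
            try:
                leaf_label[v] = int(v)
            except ValueError:
                raise NetworkSyntaxError(
                    f"leaf name {v!r} is not a decimal integer") from None
    return PhyloNetwork(edges, leaf_label)


def write_edgelist(net: PhyloNetwork) -> str:
    """Serialise as ``parent<TAB>child`` lines (with header).

    Leaves are written as their labels; other vertices get fresh names
    ``v1, v2, ...`` in topological order (the root is ``v1``).
    """
    g = net.digraph()
    rename: dict[Vertex, str] = {}
    counter = itertools.count(1)
    for v in nx.topological_sort(g):
        if net.is_leaf(v):
            rename[v] = str(net.leaf_label[v])
        else:
            rename[v] = f"v{next(counter)}"
    lines = ["parent\tchild"]
    for u, v in sorted(g.edges(), key=lambda e: (rename[e[0]], rename[e[1]])):
        lines.append(f"{rename[u]}\t{rename[v]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def parse_network(text: str, format: str = "enewick") -> PhyloNetwork:
    """Parse ``text`` in the named dialect (``enewick`` or ``edgelist``)."""
    if format == "enewick":
        return parse_enewick(text)
    if format == "edgelist":
        return parse_edgelist(text)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: PhyloNetwork, format: str = "enewick") -> str:
    """Serialise ``net``; ``parse_network(write_network(N))`` is isomorphic
    to ``N`` under a leaf-label-preserving digraph isomorphism."""
    if format == "enewick":
        return write_enewick(net)
    if format == "edgelist":
        return write_edgelist(net)
    raise ValueError(f"unknown network format {format!r}")
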