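# Methods

This note records the model conventions, algorithmic choices and numerical
corner cases behind `phylocover`, at the level of detail a maintainer or
reviewer needs to predict its behaviour on inputs the tests do not show.

## Network model

A `PhyloNetwork` is a finite DAG with one in-degree-0 vertex (the root) and
with the out-degree-0 vertices (leaves) bijectively labelled `1..n`; every
leaf has in-degree exactly 1 and every vertex is reachable from the root.
Internal vertices may have any nonzero in- and out-degree, so degenerate
vertices (in = out = 1, or both > 1) are representable; a root of
out-degree 1 is accepted.  Parallel edges are forbidden: children and
parents are genuine sets, which means a reticulation receiving both of its
in-edges from one parent cannot be expressed and such input is rejected at
parse time.  Vertex identifiers are opaque; every exported quantity
(labellings, covers, serialisations, class predicates) is invariant under
renaming of internal identifiers, and this is tested.

Extended Newick is parsed by a small recursive-descent reader: `#H` (or any
`#tag`) occurrences with the same tag are merged into one vertex, with the
children given at each occurrence united; branch lengths are accepted and
discarded; internal names are ignored.  The writer orders children by a
bottom-up structural signature and numbers hybrid tags by first encounter,
so output is canonical for a given leaf-labelled isomorphism class in all
non-pathological cases (two structurally identical sibling sub-DAGs may
still serialise in either order; the parse/write round trip is nevertheless
always an isomorphism, which is the tested contract).

## The order ≺ and a repaired notion of "minimal"

The pairwise relation `A ≺ B iff A ⊆ B or min(A\B) < min(B\A)` is total and
antisymmetric on distinct non-empty sets, but it is **not transitive**:
`{4} ≺ {2,4} ≺ {3} ≺ {4}` is a 3-cycle, and such cycles occur in real
eligible families (they need an element repeated across sets, i.e.
reticulate labels).  A comparison-sort against ≺ is therefore ill-defined.
`min_set` instead returns the *undominated* element of a family — the set
preceded by no other member — which is unique whenever it exists and
reproduces every worked ordering.  When a family is caught in a cycle and
has no undominated element, the deadlock is broken by the lexicographic
order on sorted tuples.

Why any fixed rule is safe: the greedy cover ordering and the
vertex-labelling loop are presented with *identical* families of sets at
every step (the set containing the top label `m` is eligible only at the
final step, which is also when the root would be reached), so as long as
both use the same deterministic selection, extraction and reconstruction
invert each other.  The property tests exercise this through thousands of
sampled covers, many containing cycles.

## Labelling and the bijection

`label_network` checks injectivity of the children-set map up front and
fails with a witness pair before doing any work, so error reporting does not
depend on traversal order.  The loop excludes the root from the candidate
pool; because a labelled vertex has all its descendants labelled, the root
can only become a candidate at the very last step, so this is equivalent to
labelling everything and discarding the root's label.  Candidate children
sets are asserted pairwise distinct at every step (they must be, by the
injectivity characterisation).

`network_from_cover` materialises the labelling order directly: vertex
identifiers in the reconstruction are the label integers themselves, with
`m+1` for the root.  Cover equality (set-of-sets) is the canonical
comparison for labellable networks; leaf-label-preserving digraph
isomorphism (VF2 via networkx) is used as the independent cross-check in
the round-trip tests rather than as the implementation.

## Order condition

`order_condition_violations` evaluates, for each `C_i` in the labelling
order with induced label `n+i ≤ m`, the multiplicity of `n+i` across the
cover.  The final set's induced label is `m+1`, belongs to the unlabelled
root, and is exempt.  A singleton final set would give the root out-degree
1; since degeneracy is defined for internal vertices only, this is reported
as a `UserWarning` rather than a violation.  The empty-violation state is
verified equivalent to non-degeneracy of the reconstruction, in both
directions, on random covers and on all expanding covers with `m ≤ 4`
(enumerated exhaustively in the tests).

## Class predicates

- **Tree-child / tree-sibling** are direct degree checks; tree-child is
  cross-validated against the all-vertices-visible criterion.
- **Visibility** removes each vertex and tests leaf reachability from the
  root; O(V·(V+E)), fine at the package's scale.
- **Orchard (binary, non-degenerate only)** applies cherry and
  reticulated-cherry reductions with a fixed deterministic policy (smallest
  leaf pair, cherries first) until a single leaf with no reticulations
  remains.  Correctness of the fixed order relies on the order-independence
  of binary cherry-picking reductions; a full backtracking reducer is kept
  as an oracle and the two are asserted equal on random and hand-built
  instances.  Non-binary orchard recognition is out of scope; `classify`
  reports the predicate as absent there.
- **Tree-based** enumerates, for each reticulation, which in-edge the
  spanning tree keeps (tree vertices have no choice) and accepts if some
  assignment leaves every non-leaf vertex with a kept child; exact by
  definition, with a configurable cap (default 2^20 assignments) beyond
  which it refuses rather than guesses.  For binary non-degenerate inputs
  the same question is reduced to 2-SAT (one boolean per reticulation; one
  clause per vertex whose children are all reticulate) solved by SCC on the
  implication graph, and the two answers are asserted equal on every call.
- **Normal** = tree-child with no shortcut edge (an edge `(u,v)` with
  another directed `u→v` path).

Two hand-built witnesses pin the non-nesting of the labellable and
tree-based classes: a completed two-parents/two-reticulations gadget
(tree-based, not labellable) and a three-reticulation zig-zag network in
which the two pendant reticulations are forced to claim their blocking
parents, leaving the middle reticulation unable to serve both tree vertices
(labellable, binary, non-degenerate, not tree-based).

## Quotient and normalisation

`quotient_step` merges non-leaf vertices with equal children sets; leaves
are exempt (their children sets are all empty, and merging them would
destroy the leaf set — the only reading consistent with the quotient
preserving leaves `1..n`).  Multi-edges arising from a merge collapse to
single edges.  Classes of merged vertices are antichains, so the quotient
is again a valid single-rooted DAG; this is revalidated after every step.
`derived_network` iterates to the fixpoint, which is labellable; vertices
strictly decrease at every non-final step.  Degree-two vertices created by
quotienting are *not* suppressed — suppression belongs to normalisation,
and keeping the quotient pure makes `D` idempotent on the nose.

`normalise` restricts to the visible vertices, builds the Hasse diagram of
their reachability order (transitive reduction), suppresses internal
vertices of in- and out-degree 1, and keeps a root of out-degree 1 (its
total degree is 1, not 2).  The result is verified normal and idempotent on
random inputs; `D(N(N)) = N(N)` always, while a seeded search in the tests
exhibits networks with `N(D(N)) ≠ N(N)`.

## Synthetic generators

All generators are driven by a single integer seed through
`numpy.random.default_rng` and are reproducible bit-for-bit.

- **Expanding covers** are sampled constructively as a sequence
  `C_i ⊆ [n+i-1]`: set sizes are geometric (p = 0.45, capped at 4), leaf
  elements are drawn without replacement, internal labels with replacement
  across sets, and the final set collects all unused elements (it always
  contains `m`).  Both expanding conditions hold by construction; the
  distribution over expanding covers is valid but unspecified — uniform
  sampling is an open problem.
- **Class-filtered networks**: `labellable` reconstructs a random cover;
  `nondegenerate` rejects covers with order-condition violations or a
  singleton root set; `orchard_binary` grows from a cherry by reverse
  cherry/reticulated-cherry expansions (membership by construction);
  `tree_child`, `tree_sibling` and `normal` add reticulation edges to a
  random coalescent-style tree by double edge subdivision, rejecting any
  addition the class predicate refutes, so generation and validation agree
  by construction; `unrestricted` plants a two-parent equal-children gadget
  with probability 0.3 (default), which makes the instance unlabellable.
- Default sizes (n around 3–10, m−n up to ~8) keep every brute-force
  oracle — backtracking orchard reduction, spanning-tree enumeration,
  VF2 isomorphism — instantaneous, which is why the property suites can
  afford hundreds of instances per run.

What the generators do not emulate: biologically calibrated shapes (birth–
hybridisation branch lengths, realistic reticulation densities), non-binary
reticulations above in-degree 2 in the grown classes, and uniformity over
any class.  Passing property suites therefore demonstrate the combinatorial
theorems and the correctness of the algorithms on their stated domains, not
statistical behaviour on empirical networks.

## Problem sizes in the shipped suites

The acceptance-style suites use 500 cover and 500 network round trips, 100
generated members per class containment, 200 quotient projections, 100
normalisation fixpoints, and an exhaustive slice of binary networks built
by reticulation-edge insertion into all binary trees at (n=2, k≤3),
(n=3, k≤2) and (n=4..5, k=1) — over a thousand tree-based instances for the
binary characterisation, chosen so the whole suite runs in seconds.

## Known limitations

- Non-binary orchard recognition and the stable/semiresolved labellability
  criterion are not implemented.
- `is_tree_based` refuses (rather than approximates) beyond its assignment
  cap; networks with ~20+ high-in-degree reticulations need the binary
  2-SAT route or an external solver.
- The eNewick writer's canonical form is best-effort under structurally
  identical sibling sub-DAGs (see above); round-trip isomorphism is
  unaffected.
- Branch lengths and unrooted networks are out of scope.
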