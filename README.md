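# phylocover

Labellable rooted phylogenetic networks and their expanding set covers.

## The problem

Rooted phylogenetic networks generalise phylogenetic trees by allowing
reticulate events (hybridisation, horizontal gene transfer): they are DAGs
with a single root and leaves bijectively labelled `1..n`, where vertices of
in-degree > 1 are reticulations.  Networks are hard to search over and
compare because, unlike trees, they have no obvious flat encoding.

A network is **labellable** when its internal vertices can be numbered
deterministically: starting from the leaf labels `1..n`, repeatedly pick the
unlabelled non-root vertex whose children are all labelled and whose
children-label set `c_N(v)` is minimal in the order

    A ≺ B  iff  A ⊆ B  or  min(A \ B) < min(B \ A),

and give it the next integer.  This is well defined exactly when the
children-set map on non-leaf vertices is injective (`c_N(x) ≠ c_N(y)` for
non-leaf `x ≠ y`).

A labelled network on `n` leaves with `m+1` vertices is fully described by
the family of sibling sets `{labels of c_N(v) : v non-leaf}` — a **cover**
of `[m]` (distinct non-empty subsets with union `{1..m}`).  Covers arising
this way are exactly the **expanding covers**: the leaf elements `1..n`
appear in exactly one set, and for each `i` at least `i` member sets lie
inside `[n+i-1]`.  The correspondence is a bijection, so a whole network can
be stored, compared and manipulated as a set of integer sets; repeated
elements mark reticulations (multiplicity = in-degree) and set sizes give
out-degrees.  A further **order condition** on the greedy *labelling order*
`C_1, ..., C_|C|` (a singleton `C_i` must have its induced label `n+i`
repeated in the cover; a larger `C_i` must not) characterises the covers of
non-degenerate networks.

The package implements, for networks read from extended Newick or edge-list
TSV:

- the labelling algorithm, labellability test with witness, and the
  cover ↔ network bijection in both directions (`label_network`,
  `cover_of`, `network_from_cover`);
- expanding-cover validation, labelling order, and the order-condition
  check (`is_expanding`, `labelling_order`, `order_condition_violations`);
- class predicates — tree-child, tree-sibling, orchard (binary),
  tree-based (exact search, cross-checked by a polynomial 2-SAT method on
  binary inputs), normal, visibility — and an aggregating `classify`;
- the derived-network quotient `D(N)` (merge vertices with equal children
  sets until labellable) and the normalisation `N(N)` (Hasse diagram of the
  visible vertices), two canonical projections with `D(N(N)) = N(N)`;
- seeded generators of random expanding covers and random networks in each
  class, used throughout the test suite.

## Worked example

The 8-set cover `{{2},{5},{1,6},{4,8},{3,6,9},{10},{7,11},{8,12}}` of [12]
describes a network with `n = 12 - 8 + 1 = 5` leaves:

```sh
$ printf '2\n5\n1,6\n4,8\n3,6,9\n10\n7,11\n8,12\n' | phylocover check-cover
{
  "m": 12,
  "num_sets": 8,
  "implied_leaf_count": 5,
  "expanding": true,
  "order_condition_violations": [
    11
  ],
  "nondegenerate": false
}
```

The cover is expanding, so it reconstructs to a unique network; its
labelling order is `({2},{1,6},{5},{4,8},{3,6,9},{10},{7,11},{8,12})`, and
the order condition flags label 11: the third singleton `{10}` induces label
`5 + 6 = 11`, which appears only once in the cover, so vertex 11 of the
reconstruction is degenerate (in- and out-degree 1).  Labels 6 and 8 appear
twice, so they are the reticulations:

```python
>>> from phylocover import parse_cover, network_from_cover
>>> net = network_from_cover(parse_cover("2\n5\n1,6\n4,8\n3,6,9\n10\n7,11\n8,12"))
>>> sorted(v for v in net.vertices() if net.in_degree(v) > 1)
[6, 8]
>>> net.in_degree(11), net.out_degree(11)
(1, 1)
```

Piping `from-cover` into `to-cover` is the identity on cover JSON — the
bijection in action.

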