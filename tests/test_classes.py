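"""Class predicates and the structural theorems connecting them."""

import itertools

import networkx as nx
import pytest

from phylocover import (GenConfig, PhyloNetwork, find_cherries,
                        find_reticulated_cherries, is_labellable, is_normal,
                        is_orchard_binary, is_tree_based, is_tree_child,
                        is_tree_sibling, classify, random_network,
                        visible_vertices)
from phylocover.classes import _orchard_backtracking, \
    _tree_based_binary_2sat, _tree_based_bruteforce


def _random_tree_net(seed, n=6):
    return random_network(GenConfig(n=n, m=n, seed=seed,
                                    class_filter="tree_child"))


class TestTreeChildAndSibling:
    def test_trees_are_tree_child_and_tree_sibling(self):
        net = _random_tree_net(0)
        assert is_tree_child(net)
        assert is_tree_sibling(net)

    def test_gadget_is_neither(self, fig2_gadget):
        assert not is_tree_child(fig2_gadget)
        assert not is_tree_sibling(fig2_gadget)

    def test_tree_child_equals_all_vertices_visible(self):
        for seed in range(25):
            net = random_network(GenConfig(n=5, m=8, seed=seed,
                                           class_filter="unrestricted"))
            assert is_tree_child(net) == \
                (visible_vertices(net) == net.vertices())


class TestVisibility:
    def test_all_tree_vertices_visible(self):
        net = _random_tree_net(3)
        assert visible_vertices(net) == net.vertices()

    def test_equal_children_parents_invisible(self, fig2_gadget):
        vis = visible_vertices(fig2_gadget)
        assert "u" not in vis and "v" not in vis

    def test_leaves_visible_via_themselves(self, min_reticulation):
        assert min_reticulation.leaves() <= visible_vertices(min_reticulation)


class TestCherries:
    def test_cherry_tree(self, cherry_tree):
        assert find_cherries(cherry_tree) == [(1, 2)]
        assert find_reticulated_cherries(cherry_tree) == []

    def test_minimal_reticulation_network(self, min_reticulation):
        # leaf 3 hangs below the reticulation x whose parents a, b are the
        # parents of leaves 1 and 2
        assert find_cherries(min_reticulation) == []
        assert find_reticulated_cherries(min_reticulation) == \
            [(3, 1), (3, 2)]

    def test_cherry_free_network_exists_and_is_not_orchard(self):
        # two tree vertices sharing three reticulate children: no cherry or
        # reticulated cherry can ever appear at step 0
        net = _two_parent_fan(3)
        assert find_cherries(net) == []
        assert find_reticulated_cherries(net) == []


def _two_parent_fan(k):
    """Root over two vertices u1, u2 sharing k reticulate children."""
    edges = [("rho", "u1"), ("rho", "u2")]
    labels = {}
    for i in range(1, k + 1):
        edges += [("u1", f"r{i}"), ("u2", f"r{i}"), (f"r{i}", f"l{i}")]
        labels[f"l{i}"] = i
    return PhyloNetwork(edges, labels)


class TestOrchard:
    def test_binary_trees_are_orchard(self):
        for seed in range(10):
            net = random_network(GenConfig(n=5, m=5, seed=seed,
                                           class_filter="orchard_binary"))
            assert is_orchard_binary(net)

    def test_generated_orchard_networks_are_orchard_and_labellable(self):
        for seed in range(60):
            n = 3 + seed % 5
            net = random_network(GenConfig(n=n, m=n + seed % 5, seed=seed,
                                           class_filter="orchard_binary"))
            assert is_orchard_binary(net)
            assert is_labellable(net)
            # no two vertices share a children set in an orchard network
            children_sets = [frozenset(net.children(v))
                             for v in net.non_leaf_vertices()]
            assert len(children_sets) == len(set(children_sets))

    def test_cherry_free_binary_network_is_not_orchard(self, zigzag):
        # the zig-zag witness is binary and non-degenerate but has no cherry
        # and no reticulated cherry at the first step
        assert find_cherries(zigzag) == []
        assert find_reticulated_cherries(zigzag) == []
        assert not is_orchard_binary(zigzag)

    def test_deterministic_reduction_agrees_with_backtracking(self):
        nets = [random_network(GenConfig(n=3 + s % 3, m=3 + s % 3 + s % 4,
                                         seed=s,
                                         class_filter="orchard_binary"))
                for s in range(15)]
        fx_nets = [_zigzag()]
        for net in nets + fx_nets:
            assert is_orchard_binary(net) == _orchard_backtracking(net)

    def test_rejects_nonbinary_input(self, fig3_cover):
        from phylocover import network_from_cover
        with pytest.raises(ValueError):
            is_orchard_binary(network_from_cover(fig3_cover))


def _zigzag():
    from phylocover import fixtures
    return fixtures()["zigzag_network"]


class TestTreeBased:
    def test_trees_are_tree_based(self):
        assert is_tree_based(_random_tree_net(1))

    def test_double_reticulation_chain_is_not_tree_based(self, zigzag):
        assert not is_tree_based(zigzag)

    def test_gadget_completed_is_tree_based_but_not_labellable(
            self, fig2_gadget):
        assert is_tree_based(fig2_gadget)
        assert not is_labellable(fig2_gadget)

    def test_zigzag_is_labellable_but_not_tree_based(self, zigzag):
        assert is_labellable(zigzag)
        assert not is_tree_based(zigzag)

    def test_2sat_matches_bruteforce_on_random_binary_networks(self):
        for seed in range(40):
            n = 3 + seed % 4
            net = random_network(GenConfig(n=n, m=n + seed % 4, seed=seed,
                                           class_filter="orchard_binary"))
            assert _tree_based_binary_2sat(net) == \
                _tree_based_bruteforce(net, 2 ** 20)

    def test_binary_tree_based_labellable_iff_distinct_retic_parent_sets(
            self):
        """Over exhaustively enumerated small binary tree-based networks,
        labellability is equivalent to all reticulation pairs having
        distinct parent sets."""
        checked = 0
        for net in _enumerate_small_binary():
            if not is_tree_based(net):
                # inserting into a previously added reticulation edge can
                # break tree-basedness; the theorem says nothing there
                continue
            retics = sorted(net.reticulations(), key=repr)
            distinct_parents = all(
                net.parents(x) != net.parents(y)
                for x, y in itertools.combinations(retics, 2))
            assert is_labellable(net) == distinct_parents
            checked += 1
        assert checked > 1000


def _binary_trees(n):
    """All rooted binary trees on leaves 1..n (vertex ids are tuples)."""

    def build(leafset):
        if len(leafset) == 1:
            return [(leafset[0], [])]
        trees = []
        rest = leafset[1:]
        first = leafset[0]
        # choose the leaves accompanying the first leaf in the left subtree
        for r in range(len(rest)):
            for left_rest in itertools.combinations(rest, r):
                left = (first,) + left_rest
                right = tuple(x for x in rest if x not in left_rest)
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(right):
                        trees.append(((left + right), [lt, rt]))
        return trees

    nets = []
    for shape in build(tuple(range(1, n + 1))):
        edges = []

        def walk(node, path):
            vid = f"v{path}"
            name, kids = node
            if not kids:
                return name
            for k, kid in enumerate(kids):
                child = walk(kid, path + str(k))
                edges.append((vid, child))
            return vid

        root = walk(shape, "0")
        nets.append(PhyloNetwork(edges, {i: i for i in range(1, n + 1)}))
    return nets


def _insertions(net, tag):
    """All networks from one reticulation-edge insertion into ``net``."""
    out = []
    edges = sorted(net.edges(), key=repr)
    for (u1, v1), (u2, v2) in itertools.permutations(edges, 2):
        g = net.digraph()
        if u1 == u2 and v1 == v2:
            continue
        if v2 == u1 or nx.has_path(g, v2, u1):
            continue
        s1, s2 = f"s{tag}a", f"s{tag}b"
        g.remove_edge(u1, v1)
        g.remove_edge(u2, v2)
        g.add_edges_from([(u1, s1), (s1, v1), (u2, s2), (s2, v2), (s1, s2)])
        try:
            out.append(PhyloNetwork(g.edges(), net.leaf_label))
        except Exception:
            continue
    return out


def _enumerate_small_binary():
    """Small binary networks built by inserting reticulation edges into
    every binary tree: (n=2, k<=3), (n=3, k<=2), (n=4..5, k=1).  Most are
    tree-based (the base tree usually spans), but an insertion into a
    previously added reticulation edge can destroy the property."""
    for n, max_k in ((2, 3), (3, 2), (4, 1), (5, 1)):
        level = _binary_trees(n)
        for k in range(1, max_k + 1):
            nxt = []
            for net in level:
                nxt.extend(_insertions(net, k))
            level = nxt
            yield from level


class TestNormal:
    def test_trees_are_normal(self):
        assert is_normal(_random_tree_net(2))

    def test_shortcut_edge_breaks_normality(self):
        # tree-child but with an edge root->r alongside root->a->r
        net = PhyloNetwork(
            [("rho", "a"), ("rho", "r"), ("a", "r"), ("a", 1),
             ("r", 2)], {1: 1, 2: 2})
        assert is_tree_child(net)
        assert not is_normal(net)

    def test_normal_networks_satisfy_the_containments(self):
        for seed in range(40):
            n = 4 + seed % 4
            net = random_network(GenConfig(n=n, m=n + seed % 4,
                                           seed=seed, class_filter="normal"))
            assert is_normal(net)
            assert is_tree_child(net)
            assert is_tree_sibling(net)
            assert is_labellable(net)


class TestContainments:
    """The containment diagram among classes, on generated members."""

    @pytest.mark.parametrize("class_filter", ["tree_child", "tree_sibling"])
    def test_class_members_are_labellable(self, class_filter):
        for seed in range(60):
            n = 3 + seed % 5
            net = random_network(GenConfig(n=n, m=n + seed % 4, seed=seed,
                                           class_filter=class_filter))
            assert is_labellable(net), seed

    def test_tree_child_members_are_fully_visible_and_tree_sibling(self):
        for seed in range(30):
            net = random_network(GenConfig(n=4, m=7, seed=seed,
                                           class_filter="tree_child"))
            assert visible_vertices(net) == net.vertices()
            assert is_tree_sibling(net)

    def test_equal_children_pairs_are_invisible(self):
        """Wherever two vertices share a children set, neither is visible."""
        for seed in range(30):
            net = random_network(GenConfig(n=4, m=7, seed=seed,
                                           class_filter="unrestricted",
                                           gadget_p=1.0))
            vis = visible_vertices(net)
            pairs = 0
            vertices = sorted(net.non_leaf_vertices(), key=repr)
            for x, y in itertools.combinations(vertices, 2):
                if net.children(x) == net.children(y):
                    pairs += 1
                    assert x not in vis and y not in vis
            assert pairs >= 1  # the gadget plants at least one pair


class TestClassify:
    def test_tree_report_is_all_true(self):
        report = classify(_random_tree_net(5))
        assert report.labellable and report.tree_child
        assert report.tree_sibling and report.nondegenerate
        assert report.tree_based and report.normal
        assert report.witnesses == []

    def test_gadget_report(self, fig2_gadget):
        report = classify(fig2_gadget)
        assert not report.labellable
        assert not report.tree_child
        assert not report.tree_sibling
        kinds = {k for k, _ in report.witnesses}
        assert "equal_children_sets" in kinds

    def test_degenerate_example_reports_absent_predicates(self, ex45_cover):
        from phylocover import network_from_cover
        report = classify(network_from_cover(ex45_cover))
        assert report.labellable
        assert not report.nondegenerate
        assert report.orchard is None
        assert report.tree_based is None and report.normal is None

    def test_report_serialises_to_json(self, fig2_gadget):
        import json
        data = json.loads(classify(fig2_gadget).to_json())
        assert data["labellable"] is False
        assert data["witnesses"]
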