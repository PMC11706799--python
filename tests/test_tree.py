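"""Tree model: Newick round-trips, edge numbering, pruning, grafting."""

import numpy as np
import pytest

from coiplace.tree import (
    NewickError,
    TreeError,
    graft_query,
    leaf_labels_below,
    mrca,
    number_edges,
    parse_newick,
    prune_taxa,
    sister_group,
    write_newick,
)

from conftest import random_binary_tree


class TestNewick:
    def test_parse_basic_structure(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.leaf_set() == {"A", "B", "C"}
        assert len(t.root.children) == 2
        assert t.n_branches == 4  # 2n-2 for n=3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_random_trees(self, seed):
        t = random_binary_tree(50, seed)
        s = write_newick(t)
        t2 = parse_newick(s)
        assert write_newick(t2) == s
        assert t2.leaf_set() == t.leaf_set()
        d1, d2 = t.leaf_distances(), t2.leaf_distances()
        assert all(abs(d1[k] - d2[k]) < 1e-12 for k in d1)

    def test_two_leaf_serialization(self):
        assert write_newick(parse_newick("(A:0.5,B:0.5);")) == "(A:0.5,B:0.5);"

    def test_edge_number_roundtrip(self):
        t = number_edges(parse_newick("((A:1,B:1):1,C:2);"))
        s = write_newick(t, with_edge_numbers=True)
        assert s.count("{") == t.n_branches
        t2 = parse_newick(s)
        assert {n.label: n.edge_number for n in t2.leaves()} == {
            n.label: n.edge_number for n in t.leaves()
        }

    @pytest.mark.parametrize(
        "bad",
        [
            "((A:1,B:1:1,C:2);",        # unbalanced
            "((A:1,B:1):1,C:2)",        # no semicolon
            "((A:1,A:1):1,C:2);",       # duplicate labels
            "((A:1,B:-1):1,C:2);",      # negative length
            "((A:1,B):1,C:2);",         # mixed lengths
            "((A|x:1,B:1):1,C:2);",     # illegal characters
        ],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises((NewickError, TreeError)):
            parse_newick(bad)

    def test_no_lengths_defaults_to_zero(self):
        t = parse_newick("((A,B),C);")
        assert all(n.length == 0 for n in t.postorder() if n.parent is not None)


class TestEdgeNumbering:
    def test_hand_postorder(self):
        t = number_edges(parse_newick("((A,B),C);"))
        numbers = {}
        for n in t.postorder():
            if n.parent is not None:
                key = n.label or "AB"
                numbers[key] = n.edge_number
        assert numbers == {"A": 0, "B": 1, "AB": 2, "C": 3}

    def test_idempotent_and_dense(self):
        t = random_binary_tree(20, 3)
        number_edges(t)
        first = {id(n): n.edge_number for n in t.postorder()}
        number_edges(t)
        assert {id(n): n.edge_number for n in t.postorder()} == first
        nums = sorted(
            n.edge_number for n in t.postorder() if n.parent is not None
        )
        assert nums == list(range(2 * 20 - 2))  # max edge number 2n-3


class TestPrune:
    def test_hand_cases(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert write_newick(prune_taxa(t, {"C"})) == "(A:1,B:1);"
        assert write_newick(prune_taxa(t, {"B"})) == "(A:2,C:2);"
        assert write_newick(prune_taxa(t, set())) == write_newick(t)

    def test_errors(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError):
            prune_taxa(t, {"A", "B"})
        with pytest.raises(TreeError):
            prune_taxa(t, {"Z"})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_path_lengths_preserved(self, seed):
        t = random_binary_tree(24, seed)
        rng = np.random.default_rng(seed)
        labels = t.leaf_labels()
        drop = set(rng.choice(labels, size=8, replace=False))
        pruned = prune_taxa(t, drop)
        d0, d1 = t.leaf_distances(), pruned.leaf_distances()
        for pair, dist in d1.items():
            assert abs(dist - d0[pair]) < 1e-9


class TestCladeQueries:
    def test_mrca(self, five_leaf_tree):
        t = five_leaf_tree
        assert leaf_labels_below(mrca(t, {"D", "E"})) == {"D", "E"}
        assert leaf_labels_below(mrca(t, {"C", "E"})) == {"C", "D", "E"}
        leaf = mrca(t, {"A"})
        assert leaf.is_leaf and leaf.label == "A"
        with pytest.raises(TreeError):
            mrca(t, {"A", "Z"})
        with pytest.raises(TreeError):
            mrca(t, set())

    def test_sister_group(self, five_leaf_tree):
        t = five_leaf_tree
        assert sister_group(t, "D") == {"E"}
        assert sister_group(t, "C") == {"D", "E"}
        assert sister_group(t, "A") == {"B"}
        assert sister_group(parse_newick("(A:1,B:1);"), "A") == {"B"}
        with pytest.raises(TreeError):
            sister_group(t, "Z")


class TestGraft:
    def test_sister_after_terminal_graft(self, five_leaf_tree):
        t = number_edges(five_leaf_tree.copy())
        e_num = next(
            n.edge_number for n in t.postorder() if n.label == "E"
        )
        g = graft_query(t, "Q", e_num, 0.5, 0.2)
        assert sister_group(g, "Q") == {"E"}
        assert g.n_leaves == 6

    def test_sister_after_internal_graft(self, five_leaf_tree):
        t = number_edges(five_leaf_tree.copy())
        e_num = next(
            n.edge_number
            for n in t.postorder()
            if not n.is_leaf and leaf_labels_below(n) == {"C", "D", "E"}
        )
        g = graft_query(t, "Q", e_num, 0.5, 0.2)
        assert sister_group(g, "Q") == {"C", "D", "E"}

    def test_existing_paths_conserved(self, five_leaf_tree):
        t = number_edges(five_leaf_tree.copy())
        d0 = t.leaf_distances()
        g = graft_query(t, "Q", 2, 0.3, 0.7)
        d1 = g.leaf_distances()
        for pair, dist in d0.items():
            assert abs(d1[pair] - dist) < 1e-12

    def test_errors(self, five_leaf_tree):
        t = number_edges(five_leaf_tree.copy())
        with pytest.raises(TreeError):
            graft_query(t, "A", 0, 0.1, 0.1)  # name collision
        with pytest.raises(TreeError):
            graft_query(t, "Q", 999, 0.1, 0.1)  # unknown edge
        with pytest.raises(TreeError):
            graft_query(t, "Q", 0, 5.0, 0.1)  # distal beyond branch

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_prune_graft_duality(self, seed):
        """Dropping a leaf and re-grafting it at its recorded true position
        recovers every pairwise path length of the original tree."""
        t = random_binary_tree(16, seed + 100)
        rng = np.random.default_rng(seed)
        q = str(rng.choice(t.leaf_labels()))
        d0 = t.leaf_distances()
        depths = t.depths()
        leaf = t.find_leaf(q)
        attach = leaf.parent
        sibling = next(c for c in attach.children if c is not leaf)
        sib_leaves = leaf_labels_below(sibling)
        pendant = depths[leaf] - depths[attach]
        pruned = number_edges(prune_taxa(t, {q}))
        host_child = mrca(pruned, sib_leaves)
        # the host edge's child end sits where the sibling subtree root was
        distal = depths[sibling] - depths[attach]
        g = graft_query(pruned, q, host_child.edge_number, distal, pendant)
        d1 = g.leaf_distances()
        assert all(abs(d1[k] - d0[k]) < 1e-12 for k in d0)
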