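"""Sister-clade accuracy metric: hand traces, aggregation, properties."""

import numpy as np
import pytest

from coiplace.accuracy import (
    AccuracyRecord,
    assess_placement,
    build_placement_tree,
    summarize,
)
from coiplace.jplace import PlacementCandidate
from coiplace.tree import (
    leaf_labels_below,
    number_edges,
    parse_newick,
    prune_taxa,
    sister_group,
)

from conftest import random_binary_tree


def edge_of_leaf(tree, label):
    return next(n.edge_number for n in tree.postorder() if n.label == label)


def edge_of_clade(tree, leaves):
    return next(
        n.edge_number
        for n in tree.postorder()
        if n.parent is not None and not n.is_leaf and leaf_labels_below(n) == leaves
    )


def cand(edge, distal=0.5, pendant=0.1):
    return PlacementCandidate(edge, -1.0, distal, pendant, lwr=1.0)


class TestHandTraces:
    """The worked examples of the sister-clade comparison procedure."""

    def setup_method(self):
        self.ref = parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        self.backbone = number_edges(parse_newick("((A:1,B:1):1,(C:1,E:2):1);"))

    def test_graft_next_to_true_sister_is_correct_in_both_modes(self):
        pt = build_placement_tree(self.backbone, {"D": cand(edge_of_leaf(self.backbone, "E"))})
        for mode in ("sister_mrca", "sister_plus_query_mrca"):
            r = assess_placement("D", pt, self.ref, self.backbone.leaf_set(), mode)
            assert r.verdict == "correct"
            assert r.sister == {"E"} and r.difference == set()

    def test_singleton_wrong_sister_diverges_between_modes(self):
        pt = build_placement_tree(self.backbone, {"D": cand(edge_of_leaf(self.backbone, "C"))})
        lenient = assess_placement("D", pt, self.ref, self.backbone.leaf_set(), "sister_mrca")
        strict = assess_placement(
            "D", pt, self.ref, self.backbone.leaf_set(), "sister_plus_query_mrca"
        )
        assert lenient.verdict == "correct"          # singleton sister: D-list empty
        assert strict.verdict == "incorrect"         # mrca(C, D) pulls in backbone E
        assert strict.difference == {"E"}

    def test_cascading_misplacement_flagged_incorrect(self):
        ref = parse_newick("(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);")
        backbone = number_edges(parse_newick("((B:2,C:2):1,(E:2,F:2):1);"))
        pt = build_placement_tree(
            backbone,
            {
                "A": cand(edge_of_leaf(backbone, "E"), distal=1.0),
                "D": cand(edge_of_clade(backbone, {"E", "F"}), distal=0.2),
            },
        )
        r = assess_placement("D", pt, ref, backbone.leaf_set(), "sister_mrca")
        assert r.sister == {"A", "E", "F"}
        assert r.verdict == "incorrect"
        assert r.difference == {"B", "C"}


class TestBuildPlacementTree:
    def test_leaf_count_bookkeeping(self):
        backbone = number_edges(parse_newick("((A:1,B:1):1,C:2);"))
        pt = build_placement_tree(backbone, {"Q1": cand(0), "Q2": cand(3)})
        assert pt.n_leaves == 5
        assert pt.leaf_set() == {"A", "B", "C", "Q1", "Q2"}

    def test_true_position_recovers_reference_topology(self):
        ref = parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        backbone = number_edges(prune_taxa(ref, {"D"}))
        pt = build_placement_tree(backbone, {"D": cand(edge_of_leaf(backbone, "E"), 0.5, 0.5)})
        assert sister_group(pt, "D") == sister_group(ref, "D")

    def test_graft_order_permutation_invariant_topology(self):
        backbone = number_edges(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        placements = {"Q1": cand(0), "Q2": cand(3), "Q3": cand(5)}
        import itertools

        sisters = set()
        for order in itertools.permutations(placements):
            pt = build_placement_tree(backbone, {k: placements[k] for k in order})
            sisters.add(tuple(sorted((q, tuple(sorted(sister_group(pt, q)))) for q in placements)))
        assert len(sisters) == 1

    def test_shared_edge_stacking(self):
        backbone = number_edges(parse_newick("((A:1,B:1):1,C:2);"))
        pt = build_placement_tree(
            backbone, {"Q1": cand(2, distal=0.8), "Q2": cand(2, distal=0.2)}
        )
        assert pt.n_leaves == 5
        d = pt.leaf_distances()
        assert d[frozenset(("A", "C"))] == pytest.approx(4.0)

    def test_duplicate_names_rejected(self):
        backbone = number_edges(parse_newick("((A:1,B:1):1,C:2);"))
        with pytest.raises(ValueError):
            build_placement_tree(backbone, {"A": cand(2)})


class TestSummarize:
    def rec(self, verdict, lwr):
        return AccuracyRecord("q", verdict, lwr, set(), set())

    def test_basic_percentages(self):
        records = [self.rec("correct", 0.95)] * 7 + [self.rec("incorrect", 0.95)] * 3
        s = summarize(records)
        assert s.pcp == 70.0
        assert s.cp == 100.0
        assert s.pcp_cp == 70.0

    def test_threshold_strictly_greater(self):
        records = [self.rec("correct", 0.9), self.rec("correct", 0.9000001)]
        s = summarize(records)
        assert s.n_confident == 1

    def test_all_confident_correct(self):
        records = [self.rec("correct", 0.99)] * 5
        s = summarize(records)
        assert (s.pcp, s.cp, s.pcp_cp) == (100.0, 100.0, 100.0)

    def test_no_lwr_engine_has_no_cp(self):
        records = [self.rec("correct", None), self.rec("incorrect", None)]
        s = summarize(records)
        assert s.pcp == 50.0 and s.cp is None and s.pcp_cp is None

    def test_zero_confident_undefined_not_zero(self):
        records = [self.rec("correct", 0.5)] * 4
        s = summarize(records)
        assert s.cp == 0.0 and s.pcp_cp is None

    def test_unplaced_excluded_and_empty_rejected(self):
        records = [self.rec("correct", 0.95), self.rec("unplaced", None)]
        assert summarize(records).n_placed == 1
        with pytest.raises(ValueError):
            summarize([self.rec("unplaced", None)])


class TestProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_truth_identity_yields_all_correct(self, seed):
        """Queries grafted at their true positions (i.e. the reference tree
        itself as placement tree) are always judged correct, both modes."""
        tree = random_binary_tree(20, seed + 50)
        rng = np.random.default_rng(seed)
        labels = tree.leaf_labels()
        missing = set(rng.choice(labels, size=6, replace=False))
        backbone_taxa = set(labels) - missing
        for q in missing:
            for mode in ("sister_mrca", "sister_plus_query_mrca"):
                r = assess_placement(q, tree, tree, backbone_taxa, mode)
                assert r.verdict == "correct"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_strict_mode_is_never_more_lenient(self, seed):
        """Any graft judged correct under sister_plus_query_mrca is also
        correct under sister_mrca (exhaustive over edges of small trees)."""
        tree = random_binary_tree(8, seed + 10)
        labels = tree.leaf_labels()
        q = labels[seed]
        backbone = number_edges(prune_taxa(tree, {q}))
        for node in backbone.postorder():
            if node.parent is None:
                continue
            pt = build_placement_tree(backbone, {q: cand(node.edge_number, node.length / 2)})
            lenient = assess_placement(q, pt, tree, backbone.leaf_set(), "sister_mrca")
            strict = assess_placement(q, pt, tree, backbone.leaf_set(), "sister_plus_query_mrca")
            if strict.verdict == "correct":
                assert lenient.verdict == "correct"
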