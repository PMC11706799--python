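"""Placement engines: LWR behavior, distance algebra, batch contracts."""

import numpy as np
import pytest

from coiplace.alignment import GAP
from coiplace.placement import (
    DistanceEngine,
    UnplacedQueryError,
    apples_place,
    epa_place,
    jc_distance,
    place_batch,
)
from coiplace.substmodel import GTRModel, JC_MODEL
from coiplace.tree import (
    graft_query,
    number_edges,
    parse_newick,
    prune_taxa,
    sister_group,
)
from coiplace.simulate import simulate_taxon_tree

GTR = GTRModel(rates=(1.2, 3.0, 0.8, 0.9, 3.5, 1.0), freqs=(0.3, 0.2, 0.2, 0.3), alpha=0.7, k=4)


def _encode(s):
    return np.array(["ACGT-".index(c) for c in s], dtype=np.int8)


class TestEpaPlace:
    def _fixture(self, seed=0, n=6, S=200):
        tree, _ = simulate_taxon_tree(3, [2, 2, 2], seed=seed)
        number_edges(tree)
        from coiplace.simulate import PartitionSpec, evolve_alignment

        aln = evolve_alignment(tree, [PartitionSpec("COI", S, 1.0, GTR)], seed=seed + 1)
        return tree, aln

    def test_identical_query_prefers_twin_terminal_edge(self):
        tree, aln = self._fixture()
        twin = aln.species[0]
        q = aln.row(twin).copy()
        res = epa_place("Q", q, tree, aln, GTR)
        twin_edge = next(n.edge_number for n in tree.postorder() if n.label == twin)
        assert res.best.edge_number == twin_edge

    def test_lwr_normalization_and_sorting(self):
        tree, aln = self._fixture(seed=3)
        rng = np.random.default_rng(0)
        q = rng.integers(0, 4, size=aln.width).astype(np.int8)
        res = epa_place("Q", q, tree, aln, GTR)
        lwrs = [c.lwr for c in res.candidates]
        assert abs(sum(lwrs) - 1.0) < 1e-9
        scores = [c.score for c in res.candidates]
        assert scores == sorted(scores, reverse=True)
        assert len(res.candidates) == tree.n_branches

    def test_symmetric_backbone_equal_lwr(self):
        tree = number_edges(parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"))
        rows = {
            "A": _encode("AAAAAAAAAA"),
            "B": _encode("CCCCCCCCCC"),
            "C": _encode("AAAAAAAAAA"),
            "D": _encode("CCCCCCCCCC"),
        }
        from coiplace.likelihood import BackboneEngine

        eng = BackboneEngine(tree, rows, JC_MODEL)
        ll, t, d = eng.scan(_encode("GGGGGGGGGG"))
        by_label = {n.label: i for i, n in enumerate(eng.edge_child) if n.is_leaf}
        # A and C are mirror images, as are B and D
        assert ll[by_label["A"]] == pytest.approx(ll[by_label["C"]], abs=1e-6)
        assert ll[by_label["B"]] == pytest.approx(ll[by_label["D"]], abs=1e-6)

    def test_query_name_collision_rejected(self):
        tree, aln = self._fixture()
        with pytest.raises(ValueError):
            epa_place(aln.species[0], aln.row(aln.species[0]), tree, aln, GTR)

    def test_lwr_concentration_grows_with_coi_length(self):
        """More signal concentrates the best-edge LWR (nested site subsets)."""
        tree, aln = self._fixture(seed=5, S=400)
        twin = aln.species[2]
        full = aln.row(twin).copy()
        best_lwrs = []
        for width in (50, 200, 400):
            q = np.full(aln.width, GAP, dtype=np.int8)
            q[:width] = full[:width]
            res = epa_place("Q", q, tree, aln, GTR)
            best_lwrs.append(res.best.lwr)
        assert best_lwrs[0] <= best_lwrs[1] + 1e-9
        assert best_lwrs[1] <= best_lwrs[2] + 1e-9


class TestJcDistance:
    def test_closed_form_values(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.3) == pytest.approx(-0.75 * np.log(0.6))

    @pytest.mark.parametrize("p", [0.75, 0.8, -0.1])
    def test_domain_errors(self, p):
        with pytest.raises(UnplacedQueryError):
            jc_distance(p)


class TestApples:
    def test_two_leaf_hand_algebra(self):
        """delta_A=0.6, delta_B=0.8 on a path of length 1: x=0.4, t=0.2."""
        tree = number_edges(parse_newick("(A:1,B:0);"))
        deltas = {"A": 0.6, "B": 0.8}

        class Fixed(DistanceEngine):
            def distances(self, qrow):
                d = np.array([deltas[s] for s in self.leaves])
                return d, np.ones(self.n, bool)

        eng = Fixed(tree, {s: np.zeros(1, dtype=np.int8) for s in "AB"})
        res = eng.place("Q", np.zeros(1, dtype=np.int8), weighting="ols")
        assert res.best.distal_length == pytest.approx(0.4)
        assert res.best.pendant_length == pytest.approx(0.2)
        assert res.best.score == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_additive_distances_recover_true_edge(self, seed):
        tree, _ = simulate_taxon_tree(6, [5, 5, 5, 5, 5, 5], seed=seed)
        number_edges(tree)
        q = tree.leaf_labels()[7]
        backbone = number_edges(prune_taxa(tree, {q}))
        D = tree.leaf_distances()
        deltas = {s: D[frozenset((q, s))] for s in backbone.leaf_labels()}

        class Oracle(DistanceEngine):
            def distances(self, qrow):
                return np.array([deltas[s] for s in self.leaves]), np.ones(self.n, bool)

        eng = Oracle(backbone, {s: np.zeros(1, dtype=np.int8) for s in backbone.leaf_labels()})
        res = eng.place("Q", np.zeros(1, dtype=np.int8))
        assert res.best.score <= 1e-9
        grafted = graft_query(
            backbone, q, res.best.edge_number, res.best.distal_length, res.best.pendant_length
        )
        Dg = grafted.leaf_distances()
        assert max(abs(Dg[k] - D[k]) for k in D) < 1e-9

    def test_ols_equals_fm_for_equal_distances(self):
        tree = number_edges(parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"))
        deltas = {s: 0.5 for s in "ABCD"}

        class Fixed(DistanceEngine):
            def distances(self, qrow):
                return np.array([deltas[s] for s in self.leaves]), np.ones(self.n, bool)

        eng = Fixed(tree, {s: np.zeros(1, dtype=np.int8) for s in "ABCD"})
        a = eng.place("Q", np.zeros(1, dtype=np.int8), weighting="ols")
        b = eng.place("Q", np.zeros(1, dtype=np.int8), weighting="fm")
        assert a.best.edge_number == b.best.edge_number
        assert a.best.pendant_length == pytest.approx(b.best.pendant_length)

    def test_saturated_query_unplaced(self):
        tree = number_edges(parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"))
        rows = {s: _encode("AAAAAAAA") for s in "ABCD"}
        eng = DistanceEngine(tree, rows)
        with pytest.warns(UserWarning):
            with pytest.raises(UnplacedQueryError):
                eng.place("Q", _encode("GGGGGGGG"))


@pytest.fixture(scope="module")
def system(small_bundle):
    b = small_bundle
    species = sorted(b.alignment.species)
    missing = species[::7][:6]
    backbone = number_edges(prune_taxa(b.tree, missing))
    queries = {q: b.alignment.row(q) for q in missing}
    return b, backbone, queries


class TestPlaceBatch:
    def test_bookkeeping_and_order_independence(self, system):
        b, backbone, queries = system
        model, mult = b.models["COI"]
        doc, results, skipped = place_batch(
            queries, backbone, b.alignment, model=model, multiplier=mult
        )
        assert len(doc["placements"]) == len(queries)
        reversed_queries = dict(reversed(list(queries.items())))
        _, results2, _ = place_batch(
            reversed_queries, backbone, b.alignment, model=model, multiplier=mult
        )
        for q in results:
            assert results[q].best.edge_number == results2[q].best.edge_number
            assert results[q].best.score == results2[q].best.score

    def test_distance_engine_has_no_lwr(self, system):
        b, backbone, queries = system
        doc, results, _ = place_batch(queries, backbone, b.alignment, engine="distance")
        assert doc["fields"][1] == "least_squares"
        for r in results.values():
            assert all(c.lwr is None for c in r.candidates)

    def test_empty_query_set_rejected(self, system):
        b, backbone, _ = system
        with pytest.raises(ValueError):
            place_batch({}, backbone, b.alignment, engine="distance")
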