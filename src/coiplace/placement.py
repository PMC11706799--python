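"""Placement engines: a likelihood-based placer with likelihood weight
ratios (EPA-style) and a distance-based least-squares placer (APPLES-style).

Both engines evaluate every backbone edge exhaustively — no candidate-edge
preselection heuristics — and break ties deterministically by lowest edge
number.  The likelihood engine restricts computation to the columns where
the query has data (all other columns contribute edge-independent factors
that cancel in the likelihood weight ratio).  The distance engine works from
Jukes–Cantor-corrected pairwise distances on the COI partition and solves a
weighted least-squares problem per edge in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignment import GAP, MultiGeneAlignment
from .jplace import PlacementCandidate, write_jplace
from .likelihood import BackboneEngine
from .substmodel import GTRModel
from .tree import PhyloTree, Node, number_edges

__all__ = [
    "PlacementResult",
    "UnplacedQueryError",
    "jc_distance",
    "epa_place",
    "apples_place",
    "place_batch",
    "DistanceEngine",
]


class UnplacedQueryError(ValueError):
    """Raised when a query cannot be placed (e.g. saturated distances)."""


@dataclass
class PlacementResult:
    query: str
    engine: str  # "likelihood" | "distance"
    candidates: List[PlacementCandidate]  # sorted best-first

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("placement result with no candidates")

    @property
    def best(self) -> PlacementCandidate:
        return self.candidates[0]


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------


def _lwr_from_loglik(ll: np.ndarray) -> np.ndarray:
    w = np.exp(ll - ll.max())
    return w / w.sum()


def _result_from_scan(
    query: str,
    engine: BackboneEngine,
    ll: np.ndarray,
    pendants: np.ndarray,
    distals: np.ndarray,
) -> PlacementResult:
    lwr = _lwr_from_loglik(ll)
    order = sorted(range(engine.E), key=lambda i: (-ll[i], engine.edge_numbers[i]))
    cands = [
        PlacementCandidate(
            edge_number=engine.edge_numbers[i],
            score=float(ll[i]),
            distal_length=float(distals[i]),
            pendant_length=float(pendants[i]),
            lwr=float(lwr[i]),
        )
        for i in order
    ]
    return PlacementResult(query, "likelihood", cands)


def epa_place(
    query_name: str,
    query_row: np.ndarray,
    backbone: PhyloTree,
    ref_aln: MultiGeneAlignment,
    model: GTRModel,
    multiplier: float = 1.0,
    optimize: bool = False,
    pendant_tol: float = 1e-6,
) -> PlacementResult:
    """Place one full-width query row on the backbone by maximum likelihood.

    Every backbone edge is scored by grafting the query at the edge midpoint
    (or at the optimized distal position when ``optimize``) with the pendant
    length fitted by bounded golden-section search; per-edge log-likelihoods
    are normalized into likelihood weight ratios.
    """
    query_row = np.asarray(query_row, dtype=np.int8)
    if len(query_row) != ref_aln.width:
        raise ValueError("query row width differs from the reference alignment")
    if query_name in backbone.leaf_set():
        raise ValueError(f"query {query_name!r} collides with a backbone leaf")
    columns = np.flatnonzero(query_row != GAP)
    if columns.size == 0:
        raise UnplacedQueryError(f"query {query_name!r} has no data")
    rows = {s: ref_aln.row(s) for s in backbone.leaf_labels()}
    engine = BackboneEngine(backbone, rows, model, multiplier, columns=columns)
    ll, t, d = engine.scan(query_row[columns], pendant_tol, optimize_distal=optimize)
    return _result_from_scan(query_name, engine, ll, t, d)


# ---------------------------------------------------------------------------
# Distance engine
# ---------------------------------------------------------------------------


def jc_distance(p: float) -> float:
    """Jukes–Cantor corrected distance from a mismatch proportion."""
    if not (0.0 <= p < 0.75):
        raise UnplacedQueryError(f"mismatch proportion {p} outside [0, 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


class DistanceEngine:
    """Per-edge least-squares placement from sequence distances.

    For edge e with length b, attaching at distal x from the child end with
    pendant t, the tree distance to leaf i is t + a_i ± x with the sign
    depending on which side of the edge holds the leaf.  The engine
    precomputes a_i and the signs for every edge so each query is a handful
    of matrix-vector products plus a closed-form constrained 2x2 solve.
    """

    def __init__(self, backbone: PhyloTree, ref_rows: Mapping[str, np.ndarray]):
        if any(n.edge_number is None for n in backbone.postorder() if n.parent is not None):
            number_edges(backbone)
        self.tree = backbone
        self.leaves = backbone.leaf_labels()
        self.n = len(self.leaves)
        leaf_index = {s: i for i, s in enumerate(self.leaves)}
        self.ref = np.stack([np.asarray(ref_rows[s], dtype=np.int8) for s in self.leaves])

        depths = backbone.depths()
        # distance from every node to every leaf
        below: Dict[Node, np.ndarray] = {}
        for node in backbone.postorder():
            mask = np.zeros(self.n, dtype=bool)
            if node.is_leaf:
                mask[leaf_index[node.label]] = True
            else:
                for c in node.children:
                    mask |= below[c]
            below[node] = mask
        leaf_depths = np.array([depths[backbone.find_leaf(s)] for s in self.leaves])
        dist: Dict[Node, np.ndarray] = {}
        for node in backbone.preorder():
            d = np.empty(self.n)
            if node.parent is None:
                d[:] = leaf_depths
            else:
                d[:] = dist[node.parent] + node.length
            d[below[node]] = leaf_depths[below[node]] - depths[node]
            dist[node] = d

        emap = backbone.edge_map()
        self.edge_numbers = sorted(emap)
        self.E = len(self.edge_numbers)
        self.b = np.array([emap[e].length for e in self.edge_numbers])
        self.A = np.empty((self.E, self.n))
        self.Sgn = np.empty((self.E, self.n))
        for idx, e in enumerate(self.edge_numbers):
            child = emap[e]
            mask = below[child]
            self.A[idx, mask] = dist[child][mask]
            self.Sgn[idx, mask] = 1.0
            self.A[idx, ~mask] = child.length + dist[child.parent][~mask]
            self.Sgn[idx, ~mask] = -1.0

    def distances(self, qrow: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """JC distances from the query to every backbone leaf; (delta, usable)."""
        qrow = np.asarray(qrow, dtype=np.int8)
        shared = (self.ref != GAP) & (qrow != GAP)[None, :]
        n_shared = shared.sum(axis=1)
        mism = ((self.ref != qrow[None, :]) & shared).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_shared > 0, mism / np.maximum(n_shared, 1), np.nan)
        usable = (n_shared > 0) & (p < 0.75)
        delta = np.full(self.n, np.nan)
        delta[usable] = -0.75 * np.log1p(-4.0 * p[usable] / 3.0)
        return delta, usable

    def place(self, query: str, qrow: np.ndarray, weighting: str = "fm") -> PlacementResult:
        delta, usable = self.distances(qrow)
        n_bad = int((~usable).sum())
        if n_bad:
            warnings.warn(
                f"{query}: {n_bad} backbone leaves with undefined distances skipped"
            )
        if usable.sum() < min(4, self.n):
            raise UnplacedQueryError(
                f"query {query!r}: distances computable to fewer than 4 leaves"
            )
        if weighting == "fm":
            w = 1.0 / np.maximum(delta, 1e-6) ** 2
        elif weighting == "ols":
            w = np.ones(self.n)
        else:
            raise ValueError("weighting must be 'fm' or 'ols'")
        w = np.where(usable, w, 0.0)

        A, Sgn, b = self.A, self.Sgn, self.b
        Sw = w.sum()
        Sws = Sgn @ w                       # (E,)
        d = np.where(usable, delta, 0.0)
        # residual r_i(x=0,t=0) = a_i - delta_i
        Swr = A @ w - (w * d).sum()
        Swsr = (Sgn * A) @ w - Sws_delta(Sgn, w, d)
        Swr2 = (A * A) @ w - 2.0 * (A @ (w * d)) + (w * d * d).sum()

        def Q(x, t):
            return (
                t * t * Sw + x * x * Sw + Swr2
                + 2.0 * t * x * Sws + 2.0 * t * Swr + 2.0 * x * Swsr
            )

        det = Sw * Sw - Sws * Sws
        with np.errstate(divide="ignore", invalid="ignore"):
            # stationary point of Q: gradient zero
            x_star = (Sws * Swr - Sw * Swsr) / det
            t_star = (Sws * Swsr - Sw * Swr) / det
        cand_x = [x_star, np.zeros(self.E), b, np.clip(-Swsr / Sw, 0.0, b)]
        cand_t = [t_star,
                  np.maximum(-(Swr) / Sw, 0.0),
                  np.maximum(-(Swr + Sws * b) / Sw, 0.0),
                  np.zeros(self.E)]
        # the unconstrained optimum only counts when feasible
        feasible = (x_star >= 0) & (x_star <= b) & (t_star >= 0) & np.isfinite(x_star)
        best_q = np.full(self.E, np.inf)
        best_x = np.zeros(self.E)
        best_t = np.zeros(self.E)
        for i, (cx, ct) in enumerate(zip(cand_x, cand_t)):
            q = Q(cx, ct)
            ok = feasible if i == 0 else np.ones(self.E, dtype=bool)
            take = ok & (q < best_q)
            best_q = np.where(take, q, best_q)
            best_x = np.where(take, cx, best_x)
            best_t = np.where(take, ct, best_t)

        order = sorted(range(self.E), key=lambda i: (best_q[i], self.edge_numbers[i]))
        cands = [
            PlacementCandidate(
                edge_number=self.edge_numbers[i],
                score=float(max(best_q[i], 0.0)),
                distal_length=float(best_x[i]),
                pendant_length=float(best_t[i]),
                lwr=None,
            )
            for i in order
        ]
        return PlacementResult(query, "distance", cands)


def Sws_delta(Sgn: np.ndarray, w: np.ndarray, d: np.ndarray) -> np.ndarray:
    return Sgn @ (w * d)


def apples_place(
    query_name: str,
    query_row: np.ndarray,
    backbone: PhyloTree,
    ref_coi_aln: Mapping[str, np.ndarray] | MultiGeneAlignment,
    weighting: str = "fm",
) -> PlacementResult:
    """Distance-based least-squares placement of one COI query row."""
    if query_name in backbone.leaf_set():
        raise ValueError(f"query {query_name!r} collides with a backbone leaf")
    if isinstance(ref_coi_aln, MultiGeneAlignment):
        rows = {s: ref_coi_aln.row(s) for s in backbone.leaf_labels()}
    else:
        rows = ref_coi_aln
    engine = DistanceEngine(backbone, rows)
    return engine.place(query_name, np.asarray(query_row, dtype=np.int8))


# ---------------------------------------------------------------------------
# Batch placement
# ---------------------------------------------------------------------------


def place_batch(
    queries: Mapping[str, np.ndarray],
    backbone: PhyloTree,
    ref_aln: MultiGeneAlignment,
    engine: str = "likelihood",
    model: Optional[GTRModel] = None,
    multiplier: float = 1.0,
    weighting: str = "fm",
    optimize: bool = False,
    coi_only: bool = True,
) -> Tuple[dict, Dict[str, PlacementResult], List[str]]:
    """Place every query independently; returns (jplace doc, results, skipped).

    The likelihood engine computes over the COI partition columns (queries
    are COI sequences; columns missing in a query contribute identical
    factors on every edge).  The distance engine uses COI rows as reference.
    """
    if not queries:
        raise ValueError("empty query set")
    overlap = set(queries) & backbone.leaf_set()
    if overlap:
        raise ValueError(f"queries already on the backbone: {sorted(overlap)[:5]}")
    if any(n.edge_number is None for n in backbone.postorder() if n.parent is not None):
        number_edges(backbone)
    coi = ref_aln.partition(ref_aln.coi_partition)
    columns = np.arange(coi.start - 1, coi.end) if coi_only else np.arange(ref_aln.width)
    results: Dict[str, PlacementResult] = {}
    skipped: List[str] = []
    if engine == "likelihood":
        if model is None:
            raise ValueError("likelihood engine requires a substitution model")
        rows = {s: ref_aln.row(s) for s in backbone.leaf_labels()}
        eng = BackboneEngine(backbone, rows, model, multiplier, columns=columns)
        for name in sorted(queries):
            q = np.asarray(queries[name], dtype=np.int8)[columns]
            if (q == GAP).all():
                skipped.append(name)
                continue
            ll, t, d = eng.scan(q, optimize_distal=optimize)
            results[name] = _result_from_scan(name, eng, ll, t, d)
    elif engine == "distance":
        rows = {s: ref_aln.row(s)[columns] for s in backbone.leaf_labels()}
        eng = DistanceEngine(backbone, rows)
        for name in sorted(queries):
            q = np.asarray(queries[name], dtype=np.int8)[columns]
            try:
                results[name] = eng.place(name, q, weighting)
            except UnplacedQueryError:
                skipped.append(name)
    else:
        raise ValueError("engine must be 'likelihood' or 'distance'")
    doc = write_jplace(
        backbone,
        {n: r.candidates for n, r in results.items()},
        engine=engine,
    )
    return doc, results, skipped
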