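"""Placement-accuracy scoring via sister-clade comparison.

A placed species is judged by comparing its sister group on the placement
tree against the reference tree: take the sister group S of the query on
the placement tree, find the smallest reference clade C containing S (the
MRCA clade — see note below), and form the difference list D = C \\ S minus
the query itself.  The placement is correct exactly when no member of D was
on the backbone — i.e. every disagreement involves only species that were
themselves missing.

Aggregates: PCP (percent of placed queries correct), CP (percent with
likelihood weight ratio strictly above a threshold, default 0.9), and
PCP-CP (PCP restricted to the confident subset).

Note on the clade rule: the verbal rule "the most inclusive clade that
includes all members of the sister group" cannot mean literally the most
inclusive (that is always the root); it is implemented as the least
inclusive such clade, i.e. the MRCA.  Because a sister group that happens to
be an exact reference clade then always yields an empty difference list, a
stricter alternative mode includes the query in the MRCA computation
(``sister_plus_query_mrca``); the default ``sister_mrca`` follows the
verbal rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .jplace import PlacementCandidate
from .tree import Node, PhyloTree, graft_query, leaf_labels_below, mrca, sister_group

__all__ = [
    "AccuracyRecord",
    "AccuracySummary",
    "build_placement_tree",
    "assess_placement",
    "summarize",
]

MODES = ("sister_mrca", "sister_plus_query_mrca")


@dataclass(frozen=True)
class AccuracyRecord:
    query: str
    verdict: str  # "correct" | "incorrect" | "unplaced"
    lwr: Optional[float]
    sister: Set[str]
    difference: Set[str]

    @property
    def placed(self) -> bool:
        return self.verdict != "unplaced"


@dataclass(frozen=True)
class AccuracySummary:
    pcp: float                      # % of placed queries correct
    cp: Optional[float]             # % of placed queries with LWR > threshold
    pcp_cp: Optional[float]         # % correct among the confident subset
    n_placed: int
    n_correct: int
    n_confident: Optional[int]
    n_confident_correct: Optional[int]
    lwr_threshold: float


def build_placement_tree(
    backbone: PhyloTree,
    placements: Mapping[str, PlacementCandidate],
) -> PhyloTree:
    """Graft every query's best candidate onto the backbone.

    Queries sharing a backbone edge are grafted in descending distal order
    (ties broken lexicographically by query name), so each later graft lands
    on the child-side segment left by the previous one and all recorded
    distal positions stay valid.
    """
    names = list(placements)
    if len(set(names)) != len(names):
        raise ValueError("duplicate query names")
    by_edge: Dict[int, List[Tuple[str, PlacementCandidate]]] = {}
    for name, cand in placements.items():
        by_edge.setdefault(cand.edge_number, []).append((name, cand))
    tree = backbone.copy()
    # remember host child nodes before any grafting invalidates edge numbers
    emap = tree.edge_map()
    hosts = {e: emap[e] for e in by_edge}
    for e, group in sorted(by_edge.items()):
        group.sort(key=lambda item: (-item[1].distal_length, item[0]))
        child = hosts[e]
        for name, cand in group:
            if name in tree.leaf_set():
                raise ValueError(f"duplicate query name {name!r}")
            b = child.length
            distal = min(cand.distal_length, b)  # guard fp round-off at the seam
            parent = child.parent
            attach = Node(None, b - distal)
            idx = parent.children.index(child)
            parent.children[idx] = attach
            attach.parent = parent
            child.length = distal
            attach.add_child(child)
            attach.add_child(Node(name, cand.pendant_length))
    return PhyloTree(tree.root)


def assess_placement(
    query: str,
    placement_tree: PhyloTree,
    reference_tree: PhyloTree,
    backbone_taxa: Set[str],
    mode: str = "sister_mrca",
    lwr: Optional[float] = None,
) -> AccuracyRecord:
    """Score one placed query by the sister-clade comparison rule."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    ref_leaves = reference_tree.leaf_set()
    if query not in placement_tree.leaf_set():
        raise ValueError(f"query {query!r} absent from the placement tree")
    if query not in ref_leaves:
        raise ValueError(f"query {query!r} absent from the reference tree")
    S = sister_group(placement_tree, query)
    seed = S if mode == "sister_mrca" else S | {query}
    # members of the sister group are reference species by construction
    C = leaf_labels_below(mrca(reference_tree, seed & ref_leaves))
    difference = (C - S) - {query}
    correct = not (difference & backbone_taxa)
    return AccuracyRecord(
        query=query,
        verdict="correct" if correct else "incorrect",
        lwr=lwr,
        sister=S,
        difference=difference,
    )


def summarize(
    records: Sequence[AccuracyRecord],
    lwr_threshold: float = 0.9,
) -> AccuracySummary:
    """Aggregate per-query verdicts into PCP / CP / PCP-CP percentages.

    CP and PCP-CP are None when the engine emitted no confidence values;
    PCP-CP is None (undefined, not zero) when no placement is confident.
    """
    placed = [r for r in records if r.placed]
    if not placed:
        raise ValueError("no placed queries to summarize")
    n_correct = sum(r.verdict == "correct" for r in placed)
    pcp = 100.0 * n_correct / len(placed)
    has_lwr = any(r.lwr is not None for r in placed)
    if not has_lwr:
        return AccuracySummary(pcp, None, None, len(placed), n_correct, None, None, lwr_threshold)
    confident = [r for r in placed if r.lwr is not None and r.lwr > lwr_threshold]
    cp = 100.0 * len(confident) / len(placed)
    if confident:
        ncc = sum(r.verdict == "correct" for r in confident)
        pcp_cp = 100.0 * ncc / len(confident)
    else:
        ncc = 0
        pcp_cp = None
    return AccuracySummary(
        pcp, cp, pcp_cp, len(placed), n_correct, len(confident), ncc, lwr_threshold
    )


def records_to_tsv(records: Sequence[AccuracyRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tverdict\tlwr\tsister_group\tdifference\n")
        for r in records:
            lwr = "" if r.lwr is None else f"{r.lwr:.6f}"
            fh.write(
                f"{r.query}\t{r.verdict}\t{lwr}\t"
                f"{','.join(sorted(r.sister))}\t{','.join(sorted(r.difference))}\n"
            )
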