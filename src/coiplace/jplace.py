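"""jplace v3 documents: the standard JSON exchange format for phylogenetic
placements, with edge numbers embedded as ``{N}`` in the tree string."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .tree import PhyloTree, parse_newick, write_newick

__all__ = ["PlacementCandidate", "read_jplace", "write_jplace"]

LIKELIHOOD_FIELDS = ["edge_num", "likelihood", "like_weight_ratio", "distal_length", "pendant_length"]
DISTANCE_FIELDS = ["edge_num", "least_squares", "distal_length", "pendant_length"]


@dataclass(frozen=True)
class PlacementCandidate:
    """One candidate attachment of a query to a backbone edge.

    ``score`` is a log-likelihood for the likelihood engine or a weighted
    least-squares error for the distance engine; ``lwr`` is the likelihood
    weight ratio (None for the distance engine, which has no confidence
    measure).
    """

    edge_number: int
    score: float
    distal_length: float
    pendant_length: float
    lwr: Optional[float] = None

    def __post_init__(self):
        if self.lwr is not None and not (0.0 <= self.lwr <= 1.0 + 1e-12):
            raise ValueError("likelihood weight ratio outside [0, 1]")
        if self.distal_length < 0 or self.pendant_length < 0:
            raise ValueError("negative placement branch length")


class JplaceError(ValueError):
    pass


def write_jplace(
    tree: PhyloTree,
    placements: Mapping[str, Sequence[PlacementCandidate]],
    engine: str = "likelihood",
    invocation: str = "coiplace",
) -> dict:
    """Build a jplace v3 document (a JSON-serializable dict)."""
    edge_numbers = set(tree.edge_map())
    fields = LIKELIHOOD_FIELDS if engine == "likelihood" else DISTANCE_FIELDS
    plist = []
    for name in placements:
        rows = []
        for cand in placements[name]:
            if cand.edge_number not in edge_numbers:
                raise JplaceError(f"candidate references unknown edge {cand.edge_number}")
            if engine == "likelihood":
                if cand.lwr is None:
                    raise JplaceError(f"likelihood placement for {name} lacks an LWR")
                rows.append([cand.edge_number, cand.score, cand.lwr,
                             cand.distal_length, cand.pendant_length])
            else:
                rows.append([cand.edge_number, cand.score,
                             cand.distal_length, cand.pendant_length])
        plist.append({"p": rows, "n": [name]})
    return {
        "version": 3,
        "tree": write_newick(tree, with_edge_numbers=True),
        "placements": plist,
        "fields": fields,
        "metadata": {"invocation": invocation},
    }


def read_jplace(source: Union[str, Path, dict]) -> Tuple[PhyloTree, Dict[str, List[PlacementCandidate]]]:
    """Parse a jplace v3 document from a path, JSON string, or dict."""
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
    for key in ("tree", "placements", "fields", "version"):
        if key not in doc:
            raise JplaceError(f"jplace document missing mandatory key {key!r}")
    fields = doc["fields"]
    if "edge_num" not in fields:
        raise JplaceError("jplace fields must include edge_num")
    tree = parse_newick(doc["tree"])
    edge_numbers = set()
    for node in tree.postorder():
        if node.parent is not None:
            if node.edge_number is None:
                raise JplaceError("jplace tree lacks {N} edge numbers")
            edge_numbers.add(node.edge_number)
    idx = {f: i for i, f in enumerate(fields)}
    score_field = "likelihood" if "likelihood" in idx else "least_squares"
    if score_field not in idx:
        raise JplaceError("jplace fields lack likelihood/least_squares")
    out: Dict[str, List[PlacementCandidate]] = {}
    for entry in doc["placements"]:
        names = entry.get("n") or entry.get("nm")
        if not names:
            raise JplaceError("placement entry without a query name")
        name = names[0] if not isinstance(names[0], list) else names[0][0]
        cands = []
        for row in entry["p"]:
            e = int(row[idx["edge_num"]])
            if e not in edge_numbers:
                raise JplaceError(f"edge number {e} not present in the jplace tree")
            cands.append(
                PlacementCandidate(
                    edge_number=e,
                    score=float(row[idx[score_field]]),
                    distal_length=float(row[idx["distal_length"]]),
                    pendant_length=float(row[idx["pendant_length"]]),
                    lwr=float(row[idx["like_weight_ratio"]]) if "like_weight_ratio" in idx else None,
                )
            )
        out[name] = cands
    return tree, out
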