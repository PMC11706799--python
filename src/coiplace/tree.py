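"""Rooted phylogenetic trees with jplace-style edge numbering.

The tree model used throughout the package: a rooted tree whose non-root
nodes each carry a branch length (expected substitutions per site) and,
optionally, a dense jplace edge number.  Operations cover Newick I/O,
pruning with unifurcation suppression, MRCA and sister-group queries, and
grafting of query leaves onto numbered edges — the substrate for backbone
construction, placement, and accuracy scoring.
"""

from __future__ import annotations

import io
import re
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set

import dendropy

__all__ = [
    "TreeError",
    "NewickError",
    "Node",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "number_edges",
    "prune_taxa",
    "mrca",
    "sister_group",
    "graft_query",
]

_LABEL_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")


class TreeError(ValueError):
    """Structural error in a tree operation."""


class NewickError(TreeError):
    """Malformed Newick input."""


class Node:
    """A tree node; ``length`` is the branch to its parent (None at the root)."""

    __slots__ = ("label", "length", "children", "parent", "edge_number")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None
        self.edge_number: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """Rooted tree with unique leaf labels and non-negative branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- iteration ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def leaf_set(self) -> Set[str]:
        return set(self.leaf_labels())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_branches(self) -> int:
        return sum(1 for n in self.postorder() if n.parent is not None)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        seen: Set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                if not _LABEL_RE.match(node.label):
                    raise TreeError(f"illegal characters in leaf label {node.label!r}")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            if node.parent is not None:
                if node.length is None:
                    raise TreeError(f"missing branch length above {node.label or 'internal node'}")
                if node.length < 0:
                    raise TreeError(f"negative branch length {node.length} above {node.label!r}")

    # -- copying -----------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            dup = Node(node.label, node.length)
            dup.edge_number = node.edge_number
            for child in node.children:
                dup.add_child(_copy(child))
            return dup

        return PhyloTree(_copy(self.root))

    # -- lookups -----------------------------------------------------------

    def find_leaf(self, label: str) -> Node:
        for node in self.postorder():
            if node.is_leaf and node.label == label:
                return node
        raise TreeError(f"leaf {label!r} not in tree")

    def edge_map(self) -> Dict[int, Node]:
        """Map edge number -> child node of that edge."""
        out: Dict[int, Node] = {}
        for node in self.postorder():
            if node.parent is not None:
                if node.edge_number is None:
                    raise TreeError("tree edges are not numbered")
                out[node.edge_number] = node
        return out

    # -- metrics -----------------------------------------------------------

    def depths(self) -> Dict[Node, float]:
        """Distance from the root to every node."""
        out: Dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[node] = out[node.parent] + node.length
        return out

    def height(self) -> float:
        d = self.depths()
        return max(d[leaf] for leaf in self.leaves())

    def leaf_distances(self) -> Dict[frozenset, float]:
        """Path lengths between all leaf pairs (small trees; testing aid)."""
        depths = self.depths()
        # leaf sets bottom-up
        below: Dict[Node, List[Node]] = {}
        out: Dict[frozenset, float] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = [node]
                continue
            kids = [below[c] for c in node.children]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for a in kids[i]:
                        for b in kids[j]:
                            out[frozenset((a.label, b.label))] = (
                                depths[a] + depths[b] - 2.0 * depths[node]
                            )
            below[node] = [x for k in kids for x in k]
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_EDGE_TOKEN_RE = re.compile(r"\{(\d+)\}")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (jplace ``{N}`` edge annotations allowed).

    Branch lengths must be either present on every non-root branch or absent
    everywhere (absent means every length defaults to 0).  Duplicate leaf
    labels, negative lengths and unbalanced parentheses are rejected.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    if text.count("(") != text.count(")"):
        raise NewickError("unbalanced parentheses in Newick string")

    # capture jplace edge numbers, then strip them for the parser
    edge_annotated = bool(_EDGE_TOKEN_RE.search(text))
    plain = _EDGE_TOKEN_RE.sub("", text)

    try:
        dtree = dendropy.Tree.get(
            data=plain,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"could not parse Newick: {exc}") from exc

    lengths = [e.length for nd in dtree for e in [nd.edge] if nd.parent_node is not None]
    has = [l is not None for l in lengths]
    if any(has) and not all(has):
        raise NewickError("mixed presence/absence of branch lengths")

    def _convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length if dnode.parent_node is not None else None
        if length is None and dnode.parent_node is not None:
            length = 0.0
        node = Node(label if dnode.is_leaf() else None, length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    tree = PhyloTree(_convert(dtree.seed_node))

    if edge_annotated:
        _assign_edge_numbers_from_text(tree, text)
    return tree


def _assign_edge_numbers_from_text(tree: PhyloTree, text: str) -> None:
    """Attach ``{N}`` tokens from a jplace-annotated Newick string.

    The textual order of ':' branch tokens equals the order in which branches
    are completed reading left to right — a postorder over non-root nodes with
    children in stored order (dendropy preserves child order), so tokens and
    nodes can be zipped.  Leaf labels in the tokens double as alignment checks.
    """
    tokens = re.findall(r"([A-Za-z0-9_.\-]+)?:[0-9eE+\-.]+(\{(\d+)\})?", text)
    nonroot = _postorder_textual(tree)
    if len(tokens) != len(nonroot):
        raise NewickError("could not align edge-number tokens with branches")
    nums = set()
    for node, (label, _, num) in zip(nonroot, tokens):
        if label and node.is_leaf and node.label != label:
            raise NewickError("edge-number token alignment failed")
        if num:
            n = int(num)
            if n in nums:
                raise NewickError(f"duplicate edge number {n}")
            nums.add(n)
            node.edge_number = n


def _postorder_textual(tree: PhyloTree) -> List[Node]:
    """Non-root nodes in the order their branch tokens appear in Newick text."""
    out: List[Node] = []

    def _walk(node: Node) -> None:
        for child in node.children:
            _walk(child)
            out.append(child)

    _walk(tree.root)
    return out


def _format_length(x: float) -> str:
    s = repr(float(x))
    if s.endswith(".0"):
        s = s[:-2]
    return s


def write_newick(tree: PhyloTree, with_edge_numbers: bool = False) -> str:
    """Serialize to Newick; with ``with_edge_numbers`` append jplace ``{N}``."""

    def _fmt(node: Node) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(_fmt(c) for c in node.children) + ")"
        if node.parent is None:
            return core
        out = f"{core}:{_format_length(node.length)}"
        if with_edge_numbers:
            if node.edge_number is None:
                raise TreeError("cannot write edge numbers: tree is unnumbered")
            out += "{%d}" % node.edge_number
        return out

    return _fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Structure operations
# ---------------------------------------------------------------------------


def number_edges(tree: PhyloTree) -> PhyloTree:
    """Assign dense edge numbers 0..#branches-1 in depth-first postorder.

    Deterministic for a given topology and child order; renumbering an
    already numbered tree reproduces the same numbers.
    """
    i = 0
    for node in tree.postorder():
        if node.parent is not None:
            node.edge_number = i
            i += 1
    return tree


def prune_taxa(tree: PhyloTree, drop: Iterable[str]) -> PhyloTree:
    """Remove leaves in ``drop``; suppress unifurcations by summing lengths.

    Path lengths between all retained leaf pairs are unchanged.  Edge numbers
    are invalidated (the pruned tree must be renumbered before jplace use).
    """
    drop = set(drop)
    if not drop:
        return tree.copy()
    leaf_set = tree.leaf_set()
    unknown = drop - leaf_set
    if unknown:
        raise TreeError(f"cannot prune unknown taxa: {sorted(unknown)[:5]}")
    if len(leaf_set - drop) < 2:
        raise TreeError("pruning would leave fewer than 2 leaves")

    out = tree.copy()

    def _prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return None if node.label in drop else node
        kept = []
        for child in node.children:
            res = _prune(child)
            if res is not None:
                kept.append(res)
        if not kept:
            return None
        if len(kept) == 1:
            # suppress unifurcation: child absorbs this node's branch
            child = kept[0]
            if node.parent is not None:
                child.length = child.length + node.length
            else:
                child.length = None  # becomes new root
            child.parent = node.parent
            return child
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    new_root = _prune(out.root)
    assert new_root is not None
    new_root.parent = None
    if new_root.length is not None:
        new_root.length = None
    pruned = PhyloTree(new_root)
    for n in pruned.postorder():
        n.edge_number = None
    return pruned


def mrca(tree: PhyloTree, taxa: Iterable[str]) -> Node:
    """Least inclusive node whose leaf set contains ``taxa``."""
    taxa = set(taxa)
    if not taxa:
        raise TreeError("mrca of an empty taxon set")
    unknown = taxa - tree.leaf_set()
    if unknown:
        raise TreeError(f"unknown taxa in mrca query: {sorted(unknown)[:5]}")
    counts: Dict[Node, int] = {}
    target = len(taxa)
    for node in tree.postorder():
        if node.is_leaf:
            counts[node] = 1 if node.label in taxa else 0
        else:
            counts[node] = sum(counts[c] for c in node.children)
        if counts[node] == target:
            return node
    raise TreeError("unreachable: root must contain all taxa")  # pragma: no cover


def leaf_labels_below(node: Node) -> Set[str]:
    out: Set[str] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.add(n.label)
        else:
            stack.extend(n.children)
    return out


def sister_group(tree: PhyloTree, leaf: str) -> Set[str]:
    """Leaf set of the sibling subtree of ``leaf``."""
    node = tree.find_leaf(leaf)
    parent = node.parent
    if parent is None:
        raise TreeError(f"{leaf!r} is the root; no sister group")
    siblings = [c for c in parent.children if c is not node]
    if len(siblings) != 1:
        raise TreeError(f"tree is not binary at the parent of {leaf!r}")
    return leaf_labels_below(siblings[0])


def graft_query(
    tree: PhyloTree,
    query: str,
    edge_number: int,
    distal: float,
    pendant: float,
) -> PhyloTree:
    """Attach ``query`` on the numbered edge, ``distal`` from its child end.

    The host branch is split at the attachment point; a new internal node
    gains the query as a pendant leaf.  Pre-existing leaf-to-leaf path
    lengths are unchanged.
    """
    if pendant < 0:
        raise TreeError("pendant length must be >= 0")
    if query in tree.leaf_set():
        raise TreeError(f"query label {query!r} already present in tree")
    out = tree.copy()
    emap = out.edge_map()
    if edge_number not in emap:
        raise TreeError(f"unknown edge number {edge_number}")
    child = emap[edge_number]
    b = child.length
    if not (0.0 <= distal <= b):
        raise TreeError(f"distal {distal} outside [0, {b}] for edge {edge_number}")
    parent = child.parent
    attach = Node(None, b - distal)
    attach.edge_number = None
    idx = parent.children.index(child)
    parent.children[idx] = attach
    attach.parent = parent
    child.length = distal
    attach.add_child(child)
    qleaf = Node(query, pendant)
    attach.add_child(qleaf)
    return PhyloTree(out.root)
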