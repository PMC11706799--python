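"""Synthetic truth generation: family-structured trees, GTR+Γ multigene
alignments with a COI barcode partition, missing-gene masks, and planted
quality-control violations.

The generator emulates the statistical shape of a multigene fish barcoding
dataset: a birth–death backbone over families, each family expanded into its
own birth–death subtree (families are monophyletic by construction), a
concatenated alignment with a fast-evolving ~660 bp COI partition plus
slower nuclear/mitochondrial genes, and per-species gene presence satisfying
"at least three genes, one of which is COI".  Gaps arise only from masking
and planted artifacts — sequences are born aligned and indel-free.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from dendropy.simulate import treesim

from .alignment import ENCODE, GAP, MultiGeneAlignment, Partition, Taxonomy
from .substmodel import GTRModel
from .tree import Node, PhyloTree

__all__ = [
    "PartitionSpec",
    "TruthBundle",
    "simulate_taxon_tree",
    "evolve_alignment",
    "apply_gene_mask",
    "inject_artifacts",
    "default_partition_specs",
    "default_species_counts",
    "make_truth_bundle",
]

_MIN_BRANCH = 1e-6


@dataclass(frozen=True)
class PartitionSpec:
    """One gene to simulate: name, aligned length, rate multiplier, model."""

    name: str
    length: int
    multiplier: float
    model: GTRModel


@dataclass
class TruthBundle:
    """A simulated study system: true tree, alignment, taxonomy, models."""

    tree: PhyloTree
    alignment: MultiGeneAlignment
    taxonomy: Taxonomy
    seed: int
    models: Dict[str, Tuple[GTRModel, float]]  # partition -> (model, multiplier)

    def __post_init__(self):
        if self.tree.leaf_set() != set(self.alignment.species):
            raise ValueError("tree and alignment species differ")
        if self.tree.leaf_set() != set(self.taxonomy.species):
            raise ValueError("tree and taxonomy species differ")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _bd_tree(n_tips: int, birth: float, death: float, rng: random.Random) -> Node:
    """A birth–death tree with n_tips extant leaves, as our Node structure
    with placeholder leaf labels t0..t{n-1} in dendropy leaf order."""
    if n_tips == 1:
        return Node("t0", 0.0)
    dtree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    counter = [0]

    def _convert(dnode) -> Node:
        length = dnode.edge.length if dnode.parent_node is not None else None
        if length is not None:
            length = max(float(length), _MIN_BRANCH)
        if dnode.is_leaf():
            node = Node(f"t{counter[0]}", length)
            counter[0] += 1
            return node
        node = Node(None, length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    # suppress any unifurcate root dendropy may leave
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    root.length = None
    return root


def _scale_to_height(root: Node, height: float) -> None:
    def depth(node: Node, acc: float) -> float:
        if not node.children:
            return acc
        return max(depth(c, acc + c.length) for c in node.children)

    h = depth(root, 0.0)
    if h <= 0:
        return
    factor = height / h
    stack = list(root.children)
    while stack:
        n = stack.pop()
        n.length *= factor
        stack.extend(n.children)


def simulate_taxon_tree(
    n_families: int,
    species_counts: Sequence[int] | Callable[[np.random.Generator], int],
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    family_height: float = 0.10,
    backbone_height: float = 0.25,
) -> Tuple[PhyloTree, Taxonomy]:
    """Simulate a family-structured species tree.

    A birth–death backbone over families is scaled to ``backbone_height``
    (substitutions/site from root to family tips); each family is expanded
    in place by its own birth–death subtree scaled to ``family_height``.
    Every family is monophyletic by construction.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if death_rate >= birth_rate:
        raise ValueError("death_rate must be < birth_rate")
    rng_py = random.Random(seed)
    rng_np = np.random.default_rng(seed)
    if callable(species_counts):
        counts = [int(species_counts(rng_np)) for _ in range(n_families)]
    else:
        counts = [int(c) for c in species_counts]
        if len(counts) != n_families:
            raise ValueError("species_counts length must equal n_families")
    if any(c < 1 for c in counts):
        raise ValueError("every family must have at least one species")

    fam_names = [f"Fam{i + 1:02d}" for i in range(n_families)]
    backbone = _bd_tree(n_families, birth_rate, death_rate, rng_py)
    _scale_to_height(backbone, backbone_height)

    # map backbone leaves (in postorder) to families
    tree = PhyloTree(backbone)
    fam_leaves = tree.leaves()
    family_of: Dict[str, str] = {}
    for fam, count, leaf in zip(fam_names, counts, fam_leaves):
        species = [f"{fam}_s{j + 1:03d}" for j in range(count)]
        for s in species:
            family_of[s] = fam
        if count == 1:
            leaf.label = species[0]
            continue
        sub = _bd_tree(count, birth_rate, death_rate, rng_py)
        _scale_to_height(sub, family_height)
        for j, subleaf in enumerate(PhyloTree(sub).leaves()):
            subleaf.label = species[j]
        # replace the family tip with the family subtree
        sub.length = max(leaf.length - family_height, _MIN_BRANCH)
        sub.parent = leaf.parent
        idx = leaf.parent.children.index(leaf)
        leaf.parent.children[idx] = sub
        sub.label = None

    out = PhyloTree(tree.root)
    return out, Taxonomy(family_of)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _evolve_partition(
    tree: PhyloTree,
    length: int,
    multiplier: float,
    model: GTRModel,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Evolve one gene along the tree; returns leaf label -> int8 states."""
    pi = model.pi
    cat_rates = model.gamma_rates()
    k = len(cat_rates)
    site_cat = rng.integers(0, k, size=length)
    states: Dict[Node, np.ndarray] = {}
    root_states = rng.choice(4, size=length, p=pi)
    states[tree.root] = root_states
    out: Dict[str, np.ndarray] = {}
    lam, A, B = model.eigensystem()
    for node in tree.preorder():
        if node.parent is not None:
            parent_states = states[node.parent]
            child = np.empty(length, dtype=np.int64)
            for c in range(k):
                mask = site_cat == c
                if not mask.any():
                    continue
                t = node.length * multiplier * cat_rates[c]
                P = np.clip(A @ np.diag(np.exp(lam * t)) @ B, 0.0, None)
                P /= P.sum(axis=1, keepdims=True)
                rows = P[parent_states[mask]]
                u = rng.random(mask.sum())
                child[mask] = (u[:, None] > rows.cumsum(axis=1)).sum(axis=1)
            states[node] = child
        if node.is_leaf:
            out[node.label] = states[node].astype(np.int8)
        # free memory for internal nodes whose children are all done is not
        # necessary at desk scale
    return out


def evolve_alignment(
    tree: PhyloTree,
    partitions: Sequence[PartitionSpec],
    seed: int = 0,
) -> MultiGeneAlignment:
    """Simulate a concatenated multigene alignment under per-partition GTR+Γ.

    Root states are drawn from the stationary frequencies; per-site gamma
    categories are fixed across the whole tree; branch lengths are scaled by
    the partition rate multiplier.
    """
    if tree.n_leaves < 2:
        raise ValueError("tree must have at least 2 leaves")
    if any(p.length < 1 for p in partitions):
        raise ValueError("partition lengths must be >= 1")
    rng = np.random.default_rng(seed)
    blocks: List[Dict[str, np.ndarray]] = []
    parts: List[Partition] = []
    pos = 1
    for spec in partitions:
        blocks.append(_evolve_partition(tree, spec.length, spec.multiplier, spec.model, rng))
        parts.append(Partition(spec.name, pos, pos + spec.length - 1))
        pos += spec.length
    alphabet = "ACGT-"
    species = sorted(tree.leaf_labels())
    seqs = {
        s: "".join("".join(alphabet[c] for c in blk[s]) for blk in blocks)
        for s in species
    }
    coi = "COI" if any(p.name == "COI" for p in parts) else parts[0].name
    return MultiGeneAlignment(species, seqs, parts, coi)


# ---------------------------------------------------------------------------
# Missing-gene masks and planted artifacts
# ---------------------------------------------------------------------------


def _default_presence_sampler(p_present: float = 0.65):
    def sampler(rng: np.random.Generator, genes: Sequence[str], coi: str) -> Set[str]:
        present = {coi}
        for g in genes:
            if g != coi and rng.random() < p_present:
                present.add(g)
        return present

    return sampler


def apply_gene_mask(
    aln: MultiGeneAlignment,
    min_genes: int = 3,
    coi_required: bool = True,
    gene_presence_sampler: Optional[Callable] = None,
    seed: int = 0,
) -> MultiGeneAlignment:
    """Blank whole genes per species to emulate incomplete gene sampling.

    Every emitted species keeps at least ``min_genes`` partitions, always
    including COI when ``coi_required``; proposals violating the constraint
    are resampled internally.
    """
    genes = aln.gene_names
    if min_genes > len(genes):
        raise ValueError("min_genes exceeds the number of partitions")
    if min_genes == len(genes):
        return aln.copy()
    sampler = gene_presence_sampler or _default_presence_sampler()
    rng = np.random.default_rng(seed)
    coi = aln.coi_partition
    mat = aln.matrix.copy()
    for i, species in enumerate(aln.species):
        for _ in range(1000):
            present = set(sampler(rng, genes, coi))
            if coi_required and coi not in present:
                continue
            if len(present) >= min_genes:
                break
        else:
            raise RuntimeError("gene-presence sampler kept proposing invalid sets")
        for g in genes:
            if g not in present:
                mat[i, aln.partition(g).sl] = GAP
    return aln.with_matrix(mat)


def inject_artifacts(
    aln: MultiGeneAlignment,
    n_long_gap: int,
    n_short_gene: int,
    seed: int = 0,
    gap_length: int = 151,
    short_keep: int = 70,
) -> Tuple[MultiGeneAlignment, List[Dict[str, str]]]:
    """Plant QC violations: internal gap runs > 150 and genes < 100 bp.

    Returns the modified alignment and a manifest of planted cells, each a
    dict with keys species/gene/rule (rules: ``long_gap``, ``short_gene``).
    Cells are chosen among present genes, at most one artifact per cell, and
    long-gap cells keep >= 100 flanking bases so only the gap rule fires.
    """
    if n_long_gap == 0 and n_short_gene == 0:
        return aln.copy(), []
    rng = np.random.default_rng(seed)
    # eligible cells per rule
    cells = [
        (s, g)
        for s in aln.species
        for g in aln.gene_names
        if aln.gene_present(s, g)
    ]
    gap_ok = [
        (s, g) for (s, g) in cells if aln.partition(g).length >= gap_length + 102
    ]
    if n_long_gap > 0 and not gap_ok:
        raise ValueError("no partition long enough for the requested gap run")
    if n_long_gap + n_short_gene > len(cells):
        raise ValueError("more artifacts requested than available gene cells")

    mat = aln.matrix.copy()
    manifest: List[Dict[str, str]] = []
    used: Set[Tuple[str, str]] = set()

    def _pick(pool):
        pool = [c for c in pool if c not in used]
        idx = rng.integers(0, len(pool))
        used.add(pool[idx])
        return pool[idx]

    for _ in range(n_long_gap):
        s, g = _pick(gap_ok)
        part = aln.partition(g)
        i = aln.species.index(s)
        # keep >= 51 bases on each side so the run is internal and the cell
        # stays >= 100 bp after blanking
        lo = 51
        hi = part.length - gap_length - 51
        start = int(rng.integers(lo, hi + 1))
        mat[i, part.start - 1 + start : part.start - 1 + start + gap_length] = GAP
        manifest.append({"species": s, "gene": g, "rule": "long_gap"})

    for _ in range(n_short_gene):
        s, g = _pick(cells)
        part = aln.partition(g)
        i = aln.species.index(s)
        cell = mat[i, part.sl]
        nongap = np.flatnonzero(cell != GAP)
        keep = nongap[:short_keep]
        blank = np.setdiff1d(nongap, keep)
        cell[blank] = GAP
        mat[i, part.sl] = cell
        manifest.append({"species": s, "gene": g, "rule": "short_gene"})

    return aln.with_matrix(mat), manifest


# ---------------------------------------------------------------------------
# Default study system
# ---------------------------------------------------------------------------

_COI_MODEL = GTRModel(
    rates=(1.4, 9.0, 1.2, 0.9, 22.0, 1.0),
    freqs=(0.25, 0.28, 0.17, 0.30),
    alpha=0.35,
    k=4,
)
_MT_MODEL = GTRModel(
    rates=(1.2, 7.0, 1.0, 0.8, 15.0, 1.0),
    freqs=(0.28, 0.27, 0.15, 0.30),
    alpha=0.45,
    k=4,
)
_NUC_MODEL = GTRModel(
    rates=(1.3, 3.5, 0.9, 1.1, 4.0, 1.0),
    freqs=(0.27, 0.23, 0.24, 0.26),
    alpha=0.8,
    k=4,
)


def default_partition_specs() -> List[PartitionSpec]:
    """Five genes: fast mitochondrial COI/cytb, slower nuclear markers."""
    return [
        PartitionSpec("COI", 660, 1.0, _COI_MODEL),
        PartitionSpec("cytb", 1140, 0.9, _MT_MODEL),
        PartitionSpec("rag1", 1200, 0.35, _NUC_MODEL),
        PartitionSpec("rho", 800, 0.45, _NUC_MODEL),
        PartitionSpec("s7", 400, 0.55, _NUC_MODEL),
    ]


def default_species_counts() -> List[int]:
    """20 family sizes spanning species-poor (<5) to species-rich; total 200."""
    return [2, 3, 3, 4, 4, 5, 6, 7, 8, 9, 10, 10, 11, 12, 13, 14, 15, 16, 22, 26]


def make_truth_bundle(
    seed: int = 0,
    species_counts: Optional[Sequence[int]] = None,
    partitions: Optional[Sequence[PartitionSpec]] = None,
    mask_genes: bool = True,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
) -> TruthBundle:
    """Simulate the default desk-scale study system (200 species, 20 families,
    5 genes with COI = 660 bp)."""
    counts = list(species_counts) if species_counts is not None else default_species_counts()
    specs = list(partitions) if partitions is not None else default_partition_specs()
    tree, taxonomy = simulate_taxon_tree(
        len(counts), counts, birth_rate=birth_rate, death_rate=death_rate, seed=seed
    )
    aln = evolve_alignment(tree, specs, seed=seed + 1)
    if mask_genes and len(specs) > 3:
        aln = apply_gene_mask(aln, seed=seed + 2)
    models = {p.name: (p.model, p.multiplier) for p in specs}
    return TruthBundle(tree, aln, taxonomy, seed, models)
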