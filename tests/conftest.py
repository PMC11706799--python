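"""Shared fixtures: small synthetic study systems and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from coiplace.simulate import (
    PartitionSpec,
    default_partition_specs,
    make_truth_bundle,
    simulate_taxon_tree,
)
from coiplace.substmodel import GTRModel
from coiplace.tree import number_edges, parse_newick


SMALL_COUNTS = (4, 5, 6, 7, 8, 10, 6, 4)  # 50 species, 8 families


@pytest.fixture(scope="session")
def small_bundle():
    """50-species, 8-family bundle with the default 5-gene layout."""
    return make_truth_bundle(seed=11, species_counts=SMALL_COUNTS)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Very small, fast bundle: 18 species, 4 families, short genes."""
    specs = [
        PartitionSpec("COI", 300, 1.0, GTRModel(alpha=0.5)),
        PartitionSpec("g2", 200, 0.5, GTRModel(alpha=1.0)),
        PartitionSpec("g3", 150, 0.7, GTRModel(alpha=1.0)),
    ]
    return make_truth_bundle(
        seed=5, species_counts=(4, 5, 6, 3), partitions=specs, mask_genes=False
    )


@pytest.fixture
def five_leaf_tree():
    return parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")


def random_binary_tree(n_leaves: int, seed: int):
    """A random family-structured tree used as a generic random binary tree."""
    rng = np.random.default_rng(seed)
    n_fam = max(2, n_leaves // 4)
    counts = np.ones(n_fam, dtype=int)
    for _ in range(n_leaves - n_fam):
        counts[rng.integers(0, n_fam)] += 1
    tree, _ = simulate_taxon_tree(n_fam, counts.tolist(), seed=seed)
    return tree
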