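"""Quality-control filters for multigene alignments.

Three rules, applied in order: blank gene cells containing an internal gap
run longer than 150 bp; blank gene cells shorter than 100 non-gap bp; drop
species left with fewer than three genes or without COI.  Thresholds are
strict inequalities.  All removals are logged in a FilterReport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .alignment import GAP, MultiGeneAlignment

__all__ = [
    "FilterEntry",
    "FilterReport",
    "strip_long_gap_genes",
    "strip_short_genes",
    "enforce_min_genes",
    "run_qc",
]


@dataclass(frozen=True)
class FilterEntry:
    species: str
    gene: str  # "*" for whole-species removals
    rule: str
    detail: str = ""


@dataclass
class FilterReport:
    entries: List[FilterEntry] = field(default_factory=list)
    dropped_species: List[str] = field(default_factory=list)

    def add(self, species: str, gene: str, rule: str, detail: str = "") -> None:
        self.entries.append(FilterEntry(species, gene, rule, detail))

    def merge(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport(list(self.entries), list(self.dropped_species))
        out.entries.extend(other.entries)
        out.dropped_species.extend(other.dropped_species)
        return out

    def to_tsv(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tgene\trule\tdetail\n")
            for e in self.entries:
                fh.write(f"{e.species}\t{e.gene}\t{e.rule}\t{e.detail}\n")


def _max_gap_run(cell: np.ndarray, include_terminal: bool) -> int:
    """Longest '-' run; by default only runs inside the aligned span count
    (leading/trailing absence is incompleteness, not an internal gap)."""
    is_gap = cell == GAP
    if not is_gap.any():
        return 0
    if not include_terminal:
        nongap = np.flatnonzero(~is_gap)
        if nongap.size == 0:
            return 0
        is_gap = is_gap[nongap[0] : nongap[-1] + 1]
    # run lengths of True values
    padded = np.concatenate([[False], is_gap, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    if starts.size == 0:
        return 0
    return int((ends - starts).max())


def strip_long_gap_genes(
    aln: MultiGeneAlignment,
    threshold: int = 150,
    include_terminal: bool = False,
) -> Tuple[MultiGeneAlignment, FilterReport]:
    """Blank cells whose longest internal gap run is strictly > threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    report = FilterReport()
    mat = aln.matrix.copy()
    for i, s in enumerate(aln.species):
        for p in aln.partitions:
            cell = mat[i, p.sl]
            if not (cell != GAP).any():
                continue  # already missing
            run = _max_gap_run(cell, include_terminal)
            if run > threshold:
                mat[i, p.sl] = GAP
                report.add(s, p.name, "long_gap", f"max_gap_run={run}")
    return aln.with_matrix(mat), report


def strip_short_genes(
    aln: MultiGeneAlignment,
    min_len: int = 100,
) -> Tuple[MultiGeneAlignment, FilterReport]:
    """Blank cells with strictly fewer than min_len non-gap characters."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    report = FilterReport()
    mat = aln.matrix.copy()
    for i, s in enumerate(aln.species):
        for p in aln.partitions:
            cell = mat[i, p.sl]
            n = int((cell != GAP).sum())
            if n == 0:
                continue
            if n < min_len:
                mat[i, p.sl] = GAP
                report.add(s, p.name, "short_gene", f"length={n}")
    return aln.with_matrix(mat), report


def enforce_min_genes(
    aln: MultiGeneAlignment,
    min_genes: int = 3,
    require_coi: bool = True,
) -> Tuple[MultiGeneAlignment, FilterReport]:
    """Drop species with fewer than min_genes genes, or without COI."""
    report = FilterReport()
    keep = []
    for s in aln.species:
        present = aln.genes_present(s)
        if require_coi and aln.coi_partition not in present:
            report.add(s, "*", "missing_coi", f"genes={','.join(present)}")
            report.dropped_species.append(s)
        elif len(present) < min_genes:
            report.add(s, "*", "too_few_genes", f"n_genes={len(present)}")
            report.dropped_species.append(s)
        else:
            keep.append(s)
    if len(keep) < 4:
        raise ValueError("fewer than 4 species survive gene-count filtering")
    return aln.subset_species(keep), report


def run_qc(
    aln: MultiGeneAlignment,
    gap_threshold: int = 150,
    min_len: int = 100,
    min_genes: int = 3,
    require_coi: bool = True,
    include_terminal_gaps: bool = False,
) -> Tuple[MultiGeneAlignment, FilterReport]:
    """The full filter cascade: long gaps, short genes, then gene counts."""
    aln1, r1 = strip_long_gap_genes(aln, gap_threshold, include_terminal_gaps)
    aln2, r2 = strip_short_genes(aln1, min_len)
    aln3, r3 = enforce_min_genes(aln2, min_genes, require_coi)
    return aln3, r1.merge(r2).merge(r3)
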