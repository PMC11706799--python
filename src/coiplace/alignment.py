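"""Multigene alignment container with named partitions, plus flat-file I/O.

Sequences are concatenated per-species strings over {A,C,G,T,-}; '-' encodes
both alignment gaps and wholly missing genes.  Partitions are named 1-based
inclusive column ranges (RAxML-style), one of which is designated the COI
barcode partition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Partition",
    "MultiGeneAlignment",
    "Taxonomy",
    "read_fasta",
    "write_fasta",
    "read_partitions",
    "write_partitions",
    "read_taxonomy",
    "write_taxonomy",
]

_ALPHABET = "ACGT-"
ENCODE = {c: i for i, c in enumerate(_ALPHABET)}
GAP = ENCODE["-"]


@dataclass(frozen=True)
class Partition:
    """A named gene block: 1-based inclusive column range."""

    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def sl(self) -> slice:
        return slice(self.start - 1, self.end)


class MultiGeneAlignment:
    """Species x concatenated-columns alignment with named gene partitions."""

    def __init__(
        self,
        species: Sequence[str],
        sequences: Mapping[str, str],
        partitions: Sequence[Partition],
        coi_partition: str = "COI",
    ):
        self.species = list(species)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in alignment")
        widths = {len(sequences[s]) for s in self.species}
        if len(widths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self.width = widths.pop()
        self.partitions = list(partitions)
        self._check_partitions()
        if coi_partition not in {p.name for p in self.partitions}:
            raise ValueError(f"COI partition {coi_partition!r} not among partitions")
        self.coi_partition = coi_partition
        # encoded matrix: rows follow self.species order
        mat = np.empty((len(self.species), self.width), dtype=np.int8)
        for i, s in enumerate(self.species):
            row = sequences[s].upper()
            try:
                mat[i] = [ENCODE[c] for c in row]
            except KeyError as exc:
                raise ValueError(f"illegal character {exc} in sequence for {s}") from exc
        self.matrix = mat
        self._index = {s: i for i, s in enumerate(self.species)}

    def _check_partitions(self) -> None:
        spans = sorted((p.start, p.end, p.name) for p in self.partitions)
        pos = 1
        for start, end, name in spans:
            if start != pos:
                raise ValueError(f"partitions not covering/non-overlapping at {name}")
            if end < start:
                raise ValueError(f"empty partition {name}")
            pos = end + 1
        if pos != self.width + 1:
            raise ValueError("partitions do not cover the alignment")

    # -- access ------------------------------------------------------------

    def partition(self, name: str) -> Partition:
        for p in self.partitions:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def gene_names(self) -> List[str]:
        return [p.name for p in self.partitions]

    def row(self, species: str) -> np.ndarray:
        return self.matrix[self._index[species]]

    def sequence(self, species: str) -> str:
        return "".join(_ALPHABET[c] for c in self.row(species))

    def gene_cell(self, species: str, gene: str) -> np.ndarray:
        return self.row(species)[self.partition(gene).sl]

    def gene_present(self, species: str, gene: str) -> bool:
        """A gene is present when its cell has at least one non-gap character."""
        return bool((self.gene_cell(species, gene) != GAP).any())

    def genes_present(self, species: str) -> List[str]:
        return [g for g in self.gene_names if self.gene_present(species, g)]

    def subset_species(self, keep: Sequence[str]) -> "MultiGeneAlignment":
        keep = list(keep)
        missing = set(keep) - set(self.species)
        if missing:
            raise ValueError(f"unknown species: {sorted(missing)[:5]}")
        seqs = {s: self.sequence(s) for s in keep}
        return MultiGeneAlignment(keep, seqs, self.partitions, self.coi_partition)

    def subset_columns(self, part_names: Sequence[str]) -> "MultiGeneAlignment":
        """Restrict to the given partitions (re-indexed to cover)."""
        parts = [self.partition(n) for n in part_names]
        pos = 1
        new_parts = []
        chunks = []
        for p in parts:
            new_parts.append(Partition(p.name, pos, pos + p.length - 1))
            chunks.append(self.matrix[:, p.sl])
            pos += p.length
        mat = np.concatenate(chunks, axis=1)
        seqs = {
            s: "".join(_ALPHABET[c] for c in mat[i])
            for i, s in enumerate(self.species)
        }
        coi = self.coi_partition if self.coi_partition in part_names else part_names[0]
        return MultiGeneAlignment(list(self.species), seqs, new_parts, coi)

    def with_matrix(self, matrix: np.ndarray) -> "MultiGeneAlignment":
        """Same species/partitions, new character matrix."""
        seqs = {
            s: "".join(_ALPHABET[c] for c in matrix[i])
            for i, s in enumerate(self.species)
        }
        return MultiGeneAlignment(list(self.species), seqs, self.partitions, self.coi_partition)

    def copy(self) -> "MultiGeneAlignment":
        return self.with_matrix(self.matrix.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MultiGeneAlignment {len(self.species)} species x {self.width} cols, "
            f"{len(self.partitions)} partitions>"
        )


@dataclass
class Taxonomy:
    """Species -> family mapping used as the stratification for sampling."""

    family_of: Dict[str, str]

    def families(self) -> List[str]:
        return sorted(set(self.family_of.values()))

    def members(self, family: str) -> List[str]:
        return sorted(s for s, f in self.family_of.items() if f == family)

    def family_sizes(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for f in self.family_of.values():
            out[f] = out.get(f, 0) + 1
        return out

    @property
    def species(self) -> List[str]:
        return sorted(self.family_of)


# ---------------------------------------------------------------------------
# I/O — plain-text formats only
# ---------------------------------------------------------------------------


def write_fasta(aln_or_seqs, path: Path) -> None:
    if isinstance(aln_or_seqs, MultiGeneAlignment):
        items = [(s, aln_or_seqs.sequence(s)) for s in aln_or_seqs.species]
    else:
        items = list(aln_or_seqs.items())
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: Path) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_partitions(partitions: Sequence[Partition], path: Path) -> None:
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(f"DNA, {p.name} = {p.start}-{p.end}\n")


def read_partitions(path: Path) -> List[Partition]:
    out = []
    pat = re.compile(r"^\s*DNA\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            m = pat.match(line)
            if not m:
                raise ValueError(f"bad partition line: {line!r}")
            out.append(Partition(m.group(1), int(m.group(2)), int(m.group(3))))
    return out


def write_taxonomy(tax: Taxonomy, path: Path) -> None:
    with open(path, "w") as fh:
        for s in tax.species:
            fh.write(f"{s}\t{tax.family_of[s]}\n")


def read_taxonomy(path: Path) -> Taxonomy:
    fam: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            s, f = line.rstrip("\n").split("\t")
            fam[s] = f
    return Taxonomy(fam)
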