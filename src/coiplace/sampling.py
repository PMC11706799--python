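"""Backbone subsampling: nested completeness series under random,
taxonomically stratified, and database-biased strategies.

A CompletenessSeries records, for one replicate of one strategy, the species
retained on the backbone at each completeness level (percent of the full
species set, descending).  Levels are nested: each level's retained set is a
subset of the previous (higher) level's — lower-completeness backbones are
obtained by removing species from higher ones, never by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np

from .alignment import Taxonomy

__all__ = [
    "CompletenessSeries",
    "random_series",
    "stratified_series",
    "biased_retention_from_counts",
    "biased_series",
    "default_biased_fractions",
]

DEFAULT_LEVELS = (99, 80, 60, 40, 20)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class CompletenessSeries:
    strategy: str
    replicate: int
    levels: List[float]  # percents, descending
    retained: Dict[float, Set[str]]  # level -> retained species
    seed: int

    def __post_init__(self):
        prev: Optional[Set[str]] = None
        for lvl in self.levels:
            cur = self.retained[lvl]
            if prev is not None and not cur <= prev:
                raise ValueError("completeness levels are not nested")
            prev = cur

    def missing(self, level: float, universe: Iterable[str]) -> Set[str]:
        return set(universe) - self.retained[level]

    def to_tsv(self, path: Path, universe: Iterable[str]) -> None:
        universe = sorted(universe)
        with open(path, "w") as fh:
            fh.write("replicate\tstrategy\tlevel\tspecies\tretained\n")
            for lvl in self.levels:
                kept = self.retained[lvl]
                for s in universe:
                    fh.write(
                        f"{self.replicate}\t{self.strategy}\t{lvl}\t{s}\t{int(s in kept)}\n"
                    )


def _check_levels(levels: Sequence[float]) -> List[float]:
    levels = [float(l) for l in levels]
    if any(not (0 < l < 100) for l in levels):
        raise ValueError("levels must lie strictly between 0 and 100")
    if any(nxt >= prev for nxt, prev in zip(levels[1:], levels[:-1])):
        raise ValueError("levels must be strictly descending")
    return levels


def random_series(
    species: Iterable[str],
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: int = 0,
    replicate: int = 0,
) -> CompletenessSeries:
    """Uniform subsampling ignoring taxonomy; nested across levels.

    Retained counts are round-half-up of level% of n, clamped to [1, n-1] so
    at least one species is always missing (placement needs queries).
    """
    species = sorted(set(species))
    n = len(species)
    if n < 4:
        raise ValueError("need at least 4 species")
    levels = _check_levels(levels)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(species))
    retained: Dict[float, Set[str]] = {}
    for lvl in levels:
        size = min(max(_round_half_up(lvl / 100.0 * n), 1), n - 1)
        size = min(size, len(order))
        order = order[:size]
        retained[lvl] = set(order)
    return CompletenessSeries("random", replicate, levels, retained, seed)


def stratified_series(
    species: Iterable[str],
    taxonomy: Taxonomy,
    levels: Sequence[float] = DEFAULT_LEVELS,
    small_family_threshold: int = 5,
    seed: int = 0,
    replicate: int = 0,
) -> CompletenessSeries:
    """Per-family subsampling that never drops a family.

    Families below ``small_family_threshold`` keep all members at every
    level; others keep max(1, round(level% of family size)), nested.  If a
    level would retain everything (possible when percentages round up to
    full families), one species is removed from the largest non-small family
    so placement always has at least one query.
    """
    species = sorted(set(species))
    unknown = [s for s in species if s not in taxonomy.family_of]
    if unknown:
        raise ValueError(f"species missing from taxonomy: {unknown[:5]}")
    levels = _check_levels(levels)
    rng = np.random.default_rng(seed)
    by_family: Dict[str, List[str]] = {}
    for s in species:
        by_family.setdefault(taxonomy.family_of[s], []).append(s)
    # fixed per-family permutation => per-level prefixes are nested
    perms = {f: list(rng.permutation(sorted(m))) for f, m in by_family.items()}

    counts: Dict[float, Dict[str, int]] = {}
    for lvl in levels:
        counts[lvl] = {}
        for fam, members in by_family.items():
            nf = len(members)
            if nf < small_family_threshold:
                counts[lvl][fam] = nf
            else:
                counts[lvl][fam] = max(1, _round_half_up(lvl / 100.0 * nf))
        if sum(counts[lvl].values()) >= len(species):
            big = [
                f
                for f in by_family
                if len(by_family[f]) >= small_family_threshold and counts[lvl][f] > 1
            ]
            if big:
                target = max(big, key=lambda f: (counts[lvl][f], f))
                counts[lvl][target] -= 1
            # else: every family is small (all species protected) — the
            # series legitimately retains everything at this level
    retained: Dict[float, Set[str]] = {
        lvl: {s for fam, c in counts[lvl].items() for s in perms[fam][:c]}
        for lvl in levels
    }
    return CompletenessSeries("stratified", replicate, levels, retained, seed)


def biased_retention_from_counts(
    complete_counts: Mapping[str, int],
    observed_counts: Mapping[str, int],
) -> Dict[str, float]:
    """Per-family missing fractions from a complete vs observed census."""
    out: Dict[str, float] = {}
    for fam, total in complete_counts.items():
        if total < 1:
            raise ValueError(f"complete count for {fam} must be >= 1")
        obs = observed_counts.get(fam, 0)
        if obs > total:
            raise ValueError(f"observed > complete for family {fam}")
        out[fam] = 1.0 - obs / total
    return out


def default_biased_fractions(taxonomy: Taxonomy) -> Dict[str, float]:
    """A deterministic per-family missing-fraction profile emulating
    database coverage gaps; overall completeness lands near 20%."""
    profile = [0.72, 0.95, 0.80, 0.90, 0.65, 0.85, 0.75, 0.92, 0.70, 0.88]
    fams = sorted(taxonomy.families(), key=lambda f: (-len(taxonomy.members(f)), f))
    return {f: profile[i % len(profile)] for i, f in enumerate(fams)}


def biased_series(
    species: Iterable[str],
    taxonomy: Taxonomy,
    missing_fractions: Mapping[str, float],
    seed: int = 0,
    replicate: int = 0,
) -> CompletenessSeries:
    """Single-level subsampling with per-family missing fractions.

    Families may be emptied entirely — bias can omit whole lineages.  The
    series level is the realized overall completeness percentage.
    """
    species = sorted(set(species))
    if any(not (0 <= f <= 1) for f in missing_fractions.values()):
        raise ValueError("missing fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    by_family: Dict[str, List[str]] = {}
    for s in species:
        by_family.setdefault(taxonomy.family_of[s], []).append(s)
    kept: Set[str] = set()
    for fam, members in sorted(by_family.items()):
        frac_missing = missing_fractions.get(fam, 0.0)
        k = _round_half_up((1.0 - frac_missing) * len(members))
        if k > 0:
            kept.update(rng.permutation(sorted(members))[:k])
    if not kept:
        raise ValueError("biased sampling removed every species")
    level = 100.0 * len(kept) / len(species)
    return CompletenessSeries("biased", replicate, [level], {level: kept}, seed)
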