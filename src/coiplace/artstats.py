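"""Aligned rank transform (ART) factorial analysis of accuracy metrics.

The design is a two-factor layout (completeness level x sampling strategy)
with replicate as an additive block.  For each effect of interest the
responses are *aligned* — every estimated effect except the one of interest
is subtracted — then mid-ranked, and a classical fixed-effects ANOVA is run
on the ranks; only the matching effect's F and p are reported.  Post hoc
pairwise comparisons (ART-C style) run two-sample t contrasts on the ranks
of data aligned for the contrasted effect, with Holm adjustment by default.

Effect estimates come from cell and marginal means, so the procedure is
exact for balanced layouts (the pipeline always produces balanced tables).
The repeated-measures structure of the sampling design is approximated by
the additive replicate block rather than a full mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "ContrastRow",
    "ARTResult",
    "align_and_rank",
    "art_anova",
    "art_contrasts",
]

ALPHA = 0.05

FACTORS = ("level", "strategy")
INTERACTION = "level:strategy"


@dataclass(frozen=True)
class EffectResult:
    effect: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass(frozen=True)
class ContrastRow:
    effect: str
    level_a: str
    level_b: str
    t_stat: float
    df: int
    p_value: float
    p_adjusted: float


@dataclass
class ARTResult:
    effects: Dict[str, EffectResult]
    alpha: float = ALPHA

    def significant(self, effect: str) -> bool:
        return self.effects[effect].p_value < self.alpha


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"replicate", "level", "strategy", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"design table missing columns {sorted(missing)}")
    if not np.isfinite(table["value"]).all():
        raise ValueError("non-finite metric values in design table")
    return table.reset_index(drop=True)


def _effect_estimates(table: pd.DataFrame) -> Dict[str, pd.Series | float]:
    """Means-based estimates of mu, main effects, interaction, block."""
    y = table["value"]
    mu = y.mean()
    a = table.groupby("level")["value"].mean() - mu
    b = table.groupby("strategy")["value"].mean() - mu
    cell = table.groupby(["level", "strategy"])["value"].mean()
    r = table.groupby("replicate")["value"].mean() - mu
    return {"mu": mu, "level": a, "strategy": b, "cell": cell, "replicate": r}


def _fitted(table: pd.DataFrame, est) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    lev = table["level"].to_numpy()
    strat = table["strategy"].to_numpy()
    rep = table["replicate"].to_numpy()
    A = est["level"].reindex(lev).to_numpy()
    B = est["strategy"].reindex(strat).to_numpy()
    cell = est["cell"].reindex(list(zip(lev, strat))).to_numpy()
    AB = cell - est["mu"] - A - B
    R = est["replicate"].reindex(rep).to_numpy()
    fitted = est["mu"] + A + B + AB + R
    return fitted, {"level": A, "strategy": B, INTERACTION: AB, "replicate": R}


def align_and_rank(table: pd.DataFrame, effect: str) -> pd.DataFrame:
    """Align responses for one effect and mid-rank them.

    Returns a copy of the table with columns ``aligned`` and ``rank``.
    Aligned values are residual + (estimate of the effect of interest) and
    sum to zero up to floating point for balanced layouts.
    """
    table = _check_table(table)
    for factor in FACTORS:
        if table[factor].nunique() < 2 and effect in (factor, INTERACTION):
            raise ValueError(f"factor {factor!r} has a single level")
    est = _effect_estimates(table)
    fitted, parts = _fitted(table, est)
    if effect not in parts:
        raise ValueError(f"unknown effect {effect!r}")
    y = table["value"].to_numpy(dtype=float)
    aligned = y - fitted + parts[effect]
    out = table.copy()
    out["aligned"] = aligned
    out["rank"] = sps.rankdata(aligned)  # mid-ranks for ties
    return out


def _balanced_anova_on_ranks(table: pd.DataFrame, effect: str) -> EffectResult:
    """Classical sums-of-squares partition of the ranks for one effect.

    Model: rank ~ level + strategy + level:strategy + replicate(block).
    For a single-factor collapse (one strategy, or one level) the model
    drops the constant terms automatically (their SS is zero).
    """
    r = table["rank"].to_numpy(dtype=float)
    n = len(r)
    mu = r.mean()
    sst = ((r - mu) ** 2).sum()

    def _ss(groups: pd.Series) -> Tuple[float, int]:
        g = table.groupby(groups.name)["rank"]
        counts = g.count()
        means = g.mean()
        return float((counts * (means - mu) ** 2).sum()), len(means) - 1

    ss_a, df_a = _ss(table["level"])
    ss_b, df_b = _ss(table["strategy"])
    ss_r, df_r = _ss(table["replicate"])
    cells = table.groupby(["level", "strategy"])["rank"]
    cell_counts = cells.count()
    cell_means = cells.mean()
    ss_cells = float((cell_counts * (cell_means - mu) ** 2).sum())
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)
    df_ab = df_a * df_b

    df_err = n - 1 - df_a - df_b - df_ab - df_r
    if df_err <= 0:
        raise ValueError("design has no residual degrees of freedom")
    ss_err = max(sst - ss_a - ss_b - ss_ab - ss_r, 0.0)

    ss_eff, df_eff = {
        "level": (ss_a, df_a),
        "strategy": (ss_b, df_b),
        INTERACTION: (ss_ab, df_ab),
    }[effect]
    if df_eff == 0:
        raise ValueError(f"effect {effect!r} has zero degrees of freedom")
    mse = ss_err / df_err
    f = (ss_eff / df_eff) / mse if mse > 0 else np.inf
    p = float(sps.f.sf(f, df_eff, df_err))
    return EffectResult(effect, float(f), df_eff, df_err, p)


def art_anova(table: pd.DataFrame) -> ARTResult:
    """ART ANOVA: one aligned-rank ANOVA per effect, reporting that effect.

    With both factors varying, effects are the two main effects and their
    interaction; in a single-factor collapse only the varying factor is
    analyzed (equivalent to one-way ANOVA on its aligned ranks).
    """
    table = _check_table(table)
    n_lev = table["level"].nunique()
    n_str = table["strategy"].nunique()
    if n_lev < 2 and n_str < 2:
        raise ValueError("no factor with at least 2 levels")
    effects = []
    if n_lev >= 2:
        effects.append("level")
    if n_str >= 2:
        effects.append("strategy")
    if n_lev >= 2 and n_str >= 2:
        effects.append(INTERACTION)
    out: Dict[str, EffectResult] = {}
    for eff in effects:
        ranked = align_and_rank(table, eff)
        out[eff] = _balanced_anova_on_ranks(ranked, eff)
    return ARTResult(out)


def art_contrasts(
    table: pd.DataFrame,
    effect: str,
    within: Optional[Tuple[str, object]] = None,
    adjust: str = "holm",
) -> List[ContrastRow]:
    """ART-C pairwise contrasts for one factor, optionally conditional.

    ``within`` restricts the table to one level of the other factor, e.g.
    ``("level", 99)`` to compare strategies at 99% completeness.  Contrasts
    are two-sample t statistics on the aligned ranks using the pooled
    residual mean square of the rank model (effect + block), so with two
    levels and no adjustment the contrast p equals the ANOVA p.
    """
    table = _check_table(table)
    if effect not in FACTORS:
        raise ValueError("contrasts support the two main factors")
    if within is not None:
        col, value = within
        table = table[table[col] == value].reset_index(drop=True)
        if table.empty:
            raise ValueError(f"no rows with {col} == {value!r}")
    levels = sorted(table[effect].unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"effect {effect!r} has fewer than 2 levels")
    counts = table.groupby(effect)["value"].count()
    if (counts < 2).any():
        raise ValueError("every level needs at least 2 observations")
    ranked = align_and_rank(table, effect)
    r = ranked["rank"].to_numpy(dtype=float)
    n = len(r)
    mu = r.mean()
    grp = ranked.groupby(effect)["rank"]
    means = grp.mean()
    sizes = grp.count()
    ss_eff = float((sizes * (means - mu) ** 2).sum())
    rep = ranked.groupby("replicate")["rank"]
    n_rep = ranked["replicate"].nunique()
    ss_rep = float((rep.count() * (rep.mean() - mu) ** 2).sum()) if n_rep > 1 else 0.0
    df_rep = n_rep - 1 if n_rep > 1 else 0
    sst = float(((r - mu) ** 2).sum())
    df_err = n - 1 - (len(levels) - 1) - df_rep
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom for contrasts")
    mse = max(sst - ss_eff - ss_rep, 0.0) / df_err

    raw: List[Tuple[str, str, float]] = []
    for a, b in combinations(levels, 2):
        se = np.sqrt(mse * (1.0 / sizes[a] + 1.0 / sizes[b]))
        t = (means[a] - means[b]) / se if se > 0 else np.inf
        raw.append((a, b, float(t)))
    pvals = [2.0 * float(sps.t.sf(abs(t), df_err)) for _, _, t in raw]
    adj = _adjust(pvals, adjust)
    return [
        ContrastRow(effect, str(a), str(b), t, df_err, p, pa)
        for (a, b, t), p, pa in zip(raw, pvals, adj)
    ]


def _adjust(pvals: Sequence[float], method: str) -> List[float]:
    if method == "none":
        return list(pvals)
    if method != "holm":
        raise ValueError("adjust must be 'holm' or 'none'")
    m = len(pvals)
    order = np.argsort(pvals)
    out = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * pvals[idx]
        running = max(running, val)
        out[idx] = min(running, 1.0)
    return out.tolist()
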