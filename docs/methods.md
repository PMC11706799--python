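# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `coiplace`, in the spirit of a package methods appendix.

## Synthetic study system

The generator produces a *truth bundle*: a reference tree, a multigene
alignment, and a species→family taxonomy with identical label sets.

**Tree.** A birth–death tree (birth 1.0, death 0.0 by default) over
families is scaled to a backbone height of 0.25 expected substitutions per
site; each family tip is replaced by an independent birth–death subtree
scaled to height 0.10. Families are therefore monophyletic by construction
(real families need not be; this is acceptable because families only drive
the sampling strata). Branch lengths are clamped to ≥ 1e-6. Default sizes:
200 species in 20 families, with family sizes 2–26 so that species-poor
(< 5) and species-rich families both occur.

**Sequences.** Each gene evolves independently under GTR+Γ (discrete gamma,
k = 4, category rates by the mean-of-equal-probability-bins construction,
scaled to mean 1; the rate matrix is normalized to one expected substitution
per unit branch length). Per-site categories are drawn once and fixed across
the tree. Defaults: COI (660 bp, multiplier 1.0, transition-biased rates,
α = 0.35), cytb (1140 bp, 0.9), rag1 (1200 bp, 0.35), rho (800 bp, 0.45),
s7 (400 bp, 0.55); mitochondrial partitions get stronger rate heterogeneity
and AT-shifted frequencies than the nuclear ones. These heights and rates
put within-family COI p-distances around 0.05–0.15 and between-family ones
around 0.2–0.3 — the range familiar from fish barcoding surveys, clear of
Jukes–Cantor saturation.

**Missing genes.** Each species keeps COI and every other gene
independently with probability 0.65, resampled until ≥ 3 genes survive.
Gaps otherwise do not exist: there is no indel process, so '-' always means
"masked gene", "planted artifact" or "QC-blanked cell". Consequently the
synthetic data do not exercise alignment error, contamination, or
mitochondrial/nuclear discordance — passing tests demonstrate correctness
of the pipeline machinery and the direction of sampling effects, not
real-data error rates.

**Planted QC violations.** `inject_artifacts` writes internal gap runs of
151 bp (placed ≥ 51 bp from the cell ends so the cell stays ≥ 100 bp and
only the gap rule fires) and truncates cells to 70 bp, returning a manifest
used by the QC cross-check tests.

## Quality control

Cells are blanked when their longest gap run strictly exceeds 150 columns
or when they hold strictly fewer than 100 non-gap characters; species are
dropped when fewer than 3 genes or no COI remain. Gap runs are measured
inside the cell's aligned span by default — leading/trailing absence is
incompleteness, not a gap — with `include_terminal=True` available since
the convention is genuinely ambiguous. Filters are idempotent and every
removal is logged.

## Subsampling

Retained counts use round-half-up. Random sampling clamps to [1, n−1] so a
query always exists. Stratified sampling permutes each family once and
takes nested prefixes, keeping every family at every level and whole
families below 5 species; when a high level would round up to retaining
everything, one species is dropped from the largest non-small family
(deterministically) so placement still has a query — except in the
degenerate all-small-families case, where full retention stands. Biased
sampling applies per-family missing fractions at a single level; the
shipped default profile cycles fixed fractions (0.65–0.95) over families
ordered by size and lands near 20 % overall completeness.

## Likelihood engine

Felsenstein pruning with per-(category, site) log-scaling throughout (a
4 500-leaf tree underflows doubles without it). For placement, the engine
precomputes, for every backbone edge, the product of the inside (child)
and outside (rest-of-tree, including the root prior) conditional vectors at
the edge midpoint; attaching a query with pendant length t then costs one
4×4 transition matrix per category and a weighted sum per site. The
per-edge score equals the full grafted-tree likelihood to machine
precision (tested). Sites where the query is missing contribute identical
factors on every edge, so computation is restricted to the query's non-gap
columns — exact for LWR and for the best edge.

Pendant length is optimized by vectorized golden-section search on
[0, 2 × tree height] to width 1e-6; the distal position defaults to the
edge midpoint, with joint coordinate-descent optimization behind
`optimize=True` (three rounds of alternating golden-section searches).
LWRs are the softmax of per-edge log-likelihoods; ties break toward the
lowest edge number.

## Distance engine

Query-to-leaf distances are Jukes–Cantor corrected mismatch proportions
over shared non-gap COI sites; p ≥ 0.75 or empty overlap makes a leaf
unusable, and a query with fewer than four usable leaves is reported
unplaced. For an edge of length b, the attachment at distal x and pendant
t predicts the distance to leaf i as t + a_i ± x with precomputed per-edge
constants; minimizing the weighted squared error (weights 1/δ² by default,
"fm"; or 1, "ols") is a 2×2 linear solve per edge with box constraints
handled by evaluating the clamped boundary candidates. Noise-free additive
distances recover the true edge with zero residual (tested). The engine
emits no confidence value, so CP/PCP-CP are undefined for it.

## Accuracy metric

The sister-clade rule needs one interpretation call: the verbal instruction
"the most inclusive clade containing all members of the sister group" is
implemented as the *least* inclusive such clade (the MRCA) — the literal
reading is always the whole tree and discriminates nothing. Because a
sister group that is itself an exact reference clade (in particular, any
singleton) then yields an empty difference list, two modes ship:

- `sister_mrca` (default of `assess_placement`; closest to the verbal rule),
- `sister_plus_query_mrca` (the pipeline's default): the MRCA additionally
  spans the query, so a placement next to the wrong single species is
  penalized whenever backbone species separate them in the reference.

Queries are assessed on the fully grafted placement tree (same species
composition as the reference), so sister groups may contain other queries;
the difference-list rule handles them naturally. Multiple queries on one
edge are grafted in descending distal order, ties broken by name.

Even the strict mode is lenient toward *conservative* placements —
attachments basal to a clade that contains the query's true position, or
next to the nearest sampled relative, often produce difference lists made
of missing species only. At desk scale (few backbone species per family)
this leniency is strong enough that the distance engine, whose
least-squares fits gravitate to exactly such attachments, can score higher
PCP than the likelihood engine even though the likelihood engine recovers
the *true* attachment edge for far more queries (roughly 85–95 % vs
15–30 % in the shipped simulations). Interpret PCP accordingly: it measures
consistency with the reference up to missing-species ambiguity, not exact
edge recovery.

## ART statistics

For each effect, responses are aligned (all estimated effects except the
effect of interest subtracted; estimates from cell/marginal means, exact
for the balanced tables the pipeline emits), mid-ranked, and fed to a
classical fixed-effects ANOVA (completeness + strategy + interaction +
replicate block); only the matching effect's F is reported. The
repeated-measures structure induced by nested subsampling is approximated
by the additive replicate block — a deliberate simplification; a mixed
model is out of scope. ART-C contrasts are pairwise t statistics on the
aligned ranks using the rank model's pooled MSE, Holm-adjusted by default
(Holm is exact without studentized-range tables; `adjust="none"`
available). Null simulations (5×2 design, 3 replicates) put the type-I
rate of each effect at 0.04–0.06 at α = 0.05.

## Problem sizes and determinism

The default experiment (200 species; 5 levels × 2 strategies × 3
replicates × 2 engines ≈ 2 400 likelihood placements of 660 bp queries on
backbones of 40–198 leaves) runs in minutes on one CPU; every stage derives
its seed from the master seed via a crc32-tagged counter scheme, so any
stage can be reproduced in isolation and reruns are bit-identical. The
replicate count is configurable (3 by default at desk scale; 10 mirrors the
full design).

## Known limitations

- No indels, alignment error, or gene-tree/species-tree discordance in the
  generator; placement difficulty comes only from substitution noise,
  short query length, and backbone sparsity.
- The likelihood engine evaluates every edge exactly rather than using
  candidate-edge heuristics; fine at desk scale, not meant for 10⁵-leaf
  backbones.
- The biased strategy's default fraction profile is a stylized stand-in
  for database coverage gaps, not fitted to any census.
- PCP depends on the assessment mode near singleton sister groups; both
  modes are reported machinery, and the strict mode is the pipeline
  default.
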