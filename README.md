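# coiplace

Benchmarking phylogenetic placement of DNA-barcode (COI) sequences on
multigene backbone trees.

## The problem

Large reference phylogenies are expensive to build, but millions of short
(~660 bp) cytochrome *c* oxidase subunit 1 (COI) barcode sequences are
available for species that no multigene dataset covers. *Phylogenetic
placement* grafts each such species independently onto a fixed backbone
tree. How reliable is that, and how does it depend on how complete — and
how taxonomically representative — the backbone is?

`coiplace` answers this with a fully synthetic, truth-known pipeline aimed
at methodologists and instructors:

1. **Simulate** a family-structured species tree (birth–death backbone over
   families, birth–death subtrees within families; families monophyletic by
   construction) and evolve a concatenated multigene alignment under
   per-gene GTR+Γ models, including a fast mitochondrial COI partition.
   Per-species missing-gene masks keep at least three genes per species,
   COI always among them.
2. **Filter** (QC): blank gene cells with internal gap runs > 150 bp or
   fewer than 100 bp of sequence; drop species with < 3 genes or no COI.
3. **Subsample** backbones at 99/80/60/40/20 % completeness, nested within
   a replicate, under three strategies: *random*, *stratified* (every
   family keeps ≥ 1 species; families with < 5 species keep all), and
   *biased* (per-family missing fractions mimicking database gaps,
   ~20 % overall).
4. **Place** every missing species from its COI row with two engines:
   a likelihood engine (per-edge GTR+Γ log-likelihood with optimized
   pendant length; likelihood weight ratio LWR = softmax of per-edge
   log-likelihoods) and a distance engine (Jukes–Cantor distances,
   per-edge weighted least-squares attachment in closed form, no
   confidence value). Results are exchanged as jplace v3.
5. **Score** each placement by the sister-clade rule: take the query's
   sister group S on the placement tree, find the MRCA clade C of S on the
   reference tree, and call the placement correct iff the difference
   (C \ S) \ {query} contains no backbone species. Aggregates: **PCP**
   (% correct of placed), **CP** (% with LWR > 0.9), **PCP-CP** (PCP within
   the confident subset).
6. **Analyze** the replicate × completeness × strategy design with aligned
   rank transform (ART) ANOVA and ART-C pairwise contrasts (α = 0.05).

## Worked example

```python
from coiplace import ExperimentConfig, run_experiment, report_table

cfg = ExperimentConfig(seed=2, replicates=2, levels=(80, 40),
                       species_counts=(4, 5, 6, 7, 8, 10, 6, 4))
res = run_experiment(cfg)
print(report_table(res.summary)[("stratified", "likelihood")])
```

prints (metric columns for the stratified strategy, likelihood engine):

```
metric         PCP          CP       PCP-CP
level
80.0    75 (62-88)  75 (62-88)  90 (80-100)
40.0    69 (62-77)  81 (73-88)   73 (68-78)
```

Each cell is "mean (min–max)" over replicates, in percent: at 80 %
backbone completeness, 75 % of the placed species land in positions the
sister-clade rule accepts; among the 75 % of placements that are confident
(LWR > 0.9), 90 % are accepted.
The same table carries the random-strategy and distance-engine columns
(the distance engine has no CP/PCP-CP — it emits no confidence value).

The same workflow is available from the shell:

```bash
coiplace run-all --seed 2 --out-dir runs/demo
coiplace report --summary runs/demo/summary.tsv
```

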