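# orthodelta

Tools for linking lineage-specific gene duplication to transcriptome
divergence across species. The motivating biology is the hemoglobinless
Antarctic icefish: did gene-family expansion in that lineage raise
expression through dosage, narrow expression breadth, and reshape
promoters? The package answers such questions for any focal-vs-comparator
species design, working at the level of orthology groups (OGs) so species
with different gene copy numbers stay comparable.

## What it computes

- **Copy-number divergence.** Per OG, `MΔ = mean(copies, focal group) −
  mean(copies, comparator group)` after a fragmentation-correction filter
  (genes covering < 60% of the reference-species ortholog are dropped).
  OGs with `MΔ ≥ 1` are *duplicated*, `MΔ ≤ 0` *background*, the rest
  intermediate and excluded from two-class tests.
- **Cross-species differential expression.** Per-species counts → cpm →
  summed per OG → low-expression filter → TMM normalization → common and
  tagwise negative-binomial dispersions (Cox-Reid adjusted profile
  likelihood) → NB GLM likelihood-ratio test (χ², 1 df), BH FDR, calls at
  `|log2FC| ≥ 1` and `FDR ≤ 0.05`.
- **Preranked gene-set enrichment.** Scores `±(1 − p)` signed by log2FC,
  the unweighted ("classic") running-sum ES, gene-label permutations,
  meandiv-normalized NES, and pooled-null FDR q (floored at 1/n_perm).
- **Tissue specificity.** `τ = Σ(1 − x_i)/(N − 1)` on max-normalized
  TMM-log2-cpm profiles (1 = single tissue, 0 = ubiquitous), compared
  across duplication categories with Wilcoxon rank-sum tests.
- **Promoter binding-site divergence.** 5-kb upstream regions scanned with
  a JASPAR PFM turned into a log-odds PWM; hits thresholded by *exact*
  p-values from a dynamic program over integer-scaled scores; per-gene
  `ΔTFBS = focal hits − median(comparison hits)` and its Fisher
  association with upregulation.
- **Synthetic data.** A generator that reproduces this whole statistical
  structure (planted duplications with dosage effects, planted DE,
  tissue-specific genes, planted promoter motifs, enriched gene sets) with
  a ground-truth manifest, so every stage is testable by parameter
  recovery.

## Worked example

Simulate a full study-shaped dataset and run the pipeline:

```python
from orthodelta.simulate import SimConfig, simulate_all
from orthodelta.expression import de_pipeline
from orthodelta.orthology import copy_number_matrix, mean_delta, classify_duplication
from orthodelta.enrichment import rank_scores, permutation_nes, \
    duplication_set_enrichment, duplication_expression_association

cfg = SimConfig(seed=42)                      # 2000 OGs, 5/4/15 replicates
out = simulate_all(cfg, "demo")               # writes TSV/FASTA/GMT/JSON
table = out["orthology"]

de, info = de_pipeline(out["counts"], out["metadata"], table.gene_to_og(),
                       "focal", "comparator")
copies = copy_number_matrix(table)
md = mean_delta(copies, cfg.species_groups["focal"],
                cfg.species_groups["comparator"])
dup = classify_duplication(md)

gsea = permutation_nes(rank_scores(de), out["gene_sets"], n_perm=1000, seed=42)
print(info["n_ogs_tested"], info["dispersion"].common)
print(de["de_class"].value_counts().to_dict())
print(dup.counts)
print(gsea.table)
print(duplication_set_enrichment(dup, out["gene_sets"]["mito_like"]).pvalue)
print(duplication_expression_association(dup, de).pvalue)
```

Output (seed 42):

```
2000 0.09330668970753418
{'ns': 1610, 'up': 287, 'down': 103}
{'duplicated': 300, 'background': 1700, 'intermediate': 0}
                size      es     nes  pvalue   fdr_q
mito_like        308  0.2224  4.2164  0.0010  0.0010
random_control   300 -0.0398 -0.7404  0.8277  0.8255
2.14e-19
1.74e-174
```

Reading it: all 2000 simulated OGs survive the expression filter and the
common dispersion estimate (0.093) recovers the simulated value (0.1).
The planted dosage effect makes duplicated OGs upregulated, so the
"mito-like" set — built to over-represent duplicated OGs at odds ratio 3 —
comes out strongly enriched (NES 4.2, q at the 1/1000 permutation floor)
while the random control does not; the Fisher tests confirm both the
duplication–gene-set association and the duplication–upregulation
association. The matching ground truth lives in `demo/truth.json`.

A thin CLI wraps the same functions: `orthodelta simulate|copynumber|de|
gsea|tau|tfbs --help`.

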