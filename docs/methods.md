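# Methods

## Overview

`orthodelta` implements a comparative framework for asking whether
lineage-specific gene duplication in a focal clade (the motivating case is
the hemoglobinless Antarctic icefish versus red-blooded notothenioids) is
linked to transcriptome divergence: more copies, higher expression (a dosage
effect), narrower expression breadth, and promoter divergence in
transcription-factor binding-site counts. All cross-species comparisons are
made at the level of orthology groups (OGs) — clusters of genes descended
from one ancestral gene, as produced by standard orthology inference — so
that species with different copy numbers remain comparable.

## Copy-number divergence

Copy counts per OG and species are simple gene-list lengths after a
fragmentation-correction filter: genes whose protein covers less than a
minimum fraction (default 0.60, boundary inclusive) of the reference-species
ortholog are removed, because fragmented assemblies split genes into
multiple partial models and inflate apparent copy number. Genes with no
coverage record are treated as unalignable and removed with a warning.

Divergence per OG is the mean copy-number difference

    MDelta = mean(copies, focal group) - mean(copies, comparator group),

with means over *all* group members (an absent species contributes zero
copies; the alternative — averaging over present species only — is not
offered, since absence in a high-quality assembly is itself signal).
OGs are classified duplicated (MDelta >= 1: at least one extra copy on
average in the focal lineage), background (MDelta <= 0), or intermediate
(0 < MDelta < 1, excluded from two-class association tests). Both
thresholds are parameters: a laxer "duplicated" rule of MDelta > 0 is
obtained by setting `dup_threshold` just above zero.

## Differential expression on OG-summed cpm

Per species, raw counts are scaled to counts-per-million (cpm) and summed
over the member genes of each OG; species matrices are then joined on the
OG universe. OGs with cpm < 1 in more than half of the samples of *every*
species are removed — an OG adequately expressed in at least one species is
kept, which preserves species-specific expression (the stricter any-species
rule is a switch). The summed-cpm matrix is rounded to the nearest integer
and treated as counts on a nominal library of 10^6 per sample. Feeding
summed cpm to a count model is unconventional; rounding plus a fixed
nominal library isolates that choice in one place. A switch keeps real
values instead.

Between-sample normalization is TMM (trimmed mean of M-values), implemented
to match the published algorithm: reference = sample whose upper quartile of
library-scaled values is closest to the mean upper quartile; M (log2 ratio)
and A (mean log2 abundance) computed over rows nonzero in both sample and
reference; 30% double-sided trim on M and 5% on A; factor = 2^(inverse
asymptotic-variance weighted mean of retained M); factors rescaled to
geometric mean 1. The test suite verifies agreement with edgeR's
`calcNormFactors` to 1e-6 on a fixture.

Dispersion is estimated by Cox-Reid adjusted profile likelihood (APL) under
the one-way group-means NB model: the common dispersion maximizes the APL
summed over OGs (golden-section search on log10 dispersion over
[1e-6, 5], ~35 iterations, resolution far below 1e-4 on the log scale);
tagwise (per-OG) dispersions maximize the weighted likelihood
`APL_g(phi) + (prior_df / df_resid) * meanAPL(phi)`, an empirical-Bayes
shrinkage toward the common value. `meanAPL` is interpolated with a cubic
spline on a 61-point log grid so the per-OG search stays linear in the
number of OGs; as `prior_df -> infinity` the tagwise estimates converge to
the common one (verified to < 1e-3). Default `prior_df = 10`. No trended
(abundance-dependent) dispersion is fitted.

The two-group test is a likelihood-ratio test between NB log-link GLMs with
and without the group effect, offsets `log(library * TMM factor)`. Because
the design is one-way, the alternative model separates into one intercept
per group, fitted by vectorized Fisher scoring (max 50 iterations, step
tolerance 1e-10, steps clipped at +-5 on the log scale). The statistic is
referred to chi-square with 1 df. log2FC is the log2 ratio of the
offset-adjusted fitted group means; when a group total is zero, both group
means are recomputed with 0.125 pseudo-counts per observation so the fold
change stays finite (a continuity rule, not shrinkage — it only engages at
the boundary). Multiple testing uses Benjamini-Hochberg; an OG is called
up if logFC >= 1 and FDR <= 0.05, down if logFC <= -1 and FDR <= 0.05
(bounds inclusive).

The intended study design runs this twice: focal group (5 replicates)
against the pooled outgroup (3 species x 5 replicates) and against the
comparator group (4 replicates). The pooled comparison is a plain two-group
contrast; species is not modeled as a blocking factor.

## Preranked enrichment

Ranking score: `1 - p` for logFC > 0, `-(1 - p)` for logFC < 0, 0 at
logFC = 0; sorted descending with ties broken by OG id so permutation nulls
are reproducible. The enrichment statistic is the unweighted ("classic")
running sum — hits add 1/Nh, misses subtract 1/(N - Nh) — and ES is the
maximum-magnitude deviation (positive wins an exact magnitude tie). The
null is n_perm (default 1000) random placements of the set's labels.
NES divides ES by the mean of same-sign permuted ES ("meandiv"); the
nominal p is the same-sign permutation tail; FDR q compares the observed
NES against the pooled permuted NES of the same sign, per the standard
preranked recipe. Permutation p and q are floored at 1/n_perm and never
reported as 0. Sets that miss the ranked universe entirely, or cover it
entirely, are skipped with a report.

## Tissue specificity

tau = sum_i (1 - x_i) / (N - 1) on max-normalized profiles; 1 means
single-tissue, 0 ubiquitous. Inputs are TMM-normalized log2 cpm clipped at
0 (tau assumes non-negative components; a log2(cpm + 1) offset is a
config option), with replicates averaged per tissue first. All-zero
profiles are excluded with a report. tau is computed per gene; categories
(duplicated-OG member / non-duplicated multi-copy member / strict
one-to-one ortholog) attach through OG membership, and category medians are
compared with pairwise Wilcoxon rank-sum tests. Note that on log2 cpm the
index cannot reach 1 for genes with appreciable baseline expression — the
analytic limits hold for the index itself, not for log-compressed
pipelines.

## Promoter binding-site divergence

Promoters are the 5 kb immediately upstream of the annotated transcription
start (reverse-complemented for minus-strand genes), truncated and flagged
at contig boundaries. No masking of neighboring genes inside the window is
performed. A JASPAR PFM becomes a log2-odds PWM against a background model
(counts + pseudocount x background; default pseudocount 0.1). The default
background is uniform; a 0-order composition estimated from the scanned
promoter set is available. The exact null distribution of window scores is
computed by dynamic programming over integer-scaled scores (scale 1000,
i.e. scores rounded to 0.001 bits), giving exact p-values and exact
p-to-score thresholds. Scanning reports every window on both strands with
p <= threshold (default 1e-4); windows containing N never match;
overlapping hits are all counted (a greedy non-overlap collapse is a flag).

Per-gene divergence on 1-to-1 orthologs is
`delta = hits(focal) - median(hits across comparison species)` (plain
difference for a single comparison species). Association with expression is
a one-sided Fisher test of (delta >= k) x (upregulated), where upregulated
means logFC > 0 with raw p <= 0.05 and significantly downregulated genes
are excluded; k = 1 and 2 are both reported by default.

## Statistics layer

Fisher's exact test (hypergeometric; conditional-MLE odds ratio; two-sided
by the minimum-likelihood rule), Wilcoxon rank-sum (exact enumeration when
n <= 20 and tie-free, otherwise normal approximation with tie and
continuity corrections) and BH step-up. Association tests default to
one-sided "greater" because the hypotheses are directional; this is a
declared choice, recorded in every report, not an inference about any
particular study's practice.

## Synthetic data

The generator reproduces the statistical structure the pipeline assumes,
not any real dataset:

- 2000 OGs across 5 species groups (2 focal, 2 comparator, 3 outgroup);
  15% of OGs carry 1-3 extra copies in both focal species; 5% carry an
  ancient duplication shared by all species (2 copies everywhere,
  MDelta = 0) so the non-duplicated multi-copy gene category is populated.
- NB counts (dispersion 0.1) around lognormal baselines (meanlog 4,
  sdlog 1.5 on the count scale), library sizes uniform in [8e5, 1.2e6];
  5 replicates for focal and outgroup sample groups, 4 for the comparator —
  the sample-size regime of the motivating study design.
- Dosage: a duplication with k extra copies multiplies the focal OG-level
  mean by 2^(dosage_logfc x k), spread evenly over the copies (expression
  is measured on summed-OG cpm, so the effect is modeled at the OG level).
  The magnitude (default 1.0 log2 per extra copy) is a free parameter —
  no literature estimate is implied.
- Independent DE: 10% of non-duplicated OGs get |log2FC| uniform in [1, 3]
  with random sign, applied to the focal species.
- Tissue panel: 5 tissues x 3 replicates for the first focal species; 20%
  of genes are tissue-specific (planted preferentially in duplicated OGs at
  odds ratio 3, so the breadth comparison has planted signal), boosted
  2^4 in exactly one tissue.
- Promoters: uniform background bases over 5 kb for all 1-to-1 OGs in the
  first focal species, the first comparator species and all outgroup
  species; every gene gets 1 planted motif occurrence (sampled column-wise
  from the PFM) and focal copies of planted-upregulated genes get 2 extra,
  at non-overlapping positions recorded exactly in the manifest. The
  default motif is a sharp 10-bp GABPA-like PFM (dominant base 197/200)
  so sampled occurrences score near consensus.
- Gene sets: a "mito-like" set over-representing duplicated OGs at odds
  ratio 3 (expected size 300) plus a same-size random control.

Every artifact draws from its own random stream derived from the master
seed, so adding one artifact never perturbs another, and identical
configurations produce byte-identical files.

What the generator does *not* emulate: read-level noise and mapping
artifacts, assembly fragmentation (beyond accepting a coverage table),
phylogenetic correlation between species, trended dispersion,
non-uniform promoter composition, and overlapping genes. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to every property of real data.

## Validation problem sizes

The test suite validates against independent oracles (hypergeometric and
rank enumeration, prefix enumeration for ES, an all-window scorer for
scans, edgeR's TMM) at small fixture sizes, and runs parameter-recovery
and calibration simulations at the generator's default scale: dispersion
recovery and null type-I error on 2000 OGs with 2x5 samples; association
power over 100 seeded replicates of the full synthetic pipeline. The
planted-logFC recovery simulation turns off copy-number planting so the
estimate is not confounded by the composition shift that planted dosage
induces in library-normalized data; with dosage active the same recovery
is biased low by roughly 0.2 log2 units, which is expected behavior of
normalization, not an estimation defect.

## Known limitations

- The NB LRT is slightly liberal at small sample sizes (type-I error near
  0.06 at n = 5 + 5 in the calibration simulations), as is typical for
  likelihood-ratio tests with plug-in tagwise dispersions.
- The DP score distribution is exact only on the integer grid; scores are
  rounded to 0.001 bits before thresholding (scale configurable).
- GSEA FDR q follows the pooled-null preranked recipe; with few sets the
  pooled estimate is coarse.
- The 5-kb promoter window may overlap neighboring genes; no masking is
  attempted.
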