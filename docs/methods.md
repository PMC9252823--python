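# Methods

## Problem and model

Secondary metabolites such as antibiotics are encoded in biosynthetic gene
clusters (BGCs) that are frequently silent under laboratory conditions.
Comparative RNA-seq — the same strain under different physiological
conditions, or genetic variants of it — reveals which genes move together
with a cluster of interest, and genes with regulatory, transport,
resistance or precursor-supply functions that co-vary with the cluster are
the natural candidates for overexpression engineering. `bgcoex` implements
the analytical core of that workflow: normalization, per-contrast fold
changes, cluster-level aggregation against a reference expression level,
and a co-expression score that ranks every gene in the genome against the
cluster.

The pipeline consumes a featureCounts-style per-gene count matrix, a gene
catalog (GFF3 or TSV), cluster definitions with a core-biosynthetic subset,
an optional functional annotation table and housekeeping list, and an
experiment design that names ordered condition contrasts ("experiments").
Upstream read processing (trimming, alignment, counting) and annotation
(BGC prediction, essential-gene HMM search, KEGG mapping) are out of scope;
their outputs are inputs here.

## Normalization

**TPM.** For gene g with count c and length L (bp) in a sample,
`TPM = (c/L) / Σ(c'/L') × 10⁶`. Per-sample TPM columns sum to one million;
a fully unexpressed sample is defined as all-zero rather than NaN. The
length is the annotated gene span unless the input carries an explicit
`Length` column (featureCounts exon-union lengths), which wins.

**Size factors.** Median-of-ratios: genes with nonzero counts in every
sample get a cross-sample geometric-mean reference (computed in log space
for overflow safety); a sample's factor is the median over those genes of
count/reference. Factors are *not* rescaled to geometric mean 1 — only
ratios of factors matter downstream, and the unnormalized contract is
simpler to test. A consequence worth noting: scaling one sample's counts by
k scales every factor by a common k^(1/n) through the reference, so the
scale-equivariance that holds exactly is for factor ratios
(factor_s/factor_t), not individual factors. When no gene is nonzero
everywhere the factors are undefined; an optional pseudocount mode (+1 to
all counts) is offered instead of silently guessing.

## Fold changes

The built-in estimator divides counts by their sample's size factor,
averages per condition (arithmetic mean over replicates), and reports

    log2fc = log2(mean_B + pc) − log2(mean_A + pc)

with pseudocount `pc` (default 1 normalized count). Computing the
difference of logs rather than the log of the ratio makes contrast reversal
negate every value bit-exactly. Genes with `mean_A + mean_B < min_count`
(default 10) are flagged not-expressed and excluded from cluster averages
and scoring; their fold changes are written as `NA`, never as silent
zeros. This estimator is intentionally a ranking device, not inference: no
dispersion estimation, shrinkage or p-values. Where calibrated inference
matters, externally computed tables (e.g. DESeq2 results exports) are
imported verbatim via `import_de_table` / the `score` subcommand, with
`padj` passed through untouched.

## Cluster aggregation and the expressed label

A cluster is represented by the arithmetic mean over its *core
biosynthetic* genes: mean TPM per condition for expression level, mean
log2 fold change (equivalently the geometric mean of linear fold changes —
chosen so up- and down-regulation average symmetrically) per experiment for
regulation. Zero-TPM core genes are included in expression means — a
silent gene should drag the cluster mean down — while fold-change means
skip filtered genes, and an experiment with no evaluable core gene yields a
missing marker, not zero.

Because no exact TPM threshold separates expressed from silent clusters,
the label is relative: cluster TPM is divided by a reference level — the
mean TPM of housekeeping genes (`hk`), of all other genes (`non_hk`), or of
all genes (`all`) — and the cluster is called expressed when the ratio
reaches a user multiplier (default 1.0, boundary inclusive). References are
compared at per-*condition* TPM means (per-sample means averaged over the
condition's samples); per-sample values are also exposed. Housekeeping
genes are supplied as a list (they come from reference-set-specific
essential-gene HMM searches, which are external to this package).

## Co-expression score

For a gene g and selected experiments E,

    score(g) = Σ_{e∈E} bgc_log2fc_e × gene_log2fc_e .

Both factors are log2 fold changes: on the linear scale two strong
down-regulations would multiply to a small positive number, destroying the
sign semantics; on the log2 scale co-directional regulation contributes
positively and opposite regulation negatively, so score > 0 marks
concordantly and score < 0 discordantly co-regulated genes. Experiments
where the gene is filtered contribute 0 and are dropped from the gene's
"combination" (the experiments actually backing its score); a gene with no
evaluable experiment is omitted. Cluster member genes are excluded from
target tables by default (engineering targets lie outside the cluster).
Concordant tables sort by score descending, discordant ascending, ties by
gene id; filters select one functional category or genes sharing ≥1 KEGG
pathway with any cluster member. The score attaches no significance — a
high score flags parallel expression changes, not a proven association.

## Synthetic data generator

The generator emulates the comparative designs the pipeline targets — and
is also the package's test bed. Defaults, fixed once as the reference
study conditions: 1000 genes on one contig (lengths uniform 300–5000 bp,
100 bp gaps); one control plus four treatment conditions, 3 replicates
each, experiments e_j = ctrl vs t_j; counts negative binomial with
variance μ + μ²/k, k = 10; baseline means log-normal(ln 100, 1);
per-sample library factors log-normal(0, 0.1) so size-factor estimation is
exercised; a 10-gene cluster (5 core) with log2 effect +2 in every
treatment; 10 concordant satellites (same signed effects) and 10
discordant (negated); 50 housekeeping genes with zero effect; default
seed 1 fixes all randomness.

Two deliberate departures from a pure log-normal draw: planted genes
(cluster and satellites) take baselines from the upper half of the baseline
distribution — planted co-regulated pathway genes are meant to be genuinely
expressed, not buried below the count filter — and housekeeping genes from
the top quartile, with NB size k multiplied by a stability factor (default
5), reflecting that essential housekeeping genes are constitutively and
stably expressed. What the generator does **not** emulate: operon/
positional correlation, condition-specific library composition effects,
overdispersion heterogeneity across genes, and partial co-regulation.
Passing recovery tests therefore demonstrate correctness of the scoring
machinery under the assumed NB model, not performance on real transcriptomes.

## Numerical and interface choices

- Coordinates 1-based inclusive throughout (GFF3 convention).
- Sample ids from count headers are normalized by stripping directories and
  a trailing `.bam`, so designs can be written against clean names.
- Unknown genes in the functional map warn; unknown genes in cluster
  definitions are errors (they would corrupt core-gene averages).
- All output floats print with 6 significant digits; output tables are
  byte-deterministic and round-trip exactly (write → read → write is a
  fixed point), which the regression tests rely on.
- Counts are validated as integers but stored as floats to admit the
  pseudocount mode.
- Tie-breaks in rankings are lexicographic on gene id.

## Problem sizes

Tests and the acceptance script run the full pipeline on the default
1000-gene, 15-sample simulation, plus 1000 random small matrices for TPM
conservation and 50-gene instances for the loop-oracle comparisons; the
whole suite completes in well under a minute on one CPU.

## Known limitations

The built-in fold-change estimator is unshrunken; at low counts its
variance is controlled only by the pseudocount and the expression filter.
The expressed label depends on the supplied housekeeping list and carries
no uncertainty. Scores are not comparable across datasets with different
experiment counts (they grow additively). Automatic cluster-boundary
refinement and co-expression-network methods (e.g. correlation mining) are
out of scope.
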