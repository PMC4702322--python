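# Methods

## Count model

Read counts for gene *i* in sample *k* are modeled as negative binomial,
`x_ik ~ NB(μ_ik, σ²_ik)` with the quadratic mean–variance law
`σ² = μ + μ²φ_i` and a log link on the mean. The per-gene dispersion φ_i is
estimated once and then held fixed while nested models in the three crossed
factors — sex (S), genotype (G), environment (E) — are compared by
likelihood ratio. The statistic is the difference of residual deviances of
the reduced and full fits; it is identical whether "deviance" is measured
against the saturated model or as −2·log-likelihood, since the saturated
term cancels in the difference. Reference distribution: χ² with degrees of
freedom equal to the difference in estimated coefficients after aliased
columns are dropped (pivoted-QR rank detection).

The model ladder is

    Model 1:    β₀ + S + G + E
    Model 2(a): Model 1 + G×E
    Model 2(b): Model 2(a) + G×S
    Model 2:    Model 2(b) + E×S
    Full:       Model 2 + G×E×S

Main effects are tested by dropping each from Model 1. First-order
interactions are tested three ways: `sequential` walks the ladder rung by
rung; `add_one` adds each interaction alone to Model 1; `drop_one` removes
each from Model 2. The first rung of the sequential ladder coincides with
`add_one` for G×E and the last with `drop_one` for E×S, which the tests
assert as exact (1e-10) gene-wise identities. The three-way term always
compares the full model to Model 2. BH FDR is applied within each term
across genes — per-term and global correction differ, and the per-term
choice matches how the per-term gene counts are reported downstream.

### Fitting

Fitting is IRLS at fixed φ, vectorized across genes in blocks; every gene
shares the design matrix but carries its own working weights, so the normal
equations are solved as batched matrix products with a 1e-10 ridge, with
step-halving on deviance increase, convergence at a 1e-10 relative deviance
change, and fitted means floored at 1e-8. Genes that fail to converge are
flagged rather than dropped. A per-gene statsmodels GLM (NegativeBinomial
family at the same α) is the independent oracle in the test suite; the two
routes agree in deviance to ~1e-5 on random inputs.

For purely factorial models without per-sample offsets the fitted mean is
constant within each G×E×S cell, so the likelihood depends on the data only
through per-cell count sums. The engine exploits this: fitting operates on
cell aggregates (exactly — the tests verify equality of LRT statistics with
the sample-level route), the cost becomes independent of the number of
replicates per cell, and the model containing all interactions is the
cell-saturated model whose MLE is the cell mean in closed form (the NB
score equation at fixed φ reduces to Σ(y − μ) = 0 within a cell). The
sample-level IRLS path remains for offset mode and extra covariates
(RUVg factors).

### Count input modes

Count engines expect integers, so normalized values enter the NB GLM as
counts rounded half-to-even (`rounded` mode, the default, reproducing the
common practice for methods like RPKM and Q that have no per-sample scale
factor). For scale-factor methods the statistically cleaner `offset` mode
is also available: raw counts with ln(scaling factor) per-sample offsets.
In offset mode dispersions are estimated from scale-adjusted values so that
depth variation is not mistaken for biological overdispersion.

### Dispersion estimation

The raw per-gene estimate is method-of-moments on within-cell replicate
variation: pooled within-cell variance V and grand mean m give
`φ_raw = max(0, (V − m)/m²)`. A trend `φ(μ) = a₀ + a₁/μ` is fitted by
robust (Huber) regression over genes with positive raw estimates and mean
at least 5 — near-zero means give the 1/μ regressor unbounded leverage, and
without the floor a handful of barely expressed genes steer the trend for
every gene (noticeably destabilizing Workflow-2 refits). Two final rules:

- `trend_max` (default): φ = max(raw, fitted) — the conservative
  greater-of rule.
- `eb_shrink`: φ = w·fitted + (1−w)·raw with w = n₀/(n₀ + residual df),
  prior weight n₀ = 10 — an empirical-Bayes-style shrink toward the trend,
  not a re-implementation of any specific package's estimator.

Dispersion is estimated once per gene on the matrix the workflow defines
and reused for every nested test of that gene.

**Calibration caveat.** With the dispersion fixed at its true value the
deviance LRT is slightly anticonservative for high-df terms at small
per-cell replication: at a 4×3×2 design with n = 4 the three-way term
(df = 6) has empirical size ≈ 0.06–0.07 at nominal 0.05, converging to
0.05 by n = 16. This is a finite-sample property of the χ² reference shared
by the standard fixed-dispersion NB LRT implementations, not of this
engine; quasi-likelihood F corrections are out of scope. With
pipeline-estimated `trend_max` dispersions the tests instead run slightly
conservative (size ≈ 0.035–0.05), and BH keeps the null significant
fraction at zero in practice.

## ln & ANOVA engine

The normal-theory alternative fits, per gene, a fixed-effects linear model
to ln(normalized count + 1) with all seven terms, sum-to-zero coded, and
tests each term by partial (Type III) sums of squares — appropriate for the
unbalanced designs that QC exclusion produces; on balanced data Type III
and sequential F statistics coincide, which the tests assert. Genes with no
residual variation report p = 1 by contract.

## Normalization

TC, UQ and Med divide each sample by a ratio: library size / mean library
size; upper quartile / mean upper quartile; median / mean median — the
latter two computed after removing genes with zero counts in every sample.
Quantiles use linear interpolation between order statistics (type 7)
throughout the package. DESeq size factors are the median, over genes
positive in all samples, of the ratio of counts to the per-gene geometric
mean (median taken in ratio space; the log-space median differs for even
gene counts). Output is x/s_k with no further library rescale. TMM trims to
the middle 40 % of M-values and the middle 90 % of A-values (intersected),
weights by inverse approximate asymptotic variance, and takes
factor = 2^(Σ wM / Σ w) against a reference sample chosen as the one whose
upper quartile is closest to the mean upper quartile (ties to the lowest
index); factors are recentred to geometric mean 1 by default (switchable),
and normalized counts are divided by factor·N and rescaled by the mean
normalized library size to stay count-like. Quantile normalization assigns
the mean sorted profile by rank, with ties receiving the mean of the target
values their positions span (deterministic and order-independent). RPKM is
x·10⁹/(N·length). RUVg extracts k sample-wise singular factors from the
row-centred log(x+1) spike-in submatrix, for use as model covariates; it is
a minimal factor construction, off by default downstream.

Library sizes N_k default to the genic column sums of the input matrix and
are then frozen: Workflow 2's re-normalization sees the same N_k, so
total-count scaling is filter-invariant by construction while
quantile/median-based factors shift — the mechanism behind the
filter-sensitivity pattern the acceptance tests measure.

## Thresholding and workflows

Genic and intergenic rows are normalized jointly (per method), and the
detection threshold is the chosen percentile (default 95th) of the pooled
intergenic values on the log₂(normalized + 1) scale. Intergenic features
shorter than the read length (default 76 bp) are excluded — they cannot
carry uniquely mapped reads. Pooling across samples yields a single scalar
threshold per method; a gene is removed only if it is below threshold in
*every* sample. Workflow 1 normalizes, estimates distribution parameters on
the unfiltered matrix, then filters; Workflow 2 filters first (using the
same threshold) and re-normalizes the remaining genes; Workflow 3 never
filters. Intergenic rows never enter DE fitting.

## Sample QC

Genotype: r_ij = D_ij/M_ij over SNP sites where both the sample and the
candidate line have calls (missing calls excluded pairwise, so r stays a
ratio of comparable sites); R_ij = 1 − (r − min)/(max − min) per sample;
assignment to the line with R = 1, a tie flag when several lines attain the
minimum, and a pass flag at r ≤ 0.10. Sex: per-gene median expression
standards per sex, Spearman correlation (average ranks) of each sample
against both standards, pass at same-sex correlation ≥ 0.795 (a default
inherited from large-study calibration; at synthetic scale the tests
re-derive the cutoff from the two correlation distributions). The standard
for a sample's own sex is computed leaving that sample out by default —
negligible at hundreds of samples per sex, material at synthetic scale.
Duplicate libraries: per-gene NB LRT of log μ = β₀ + F (F = individual)
against the intercept, with spike-ins summarized separately and per-fly
absolute raw-count differences reported.

## Power

For the balanced a×b×c ANOVA the three-way F test has noncentrality
λ = n·Σ(αβγ)²_ijk/σ², equivalently φ² = λ/[(a−1)(b−1)(c−1)+1], with
df₁ = (a−1)(b−1)(c−1) and df₂ = abc(n−1). With d = D/σ, D the ln-scale
range of cell means, the minimum λ over patterns of range D is nd²/2, so
power computed at λ_min is conservative; the detectable D at target power
(default 0.80, α = 0.05) is found by bracketed root-finding (1e-8).
First-order variant: df₁ = (a−1)(b−1) and effective replication cn. D is
carried on the ln scale with exp(D) reported alongside; σ² is a pooled
scalar input (the acceptance script estimates it from the synthetic study's
own within-cell ln-scale mean squares, over genes with mean count ≥ 10).
α for the curves is 0.05, exposed in the spec object. The empirical
counterpart subsamples flies without replacement within cells, reruns the
NB analysis, and reports the percentage of the full data set's significant
genes recovered per term and FDR threshold.

## Agreement

"Percentage of agreement" between two significant-gene sets defaults to the
Jaccard percentage 100·|A∩B|/|A∪B|, with both directed recalls always
reported, since any of the three supports the directional conclusions
drawn. Two empty sets agree at 100 (two null results). The PCA diagnostic
takes the first two components of the centred log₂(normalized+1) matrix
(samples as observations) and scores sex separation by the silhouette of
the two sexes along PC1.

## Synthetic data generator

The generator emulates the study structure end to end: a (default 16)
genotypes × b (3) environments × c (2) sexes with up to 8 replicates per
cell; heavy-tailed baseline expression (ln-mean Normal(3, 1.8), so a small
gene set carries a large share of reads) plus a 20 % block of genes near
the detection limit (ln-mean Normal(0, 1)) so that low-expression filtering
has something to act on; log-normal dispersions (median 0.15, σ_log 0.6,
the range typical of replicated fly data); library-size factors log-normal
(σ 0.25); 32 spike-in rows whose means are independent of the biology;
intergenic background as per-feature Poisson with a per-kilobase
exponential rate (reads accrue with region length, and some regions are
shorter than the read length to exercise the validity filter); duplicate
libraries for 5 % of individuals. Counts are drawn gamma–Poisson: each
fly's biological intensity t ~ Gamma(1/φ, μφ) and each of its libraries
~ Poisson(s_k·t), which realizes σ² = μ + μ²φ exactly and lets duplicate
libraries share biology while resampling only technical noise.

Differential expression truth: per term, a configured fraction of genes
receives an effect pattern built from random ±(effect/2) assignments,
projected onto the pure-interaction subspace (zero margins) and rescaled so
the realized max−min equals the configured ln-scale effect size — aligning
the truth with the d = D/σ convention of the power analysis. Effect-size
defaults: 2.0 (ln) for sex, 1.0 for the other terms; DE fractions 0.30
(S), 0.20 (G), 0.15 (E), 0.05 per interaction — sex-dominated, as in adult
whole-fly expression. One global seed feeds independent spawned streams per
component (effects, counts, library factors, features, SNPs) so stages are
reproducible in isolation.

What the generator does not emulate: read-level artifacts (mapping bias,
GC/length bias beyond the length field RPKM uses), batch/flow-cell
structure, correlated gene–gene expression, and annotation errors. Passing
tests therefore demonstrate correctness of the statistical machinery and
the direction of method sensitivities under the assumed NB model, not
performance on any particular real data set; quantities like the per-method
thresholds or detectable fold-changes are properties of the simulated
noise level, not of real libraries.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: 2000
genes for calibration and recovery studies, the full 16×3×2 factor grid
with 3 replicates per cell for the workflow-sensitivity comparisons (10
seeds, sign test), 8 replicates per cell for the subsampling-power study
(cell aggregation makes fitting cost independent of replication), and 10⁵
Monte-Carlo replicates for the power cross-validation. Full-pipeline runs
are byte-reproducible under a fixed seed; result tables are TSV with
repr-precision floats to keep them diffable.
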