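# Methods

## Discovery model

A reference gene should be (i) weakly variable across conditions and
(ii) approximately normally distributed — systematic condition effects
(tissue, stress, genotype) show up either as inflated spread or as
multimodal/skewed profiles. Each gene with at least three samples and a
positive median is therefore scored by:

* **CV** — sample standard deviation (ddof = 1) over the mean. We use the
  conventional σ/x̄ orientation: stable genes have *low* CV.
* **nMAD** — median absolute deviation about the median, divided by the
  median. The 1.4826 normal-consistency constant is *not* applied; the
  statistic is used as a relative spread measure, not as a σ estimator.
* **1 − p** from the Shapiro-Wilk test on the raw expression values (a
  `log_transform` flag applies log2(x+1) first; off by default). Valid
  for 3 ≤ n ≤ 5000 non-constant samples; p < 0.05 flags non-normality.

### Scaling of the three parameters

CV and nMAD are z-scored across genes (sample SD). The 1 − p column is
kept **raw** by default. This was a genuinely open design choice, and the
reasons for the raw default are worth recording:

1. 1 − p already lives on a calibrated, dimensionless [0, 1] scale;
   z-scoring is only needed for the unbounded spread statistics.
2. Standardizing 1 − p is degenerate in exactly the regime the screen
   targets: in a genome-scale matrix most genes reject normality hard, so
   the column piles up at 1 with a tiny SD. Dividing by that SD stretches
   the minority of near-normal genes (p uniform under the null) into a
   needle of 10+ standard deviations along one axis — the stable genes
   then cannot form a compact cluster, and their distance ranking is
   dominated by p-value noise. Empirically (5,000-gene planted matrices),
   planted-reference recovery is 0–75% with the z-scored column and 100%
   with the raw column, across seeds.

`compute_gene_scores(zscore_one_minus_p=True)` provides the fully
standardized variant; with it the score table's three z-columns each have
mean 0 and sample SD 1 to 1e−9.

### Clustering and selection

PAM (k-medoids) under Euclidean distance, chosen over k-means so outlier
genes cannot drag cluster centers. The implementation is deterministic:
greedy BUILD initialization (first medoid minimizes total distance, each
further medoid maximizes cost reduction) followed by best-improvement
SWAP until no exchange reduces cost by more than 1e−12; all ties break
toward lower indices. Cost is non-increasing and strictly decreases at
every accepted swap, so termination is guaranteed. Above
`clara_threshold` (default 5,000) points, a CLARA scheme clusters five
fixed-seed subsamples of size 1000 + 2k and keeps the medoid set with the
lowest full-data cost.

k is selected by mean silhouette width over k ∈ {2, …, 10} (singleton
clusters contribute s = 0; ties go to the smaller k). The **stable
cluster** is the one whose medoid is component-wise minimal in all three
parameters; when no medoid dominates, the fallback is the smallest medoid
norm, ties to the lower label. Members are ranked ascending by
d = √(z_CV² + z_nMAD² + (1 − p)²), ties broken by gene id, and the top
100 kept.

The GO filter excludes candidates annotated to the nucleus
(cellular_component GO:0005634 or a label containing "nucleus") or to
translation (biological_process GO:0006412 or a label containing
"translation") — such genes are transcription/translation machinery whose
expression responds to the very perturbations being studied. Matching is
flat: no ancestor closure over the ontology graph is performed (no
ontology-file dependency), so an annotation to a *descendant* term with a
different label escapes the filter. Genes without GO records are kept and
flagged `unannotated`.

## qPCR model

ΔCq is referenced to the per-gene mean NTC Cq (ΔCq = Cq − mean NTC Cq),
and relative expression is E^(−ΔCq) per technical replicate, summarized
per (gene, sample) by the geometric mean. A `calibrator=True` option
substitutes the per-gene minimum Cq (conventional highest-expression
calibrator) when NTC reactions are unavailable. Cq must lie in (0, 45]
(the assay's cycle budget); values above 35 are flagged "no
amplification" but still computed. BestKeeper and ΔCt consume mean Cq per
(gene, sample) instead of relative expression, matching those tools'
native inputs.

* **geNorm**: M_j = mean over partners k of SD across samples of
  log2(x_j/x_k); the highest-M gene is removed until two remain, which
  share rank 1 (rank 3 goes to the last-excluded gene, so rank sums are
  preserved). V(n/n+1) is the SD across samples of the log2 ratio of the
  n- and (n+1)-gene geometric-mean normalization factors, computed along
  the stability ordering.
* **NormFinder**: on log2 expression with two sample groups, per-group
  two-way residuals give a per-gene variance estimate (with the
  small-panel bias inversion σ̂²ᵢ = (uᵢ − ū/(n−1))·n/(n−2), truncated at
  0); the gene × group interaction d̂ᵢg estimates intergroup bias and is
  shrunk by γ̂²/(γ̂² + Var(d̂ᵢg)), where γ̂² is the between-gene bias
  variance. Stability = mean over groups of |d̃ᵢg| + SE of the group
  mean. A single group falls back to the intragroup-only variant with a
  logged notice.
* **BestKeeper**: index = per-sample geometric mean of Cq; per gene the
  SD about the arithmetic mean (the original spreadsheet's descriptive
  statistic is a mean absolute deviation; the standard SD is used here
  and documented as an approximation), CV% and Pearson r against the
  index. Both ranking modes are first-class — descending r and ascending
  SD genuinely disagree, because the index correlation rewards genes that
  *follow* shared sample-to-sample variation while the SD penalizes all
  variation.
* **ΔCt**: stability = mean over partners of the SD of pairwise Cq
  differences.

Ranks use average-tie assignment. The comprehensive ranking (default
`fig6` mode) is the geometric mean of four rank columns — geNorm,
NormFinder, BestKeeper (correlation mode by default, configurable) and a
RefFinder-style column that is itself the geometric-mean rank of {geNorm,
NormFinder, BestKeeper SD-mode, ΔCt}; `reffinder-only` mode uses the last
column alone. A constant gene has undefined r and enters the aggregate
with its SD-mode rank, with a notice.

## Synthetic data

`generate_expression_matrix` plants four classes: *reference_like*
(per-sample normal, gene mean in [10, 200], CV in [0.05, 0.15]),
*variable* (normal truncated at zero with CV in [1.0, 1.2] — the
truncation makes these strongly non-normal, as condition-responsive genes
are), *skewed* (log-normal, σ in [0.75, 0.85], median matched to the same
mean range — chosen so its realized CV overlaps the variable class and
the background stays unimodal), and *low_expressed* (small positive
values with round(0.6·n) zeros per gene, so the median filter removes
them). Defaults: 5,000 genes × 55 conditions, fractions
2% / 58% / 20% / 20%. These parameters were chosen once so the planted
classes are separable by construction — the generator exists to verify
the pipeline's mechanics, and a validation dataset in which the truth is
not recoverable would test nothing.

What the generator does **not** emulate: library-size and length biases,
correlated co-expression modules, a CV-vs-mean trend, or a continuum
between stable and unstable genes. Real screens face exactly that
continuum, so passing the planted-recovery tests demonstrates the
machinery is correct, not that any real matrix contains 100 cleanly
separated reference genes.

`generate_qpcr_dataset` builds Cq = gene base (U[20, 30]) + group shift
(0.3 cycles, group-shifted genes in the second group only) + shared
sample effect (SD 0.3 cycles) + class noise (ultra-stable 0.05, stable
0.15, noisy 0.8 cycles) + replicate noise (SD 0.05), for 7 genes
(2 ultra-stable, 3 stable, 1 group-shifted, 1 noisy), 2 × 8 samples,
3 replicates, efficiencies U[1.9, 2.0], NTC mean 38. Cq outside (0, 45]
is clipped and counted (zero clips under defaults). A single seed drives
a named substream per component, so modifying one noise source never
perturbs the other draws.

## Numerical choices

* Sample (n−1) SD throughout (CV, z-scores, geNorm, BestKeeper, ΔCt).
* Even-length medians are the mean of the central order statistics, which
  decides borderline low-expression cases.
* Zeros are true zeros; no pseudocount anywhere. The low-expression
  filter (median > 0) is the only zero-handling step.
* PAM swap tolerance 1e−12; standard-curve QC bounds carry a 1e−9 guard
  so an exactly doubling curve passes E ≤ 2.0.
* Report TSVs print 6 significant digits; JSON summaries keep full
  precision. Identical inputs reproduce byte-identical reports.

## Known limitations

* The distance ranking measures closeness to the *population average* of
  the three parameters, not to their minimum — it is meaningful inside
  the low-variation cluster, which is why cluster selection precedes it.
* NormFinder and BestKeeper discriminate weakly between noise SDs of
  0.05 and 0.15 cycles at a 7-gene, 16-sample design (few degrees of
  freedom; the σ̂² truncation can flatter a gene; the shared sample
  effect dominates BestKeeper's statistics). Over 300 simulation seeds
  the comprehensive top-2 recovery of the planted ultra-stable pair is
  ≈ 84%, while geNorm and ΔCt alone identify the noisy gene essentially
  always. Larger panels or more samples sharpen all four algorithms.
* GO filtering is flat (no ancestor closure) and label matching is
  substring-based.
* NormFinder follows the cited model-based decomposition but is not
  bit-compatible with any particular legacy implementation; comparisons
  should be at the ranking level.
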