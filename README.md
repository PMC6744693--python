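# normgene

Data-driven selection of reference (housekeeping) genes for qPCR
normalization — for plant molecular biologists and other wet-lab groups
who need stable normalizers for a new tissue panel, stress condition or
transgenic line, and for bioinformaticians automating that screen.

Accurate qPCR quantification stands or falls with the reference gene the
target is normalized against. Instead of recycling the usual suspects
(actin, ubiquitin, tubulin), `normgene` implements an unbiased two-stage
workflow:

1. **Genome-wide discovery.** From a genes × conditions expression matrix
   (FPKM/TPM), each gene is scored by three variation parameters —
   coefficient of variation CV = σ/x̄, the median-normalized MAD
   (median|x − x̂| / x̂), and 1 − p from the Shapiro-Wilk normality test.
   Genes are clustered in this 3-parameter space with PAM (k-medoids,
   deterministic BUILD + SWAP), the number of clusters is chosen by mean
   silhouette width s(i) = (b − a)/max(a, b), the cluster whose medoid is
   lowest in all three parameters is taken as the stable cluster, its
   members are ranked by the Euclidean distance
   d = √(z_CV² + z_MAD² + (1 − p)²), and candidates annotated to the
   nucleus (GO:0005634) or to translation (GO:0006412) are flagged for
   exclusion.
2. **qPCR validation.** Candidate panels are ranked from Cq data by four
   standard stability algorithms — geNorm (mean pairwise SD of log₂
   expression ratios, stepwise exclusion, plus the V(n/n+1) pairwise
   variation), NormFinder (model-based intra/intergroup decomposition on
   log₂ expression, two groups), BestKeeper (Cq SD/CV% and Pearson r
   against the per-sample geometric-mean index; both ranking modes), and
   the comparative ΔCt method — and aggregated by the geometric mean of
   ranks. Relative expression is E^(−ΔCq) with per-gene primer efficiency
   E from the standard-curve slope: efficiency% = (10^(−1/slope) − 1)·100.

A synthetic-data module generates expression matrices and Cq datasets
with planted ground truth (reference-like / variable / skewed /
low-expressed genes; ultra-stable / stable / group-shifted / noisy qPCR
panels), so the whole pipeline is testable without any downloads.

## Worked example

```bash
python examples/qpcr_stability_ranking.py
```

```
gene_id         class  genorm_m  genorm_rank  normfinder_rank  bestkeeper_rank_correlation  delta_ct_rank  reffinder_rank  final_rank
    q01  ultra_stable  0.081723          1.0              1.0                          2.0            1.0             1.0         1.0
    q02  ultra_stable  0.081723          1.0              4.0                          3.0            2.0             2.0         2.0
    q04        stable  0.164179          4.0              3.0                          1.0            4.0             5.0         3.0
    q05        stable  0.127407          3.0              5.0                          4.0            3.0             4.0         4.0
    q06 group_shifted  0.226529          6.0              2.0                          5.0            6.0             6.0         5.0
    q03        stable  0.182739          5.0              6.0                          7.0            5.0             3.0         6.0
    q07         noisy  0.860430          7.0              7.0                          6.0            7.0             7.0         7.0

geNorm pairwise variation V(n/n+1) — values < 0.15 mean n genes suffice:
  V2/3: 0.0403
  ...
```

The two planted ultra-stable genes (q01, q02) head the comprehensive
ranking: their geNorm M ≈ 0.08 (an M below 0.5 marks a usable reference
gene) and they share geNorm rank 1 because the final surviving pair
cannot be ordered further. The noisy gene (q07, M ≈ 0.86) is excluded
first. V2/3 ≈ 0.04 < 0.15 says two reference genes are enough — adding a
third barely changes the normalization factor.

`examples/discover_candidates.py` runs the genome-scale funnel the same
way (it prints the gene-count funnel, the silhouette choice of k, the
cluster medoids and the planted-gene recovery), and
`examples/primer_efficiency.py` shows the standard-curve fit. The same
workflows are available from the shell:

```bash
normgene simulate-expression --seed 1 --out-dir data/
normgene discover --matrix data/expression.tsv --out-dir results/
normgene simulate-qpcr --seed 1 --out-dir data/
normgene qpcr-stability --cq data/cq.csv --efficiencies data/efficiencies.csv --out-dir results/
```

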