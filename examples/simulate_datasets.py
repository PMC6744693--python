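"""Write synthetic datasets to disk in the formats the readers consume.

Produces a small expression matrix TSV (+ truth-label sidecar) and a qPCR
Cq CSV with NTC rows and a per-gene efficiency table — the same files the
`normgene discover` and `normgene qpcr-stability` commands accept.
"""

from pathlib import Path

from normgene import (
    ExpressionSimConfig,
    QpcrSimConfig,
    generate_expression_matrix,
    generate_qpcr_dataset,
)
from normgene.expr_io import write_expression_matrix
from normgene.qpcr_stability import write_qpcr_dataset
from normgene.synthetic import write_truth_labels

out = Path("example_data")
out.mkdir(exist_ok=True)

matrix, expr_truth = generate_expression_matrix(
    ExpressionSimConfig(n_genes=300, n_samples=55, seed=7)
)
write_expression_matrix(matrix, out / "expression.tsv")
write_truth_labels(expr_truth, out / "expression_truth.tsv")

dataset, qpcr_truth = generate_qpcr_dataset(QpcrSimConfig(seed=7))
write_qpcr_dataset(dataset, out / "cq.csv", out / "efficiencies.csv")
write_truth_labels(qpcr_truth, out / "cq_truth.tsv")

for p in sorted(out.iterdir()):
    print(f"wrote {p} ({p.stat().st_size} bytes)")
print("\nnext: normgene discover --matrix example_data/expression.tsv --out-dir results/")
print("      normgene qpcr-stability --cq example_data/cq.csv "
      "--efficiencies example_data/efficiencies.csv --out-dir results/")
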