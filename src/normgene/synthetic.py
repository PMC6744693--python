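"""Synthetic expression matrices and qPCR datasets with planted ground truth.

Every pipeline stage can be validated without external downloads by
generating data whose stable genes are known by construction:

* :func:`generate_expression_matrix` plants four gene classes in an
  FPKM-like matrix — ``reference_like`` (low CV, approximately normal),
  ``variable`` (high CV), ``skewed`` (log-normal with matched median) and
  ``low_expressed`` (a configurable fraction of samples set to zero, so
  the median filter removes them).
* :func:`generate_qpcr_dataset` builds two-group (normal / transgenic
  analog) Cq data with per-gene stability classes, a shared per-sample
  effect, replicate noise, NTC records and primer efficiencies.

A single integer seed drives a named pseudo-random stream per component,
so adding a gene class or tweaking one noise source does not perturb the
other draws — generated datasets are stable regression fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .expr_io import ExpressionMatrix
from .qpcr_stability import CQ_MAX, QpcrDataset

__all__ = [
    "ExpressionSimConfig",
    "QpcrSimConfig",
    "generate_expression_matrix",
    "generate_qpcr_dataset",
    "largest_remainder_counts",
]

GENE_CLASSES = ("reference_like", "variable", "skewed", "low_expressed")

# per-component offsets for named substreams; appending entries is safe,
# reordering is not (it would change existing draws)
_STREAMS = {
    "gene_means": 0,
    "reference_values": 1,
    "variable_values": 2,
    "skewed_values": 3,
    "low_values": 4,
    "zero_positions": 5,
    "qpcr_base_cq": 10,
    "qpcr_sample_effects": 11,
    "qpcr_gene_noise": 12,
    "qpcr_replicate_noise": 13,
    "qpcr_efficiencies": 14,
}

QPCR_CLASS_NOISE_SD = {  # per-class gene-sample noise, cycles
    "ultra_stable": 0.05,
    "stable": 0.15,
    "group_shifted": 0.15,
    "noisy": 0.8,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],)))


def largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer class counts: round(fraction*total) with largest-remainder correction."""
    raw = {k: f * total for k, f in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    by_remainder = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Planted-structure expression matrix configuration.

    Defaults emulate a genome-scale screen scaled to desk size: 5,000
    genes x 55 conditions with 2% reference-like genes (CV 0.05-0.15),
    20% low-expressed genes carrying 60% zeros, and the remainder split
    between high-CV and skewed genes.
    """

    n_genes: int = 5000
    n_samples: int = 55
    fractions: dict = field(
        default_factory=lambda: {
            "reference_like": 0.02,
            "variable": 0.58,
            "skewed": 0.20,
            "low_expressed": 0.20,
        }
    )
    reference_cv_range: tuple[float, float] = (0.05, 0.15)
    variable_cv_range: tuple[float, float] = (1.0, 1.2)
    skewed_sigma_range: tuple[float, float] = (0.75, 0.85)
    mean_range: tuple[float, float] = (10.0, 200.0)
    low_mean_range: tuple[float, float] = (0.1, 2.0)
    zero_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.fractions) != set(GENE_CLASSES):
            raise ConfigurationError(f"fractions must cover exactly {GENE_CLASSES}")
        vals = list(self.fractions.values())
        if any(not 0 <= v <= 1 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError("class fractions must lie in [0,1] and sum to 1")
        if self.n_samples < 3:
            raise ConfigurationError("n_samples must be >= 3")
        if not 0 <= self.zero_fraction <= 1:
            raise ConfigurationError("zero_fraction must lie in [0, 1]")


def generate_expression_matrix(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a planted expression matrix and its truth labels.

    Returns the matrix and a DataFrame (gene_id, class).  Fully
    deterministic in ``config.seed``.
    """
    counts = largest_remainder_counts(config.fractions, config.n_genes)
    n, m = config.n_genes, config.n_samples
    rng_means = _stream(config.seed, "gene_means")

    classes: list[str] = []
    for cls in GENE_CLASSES:
        classes.extend([cls] * counts[cls])
    values = np.zeros((n, m))
    labels = np.array(classes)

    idx = {cls: np.flatnonzero(labels == cls) for cls in GENE_CLASSES}

    # reference-like: normal around a gene mean with low CV, truncated at 0
    ref = idx["reference_like"]
    if ref.size:
        rng = _stream(config.seed, "reference_values")
        means = rng_means.uniform(*config.mean_range, size=ref.size)
        cvs = rng_means.uniform(*config.reference_cv_range, size=ref.size)
        values[ref] = np.maximum(
            rng.normal(means[:, None], (means * cvs)[:, None], size=(ref.size, m)), 0.0
        )

    # variable: normal with high CV (truncation at 0 adds skew, acceptable)
    var = idx["variable"]
    if var.size:
        rng = _stream(config.seed, "variable_values")
        means = rng_means.uniform(*config.mean_range, size=var.size)
        cvs = rng_means.uniform(*config.variable_cv_range, size=var.size)
        values[var] = np.maximum(
            rng.normal(means[:, None], (means * cvs)[:, None], size=(var.size, m)), 0.0
        )

    # skewed: log-normal with median matched to a drawn target median
    skw = idx["skewed"]
    if skw.size:
        rng = _stream(config.seed, "skewed_values")
        medians = rng_means.uniform(*config.mean_range, size=skw.size)
        sigmas = rng_means.uniform(*config.skewed_sigma_range, size=skw.size)
        values[skw] = rng.lognormal(
            np.log(medians)[:, None], sigmas[:, None], size=(skw.size, m)
        )

    # low-expressed: small positive values with round(zero_fraction*m) zeros
    low = idx["low_expressed"]
    if low.size:
        rng = _stream(config.seed, "low_values")
        rng_zero = _stream(config.seed, "zero_positions")
        means = rng_means.uniform(*config.low_mean_range, size=low.size)
        block = np.abs(rng.normal(means[:, None], means[:, None], size=(low.size, m)))
        n_zero = int(round(config.zero_fraction * m))
        for row in block:
            row[rng_zero.choice(m, size=n_zero, replace=False)] = 0.0
        values[low] = block

    gene_ids = tuple(f"gene{i:05d}" for i in range(n))
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=tuple(f"sample{j:02d}" for j in range(m)),
        values=values,
    )
    truth = pd.DataFrame({"gene_id": list(gene_ids), "class": labels})
    return matrix, truth


@dataclass(frozen=True)
class QpcrSimConfig:
    """Two-group qPCR simulation configuration.

    The default design mirrors a small validation panel: 7 genes (2
    ultra-stable, 3 stable, 1 shifted between groups, 1 noisy), 8 samples
    per group in two groups (normal / transgenic analog), 3 technical
    replicates, a shared per-sample effect of 0.3 cycles SD, and
    class-specific gene-sample noise (ultra_stable 0.05, stable 0.15,
    noisy 0.8 cycles).
    """

    gene_classes: tuple[str, ...] = (
        "ultra_stable",
        "ultra_stable",
        "stable",
        "stable",
        "stable",
        "group_shifted",
        "noisy",
    )
    n_samples_per_group: int = 8
    group_labels: tuple[str, str] = ("normal", "transgenic")
    n_replicates: int = 3
    replicate_noise_sd: float = 0.05
    sample_effect_sd: float = 0.3
    group_shift: float = 0.3
    base_cq_range: tuple[float, float] = (20.0, 30.0)
    efficiency_range: tuple[float, float] = (1.9, 2.0)
    ntc_mean_cq: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.replicate_noise_sd <= 0:
            raise ConfigurationError("replicate_noise_sd must be > 0")
        if sum(c == "ultra_stable" for c in self.gene_classes) < 2:
            raise ConfigurationError("at least 2 ultra_stable genes are required")
        unknown = set(self.gene_classes) - set(QPCR_CLASS_NOISE_SD)
        if unknown:
            raise ConfigurationError(f"unknown stability classes: {sorted(unknown)}")
        if self.ntc_mean_cq > CQ_MAX:
            raise ConfigurationError(f"ntc_mean_cq must be <= {CQ_MAX}")


def generate_qpcr_dataset(config: QpcrSimConfig) -> tuple[QpcrDataset, pd.DataFrame]:
    """Generate a planted two-group Cq dataset and its truth labels.

    Cq = gene base + group shift (group_shifted genes, group 2 only)
    + shared sample effect + class-specific gene-sample noise
    + replicate noise.  Values outside (0, 45] are clipped and counted;
    the count is stored on the dataset.  Deterministic in ``config.seed``.
    """
    n_genes = len(config.gene_classes)
    gene_ids = [f"q{i + 1:02d}" for i in range(n_genes)]
    n_per = config.n_samples_per_group
    samples = [
        (f"{grp}_{j + 1:02d}", grp) for grp in config.group_labels for j in range(n_per)
    ]

    rng_base = _stream(config.seed, "qpcr_base_cq")
    rng_sample = _stream(config.seed, "qpcr_sample_effects")
    rng_noise = _stream(config.seed, "qpcr_gene_noise")
    rng_rep = _stream(config.seed, "qpcr_replicate_noise")
    rng_eff = _stream(config.seed, "qpcr_efficiencies")

    base_cq = rng_base.uniform(*config.base_cq_range, size=n_genes)
    sample_effect = rng_sample.normal(0.0, config.sample_effect_sd, size=len(samples))
    noise_sd = np.array([QPCR_CLASS_NOISE_SD[c] for c in config.gene_classes])
    gene_sample_noise = rng_noise.normal(0.0, 1.0, size=(n_genes, len(samples))) * noise_sd[:, None]
    efficiencies = rng_eff.uniform(*config.efficiency_range, size=n_genes)

    records = []
    clip_count = 0
    for i, gid in enumerate(gene_ids):
        for s, (sid, grp) in enumerate(samples):
            mean_cq = base_cq[i] + sample_effect[s] + gene_sample_noise[i, s]
            if config.gene_classes[i] == "group_shifted" and grp == config.group_labels[1]:
                mean_cq += config.group_shift
            for rep in range(1, config.n_replicates + 1):
                cq = mean_cq + rng_rep.normal(0.0, config.replicate_noise_sd)
                clipped = min(max(cq, 1e-6), CQ_MAX)
                if clipped != cq:
                    clip_count += 1
                records.append(
                    {
                        "gene_id": gid,
                        "sample_id": sid,
                        "group": grp,
                        "replicate": rep,
                        "cq": clipped,
                    }
                )
    dataset = QpcrDataset(
        records=pd.DataFrame(records),
        ntc_mean_cq={g: config.ntc_mean_cq for g in gene_ids},
        efficiencies={g: float(e) for g, e in zip(gene_ids, efficiencies)},
        clip_count=clip_count,
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "class": list(config.gene_classes)})
    return dataset, truth


def write_truth_labels(truth: pd.DataFrame, path) -> None:
    """Sidecar TSV (gene_id, class) matching a generated dataset."""
    truth.to_csv(path, sep="\t", index=False)
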