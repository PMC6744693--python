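"""qPCR processing and reference-gene stability ranking.

From quantification-cycle (Cq) data this module computes relative
expression and ranks candidate reference genes with four complementary
stability algorithms plus a geometric-mean aggregate:

* **geNorm** — M_j is the mean, over all partner genes k, of the standard
  deviation across samples of log2(x_j/x_k); the highest-M gene is removed
  iteratively until two remain (which share rank 1).  Pairwise variation
  V_{n/n+1} tracks how much the normalization factor changes when an
  (n+1)-th gene is added.
* **NormFinder** — a model-based estimator on log2 expression that
  separates intragroup variance from intergroup bias (here: two groups,
  e.g. normal vs transgenic); stability combines the shrunken bias
  magnitude with the standard error of the gene's group mean.
* **BestKeeper** — descriptive Cq statistics (SD, CV%) plus the Pearson
  correlation of each gene's Cq with the BestKeeper index (per-experiment
  geometric mean of Cq).  Two ranking modes are first-class because they
  genuinely disagree: "correlation" (descending r) and "sd" (ascending SD).
* **DeltaCt** — mean, over partner genes, of the SD of pairwise Cq
  differences.

Relative expression follows E^(-dCq) with dCq = Cq - mean NTC Cq per
gene; technical replicates are summarized by their geometric mean.  Cq
values above 35 cycles are flagged "no amplification" but still computed;
45 cycles is the hard upper bound of the assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    InputMismatchError,
    InsufficientDataError,
    ParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "QpcrDataset",
    "read_qpcr_dataset",
    "write_qpcr_dataset",
    "primer_efficiency_from_slope",
    "standard_curve",
    "relative_expression",
    "mean_cq_matrix",
    "quality_flags",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_ct",
    "comprehensive_rank",
    "rank_series",
    "GenormResult",
    "BestKeeperResult",
]

logger = logging.getLogger(__name__)

CQ_NO_AMPLIFICATION = 35.0  # Cq beyond this is treated as no amplification
CQ_MAX = 45.0  # amplification protocol runs 45 cycles

NTC_SAMPLE_ID = "NTC"


@dataclass(frozen=True)
class QpcrDataset:
    """Long-format Cq records plus per-gene NTC means and efficiencies.

    ``records`` columns: gene_id, sample_id, group, replicate, cq.
    NTC reactions are separated out into ``ntc_mean_cq``.
    """

    records: pd.DataFrame
    ntc_mean_cq: dict[str, float]
    efficiencies: dict[str, float]
    clip_count: int = 0

    def __post_init__(self) -> None:
        required = {"gene_id", "sample_id", "group", "replicate", "cq"}
        missing = required - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"Cq records missing columns: {sorted(missing)}")
        cq = self.records["cq"].to_numpy(dtype=float)
        if cq.size and (np.any(cq <= 0) or np.any(cq > CQ_MAX)):
            bad = self.records.iloc[int(np.argmax((cq <= 0) | (cq > CQ_MAX)))]
            raise ConfigurationError(
                f"Cq out of (0, {CQ_MAX}] for gene {bad['gene_id']!r}, "
                f"sample {bad['sample_id']!r}: {bad['cq']}"
            )
        for gid in self.gene_ids:
            eff = self.efficiencies.get(gid)
            if eff is None:
                raise ConfigurationError(f"gene {gid!r} has no primer efficiency")
            if not 1.0 < eff <= 2.2:
                raise ConfigurationError(
                    f"efficiency for gene {gid!r} must be in (1, 2.2], got {eff}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["gene_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample_id"]))

    @property
    def groups(self) -> dict[str, str]:
        """sample_id -> group label."""
        sub = self.records[["sample_id", "group"]].drop_duplicates()
        return dict(zip(sub["sample_id"], sub["group"]))


def read_qpcr_dataset(cq_path, efficiency_path) -> QpcrDataset:
    """Read Cq records (CSV: gene_id, sample_id, group, replicate, cq) and
    per-gene efficiencies.

    The efficiency file is either a direct table (gene_id, efficiency_E)
    or a per-gene dilution series (gene_id, log10_concentration, cq) from
    which E is fitted via the standard curve.  Rows with sample_id "NTC"
    are non-template controls; their per-gene mean Cq becomes the dCq
    reference.
    """
    raw = pd.read_csv(cq_path, dtype={"gene_id": str, "sample_id": str, "group": str})
    is_ntc = raw["sample_id"] == NTC_SAMPLE_ID
    ntc = raw[is_ntc].groupby("gene_id")["cq"].mean().to_dict()
    eff_frame = pd.read_csv(efficiency_path, dtype={"gene_id": str})
    if "efficiency_E" in eff_frame.columns:
        eff = dict(zip(eff_frame["gene_id"], eff_frame["efficiency_E"].astype(float)))
    elif {"log10_concentration", "cq"} <= set(eff_frame.columns):
        eff = {
            gid: standard_curve(zip(sub["log10_concentration"], sub["cq"]))["E"]
            for gid, sub in eff_frame.groupby("gene_id")
        }
    else:
        raise ConfigurationError(
            "efficiency table needs either an 'efficiency_E' column or "
            "dilution-series columns 'log10_concentration' and 'cq'"
        )
    return QpcrDataset(
        records=raw[~is_ntc].reset_index(drop=True),
        ntc_mean_cq={k: float(v) for k, v in ntc.items()},
        efficiencies=eff,
    )


def write_qpcr_dataset(dataset: QpcrDataset, cq_path, efficiency_path) -> None:
    """Write a dataset back to the CSV dialect :func:`read_qpcr_dataset` reads.

    NTC means are expanded to single rows with sample_id "NTC" and an
    empty group.
    """
    ntc_rows = pd.DataFrame(
        {
            "gene_id": list(dataset.ntc_mean_cq),
            "sample_id": NTC_SAMPLE_ID,
            "group": "",
            "replicate": 1,
            "cq": list(dataset.ntc_mean_cq.values()),
        }
    )
    out = pd.concat([dataset.records, ntc_rows], ignore_index=True)
    out.to_csv(cq_path, index=False)
    pd.DataFrame(
        {"gene_id": list(dataset.efficiencies), "efficiency_E": list(dataset.efficiencies.values())}
    ).to_csv(efficiency_path, index=False)


def primer_efficiency_from_slope(slope: float) -> tuple[float, float]:
    """Amplification factor E and efficiency percent from a standard-curve slope.

    efficiency% = (10^(-1/slope) - 1) * 100; E = 10^(-1/slope).  A perfect
    doubling per cycle gives slope = -1/log10(2) ~ -3.3219 and E = 2.
    """
    if slope >= 0:
        raise ParameterError(f"standard-curve slope must be negative, got {slope}")
    e_factor = 10.0 ** (-1.0 / slope)
    return e_factor, (e_factor - 1.0) * 100.0


def standard_curve(dilution_series) -> dict:
    """OLS fit of Cq on log10 relative concentration.

    ``dilution_series``: iterable of (log10 concentration, Cq) pairs, at
    least 3 points with distinct concentrations.  QC passes iff r^2 > 0.97
    and 1.9 <= E <= 2.0.
    """
    pts = np.asarray(list(dilution_series), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("standard curve needs >= 3 dilution points")
    logc, cq = pts[:, 0], pts[:, 1]
    if np.unique(logc).size < 2:
        raise InsufficientDataError("dilution points must span distinct concentrations")
    fit = stats.linregress(logc, cq)
    slope = float(fit.slope)
    r_squared = float(fit.rvalue**2)
    e_factor, eff_pct = primer_efficiency_from_slope(slope)
    return {
        "slope": slope,
        "intercept": float(fit.intercept),
        "r_squared": r_squared,
        "E": e_factor,
        "efficiency_percent": eff_pct,
        # 1e-9 guard so an exactly-doubling curve (E = 2 up to rounding) passes
        "qc_pass": bool(r_squared > 0.97 and 1.9 - 1e-9 <= e_factor <= 2.0 + 1e-9),
    }


def quality_flags(dataset: QpcrDataset) -> pd.DataFrame:
    """Per-record QC flags; currently: Cq > 35 -> "no amplification"."""
    rec = dataset.records
    flagged = rec[rec["cq"] > CQ_NO_AMPLIFICATION].copy()
    flagged["flag"] = "no amplification"
    return flagged.reset_index(drop=True)


def relative_expression(dataset: QpcrDataset, *, calibrator: bool = False) -> pd.DataFrame:
    """Relative expression E^(-dCq) per (gene, sample), geometric mean over replicates.

    dCq is referenced to the gene's mean NTC Cq.  With ``calibrator=True``
    the per-gene minimum Cq replaces the NTC mean (the conventional
    highest-expression calibrator), for datasets lacking NTC reactions.
    Returns a genes x samples DataFrame (rows/columns in first-seen order).
    """
    rec = dataset.records.copy()
    refs: dict[str, float] = {}
    for gid in dataset.gene_ids:
        if calibrator:
            refs[gid] = float(rec.loc[rec["gene_id"] == gid, "cq"].min())
        else:
            if gid not in dataset.ntc_mean_cq:
                raise ConfigurationError(
                    f"gene {gid!r} has no NTC records and the calibrator option is off"
                )
            refs[gid] = dataset.ntc_mean_cq[gid]
    rec["dcq"] = rec["cq"] - rec["gene_id"].map(refs)
    rec["expression"] = rec["gene_id"].map(dataset.efficiencies) ** (-rec["dcq"])
    geo = (
        rec.groupby(["gene_id", "sample_id"], sort=False)["expression"]
        .apply(lambda x: float(np.exp(np.mean(np.log(x)))))
        .unstack("sample_id")
    )
    return geo.loc[dataset.gene_ids, dataset.sample_ids]


def mean_cq_matrix(dataset: QpcrDataset) -> pd.DataFrame:
    """Mean Cq over technical replicates, genes x samples."""
    m = (
        dataset.records.groupby(["gene_id", "sample_id"], sort=False)["cq"]
        .mean()
        .unstack("sample_id")
    )
    return m.loc[dataset.gene_ids, dataset.sample_ids]


def rank_series(statistic: pd.Series, ascending: bool = True) -> pd.Series:
    """Ranks with ties sharing the mean of the tied positions."""
    vals = statistic.to_numpy(dtype=float)
    ranked = stats.rankdata(vals if ascending else -vals, method="average")
    return pd.Series(ranked, index=statistic.index)


# ---------------------------------------------------------------------------
# geNorm


@dataclass(frozen=True)
class GenormResult:
    m_steps: pd.DataFrame  # columns: step, n_genes, gene_id, m
    ranking: pd.DataFrame  # columns: gene_id, m, rank  (final pair shares rank 1)
    pairwise_variation: dict[str, float]  # e.g. {"V2/3": ...}
    exclusion_order: tuple[str, ...] = field(default=())  # first excluded first


def _genorm_m(log_expr: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of SD across samples of log2(x_j / x_k)."""
    X = log_expr.to_numpy()
    n = len(X)
    diffs = X[:, None, :] - X[None, :, :]  # (j, k, sample)
    sds = diffs.std(axis=2, ddof=1)
    m = (sds.sum(axis=1)) / (n - 1)  # diagonal contributes 0
    return pd.Series(m, index=log_expr.index)


def genorm(expression: pd.DataFrame) -> GenormResult:
    """geNorm stepwise-exclusion stability analysis on relative expression.

    Requires > 0 expression and at least 2 genes (3 for a meaningful
    exclusion series).  The two genes surviving to the end cannot be
    distinguished by M and share rank 1; the next-excluded gene has rank
    3, and so on backwards through the exclusion order.
    """
    if len(expression) < 2:
        raise InsufficientDataError("geNorm needs >= 2 genes")
    if expression.shape[1] < 2:
        raise InsufficientDataError("geNorm needs >= 2 samples")
    vals = expression.to_numpy(dtype=float)
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise UndefinedStatisticError("geNorm requires strictly positive finite expression")
    log_expr = np.log2(expression)

    steps = []
    exclusion: list[str] = []
    m_at_exclusion: dict[str, float] = {}
    current = log_expr.copy()
    step = 0
    while len(current) >= 2:
        m = _genorm_m(current)
        for gid, mv in m.items():
            steps.append({"step": step, "n_genes": len(current), "gene_id": gid, "m": float(mv)})
        if len(current) == 2:
            for gid, mv in m.items():
                m_at_exclusion[gid] = float(mv)
            break
        # exclude the least stable gene; ties to the lexicographically
        # later id so the earlier id survives deterministically
        worst_m = m.max()
        worst = max(m.index[m == worst_m])
        m_at_exclusion[worst] = float(m[worst])
        exclusion.append(worst)
        current = current.drop(index=worst)
        step += 1

    # ranking: final pair shares rank 1; exclusion order fills 3..n backwards
    gene_ids = list(log_expr.index)
    rank_map: dict[str, float] = {}
    final_pair = [g for g in gene_ids if g not in exclusion]
    for g in final_pair:
        rank_map[g] = 1.0
    r = len(gene_ids)
    for g in exclusion:  # first excluded = least stable = rank n
        rank_map[g] = float(r)
        r -= 1
    ranking = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "m": [m_at_exclusion[g] for g in gene_ids],
            "rank": [rank_map[g] for g in gene_ids],
        }
    ).sort_values(["rank", "gene_id"], kind="mergesort", ignore_index=True)

    # pairwise variation V_{n/n+1} over the stability ordering
    order = final_pair + exclusion[::-1]  # most stable first
    v: dict[str, float] = {}
    for n_top in range(2, len(order)):
        nf_n = log_expr.loc[order[:n_top]].mean(axis=0)  # log2 of geometric mean
        nf_n1 = log_expr.loc[order[: n_top + 1]].mean(axis=0)
        v[f"V{n_top}/{n_top + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    return GenormResult(
        m_steps=pd.DataFrame(steps),
        ranking=ranking,
        pairwise_variation=v,
        exclusion_order=tuple(exclusion),
    )


# ---------------------------------------------------------------------------
# NormFinder


def normfinder(expression: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Model-based stability on log2 expression with grouped samples.

    The model decomposes each gene's log2 expression into a gene effect, a
    sample effect and noise; per group it estimates the gene's residual
    variance sigma^2_ig (with the small-gene-panel bias correction
    n/(n-2)) and the gene x group interaction d_ig (intergroup bias).
    The bias estimates are shrunk toward zero by the ratio
    gamma^2 / (gamma^2 + Var(d_hat)), where gamma^2 is the between-gene
    variance of true biases.  Stability per gene is the mean over groups
    of |shrunken bias| + SE of the group mean; lower is more stable.

    With a single group, falls back to an intragroup-only variant (the
    square root of the estimated residual variance) with a logged notice.

    Returns a DataFrame: gene_id, stability, rank.
    """
    vals = expression.to_numpy(dtype=float)
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise UndefinedStatisticError("NormFinder requires strictly positive finite expression")
    if len(expression) < 2:
        raise InsufficientDataError("NormFinder needs >= 2 genes")
    missing = [s for s in expression.columns if s not in groups]
    if missing:
        raise ConfigurationError(f"samples without a group label: {missing[:5]}")
    y = np.log2(vals)
    labels = np.array([groups[s] for s in expression.columns])
    unique_groups = list(dict.fromkeys(labels))
    n = len(expression)

    if len(unique_groups) == 1:
        logger.info("NormFinder: single group; using intragroup-only stability")
        sigma2 = _normfinder_group_variance(y)
        stability = pd.Series(np.sqrt(sigma2), index=expression.index)
    else:
        group_means = np.empty((n, len(unique_groups)))
        sigma2 = np.empty((n, len(unique_groups)))
        m_sizes = np.empty(len(unique_groups))
        for gi, g in enumerate(unique_groups):
            cols = labels == g
            m_g = int(cols.sum())
            if m_g < 2:
                raise InsufficientDataError(
                    f"group {g!r} has {m_g} sample(s); NormFinder needs >= 2 per group"
                )
            m_sizes[gi] = m_g
            yg = y[:, cols]
            group_means[:, gi] = yg.mean(axis=1)
            sigma2[:, gi] = _normfinder_group_variance(yg)
        # gene x group interaction: bias of gene i in group g
        d = (
            group_means
            - group_means.mean(axis=1, keepdims=True)
            - group_means.mean(axis=0, keepdims=True)
            + group_means.mean()
        )
        samp_var = sigma2 / m_sizes[None, :]  # sampling variance of d_hat
        n_g = len(unique_groups)
        gamma2 = max(
            0.0,
            float((d**2).sum() / ((n - 1) * (n_g - 1)) - samp_var.mean()),
        )
        if gamma2 > 0:
            d_shrunk = d * gamma2 / (gamma2 + samp_var)
        else:
            d_shrunk = np.zeros_like(d)
        per_group = np.abs(d_shrunk) + np.sqrt(samp_var)
        stability = pd.Series(per_group.mean(axis=1), index=expression.index)

    out = pd.DataFrame({"gene_id": expression.index, "stability": stability.to_numpy()})
    out["rank"] = rank_series(out.set_index("gene_id")["stability"]).to_numpy()
    return out.sort_values(["rank", "gene_id"], kind="mergesort", ignore_index=True)


def _normfinder_group_variance(yg: np.ndarray) -> np.ndarray:
    """Per-gene residual variance of a genes x samples block after removing
    gene and sample effects, bias-corrected for the panel size."""
    n, m = yg.shape
    r = yg - yg.mean(axis=1, keepdims=True) - yg.mean(axis=0, keepdims=True) + yg.mean()
    u = (r**2).sum(axis=1) / (m - 1)
    if n > 2:
        # E[u_i] = sigma2_i (1 - 2/n) + mean(sigma2)/n, hence the unbiased
        # inversion below; for n = 2 the correction is singular and the raw
        # mean squared residual is used as-is.
        sigma2 = (u - u.mean() / (n - 1)) * n / (n - 2)
    else:
        sigma2 = u
    return np.maximum(sigma2, 0.0)


# ---------------------------------------------------------------------------
# BestKeeper


@dataclass(frozen=True)
class BestKeeperResult:
    statistics: pd.DataFrame  # gene_id, mean_cq, sd_cq, cv_pct, r, rank_correlation, rank_sd
    index: pd.Series  # BestKeeper index per experiment
    notices: tuple[str, ...] = ()


def bestkeeper(cq: pd.DataFrame) -> BestKeeperResult:
    """BestKeeper descriptive statistics and both ranking modes.

    ``cq``: genes x experiments matrix of mean Cq.  The BestKeeper index
    is the per-experiment geometric mean of Cq across genes.  Per gene:
    SD of Cq about its arithmetic mean (sample SD), CV% = 100*SD/mean,
    and Pearson r against the index.  A constant gene has undefined r: it
    is reported as NaN, ranked best in sd mode, and excluded from the
    correlation ranking with a notice.
    """
    if len(cq) < 2:
        raise InsufficientDataError("BestKeeper needs >= 2 genes")
    if cq.shape[1] < 3:
        raise InsufficientDataError("BestKeeper needs >= 3 experiments")
    vals = cq.to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise UndefinedStatisticError("BestKeeper requires Cq > 0")
    index = pd.Series(np.exp(np.log(vals).mean(axis=0)), index=cq.columns)
    mean_cq = vals.mean(axis=1)
    sd_cq = vals.std(axis=1, ddof=1)
    cv_pct = 100.0 * sd_cq / mean_cq
    notices: list[str] = []
    r = np.full(len(cq), np.nan)
    for i, gid in enumerate(cq.index):
        if sd_cq[i] == 0 or index.std(ddof=1) == 0:
            notices.append(f"gene {gid!r}: constant Cq, correlation undefined")
            continue
        r[i] = stats.pearsonr(vals[i], index.to_numpy()).statistic
    statistics = pd.DataFrame(
        {
            "gene_id": cq.index,
            "mean_cq": mean_cq,
            "sd_cq": sd_cq,
            "cv_pct": cv_pct,
            "r": r,
        }
    ).set_index("gene_id")
    statistics["rank_sd"] = rank_series(statistics["sd_cq"]).to_numpy()
    defined = statistics["r"].notna()
    rank_corr = pd.Series(np.nan, index=statistics.index)
    if defined.any():
        rank_corr[defined] = rank_series(statistics.loc[defined, "r"], ascending=False)
    statistics["rank_correlation"] = rank_corr
    return BestKeeperResult(
        statistics=statistics.reset_index(), index=index, notices=tuple(notices)
    )


# ---------------------------------------------------------------------------
# DeltaCt


def delta_ct(cq: pd.DataFrame) -> pd.DataFrame:
    """Comparative dCt stability: mean over partner genes of the SD across
    experiments of the pairwise Cq difference.  Returns gene_id,
    stability, rank (ascending: lower mean pairwise SD = more stable)."""
    if len(cq) < 2:
        raise InsufficientDataError("DeltaCt needs >= 2 genes")
    if cq.shape[1] < 2:
        raise InsufficientDataError("DeltaCt needs >= 2 experiments")
    X = cq.to_numpy(dtype=float)
    diffs = X[:, None, :] - X[None, :, :]
    sds = diffs.std(axis=2, ddof=1)
    stability = sds.sum(axis=1) / (len(X) - 1)
    out = pd.DataFrame({"gene_id": cq.index, "stability": stability})
    out["rank"] = rank_series(out.set_index("gene_id")["stability"]).to_numpy()
    return out.sort_values(["rank", "gene_id"], kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# aggregation


def comprehensive_rank(rankings: list[pd.Series]) -> pd.DataFrame:
    """Geometric mean of per-gene ranks across algorithms.

    Every ranking must cover the same gene set; otherwise the symmetric
    difference is reported.  Returns gene_id, geomean_rank, rank —
    ascending by geometric mean, residual ties broken by gene id.
    """
    if not rankings:
        raise InsufficientDataError("at least one ranking is required")
    base = set(rankings[0].index)
    for r in rankings[1:]:
        if set(r.index) != base:
            diff = sorted(base.symmetric_difference(set(r.index)))
            raise InputMismatchError(f"rankings cover different gene sets: {diff}")
    genes = sorted(base)
    mat = np.array([[float(r[g]) for r in rankings] for g in genes])
    geomean = np.exp(np.log(mat).mean(axis=1))
    out = pd.DataFrame({"gene_id": genes, "geomean_rank": geomean})
    out["rank"] = rank_series(out.set_index("gene_id")["geomean_rank"]).to_numpy()
    return out.sort_values(["rank", "gene_id"], kind="mergesort", ignore_index=True)
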