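"""End-to-end pipelines: genome-wide candidate discovery and qPCR stability.

These functions are the library face of the two workflows; the command
line is a thin wrapper around them.

* :func:`run_discovery` — expression matrix -> annotation filter ->
  low-expression filter -> per-gene variation scores -> silhouette k
  selection -> PAM -> stable-cluster choice -> distance ranking -> GO
  filter.  Returns a :class:`DiscoveryResult` carrying every intermediate
  artifact plus the stage-count funnel.
* :func:`run_stability` — Cq dataset -> relative expression -> geNorm /
  NormFinder / BestKeeper / DeltaCt -> geometric-mean aggregation.

Aggregation modes: ``"fig6"`` (default) takes the geometric mean over
four rank columns — geNorm, NormFinder, BestKeeper and a RefFinder-style
column that is itself the geometric-mean rank of {geNorm, NormFinder,
BestKeeper (SD mode), DeltaCt}; ``"reffinder-only"`` uses the
RefFinder-style column alone.  BestKeeper enters the outer aggregate in
correlation mode by default (switchable to SD mode).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import candidate_selection as cs
from . import qpcr_stability as qs
from . import variation_stats as vs
from .exceptions import ConfigurationError
from .expr_io import AnnotationTable, ExpressionMatrix, GoAnnotation, filter_annotated, filter_low_expression

__all__ = ["DiscoveryResult", "StabilityResult", "run_discovery", "run_stability"]

logger = logging.getLogger(__name__)

AGGREGATION_MODES = ("fig6", "reffinder-only")


@dataclass
class DiscoveryResult:
    scores: pd.DataFrame
    cluster: cs.ClusterResult
    silhouette_by_k: dict[int, float]
    best_k: int
    selected_cluster: int
    candidates: cs.CandidateList
    stage_counts: dict[str, int]

    def summary(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "best_k": self.best_k,
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "selected_cluster": self.selected_cluster,
            "medoid_z_scores": [list(map(float, p)) for p in self.cluster.medoid_points],
            "n_candidates": int(len(self.candidates.frame)),
            "n_retained": len(self.candidates.retained_gene_ids()),
        }


@dataclass
class StabilityResult:
    report: pd.DataFrame  # per-gene statistics and ranks for every algorithm
    genorm: qs.GenormResult
    normfinder: pd.DataFrame
    bestkeeper: qs.BestKeeperResult
    delta_ct: pd.DataFrame
    aggregate: pd.DataFrame
    qc_flags: pd.DataFrame
    notices: tuple[str, ...] = field(default=())

    def summary(self) -> dict:
        return {
            "n_genes": int(len(self.report)),
            "ranking": {
                row["gene_id"]: {
                    "final_rank": float(row["final_rank"]),
                    "geomean_rank": float(row["aggregate_geomean"]),
                }
                for _, row in self.report.iterrows()
            },
            "pairwise_variation": self.genorm.pairwise_variation,
            "qc_flag_count": int(len(self.qc_flags)),
            "notices": list(self.notices),
        }


def run_discovery(
    matrix: ExpressionMatrix,
    annotation: AnnotationTable | None = None,
    go: GoAnnotation | None = None,
    *,
    k_range=range(2, 11),
    top_n: int = 100,
    clara_threshold: int = cs.DEFAULT_CLARA_THRESHOLD,
    clara_seed: int = 0,
    go_rules: tuple[cs.GoExclusionRule, ...] = cs.DEFAULT_GO_EXCLUSIONS,
    log_transform_shapiro: bool = False,
    zscore_one_minus_p: bool = False,
) -> DiscoveryResult:
    """Run the full candidate-discovery funnel on an expression matrix.

    By default the normality parameter 1-p enters clustering and distance
    on its native [0,1] scale while CV and nMAD are z-scored: 1-p is
    already calibrated, and standardizing it is degenerate when most
    genes reject normality (the column SD collapses, so the near-normal
    minority is stretched into an arbitrarily long needle in z-space).
    Set ``zscore_one_minus_p=True`` for the fully standardized variant.
    """
    counts = {"input_genes": matrix.n_genes}
    if annotation is not None:
        matrix = filter_annotated(matrix, annotation)
    counts["annotated_genes"] = matrix.n_genes
    logger.info("annotation filter: %d genes remain", matrix.n_genes)

    matrix, removed = filter_low_expression(matrix)
    counts["expressed_genes"] = matrix.n_genes
    counts["low_expression_removed"] = removed
    logger.info("low-expression filter: removed %d, %d remain", removed, matrix.n_genes)

    scores = vs.compute_gene_scores(
        matrix,
        log_transform=log_transform_shapiro,
        zscore_one_minus_p=zscore_one_minus_p,
    )
    counts["scored_genes"] = len(scores)
    logger.info("scored %d genes", len(scores))

    points = scores[["z_cv", "z_nmad", "z_one_minus_p"]].to_numpy()
    gene_ids = tuple(scores["gene_id"])
    best_k, sil_by_k = cs.silhouette_select_k(
        points, k_range, clara_threshold=clara_threshold, clara_seed=clara_seed
    )
    cluster = cs.pam_cluster(
        points,
        best_k,
        gene_ids=gene_ids,
        clara_threshold=clara_threshold,
        clara_seed=clara_seed,
    )
    selected = cs.select_reference_cluster(cluster)
    members = [gene_ids[i] for i in cluster.members(selected)]
    counts["selected_cluster_genes"] = len(members)
    logger.info(
        "silhouette chose k=%d; stable cluster %d with %d genes",
        best_k,
        selected,
        len(members),
    )

    candidates = cs.rank_by_distance(scores, members, top_n=top_n)
    counts["candidates"] = len(candidates.frame)
    if go is not None:
        candidates = cs.go_filter(candidates, go, rules=go_rules)
    counts["retained_after_go"] = len(candidates.retained_gene_ids())
    logger.info(
        "candidate list: %d genes, %d retained after GO filter",
        len(candidates.frame),
        counts["retained_after_go"],
    )
    return DiscoveryResult(
        scores=scores,
        cluster=cluster,
        silhouette_by_k=sil_by_k,
        best_k=best_k,
        selected_cluster=selected,
        candidates=candidates,
        stage_counts=counts,
    )


def _rank_map(frame: pd.DataFrame) -> pd.Series:
    return frame.set_index("gene_id")["rank"].astype(float)


def run_stability(
    dataset: qs.QpcrDataset,
    *,
    aggregation_mode: str = "fig6",
    bestkeeper_mode: str = "correlation",
    calibrator: bool = False,
) -> StabilityResult:
    """Run the four stability algorithms and the geometric-mean aggregate."""
    if aggregation_mode not in AGGREGATION_MODES:
        raise ConfigurationError(
            f"aggregation_mode must be one of {AGGREGATION_MODES}, got {aggregation_mode!r}"
        )
    if bestkeeper_mode not in ("correlation", "sd"):
        raise ConfigurationError("bestkeeper_mode must be 'correlation' or 'sd'")
    notices: list[str] = []

    expr = qs.relative_expression(dataset, calibrator=calibrator)
    qc = qs.quality_flags(dataset)
    cq = qs.mean_cq_matrix(dataset)

    gn = qs.genorm(expr)
    nf = qs.normfinder(expr, dataset.groups)
    bk = qs.bestkeeper(cq)
    notices.extend(bk.notices)
    dc = qs.delta_ct(cq)

    gn_rank = _rank_map(gn.ranking)
    nf_rank = _rank_map(nf)
    dc_rank = _rank_map(dc)
    bk_stats = bk.statistics.set_index("gene_id")
    bk_sd_rank = bk_stats["rank_sd"].astype(float)
    bk_corr_rank = bk_stats["rank_correlation"].astype(float)
    if bk_corr_rank.isna().any():
        for g in bk_corr_rank[bk_corr_rank.isna()].index:
            notices.append(
                f"gene {g!r}: undefined BestKeeper correlation; SD-mode rank used in aggregate"
            )
        bk_corr_rank = bk_corr_rank.fillna(bk_sd_rank)
    bk_outer = bk_corr_rank if bestkeeper_mode == "correlation" else bk_sd_rank

    reffinder = qs.comprehensive_rank([gn_rank, nf_rank, bk_sd_rank, dc_rank])
    rf_rank = _rank_map(reffinder)
    if aggregation_mode == "fig6":
        aggregate = qs.comprehensive_rank([gn_rank, nf_rank, bk_outer, rf_rank])
    else:
        aggregate = reffinder.copy()

    genes = sorted(gn_rank.index)
    agg_idx = aggregate.set_index("gene_id")
    report = pd.DataFrame(
        {
            "gene_id": genes,
            "genorm_m": gn.ranking.set_index("gene_id")["m"].reindex(genes).to_numpy(),
            "genorm_rank": gn_rank.reindex(genes).to_numpy(),
            "normfinder_stability": nf.set_index("gene_id")["stability"].reindex(genes).to_numpy(),
            "normfinder_rank": nf_rank.reindex(genes).to_numpy(),
            "bestkeeper_sd": bk_stats["sd_cq"].reindex(genes).to_numpy(),
            "bestkeeper_cv_pct": bk_stats["cv_pct"].reindex(genes).to_numpy(),
            "bestkeeper_r": bk_stats["r"].reindex(genes).to_numpy(),
            "bestkeeper_rank_correlation": bk_stats["rank_correlation"].reindex(genes).to_numpy(),
            "bestkeeper_rank_sd": bk_sd_rank.reindex(genes).to_numpy(),
            "delta_ct_stability": dc.set_index("gene_id")["stability"].reindex(genes).to_numpy(),
            "delta_ct_rank": dc_rank.reindex(genes).to_numpy(),
            "reffinder_rank": rf_rank.reindex(genes).to_numpy(),
            "aggregate_geomean": agg_idx["geomean_rank"].reindex(genes).to_numpy(),
            "final_rank": agg_idx["rank"].reindex(genes).to_numpy(),
        }
    ).sort_values(["final_rank", "gene_id"], kind="mergesort", ignore_index=True)

    return StabilityResult(
        report=report,
        genorm=gn,
        normfinder=nf,
        bestkeeper=bk,
        delta_ct=dc,
        aggregate=aggregate,
        qc_flags=qc,
        notices=tuple(notices),
    )


def _format_sig(frame: pd.DataFrame, sig: int = 6) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.{sig}g}" if pd.notna(v) else "NA")
    return out


def write_discovery_artifacts(result: DiscoveryResult, out_dir) -> list[Path]:
    """Write score table, cluster summary, candidate list and run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out / "stability_scores.tsv"
    _format_sig(result.scores).to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = out / "cluster_summary.tsv"
    medoids = pd.DataFrame(
        result.cluster.medoid_points, columns=["z_cv", "z_nmad", "z_one_minus_p"]
    )
    medoids.insert(0, "cluster", np.arange(1, result.cluster.k + 1))
    medoids["n_genes"] = [
        int((result.cluster.assignment == c).sum()) for c in range(1, result.cluster.k + 1)
    ]
    medoids["selected"] = medoids["cluster"] == result.selected_cluster
    _format_sig(medoids).to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = out / "candidates.tsv"
    _format_sig(result.candidates.frame).to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = out / "discovery_summary.json"
    p.write_text(json.dumps(result.summary(), indent=2, sort_keys=True) + "\n")
    paths.append(p)
    return paths


def write_stability_artifacts(result: StabilityResult, out_dir) -> list[Path]:
    """Write the stability report TSV and the JSON run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out / "stability_report.tsv"
    _format_sig(result.report).to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = out / "stability_summary.json"
    p.write_text(json.dumps(result.summary(), indent=2, sort_keys=True) + "\n")
    paths.append(p)
    return paths
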