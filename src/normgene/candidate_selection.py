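"""Candidate selection: PAM clustering in z-space, cluster choice, ranking, GO filter.

Genes are points in the 3-D space of z-scored (CV, normalized MAD, 1-p).
They are partitioned with a deterministic PAM (k-medoids): greedy BUILD
initialization followed by best-improvement SWAP passes until no swap
reduces the total cost.  Medoid-based clustering is preferred over k-means
here because outlier genes would drag k-means centroids.

The number of clusters is chosen by mean silhouette width; the cluster
whose medoid is component-wise minimal (lowest CV, MAD and 1-p z-scores)
is the "stable" cluster.  Its members are ranked by Euclidean distance
from the z-space origin, the top ``top_n`` kept, and genes annotated to
the nucleus or to translation are flagged for exclusion (such genes are
transcription/translation machinery whose expression shifts under
experimental perturbation).

For inputs above ``clara_threshold`` points, a CLARA-style scheme runs PAM
on fixed-seed subsamples and keeps the medoid set with the best full-data
cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import InputMismatchError, ParameterError
from .expr_io import GoAnnotation

__all__ = [
    "ClusterResult",
    "CandidateList",
    "GoExclusionRule",
    "DEFAULT_GO_EXCLUSIONS",
    "pam_cluster",
    "silhouette_widths",
    "silhouette_select_k",
    "select_reference_cluster",
    "rank_by_distance",
    "go_filter",
]

_SWAP_TOL = 1e-12
DEFAULT_CLARA_THRESHOLD = 5000
DEFAULT_CLARA_SUBSAMPLES = 5
DEFAULT_CLARA_SIZE = 1000


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of a PAM run.

    ``assignment`` holds 1-based cluster labels; cluster ``c`` has medoid
    ``medoid_points[c-1]`` (a member of the input point set).  Points are
    assigned to the nearest medoid, ties to the lower label.
    """

    assignment: np.ndarray
    medoid_indices: tuple[int, ...]
    medoid_points: np.ndarray
    k: int
    total_cost: float
    silhouette_values: np.ndarray
    silhouette_mean: float
    medoid_gene_ids: tuple[str, ...] | None = None

    def members(self, label: int) -> np.ndarray:
        """Indices of the points assigned to cluster ``label`` (1-based)."""
        return np.flatnonzero(self.assignment == label)


@dataclass(frozen=True)
class CandidateList:
    """Ranked candidates with GO verdicts; distances are non-decreasing."""

    frame: pd.DataFrame  # columns: rank, gene_id, distance, verdict, reason
    warnings_: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        d = self.frame["distance"].to_numpy()
        if d.size and np.any(np.diff(d) < 0):
            raise InputMismatchError("candidate distances must be non-decreasing")

    def retained_gene_ids(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["verdict"] == "retained", "gene_id"])


@dataclass(frozen=True)
class GoExclusionRule:
    aspect: str
    accession: str
    label_substring: str
    reason: str


DEFAULT_GO_EXCLUSIONS: tuple[GoExclusionRule, ...] = (
    GoExclusionRule("cellular_component", "GO:0005634", "nucleus", "nuclear localization"),
    GoExclusionRule("biological_process", "GO:0006412", "translation", "translation"),
)


def _nearest_two(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per point: index (into medoid list) of nearest medoid, its distance,
    and the distance to the second-nearest medoid."""
    Dm = D[medoids]  # k x n
    n = D.shape[0]
    idx1 = np.argmin(Dm, axis=0)
    cols = np.arange(n)
    d1 = Dm[idx1, cols]
    if len(medoids) == 1:
        return idx1, d1, np.full(n, np.inf)
    Dm2 = Dm.copy()
    Dm2[idx1, cols] = np.inf
    d2 = Dm2.min(axis=0)
    return idx1, d1, d2


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dnear = D[medoids[0]].copy()
    chosen = np.zeros(n, dtype=bool)
    chosen[medoids[0]] = True
    while len(medoids) < k:
        # gain of adding candidate c: sum_j max(dnear_j - D_jc, 0)
        gains = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
        gains[chosen] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        chosen[c] = True
        dnear = np.minimum(dnear, D[c])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 500) -> list[int]:
    n = D.shape[0]
    meds = np.array(medoids, dtype=int)
    for _ in range(max_iter):
        idx1, d1, d2 = _nearest_two(D, meds)
        # cost change per (removed medoid a, inserted candidate h)
        gain_other = np.minimum(D - d1[:, None], 0.0)  # (point j, candidate h)
        s_all = gain_other.sum(axis=0)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[meds] = True
        best_delta = -_SWAP_TOL
        best_pair: tuple[int, int] | None = None
        for a in range(len(meds)):
            mask = idx1 == a
            if mask.any():
                corr = gain_other[mask].sum(axis=0)
                repl = (np.minimum(d2[mask][:, None], D[mask]) - d1[mask][:, None]).sum(axis=0)
                delta = s_all - corr + repl
            else:
                delta = s_all.copy()
            delta[is_medoid] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta = float(delta[h])
                best_pair = (a, h)
        if best_pair is None:
            break
        meds[best_pair[0]] = best_pair[1]
    return sorted(int(m) for m in meds)


def _assemble(
    points: np.ndarray,
    D: np.ndarray,
    medoids: list[int],
    gene_ids: tuple[str, ...] | None,
) -> ClusterResult:
    meds = np.array(sorted(medoids), dtype=int)
    idx1, d1, _ = _nearest_two(D, meds)
    assignment = idx1 + 1
    k = len(meds)
    if k >= 2:
        sil = silhouette_widths(D, assignment)
    else:
        sil = np.zeros(len(points))
    return ClusterResult(
        assignment=assignment,
        medoid_indices=tuple(int(m) for m in meds),
        medoid_points=points[meds].copy(),
        k=k,
        total_cost=float(d1.sum()),
        silhouette_values=sil,
        silhouette_mean=float(sil.mean()) if len(sil) else 0.0,
        medoid_gene_ids=tuple(gene_ids[m] for m in meds) if gene_ids is not None else None,
    )


def pam_cluster(
    points: np.ndarray,
    k: int,
    *,
    gene_ids: tuple[str, ...] | None = None,
    distances: np.ndarray | None = None,
    clara_threshold: int = DEFAULT_CLARA_THRESHOLD,
    clara_seed: int = 0,
) -> ClusterResult:
    """Deterministic PAM under Euclidean distance.

    BUILD picks medoids greedily (first: the point minimizing total
    distance; then the point with the largest cost reduction).  SWAP
    applies the single best cost-reducing (medoid, candidate) exchange
    until none remains; ties break toward lower indices, so results carry
    no random state.  Above ``clara_threshold`` points, a CLARA scheme
    clusters ``DEFAULT_CLARA_SUBSAMPLES`` fixed-seed subsamples of size
    ``DEFAULT_CLARA_SIZE + 2k`` and keeps the medoid set with the lowest
    full-data cost.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ParameterError("points must be a 2-D array")
    n = len(points)
    if not np.all(np.isfinite(points)):
        raise ParameterError("points must be finite")
    if k < 1 or k > n:
        raise ParameterError(f"k must satisfy 1 <= k <= n={n}, got k={k}")
    if n <= clara_threshold or distances is not None:
        D = squareform(pdist(points)) if distances is None else distances
        medoids = _pam_swap(D, _pam_build(D, k))
        return _assemble(points, D, medoids, gene_ids)
    # CLARA path: no full distance matrix materialized up front
    rng = np.random.default_rng(clara_seed)
    size = min(n, DEFAULT_CLARA_SIZE + 2 * k)
    best_cost = np.inf
    best_meds: list[int] | None = None
    for _ in range(DEFAULT_CLARA_SUBSAMPLES):
        sub = np.sort(rng.choice(n, size=size, replace=False))
        Dsub = squareform(pdist(points[sub]))
        meds_sub = _pam_swap(Dsub, _pam_build(Dsub, k))
        meds_full = [int(sub[m]) for m in meds_sub]
        # full-data cost of this medoid set
        cost = float(
            np.min(
                np.linalg.norm(points[:, None, :] - points[meds_full][None, :, :], axis=2),
                axis=1,
            ).sum()
        )
        if cost < best_cost - _SWAP_TOL:
            best_cost = cost
            best_meds = meds_full
    assert best_meds is not None
    D = squareform(pdist(points))
    return _assemble(points, D, best_meds, gene_ids)


def silhouette_widths(D: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Per-point silhouette s(i) = (b - a)/max(a, b) from a distance matrix.

    ``a`` is the mean distance to the point's own cluster (excluding
    itself), ``b`` the smallest mean distance to another cluster.
    Singleton clusters contribute s = 0.
    """
    labels = np.unique(assignment)
    n = D.shape[0]
    onehot = (assignment[:, None] == labels[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    sums = D @ onehot  # (point, cluster)
    own_col = np.searchsorted(labels, assignment)
    own_count = counts[own_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), own_col] / np.maximum(own_count - 1, 1)
        other = sums / counts[None, :]
        other[np.arange(n), own_col] = np.inf
        b = other.min(axis=1)
        s = (b - a) / np.maximum(a, b)
    s = np.where(own_count == 1, 0.0, s)
    s = np.where(np.maximum(a, b) == 0, 0.0, s)
    return s


def silhouette_select_k(
    points: np.ndarray,
    k_range,
    *,
    distances: np.ndarray | None = None,
    clara_threshold: int = DEFAULT_CLARA_THRESHOLD,
    clara_seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Run PAM for each k and return the k with the highest mean silhouette.

    Ties break toward the smaller k.  Every k must be >= 2 (the silhouette
    is undefined for a single cluster) and < n.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ParameterError("k_range must be non-empty")
    if min(ks) < 2:
        raise ParameterError(f"silhouette undefined for k < 2 (got k={min(ks)})")
    points = np.asarray(points, dtype=float)
    if max(ks) >= len(points):
        raise ParameterError(f"max(k_range)={max(ks)} must be < n={len(points)}")
    if distances is None and len(points) <= clara_threshold:
        distances = squareform(pdist(points))
    means: dict[int, float] = {}
    for k in ks:
        result = pam_cluster(
            points,
            k,
            distances=distances,
            clara_threshold=clara_threshold,
            clara_seed=clara_seed,
        )
        means[k] = result.silhouette_mean
    best_k = max(ks, key=lambda k: (means[k], -k))
    return best_k, means


def select_reference_cluster(result: ClusterResult) -> int:
    """Label of the stable cluster: the one whose medoid is lowest in all
    three z-parameters, if such a cluster exists.

    Fallback when no medoid dominates component-wise: the medoid with the
    smallest Euclidean norm from the origin, ties to the lower label.
    """
    med = result.medoid_points
    if result.k == 1:
        return 1
    for c in range(result.k):
        if np.all(med[c] <= med + 1e-15):
            return c + 1
    norms = np.linalg.norm(med, axis=1)
    return int(np.argmin(norms)) + 1


def rank_by_distance(
    scores: pd.DataFrame,
    members,
    top_n: int = 100,
) -> CandidateList:
    """Sort cluster members ascending by z-space distance; keep the top ``top_n``.

    Ties in distance break lexicographically by gene id for determinism.
    """
    if top_n < 1:
        raise ParameterError(f"top_n must be >= 1, got {top_n}")
    members = list(members)
    known = set(scores["gene_id"])
    missing = [m for m in members if m not in known]
    if missing:
        raise InputMismatchError(f"members not in score table: {missing[:5]}")
    warnings_: tuple[str, ...] = ()
    if not members:
        warnings_ = ("empty member set: candidate list is empty",)
    sub = scores[scores["gene_id"].isin(set(members))]
    sub = sub.sort_values(["distance", "gene_id"], kind="mergesort").head(top_n)
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(sub) + 1),
            "gene_id": sub["gene_id"].to_numpy(),
            "distance": sub["distance"].to_numpy(),
            "verdict": "retained",
            "reason": "",
        }
    )
    return CandidateList(frame=frame, warnings_=warnings_)


def go_filter(
    candidates: CandidateList,
    go: GoAnnotation,
    rules: tuple[GoExclusionRule, ...] = DEFAULT_GO_EXCLUSIONS,
) -> CandidateList:
    """Apply the GO exclusion rules to a ranked candidate list.

    A gene is excluded if any of its GO records matches a rule by
    accession (case-insensitive) or by label substring within the rule's
    aspect.  Genes with no GO records are retained with reason
    "unannotated".  Matching is flat: no ancestor closure over the
    ontology graph is performed.
    """
    go_by_gene = {g: sub for g, sub in go.frame.groupby("gene_id")}
    verdicts: list[str] = []
    reasons: list[str] = []
    for gid in candidates.frame["gene_id"]:
        records = go_by_gene.get(gid)
        if records is None or records.empty:
            verdicts.append("retained")
            reasons.append("unannotated")
            continue
        verdict, reason = "retained", ""
        for rule in rules:
            sub = records[records["aspect"] == rule.aspect]
            if sub.empty:
                continue
            acc_hit = sub["term_id"].str.casefold().eq(rule.accession.casefold()).any()
            label_hit = (
                sub["term_label"].str.casefold().str.contains(rule.label_substring.casefold()).any()
            )
            if acc_hit or label_hit:
                verdict, reason = "excluded", rule.reason
                break
        verdicts.append(verdict)
        reasons.append(reason)
    frame = candidates.frame.copy()
    frame["verdict"] = verdicts
    frame["reason"] = reasons
    return CandidateList(frame=frame, warnings_=candidates.warnings_)
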