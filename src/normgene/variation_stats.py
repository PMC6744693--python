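"""Per-gene variation statistics for reference-gene screening.

A good reference gene has low relative spread and an approximately normal
expression profile across conditions.  Three per-gene parameters capture
this:

* ``cv`` — coefficient of variation, sample standard deviation over mean;
* ``nmad`` — median absolute deviation normalized by the median (a robust
  analogue of the CV; the 1.4826 consistency constant is *not* applied);
* ``one_minus_p`` — one minus the Shapiro-Wilk normality p-value, so that
  low values mean "looks normal".

All three are z-scored across genes (sample SD, ddof=1) and combined into
a Euclidean distance d = sqrt(z_cv^2 + z_nmad^2 + z_(1-p)^2); stable genes
sit near the origin of this 3-D space.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .expr_io import ExpressionMatrix

__all__ = [
    "coefficient_of_variation",
    "median_normalized_mad",
    "shapiro_wilk_pvalue",
    "compute_gene_scores",
    "write_score_table",
]

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "gene_id",
    "cv",
    "nmad",
    "one_minus_p",
    "z_cv",
    "z_nmad",
    "z_one_minus_p",
    "distance",
]

_SHAPIRO_MAX_N = 5000


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation divided by the mean.

    Low CV marks genes with stable expression.  Requires at least two
    observations and a strictly positive mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 values, got {x.size}")
    mean = x.mean()
    if mean <= 0:
        raise UndefinedStatisticError(f"CV undefined for mean {mean} <= 0")
    return float(x.std(ddof=1) / mean)


def median_normalized_mad(values: Sequence[float]) -> float:
    """median(|x - median(x)|) / median(x); robust relative spread."""
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    if med <= 0:
        raise UndefinedStatisticError(f"normalized MAD undefined for median {med} <= 0")
    return float(np.median(np.abs(x - med)) / med)


def shapiro_wilk_pvalue(values: Sequence[float]) -> float:
    """Shapiro-Wilk normality p-value; p < 0.05 flags departure from normal.

    Defined for 3 <= n <= 5000 non-constant samples.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > _SHAPIRO_MAX_N:
        raise InsufficientDataError(
            f"Shapiro-Wilk requires 3 <= n <= {_SHAPIRO_MAX_N}, got n={x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for a constant vector")
    return float(stats.shapiro(x).pvalue)


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=1)
    if sd == 0:
        # all genes identical on this parameter: z is identically 0
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def compute_gene_scores(
    matrix: ExpressionMatrix,
    *,
    log_transform: bool = False,
    zscore_one_minus_p: bool = True,
) -> pd.DataFrame:
    """Per-gene CV, normalized MAD, 1 - Shapiro-Wilk p, z-scores and distance.

    Parameters
    ----------
    matrix
        Expression matrix, assumed already low-expression filtered (every
        gene must have positive median; offending genes are dropped with a
        logged reason rather than failing the whole table).
    log_transform
        Apply log2(x + 1) before the Shapiro-Wilk test.  Raw values are
        the default.
    zscore_one_minus_p
        If False, the raw 1-p column enters the distance un-standardized
        (its z column then simply repeats the raw values).

    Returns
    -------
    pandas.DataFrame with columns ``SCORE_COLUMNS``, one row per surviving
    gene, in input order.
    """
    rows: list[dict] = []
    for gid, vals in zip(matrix.gene_ids, matrix.values):
        try:
            cv = coefficient_of_variation(vals)
            nmad = median_normalized_mad(vals)
            sw_input = np.log2(vals + 1.0) if log_transform else vals
            p = shapiro_wilk_pvalue(sw_input)
        except (UndefinedStatisticError, InsufficientDataError, DegenerateInputError) as exc:
            logger.info("dropping gene %s from score table: %s", gid, exc)
            continue
        rows.append({"gene_id": gid, "cv": cv, "nmad": nmad, "one_minus_p": 1.0 - p})
    if len(rows) < 2:
        raise InsufficientDataError(
            f"z-scores need >= 2 scored genes, got {len(rows)}"
        )
    table = pd.DataFrame(rows)
    table["z_cv"] = _zscore(table["cv"].to_numpy())
    table["z_nmad"] = _zscore(table["nmad"].to_numpy())
    if zscore_one_minus_p:
        table["z_one_minus_p"] = _zscore(table["one_minus_p"].to_numpy())
    else:
        table["z_one_minus_p"] = table["one_minus_p"]
    table["distance"] = np.sqrt(
        table["z_cv"] ** 2 + table["z_nmad"] ** 2 + table["z_one_minus_p"] ** 2
    )
    return table[SCORE_COLUMNS]


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
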