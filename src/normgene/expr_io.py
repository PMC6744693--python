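"""Reading, validating and filtering expression matrices and annotation tables.

The expression input is a plain TSV: first column gene identifiers, header
row sample identifiers, cells non-negative FPKM/TPM-like values.  Two
filters mirror a standard candidate-screen funnel:

* :func:`filter_annotated` keeps genes with a mapped name and chromosome;
* :func:`filter_low_expression` keeps genes whose per-gene median across
  samples is strictly positive (equivalently, for n samples, at least
  ceil(n/2) strictly positive values when n is odd).

Zeros are kept as true zeros; no pseudocount and no cross-library
normalization is applied.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateIdentifierError,
    MatrixParseError,
    ShapeError,
)

__all__ = [
    "ExpressionMatrix",
    "AnnotationTable",
    "GoAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation_table",
    "read_go_annotations",
    "read_go_gaf",
    "filter_annotated",
    "filter_low_expression",
]

_MIN_SAMPLES = 3

_GAF_ASPECT = {"C": "cellular_component", "F": "molecular_function", "P": "biological_process"}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense genes x samples matrix of non-negative expression values."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64
    warnings_: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ShapeError("expression values must be a 2-D array")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ShapeError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < _MIN_SAMPLES:
            raise ShapeError(
                f"at least {_MIN_SAMPLES} samples required, got {len(self.sample_ids)}"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(values)):
            raise MatrixParseError("expression values must be finite")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise MatrixParseError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: np.ndarray, warnings_: tuple[str, ...] = ()) -> "ExpressionMatrix":
        """Return a new matrix restricted to a boolean/index gene mask, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=tuple(self.gene_ids[i] for i in keep),
            sample_ids=self.sample_ids,
            values=self.values[keep],
            warnings_=self.warnings_ + warnings_,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class AnnotationTable:
    """gene_id -> (gene_name, chromosome); empty string means missing."""

    frame: pd.DataFrame  # columns: gene_id, gene_name, chromosome

    def __post_init__(self) -> None:
        required = {"gene_id", "gene_name", "chromosome"}
        missing = required - set(self.frame.columns)
        if missing:
            raise MatrixParseError(f"annotation table missing columns: {sorted(missing)}")
        dup = self.frame["gene_id"][self.frame["gene_id"].duplicated()]
        if not dup.empty:
            raise DuplicateIdentifierError(
                f"duplicate gene id in annotation table: {dup.iloc[0]!r}"
            )

    def mapped_gene_ids(self) -> set[str]:
        """Genes with both a non-empty name and a non-empty chromosome."""
        f = self.frame.fillna("")
        ok = (f["gene_name"].astype(str).str.strip() != "") & (
            f["chromosome"].astype(str).str.strip() != ""
        )
        return set(f.loc[ok, "gene_id"])


@dataclass(frozen=True)
class GoAnnotation:
    """Long-format GO records: one row per (gene_id, term_id) pair."""

    frame: pd.DataFrame  # columns: gene_id, term_id, term_label, aspect

    def __post_init__(self) -> None:
        required = {"gene_id", "term_id", "term_label", "aspect"}
        missing = required - set(self.frame.columns)
        if missing:
            raise MatrixParseError(f"GO table missing columns: {sorted(missing)}")
        dup = self.frame.duplicated(subset=["gene_id", "term_id"])
        if dup.any():
            pair = self.frame.loc[dup, ["gene_id", "term_id"]].iloc[0]
            raise DuplicateIdentifierError(
                f"duplicate GO record for ({pair['gene_id']!r}, {pair['term_id']!r})"
            )

    def records_for(self, gene_id: str) -> pd.DataFrame:
        return self.frame[self.frame["gene_id"] == gene_id]


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DuplicateIdentifierError(f"duplicate {kind}: {x!r}")
        seen.add(x)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header = samples).

    Raises
    ------
    DuplicateIdentifierError
        if a gene id repeats.
    MatrixParseError
        if a cell is non-numeric or negative; the message names the
        offending gene row and sample column.
    ShapeError
        if fewer than 3 sample columns are present.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixParseError(f"{path}: empty file or missing header")
        cols = header.split("\t")
        sample_ids = cols[1:]
        if len(sample_ids) < _MIN_SAMPLES:
            raise ShapeError(
                f"{path}: expected at least {_MIN_SAMPLES} sample columns, got {len(sample_ids)}"
            )
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise MatrixParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            row = []
            for j, cell in enumerate(parts[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise MatrixParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} for gene "
                        f"{parts[0]!r}, sample {sample_ids[j]!r}"
                    ) from None
                if not np.isfinite(v) or v < 0:
                    raise MatrixParseError(
                        f"{path}:{lineno}: invalid expression value {cell!r} for gene "
                        f"{parts[0]!r}, sample {sample_ids[j]!r} (must be finite and >= 0)"
                    )
                row.append(v)
            rows.append(row)
    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        values=np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids))),
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix back as TSV at full (repr) float precision."""
    buf = io.StringIO()
    buf.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
    for gid, row in zip(matrix.gene_ids, matrix.values):
        buf.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_annotation_table(path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return AnnotationTable(frame=frame)


def read_go_annotations(path) -> GoAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return GoAnnotation(frame=frame)


def read_go_gaf(path) -> GoAnnotation:
    """Thin GAF 2.x adapter: columns 2 (object id), 5 (GO id), 9 (aspect).

    GAF carries no term label; the label field is left empty, so downstream
    filtering matches on accession only for GAF input.
    """
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise MatrixParseError("GAF line with fewer than 9 columns")
            records.append(
                {
                    "gene_id": parts[1],
                    "term_id": parts[4],
                    "term_label": "",
                    "aspect": _GAF_ASPECT.get(parts[8], parts[8]),
                }
            )
    frame = pd.DataFrame(records, columns=["gene_id", "term_id", "term_label", "aspect"])
    frame = frame.drop_duplicates(subset=["gene_id", "term_id"], ignore_index=True)
    return GoAnnotation(frame=frame)


def filter_annotated(matrix: ExpressionMatrix, annotation: AnnotationTable) -> ExpressionMatrix:
    """Keep genes whose annotation has both a gene name and a chromosome.

    Genes absent from the annotation table are treated as unmapped and
    dropped.  An empty result is returned with a warning attached, not an
    error.
    """
    mapped = annotation.mapped_gene_ids()
    keep = np.array([g in mapped for g in matrix.gene_ids], dtype=bool)
    extra: tuple[str, ...] = ()
    if not keep.any():
        msg = "annotation filter removed every gene"
        warnings.warn(msg, stacklevel=2)
        extra = (msg,)
    return matrix.subset(keep, warnings_=extra)


def filter_low_expression(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Keep genes whose median expression across samples is strictly > 0.

    For even sample counts the median is the mean of the two central order
    statistics, so a gene survives iff strictly more than half its values
    are positive, or exactly half with a positive upper-central value.
    Returns the filtered matrix and the number of genes removed.
    """
    if matrix.n_genes == 0:
        return matrix, 0
    medians = np.median(matrix.values, axis=1)
    keep = medians > 0
    return matrix.subset(keep), int((~keep).sum())
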