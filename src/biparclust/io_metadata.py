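"""Expression-matrix and sample-metadata I/O with joint validation.

The on-disk convention is wide-transcriptomics: genes as rows, samples as
columns, a header row of sample ids and a first column of gene ids.
MatrixMarket input/output uses sidecar ``<stem>.genes.txt`` /
``<stem>.samples.txt`` files (one name per line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHENOTYPES = ("TNIL", "TIL", "PTB", "PPROM")
CASE_PHENOTYPES = ("TIL", "PTB", "PPROM")
CONTROL_PHENOTYPE = "TNIL"
LAYERS = ("AEC", "AMC", "CTC", "DEC")


class ValidationError(ValueError):
    """Raised when an input violates the data-model invariants."""


@dataclass(frozen=True)
class SampleMetadata:
    """One profiled region of interest: which patient, condition and tissue layer."""

    sample_id: str
    patient_id: str
    phenotype: str  # one of PHENOTYPES
    layer: str  # one of LAYERS

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown phenotype {self.phenotype!r}; "
                f"expected one of {PHENOTYPES}"
            )
        if self.layer not in LAYERS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown layer {self.layer!r}; "
                f"expected one of {LAYERS}"
            )

    @property
    def is_case(self) -> bool:
        return self.phenotype in CASE_PHENOTYPES


class ExpressionMatrix:
    """Normalized counts, genes x samples, with unique name indices.

    Values must be finite and, for raw counts, nonnegative; zeros are legal
    (the log2 floor is applied downstream, not here). Derived matrices
    (log2-transformed with a sub-unit floor, z-scaled) may carry negative
    values and pass ``nonnegative=False``.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        nonnegative: bool = True,
    ) -> None:
        values = np.asarray(values, dtype=float)
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {values.shape}")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match {len(gene_ids)} genes "
                f"x {len(sample_ids)} samples"
            )
        _check_unique(gene_ids, "gene_id")
        _check_unique(sample_ids, "sample_id")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        if nonnegative and np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value {values[i, j]} at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.nonnegative = nonnegative
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}

    # -- basic container protocol -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=0.0, atol=1e-9)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    # -- conversions --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving the given order."""
        try:
            rows = [self._gene_index[g] for g in gene_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown gene_id {exc.args[0]!r}") from exc
        return ExpressionMatrix(
            self.values[rows, :], list(gene_ids), self.sample_ids,
            nonnegative=self.nonnegative,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given samples, preserving the given order."""
        try:
            cols = [self._sample_index[s] for s in sample_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown sample_id {exc.args[0]!r}") from exc
        return ExpressionMatrix(
            self.values[:, cols], self.gene_ids, list(sample_ids),
            nonnegative=self.nonnegative,
        )


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValidationError(f"duplicate {what} {name!r}")
        seen.add(name)


# -- matrix I/O -------------------------------------------------------------------


def read_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from CSV, TSV or MatrixMarket coordinate format.

    ``format`` defaults to the file suffix (.csv/.tsv/.mtx). MatrixMarket files
    need sidecar ``<stem>.genes.txt`` and ``<stem>.samples.txt`` name files.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("csv", "tsv", "mtx"):
        raise ValueError(f"unsupported matrix format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        from scipy.io import mmread

        genes_file = path.parent / (path.stem + ".genes.txt")
        samples_file = path.parent / (path.stem + ".samples.txt")
        for side in (genes_file, samples_file):
            if not side.exists():
                raise FileNotFoundError(
                    f"MatrixMarket sidecar name file missing: {side}"
                )
        raw = mmread(str(path))
        values = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        gene_ids = genes_file.read_text().split()
        sample_ids = samples_file.read_text().split()
        return ExpressionMatrix(values, gene_ids, sample_ids)

    sep = "," if format == "csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed {format} file {path}: {exc}") from exc
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric) > 0:
        col = non_numeric[0]
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
        gene = bad.index[0] if len(bad) else "?"
        raise ValidationError(
            f"non-numeric value in {path} at gene {gene!r}, sample {col!r}"
        )
    return ExpressionMatrix.from_frame(frame)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix in the same conventions :func:`read_matrix` accepts."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(matrix.values))
        (path.parent / (path.stem + ".genes.txt")).write_text(
            "\n".join(matrix.gene_ids) + "\n"
        )
        (path.parent / (path.stem + ".samples.txt")).write_text(
            "\n".join(matrix.sample_ids) + "\n"
        )
        return
    if format not in ("csv", "tsv"):
        raise ValueError(f"unsupported matrix format {format!r}")
    sep = "," if format == "csv" else "\t"
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=sep, float_format="%.10g")


# -- metadata I/O -----------------------------------------------------------------

_METADATA_COLUMNS = ("sample_id", "patient_id", "phenotype", "layer")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the per-ROI sample sheet (CSV with sample_id, patient_id, phenotype, layer)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"metadata {path} missing columns {missing}")
    records = [
        SampleMetadata(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            phenotype=row.phenotype,
            layer=row.layer,
        )
        for row in frame.itertuples(index=False)
    ]
    validate_metadata(records)
    return records


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.sample_id, r.patient_id, r.phenotype, r.layer) for r in records],
        columns=list(_METADATA_COLUMNS),
    )
    frame.to_csv(path, index=False)


def validate_metadata(records: Sequence[SampleMetadata]) -> None:
    """Enforce unique sample ids and at most one ROI per (patient, layer)."""
    _check_unique([r.sample_id for r in records], "sample_id")
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.patient_id, r.layer)
        if key in seen:
            raise ValidationError(
                f"patient {r.patient_id!r} has more than one {r.layer} ROI"
            )
        seen.add(key)


def validate_joint(matrix: ExpressionMatrix, records: Sequence[SampleMetadata]) -> None:
    """Strict join: every matrix sample must carry a metadata record.

    Silent sample loss would corrupt the case/control bookkeeping, so a missing
    record is an error, never a drop.
    """
    known = {r.sample_id for r in records}
    missing = [s for s in matrix.sample_ids if s not in known]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")


def split_cases_controls(
    matrix: ExpressionMatrix, records: Sequence[SampleMetadata]
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition samples into cases (TIL, PTB, PPROM) and controls (TNIL).

    Column order of the input is preserved in both halves.
    """
    validate_joint(matrix, records)
    by_id = {r.sample_id: r for r in records}
    case_ids = [s for s in matrix.sample_ids if by_id[s].is_case]
    control_ids = [s for s in matrix.sample_ids if not by_id[s].is_case]
    if not case_ids:
        warnings.warn("no case samples (all TNIL); case matrix is empty", stacklevel=2)
    cases = matrix.subset_samples(case_ids) if case_ids else _empty_like(matrix)
    controls = (
        matrix.subset_samples(control_ids) if control_ids else _empty_like(matrix)
    )
    return cases, controls


def _empty_like(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(
        np.zeros((matrix.n_genes, 0)), matrix.gene_ids, []
    )
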