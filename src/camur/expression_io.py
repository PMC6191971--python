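"""Reading, validating, summarizing and writing case/control expression matrices.

The on-disk layout is a plain CSV: a header row, then one row per sample.
The first column holds the sample identifier, the last column the class
label, and every column in between one gene's expression value (FPKM-like,
non-negative). Values use ``.`` as decimal separator by default; a European
dialect (``;`` delimiter, ``,`` decimals) is available as an opt-in.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import numpy as np

PathOrStream = Union[str, os.PathLike, IO[str]]


class ExpressionIOError(ValueError):
    """Base class for matrix I/O problems."""


class MatrixParseError(ExpressionIOError):
    """Structurally malformed CSV (e.g. ragged rows)."""


class MatrixValidationError(ExpressionIOError):
    """Well-formed CSV whose content violates matrix constraints."""


@dataclass(frozen=True)
class CsvDialect:
    """Field delimiter + decimal separator for matrix CSV files."""

    delimiter: str = ","
    decimal: str = "."

    def parse_number(self, text: str) -> float:
        if self.decimal != ".":
            text = text.replace(self.decimal, ".")
        return float(text)

    def format_number(self, value: float) -> str:
        text = repr(float(value))
        if self.decimal != ".":
            text = text.replace(".", self.decimal)
        return text


DEFAULT_DIALECT = CsvDialect()
EUROPEAN_DIALECT = CsvDialect(delimiter=";", decimal=",")


@dataclass
class ExpressionMatrix:
    """Samples-by-genes expression values with one class label per sample.

    ``values[i, j]`` is the expression of sample ``i`` at gene ``j``.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: list[str]
    sample_col_name: str = "Sample"
    class_col_name: str = "Class"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D array")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def distinct_labels(self) -> list[str]:
        """Distinct labels, case-insensitively, first-seen casing preserved."""
        seen: dict[str, str] = {}
        for lab in self.labels:
            seen.setdefault(lab.casefold(), lab)
        return list(seen.values())

    def drop_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """A copy of the matrix without the named gene columns."""
        drop = set(gene_ids)
        keep = [j for j, g in enumerate(self.gene_ids) if g not in drop]
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[j] for j in keep],
            values=self.values[:, keep].copy(),
            labels=list(self.labels),
            sample_col_name=self.sample_col_name,
            class_col_name=self.class_col_name,
        )

    def take_samples(self, indices) -> "ExpressionMatrix":
        idx = list(indices)
        return ExpressionMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            values=self.values[idx, :].copy(),
            labels=[self.labels[i] for i in idx],
            sample_col_name=self.sample_col_name,
            class_col_name=self.class_col_name,
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and self.labels == other.labels
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


@dataclass(frozen=True)
class ClassCount:
    label: str
    count: int
    percentage: float  # of total samples, rounded to 2 decimals


@dataclass
class ClassSummary:
    total: int
    classes: list[ClassCount]

    def percentage_of(self, label: str) -> float:
        for entry in self.classes:
            if entry.label.casefold() == label.casefold():
                return entry.percentage
        raise KeyError(label)

    def count_of(self, label: str) -> int:
        for entry in self.classes:
            if entry.label.casefold() == label.casefold():
                return entry.count
        raise KeyError(label)


@dataclass(frozen=True)
class ValidationIssue:
    locus: str
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def _open_source(source: PathOrStream):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", newline="", encoding="utf-8"), True


def load_matrix(source: PathOrStream, dialect: CsvDialect = DEFAULT_DIALECT) -> ExpressionMatrix:
    """Load a matrix CSV: first column sample ids, last column class labels.

    Raises :class:`MatrixParseError` on ragged rows and
    :class:`MatrixValidationError` on non-numeric cells, missing values or
    duplicate identifiers.
    """
    fh, should_close = _open_source(source)
    try:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixParseError("empty input: no header row")
        if len(header) < 3:
            raise MatrixParseError(
                f"header has {len(header)} columns; need at least sample id, one gene and class"
            )
        sample_col, gene_ids, class_col = header[0], header[1:-1], header[-1]
        width = len(header)

        sample_ids: list[str] = []
        labels: list[str] = []
        rows: list[list[float]] = []
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise MatrixParseError(
                    f"row {row_no} has {len(row)} fields, expected {width}"
                )
            sample_ids.append(row[0])
            labels.append(row[-1])
            numeric: list[float] = []
            for col_off, cell in enumerate(row[1:-1], start=2):
                cell = cell.strip()
                if cell == "":
                    raise MatrixValidationError(
                        f"missing value at row {row_no}, column {col_off} "
                        f"(gene {gene_ids[col_off - 2]!r}); missing data are not supported"
                    )
                try:
                    numeric.append(dialect.parse_number(cell))
                except ValueError:
                    raise MatrixValidationError(
                        f"non-numeric expression value {cell!r} at row {row_no}, "
                        f"column {col_off} (gene {gene_ids[col_off - 2]!r})"
                    ) from None
            rows.append(numeric)
        if not rows:
            raise MatrixParseError("no data rows")

        dup_genes = _duplicates(gene_ids)
        if dup_genes:
            raise MatrixValidationError(f"duplicate gene ids: {sorted(dup_genes)}")
        dup_samples = _duplicates(sample_ids)
        if dup_samples:
            raise MatrixValidationError(f"duplicate sample ids: {sorted(dup_samples)}")

        return ExpressionMatrix(
            sample_ids=sample_ids,
            gene_ids=gene_ids,
            values=np.array(rows, dtype=float),
            labels=labels,
            sample_col_name=sample_col,
            class_col_name=class_col,
        )
    finally:
        if should_close:
            fh.close()


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for item in items:
        if item in seen:
            dups.add(item)
        seen.add(item)
    return dups


def validate_matrix(m: ExpressionMatrix) -> ValidationReport:
    """Check every matrix invariant; problems are reported, never raised."""
    issues: list[ValidationIssue] = []
    n, g = m.values.shape if m.values.ndim == 2 else (0, 0)

    if len(m.sample_ids) != n:
        issues.append(ValidationIssue("matrix", "shape_mismatch",
                                      f"{len(m.sample_ids)} sample ids but {n} value rows"))
    if len(m.labels) != n:
        issues.append(ValidationIssue("matrix", "shape_mismatch",
                                      f"{len(m.labels)} labels but {n} value rows"))
    if len(m.gene_ids) != g:
        issues.append(ValidationIssue("matrix", "shape_mismatch",
                                      f"{len(m.gene_ids)} gene ids but {g} value columns"))
    for dup in sorted(_duplicates(m.gene_ids)):
        issues.append(ValidationIssue(f"gene {dup}", "duplicate_gene", f"gene id {dup!r} repeats"))
    for dup in sorted(_duplicates(m.sample_ids)):
        issues.append(ValidationIssue(f"sample {dup}", "duplicate_sample",
                                      f"sample id {dup!r} repeats"))
    bad = ~np.isfinite(m.values) | (m.values < 0)
    for i, j in zip(*np.nonzero(bad)):
        value = m.values[i, j]
        code = "negative_value" if np.isfinite(value) else "non_finite_value"
        issues.append(ValidationIssue(
            f"({i},{j})", code,
            f"value {value!r} at sample {m.sample_ids[i] if i < len(m.sample_ids) else i!r}, "
            f"gene {m.gene_ids[j] if j < len(m.gene_ids) else j!r}",
        ))
    if len(m.distinct_labels()) < 2:
        only = m.distinct_labels()[0] if m.labels else "<none>"
        issues.append(ValidationIssue(
            "labels", "single_class",
            f"only one class present ({only!r}); supervised learning needs at least two",
        ))
    return ValidationReport(issues=issues)


def class_summary(m: ExpressionMatrix) -> ClassSummary:
    """Per-class sample counts and percentages (2 decimal places).

    Labels are grouped case-insensitively; the first casing seen is kept.
    """
    counts: dict[str, int] = {}
    display: dict[str, str] = {}
    for lab in m.labels:
        key = lab.casefold()
        display.setdefault(key, lab)
        counts[key] = counts.get(key, 0) + 1
    total = len(m.labels)
    entries = [
        ClassCount(label=display[key], count=c, percentage=round(100.0 * c / total, 2))
        for key, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return ClassSummary(total=total, classes=entries)


def write_matrix(m: ExpressionMatrix, dest: PathOrStream,
                 dialect: CsvDialect = DEFAULT_DIALECT) -> None:
    """Serialize to CSV such that :func:`load_matrix` round-trips exactly."""
    if m.n_genes < 1:
        raise MatrixValidationError("cannot write a matrix without gene columns")
    if hasattr(dest, "write"):
        _write_to(m, dest, dialect)
    else:
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            _write_to(m, fh, dialect)


def _write_to(m: ExpressionMatrix, fh: IO[str], dialect: CsvDialect) -> None:
    writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
    writer.writerow([m.sample_col_name, *m.gene_ids, m.class_col_name])
    for i, sid in enumerate(m.sample_ids):
        writer.writerow([sid, *(dialect.format_number(v) for v in m.values[i]), m.labels[i]])


def matrix_to_csv_text(m: ExpressionMatrix, dialect: CsvDialect = DEFAULT_DIALECT) -> str:
    buf = io.StringIO()
    write_matrix(m, buf, dialect)
    return buf.getvalue()


def matrix_fingerprint(m: ExpressionMatrix) -> str:
    """Stable content hash of the canonical CSV serialization."""
    import hashlib

    return hashlib.sha256(matrix_to_csv_text(m).encode("utf-8")).hexdigest()
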