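"""Typed containers and TSV readers for expression and clinical data.

Expression matrices are probe-by-sample tables of log2-scale intensities,
read either from a plain TSV (first column probe IDs, header row of sample
IDs) or from a GEO series-matrix-style file where ``!``-prefixed metadata
lines and the ``!series_matrix_table_begin/end`` sentinels wrap the same
table.  Clinical tables carry one row per sample with the treatment arm,
the pCR/RD response and receptor-status covariates.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIMENS: tuple[str, ...] = ("A", "TA", "TxA")
RESPONSES: tuple[str, ...] = ("pCR", "RD")
STATUSES: tuple[str, ...] = ("positive", "negative", "unknown")

#: clinical design-matrix columns produced by :func:`encode_clinical`
CLINICAL_COLUMNS: tuple[str, ...] = (
    "age",
    "er_pos",
    "er_known",
    "pr_pos",
    "pr_known",
    "her2_pos",
    "her2_known",
)


class FormatError(ValueError):
    """Malformed input file (duplicate IDs, bad cell, missing column)."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes x samples matrix of finite log2 intensities."""

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_probes, n_samples)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} ID {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            probe_ids=tuple(str(p) for p in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            probe_ids=self.probe_ids,
            sample_ids=tuple(sample_ids),
            values=self.values[:, cols],
        )


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient: cohort, regimen arm, pCR/RD response and covariates."""

    sample_id: str
    cohort_id: str
    regimen: str
    response: str
    age: float = math.nan
    er_status: str = "unknown"
    pr_status: str = "unknown"
    her2_status: str = "unknown"
    grade: str | None = None
    t_stage: str | None = None
    nodal_status: str | None = None

    def __post_init__(self) -> None:
        if self.regimen not in REGIMENS:
            raise FormatError(
                f"unrecognized regimen {self.regimen!r} for sample "
                f"{self.sample_id!r}; allowed: {set(REGIMENS)}"
            )
        if self.response not in RESPONSES:
            raise FormatError(
                f"unrecognized response {self.response!r} for sample "
                f"{self.sample_id!r}; allowed: {set(RESPONSES)}"
            )
        for nm, st in (
            ("er_status", self.er_status),
            ("pr_status", self.pr_status),
            ("her2_status", self.her2_status),
        ):
            if st not in STATUSES:
                raise FormatError(
                    f"unrecognized {nm} {st!r} for sample {self.sample_id!r}; "
                    f"allowed: {set(STATUSES)}"
                )


@dataclass(frozen=True)
class AlignmentReport:
    """Samples present on only one side of an expression/clinical join."""

    expression_only: tuple[str, ...] = ()
    clinical_only: tuple[str, ...] = ()


@dataclass(frozen=True)
class CohortDataset:
    """Expression matrix with sample-aligned clinical records."""

    expression: ExpressionMatrix
    clinical: tuple[ClinicalRecord, ...]
    alignment_report: AlignmentReport = field(default_factory=AlignmentReport)

    def __post_init__(self) -> None:
        expr_ids = list(self.expression.sample_ids)
        clin_ids = [r.sample_id for r in self.clinical]
        if expr_ids != clin_ids:
            raise FormatError("clinical records not aligned with expression columns")
        if not self.clinical:
            raise FormatError("empty dataset")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    def cohorts(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.clinical:
            seen.setdefault(r.cohort_id, None)
        return tuple(seen)

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.clinical]).set_index("sample_id")

    def response_vector(self) -> np.ndarray:
        """Binary response, 1 = pCR."""
        return np.array([1 if r.response == "pCR" else 0 for r in self.clinical])

    def subset(self, keep: Iterable[str]) -> "CohortDataset":
        keep_set = set(keep)
        records = tuple(r for r in self.clinical if r.sample_id in keep_set)
        if not records:
            raise ValueError("subset would be empty")
        ids = [r.sample_id for r in records]
        return CohortDataset(
            expression=self.expression.select_samples(ids), clinical=records
        )

    def regimen_subset(self, regimen: str) -> "CohortDataset":
        if regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {regimen!r}")
        return self.subset(
            r.sample_id for r in self.clinical if r.regimen == regimen
        )

    def drop_cohort(self, cohort_id: str) -> "CohortDataset":
        return self.subset(
            r.sample_id for r in self.clinical if r.cohort_id != cohort_id
        )

    def only_cohort(self, cohort_id: str) -> "CohortDataset":
        return self.subset(
            r.sample_id for r in self.clinical if r.cohort_id == cohort_id
        )


# ---------------------------------------------------------------------------
# readers / writers


def _parse_table(text: str, path: str) -> pd.DataFrame:
    # check the raw header first: pandas would silently mangle duplicates
    header = text.splitlines()[0].rstrip("\n").split("\t")[1:]
    frame = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    probe_ids = [str(p) for p in frame.index]
    sample_ids = [str(s) for s in header]
    for name, ids in (("probe", probe_ids), ("sample", sample_ids)):
        dupes = pd.Series(ids)
        dup = dupes[dupes.duplicated()].tolist()
        if dup:
            raise FormatError(f"{path}: duplicate {name} ID {dup[0]!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        raw = frame[col].to_numpy(dtype=object)
        try:
            # numpy's strtod-based conversion is correctly rounded, so a
            # %.17g write/read cycle is lossless
            values[:, j] = np.asarray(raw, dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(frame[col], errors="coerce")
            row = int(np.argmax(bad.isna().to_numpy()))
            raise FormatError(
                f"{path}: non-numeric cell at probe {probe_ids[row]!r}, "
                f"sample {sample_ids[j]!r}"
            ) from None
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: missing or non-finite expression values")
    return pd.DataFrame(values, index=probe_ids, columns=sample_ids)


def read_expression(
    path: str | Path, dialect: str = "plain", log2_transform: bool = False
) -> ExpressionMatrix:
    """Read a probe-by-sample expression TSV.

    ``dialect='series_matrix'`` skips ``!``-prefixed metadata lines and the
    table sentinels of GEO series-matrix files.  ``log2_transform`` applies
    log2 for matrices stored on the linear scale (off by default: inputs are
    assumed already normalized and log2-scaled).
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "series_matrix":
        kept = [
            line
            for line in text.splitlines()
            if not line.startswith("!") and line.strip() != ""
        ]
        text = "\n".join(kept) + "\n"
    elif dialect != "plain":
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = _parse_table(text, str(path))
    if log2_transform:
        if (frame.to_numpy() <= 0).any():
            raise FormatError(f"{path}: non-positive values cannot be log2-scaled")
        frame = np.log2(frame)
    return ExpressionMatrix.from_frame(frame)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "plain"
) -> None:
    path = Path(path)
    body = matrix.to_frame()
    body.index.name = "ID_REF"
    table = body.to_csv(sep="\t", lineterminator="\n", float_format="%.17g")
    if dialect == "series_matrix":
        header = (
            "!Series_title\tsynthetic\n"
            "!Series_platform_id\tsynthetic\n"
            "!series_matrix_table_begin\n"
        )
        path.write_text(header + table + "!series_matrix_table_end\n")
    elif dialect == "plain":
        path.write_text(table)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


_OPTIONAL_STR = ("grade", "t_stage", "nodal_status")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV with columns sample_id, cohort_id, regimen,
    response and optional age / er_status / pr_status / her2_status /
    grade / t_stage / nodal_status.  Empty statuses load as ``unknown``."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "cohort_id", "regimen", "response"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records: list[ClinicalRecord] = []
    for _, row in frame.iterrows():
        def get(col: str, default: str = "") -> str:
            v = row.get(col)
            return "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v).strip()

        age_txt = get("age")
        kwargs = dict(
            sample_id=get("sample_id"),
            cohort_id=get("cohort_id"),
            regimen=get("regimen"),
            response=get("response"),
            age=float(age_txt) if age_txt else math.nan,
            er_status=get("er_status") or "unknown",
            pr_status=get("pr_status") or "unknown",
            her2_status=get("her2_status") or "unknown",
        )
        for col in _OPTIONAL_STR:
            kwargs[col] = get(col) or None
        records.append(ClinicalRecord(**kwargs))
    ids = [r.sample_id for r in records]
    dup = pd.Series(ids)
    dup = dup[dup.duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate sample ID {dup[0]!r}")
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    frame = pd.DataFrame([vars(r) for r in records])
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def align(
    expression: ExpressionMatrix, clinical: Sequence[ClinicalRecord]
) -> CohortDataset:
    """Intersection-align expression columns and clinical rows.

    Samples present on only one side are excluded but reported in the
    returned dataset's ``alignment_report``; an empty intersection raises.
    """
    expr_ids = set(expression.sample_ids)
    clin_ids = [r.sample_id for r in clinical]
    common = [s for s in clin_ids if s in expr_ids]
    if not common:
        raise FormatError("no samples shared between expression and clinical data")
    report = AlignmentReport(
        expression_only=tuple(s for s in expression.sample_ids if s not in set(clin_ids)),
        clinical_only=tuple(s for s in clin_ids if s not in expr_ids),
    )
    by_id = {r.sample_id: r for r in clinical}
    records = tuple(by_id[s] for s in common)
    return CohortDataset(
        expression=expression.select_samples(common),
        clinical=records,
        alignment_report=report,
    )


def align_dataset(dataset: CohortDataset) -> CohortDataset:
    """Idempotent re-alignment of an already-built dataset."""
    return align(dataset.expression, dataset.clinical)


def encode_clinical(
    records: Sequence[ClinicalRecord], age_fill: float | None = None
) -> pd.DataFrame:
    """Expand clinical records into a numeric design matrix.

    Each receptor status becomes two indicators (``*_pos``, ``*_known``) so
    that "unknown" is representable without imputation.  Missing ages are
    filled with ``age_fill`` (or the observed median when ``None``).
    """
    rows = []
    for r in records:
        rows.append(
            {
                "age": r.age,
                "er_pos": 1.0 if r.er_status == "positive" else 0.0,
                "er_known": 0.0 if r.er_status == "unknown" else 1.0,
                "pr_pos": 1.0 if r.pr_status == "positive" else 0.0,
                "pr_known": 0.0 if r.pr_status == "unknown" else 1.0,
                "her2_pos": 1.0 if r.her2_status == "positive" else 0.0,
                "her2_known": 0.0 if r.her2_status == "unknown" else 1.0,
            }
        )
    frame = pd.DataFrame(rows, index=[r.sample_id for r in records])
    if frame["age"].isna().any():
        fill = age_fill
        if fill is None:
            med = frame["age"].median()
            fill = 50.0 if math.isnan(med) else float(med)
        frame["age"] = frame["age"].fillna(fill)
    return frame[list(CLINICAL_COLUMNS)]
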