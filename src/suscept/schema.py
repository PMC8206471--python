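"""Cohort data model, delimited-table I/O and cohort-flow accounting.

The central rectangle of the pipeline is :class:`CohortTable`, a thin
validated wrapper around a :class:`pandas.DataFrame` with one row per
subject.  Subjects carry demographics, either raw questionnaire item
responses or pre-computed scale scores, and a raw hair-cortisol
concentration (pg/mg).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

DEPARTMENTS = (
    "ICU",
    "EICU",
    "emergency",
    "radiotherapy",
    "psychology",
    "rehabilitation",
    "other",
)
SHIFT_PATTERNS = ("three_shift_8h", "two_shift_12h")

SCALE_COLUMNS = (
    "job_control",
    "psych_demands",
    "supervisor_support",
    "coworker_support",
)
OUTCOME_COLUMNS = ("ee", "dp", "pe")
MODERATOR_COLUMNS = ("hcc_raw", "log_hcc")

#: 22 JCQ items: 6 skill discretion + 3 decision authority (job control),
#: 5 psychological demands, 4 supervisor support, 4 coworker support.
JCQ_ITEM_COLUMNS = tuple(f"jcq_{i:02d}" for i in range(1, 23))
#: 16 MBI items: 5 emotional exhaustion, 5 depersonalization,
#: 6 professional efficiency.
MBI_ITEM_COLUMNS = tuple(f"mbi_{i:02d}" for i in range(1, 17))

DEMOGRAPHIC_COLUMNS = ("department", "shift_pattern", "tenure_years")
REQUIRED_COLUMNS = ("subject_id",) + DEMOGRAPHIC_COLUMNS + ("hcc_raw",)

NA_VALUES = ("", "NA")


class CohortSchemaError(ValueError):
    """Base class for cohort-schema violations."""


class MissingColumnError(CohortSchemaError):
    """A required column could not be mapped from the input header."""


class InvalidCategoryError(CohortSchemaError):
    """A categorical field holds a value outside its closed set."""


class OutOfRangeError(CohortSchemaError):
    """A numeric field lies outside its declared range."""


class DuplicateSubjectError(CohortSchemaError):
    """Subject identifiers are not unique."""


class FlowMonotonicityError(CohortSchemaError):
    """Cohort-flow counts violate recruitment monotonicity."""


@dataclass
class SubjectRecord:
    """One subject's demographics, responses and moderator value."""

    subject_id: str
    department: str
    shift_pattern: str
    tenure_years: float
    hcc_raw: float
    jcq_items: tuple[int, ...] | None = None
    mbi_items: tuple[int, ...] | None = None
    job_control: float | None = None
    psych_demands: float | None = None
    supervisor_support: float | None = None
    coworker_support: float | None = None
    ee: float | None = None
    dp: float | None = None
    pe: float | None = None

    def validate(self) -> None:
        if self.department not in DEPARTMENTS:
            raise InvalidCategoryError(
                f"subject {self.subject_id!r}: unknown department "
                f"{self.department!r}; expected one of {DEPARTMENTS}"
            )
        if self.shift_pattern not in SHIFT_PATTERNS:
            raise InvalidCategoryError(
                f"subject {self.subject_id!r}: unknown shift pattern "
                f"{self.shift_pattern!r}; expected one of {SHIFT_PATTERNS}"
            )
        if not np.isfinite(self.tenure_years) or self.tenure_years < 0:
            raise OutOfRangeError(
                f"subject {self.subject_id!r}: tenure_years must be >= 0"
            )
        if not np.isfinite(self.hcc_raw) or self.hcc_raw <= 0:
            raise OutOfRangeError(
                f"subject {self.subject_id!r}: hcc_raw must be > 0 pg/mg"
            )
        if self.jcq_items is not None:
            if len(self.jcq_items) != 22:
                raise OutOfRangeError(
                    f"subject {self.subject_id!r}: expected 22 JCQ items, "
                    f"got {len(self.jcq_items)}"
                )
            for i, v in enumerate(self.jcq_items, start=1):
                if not 1 <= v <= 4:
                    raise OutOfRangeError(
                        f"subject {self.subject_id!r}: JCQ item {i} = {v} "
                        "outside 1..4"
                    )
        if self.mbi_items is not None:
            if len(self.mbi_items) != 16:
                raise OutOfRangeError(
                    f"subject {self.subject_id!r}: expected 16 MBI items, "
                    f"got {len(self.mbi_items)}"
                )
            for i, v in enumerate(self.mbi_items, start=1):
                if not 1 <= v <= 7:
                    raise OutOfRangeError(
                        f"subject {self.subject_id!r}: MBI item {i} = {v} "
                        "outside 1..7"
                    )


@dataclass
class CohortTable:
    """Validated per-subject rectangle plus a provenance tag."""

    data: pd.DataFrame
    provenance: str = ""

    @property
    def n(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.provenance)

    def validate(self) -> "CohortTable":
        df = self.data
        for col in ("subject_id", "department", "shift_pattern"):
            if col not in df.columns:
                raise MissingColumnError(f"required column {col!r} not present")
        ids = df["subject_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise DuplicateSubjectError(f"duplicate subject ids: {dupes}")
        _check_closed_set(df, "department", DEPARTMENTS)
        _check_closed_set(df, "shift_pattern", SHIFT_PATTERNS)
        if "tenure_years" in df.columns:
            bad = df.index[df["tenure_years"].astype(float) < 0]
            if len(bad):
                raise OutOfRangeError(
                    f"negative tenure_years at row(s) {list(bad[:5])}"
                )
        if "hcc_raw" in df.columns:
            hcc = df["hcc_raw"].astype(float)
            bad = df.index[~(hcc > 0) | hcc.isna()]
            if len(bad):
                raise OutOfRangeError(
                    f"hcc_raw must be > 0 and non-missing; offending row(s) "
                    f"{list(bad[:5])}"
                )
        _check_item_range(df, JCQ_ITEM_COLUMNS, 1, 4)
        _check_item_range(df, MBI_ITEM_COLUMNS, 1, 7)
        has_items = all(c in df.columns for c in JCQ_ITEM_COLUMNS) and all(
            c in df.columns for c in MBI_ITEM_COLUMNS
        )
        has_scores = all(
            c in df.columns for c in SCALE_COLUMNS + OUTCOME_COLUMNS
        )
        if not (has_items or has_scores):
            raise MissingColumnError(
                "cohort must carry either the full item sets "
                "(jcq_01..jcq_22, mbi_01..mbi_16) or pre-computed scale "
                "scores (job_control..coworker_support, ee, dp, pe)"
            )
        return self

    def records(self) -> Iterator[SubjectRecord]:
        df = self.data
        has_jcq = all(c in df.columns for c in JCQ_ITEM_COLUMNS)
        has_mbi = all(c in df.columns for c in MBI_ITEM_COLUMNS)
        for _, row in df.iterrows():
            yield SubjectRecord(
                subject_id=str(row["subject_id"]),
                department=row["department"],
                shift_pattern=row["shift_pattern"],
                tenure_years=float(row["tenure_years"]),
                hcc_raw=float(row["hcc_raw"]),
                jcq_items=tuple(int(row[c]) for c in JCQ_ITEM_COLUMNS)
                if has_jcq
                else None,
                mbi_items=tuple(int(row[c]) for c in MBI_ITEM_COLUMNS)
                if has_mbi
                else None,
                **{
                    c: (float(row[c]) if c in df.columns and pd.notna(row[c]) else None)
                    for c in SCALE_COLUMNS + OUTCOME_COLUMNS
                },
            )

    @classmethod
    def from_records(
        cls, records: Sequence[SubjectRecord], provenance: str = ""
    ) -> "CohortTable":
        rows = []
        for rec in records:
            rec.validate()
            row: dict[str, Any] = {
                "subject_id": rec.subject_id,
                "department": rec.department,
                "shift_pattern": rec.shift_pattern,
                "tenure_years": rec.tenure_years,
                "hcc_raw": rec.hcc_raw,
            }
            if rec.jcq_items is not None:
                row.update(dict(zip(JCQ_ITEM_COLUMNS, rec.jcq_items)))
            if rec.mbi_items is not None:
                row.update(dict(zip(MBI_ITEM_COLUMNS, rec.mbi_items)))
            for c in SCALE_COLUMNS + OUTCOME_COLUMNS:
                v = getattr(rec, c)
                if v is not None:
                    row[c] = v
            rows.append(row)
        return cls(pd.DataFrame(rows), provenance).validate()


def _check_closed_set(
    df: pd.DataFrame, column: str, allowed: tuple[str, ...]
) -> None:
    values = df[column]
    bad = ~values.isin(allowed)
    if bad.any():
        row = int(df.index[bad][0])
        raise InvalidCategoryError(
            f"invalid {column} value {values[bad].iloc[0]!r} at row {row}; "
            f"allowed: {allowed}"
        )


def _check_item_range(
    df: pd.DataFrame, columns: tuple[str, ...], lo: int, hi: int
) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            row = int(df.index[bad][0])
            raise OutOfRangeError(
                f"{col} = {vals[bad].iloc[0]!r} at row {row} outside "
                f"{lo}..{hi}"
            )


def read_cohort(
    path: str | Path,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> CohortTable:
    """Read a delimited cohort table, validate and return it.

    ``column_map`` maps file headers to canonical schema names; unmapped
    headers are kept as-is.  Empty fields and the string ``NA`` are
    treated as missing.  Out-of-range items and unknown categories are
    rejected, never coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(
        path, sep=sep, na_values=list(NA_VALUES), keep_default_na=False
    )
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(
                f"required column {col!r} missing from {path.name} "
                f"(headers: {list(df.columns)})"
            )
    table = CohortTable(df, provenance or str(path))
    return table.validate()


def write_cohort(table: CohortTable, path: str | Path, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=False, na_rep="")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            out.update(_flatten(v, key))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}[{i}]"))
    else:
        out[prefix or "value"] = obj
    return out


def write_tables(
    results: Any,
    path: str | Path,
    columns: Sequence[str] | None = None,
    sep: str = ",",
) -> tuple[Path, Path]:
    """Write a result object as delimited text plus structured text.

    Emits ``<path>.csv`` (one row per result) and ``<path>.json`` (full
    stored precision); re-reading the JSON reproduces every field
    exactly.  Returns the two paths written.
    """
    path = Path(path)
    json_path = path.with_suffix(".json")
    csv_path = path.with_suffix(".csv")
    payload = _jsonable(results)
    json_path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if isinstance(results, pd.DataFrame):
        results.to_csv(csv_path, sep=sep, index=False)
    else:
        items = results if isinstance(results, (list, tuple)) else [results]
        rows = [_flatten(_jsonable(item)) for item in items]
        if rows:
            frame = pd.DataFrame(rows)
        else:
            frame = pd.DataFrame(columns=list(columns or []))
        frame.to_csv(csv_path, sep=sep, index=False)
    return csv_path, json_path


def read_tables(path: str | Path) -> Any:
    """Read back the structured-text rendition written by write_tables."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    return json.loads(path.read_text(encoding="utf-8"))


@dataclass
class CohortFlow:
    """Recruitment-to-analysis accounting with stage percentages."""

    recruited: int
    questionnaire_complete: int
    hair_provided: int
    excluded: int
    analyzed: int = field(init=False)
    questionnaire_pct: float = field(init=False)
    hair_pct: float = field(init=False)
    excluded_pct: float = field(init=False)
    analyzed_pct: float = field(init=False)

    def __post_init__(self) -> None:
        counts = (
            self.recruited,
            self.questionnaire_complete,
            self.hair_provided,
            self.excluded,
        )
        if any(c < 0 for c in counts):
            raise FlowMonotonicityError(f"counts must be non-negative: {counts}")
        if not (
            self.recruited
            >= self.questionnaire_complete
            >= self.hair_provided
            >= self.excluded
        ):
            raise FlowMonotonicityError(
                "expected recruited >= questionnaire_complete >= "
                f"hair_provided >= excluded, got {counts}"
            )
        if self.recruited == 0:
            raise FlowMonotonicityError("recruited must be positive")
        self.analyzed = self.hair_provided - self.excluded
        pct = lambda c: round(100.0 * c / self.recruited, 2)  # noqa: E731
        self.questionnaire_pct = pct(self.questionnaire_complete)
        self.hair_pct = pct(self.hair_provided)
        self.excluded_pct = pct(self.excluded)
        self.analyzed_pct = pct(self.analyzed)


def cohort_flow(
    recruited: int,
    questionnaire_complete: int,
    hair_provided: int,
    excluded: int,
) -> CohortFlow:
    """Account for cohort flow; percentages are of the recruited count."""
    return CohortFlow(recruited, questionnaire_complete, hair_provided, excluded)
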