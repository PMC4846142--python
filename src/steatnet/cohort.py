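"""Fish records, cohorts, the health-status rule and cohort CSV/TSV I/O.

A cohort is one row per fish: id, sex, morphometrics, the averaged
veterinary pansteatitis score (0-5 in 0.5 steps) and the blood panel.
Missingness is a first-class state — an analyte a rotor failed to report
is stored as ``None``/``NaN``, never as zero or a sentinel.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

from .analytes import ANALYTE_CODES, ANALYTES, flag_value

__all__ = [
    "HealthStatus",
    "FishRecord",
    "Cohort",
    "classify_status",
    "range_flags",
    "load_cohort",
    "save_cohort",
    "CohortValidationError",
]

#: Canonical column order of the normalized cohort CSV.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "fish_id",
    "sex",
    "total_length",
    "weight",
    "age",
    "vet_score",
) + ANALYTE_CODES

SEXES = ("male", "female")


class CohortValidationError(ValueError):
    """Raised when a record or file violates the cohort contract."""


class HealthStatus(str, Enum):
    HEALTHY = "healthy"
    DISEASED = "diseased"


def _on_half_grid(score: float, tol: float = 1e-9) -> bool:
    return abs(2.0 * score - round(2.0 * score)) <= tol


def classify_status(vet_score: float, strict: bool = True) -> HealthStatus:
    """Designate health status from the averaged veterinary score.

    A fish is healthy below a score of 1 (a 0.5 — tiny, subtle lesions —
    still counts as healthy) and diseased at 1 or above.

    Parameters
    ----------
    vet_score : float
        Score in [0, 5]; expected on a 0.5 grid (multi-examiner averages).
    strict : bool
        When True (default), a score off the 0.5 grid raises; the cohort
        loader uses ``strict=False`` and warns instead.
    """
    if not 0.0 <= vet_score <= 5.0:
        raise CohortValidationError(f"vet_score {vet_score} outside [0, 5]")
    if not _on_half_grid(vet_score):
        msg = f"vet_score {vet_score} is off the 0.5 grid"
        if strict:
            raise CohortValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    return HealthStatus.HEALTHY if vet_score < 1.0 else HealthStatus.DISEASED


@dataclass
class FishRecord:
    """One sampled fish: morphometrics, vet score and the analyte panel."""

    fish_id: str
    sex: str
    total_length: float  # cm
    weight: float  # kg
    vet_score: float
    age: int | None = None  # years, from otolith annuli
    analytes: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.total_length > 0:
            raise CohortValidationError(f"total_length must be positive ({self.fish_id})")
        if not self.weight > 0:
            raise CohortValidationError(f"weight must be positive ({self.fish_id})")
        if not 0.0 <= self.vet_score <= 5.0:
            raise CohortValidationError(
                f"vet_score {self.vet_score} outside [0, 5] ({self.fish_id})"
            )
        if not _on_half_grid(self.vet_score):
            warnings.warn(
                f"vet_score {self.vet_score} off the 0.5 grid ({self.fish_id})",
                stacklevel=2,
            )
        unknown = set(self.analytes) - set(ANALYTES)
        if unknown:
            raise CohortValidationError(f"unknown analyte code(s) {sorted(unknown)}")

    @property
    def status(self) -> HealthStatus:
        return classify_status(self.vet_score, strict=False)


def range_flags(record: FishRecord) -> dict[str, str]:
    """Flag every analyte of a record against the instrument ranges.

    Missing analytes (absent from the record or ``None``) flag as
    ``"missing"``; present values flag ``below`` / ``in_range`` / ``above``
    with inclusive bounds.
    """
    return {code: flag_value(code, record.analytes.get(code)) for code in ANALYTE_CODES}


@dataclass
class Cohort:
    """Ordered collection of fish records with unique ids."""

    records: list[FishRecord]
    provenance: str = ""
    n_rows_read: int | None = None
    n_rows_rejected: int | None = None

    def __post_init__(self) -> None:
        ids = [r.fish_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate fish_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, sex: str | None = None, status: HealthStatus | str | None = None) -> "Cohort":
        recs = self.records
        if sex is not None:
            recs = [r for r in recs if r.sex == sex]
        if status is not None:
            status = HealthStatus(status)
            recs = [r for r in recs if r.status == status]
        return Cohort(list(recs), provenance=self.provenance)

    @property
    def n_healthy(self) -> int:
        return sum(r.status is HealthStatus.HEALTHY for r in self.records)

    @property
    def n_diseased(self) -> int:
        return sum(r.status is HealthStatus.DISEASED for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Normalized one-row-per-fish table in canonical column order.

        Adds a derived ``status`` column; missing analytes become NaN.
        """
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "fish_id": r.fish_id,
                "sex": r.sex,
                "total_length": r.total_length,
                "weight": r.weight,
                "age": float("nan") if r.age is None else float(r.age),
                "vet_score": r.vet_score,
            }
            for code in ANALYTE_CODES:
                v = r.analytes.get(code)
                row[code] = float("nan") if v is None else float(v)
            row["status"] = r.status.value
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + ["status"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = []
        for _, row in df.iterrows():
            age = row.get("age")
            age = None if age is None or (isinstance(age, float) and math.isnan(age)) else int(round(age))
            analytes: dict[str, float | None] = {}
            for code in ANALYTE_CODES:
                if code in df.columns:
                    v = row[code]
                    analytes[code] = None if pd.isna(v) else float(v)
            records.append(
                FishRecord(
                    fish_id=str(row["fish_id"]),
                    sex=str(row["sex"]),
                    total_length=float(row["total_length"]),
                    weight=float(row["weight"]),
                    vet_score=float(row["vet_score"]),
                    age=age,
                    analytes=analytes,
                )
            )
        return cls(records, provenance=provenance)


def _read_schema(schema: dict | str | Path | None) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        text = Path(schema).read_text()
        if str(schema).endswith(".json"):
            return json.loads(text)
        return yaml.safe_load(text) or {}
    return dict(schema)


def load_cohort(
    path: str | Path,
    schema: dict | str | Path | None = None,
    provenance: str | None = None,
) -> Cohort:
    """Read a cohort CSV/TSV into validated records.

    The optional ``schema`` (dict, or path to a YAML/JSON file) may carry:

    - ``columns``: mapping of canonical column name -> file column name,
    - ``sex_codes``: mapping of file sex value -> ``male``/``female``,
    - ``sep`` and ``decimal``: CSV dialect overrides (default inferred
      from the extension, ``.`` decimal),
    - ``units``: mapping analyte code -> units string, validated against
      the analyte registry.

    Blank analyte cells become explicit missing values.  Unknown analyte
    columns, non-numeric values and duplicate ids raise
    :class:`CohortValidationError`.  ``n_rows_read`` / ``n_rows_rejected``
    are recorded on the returned cohort (rows lacking id, sex, length,
    weight or vet score are rejected, not silently dropped analytes).
    """
    path = Path(path)
    sch = _read_schema(schema)
    sep = sch.get("sep", "\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    decimal = sch.get("decimal", ".")
    units = sch.get("units") or {}
    for code, unit in units.items():
        if code not in ANALYTES:
            raise CohortValidationError(f"unknown analyte code in schema units: {code!r}")
        if unit != ANALYTES[code].units:
            raise CohortValidationError(
                f"units mismatch for {code}: file says {unit!r}, registry says "
                f"{ANALYTES[code].units!r}"
            )

    try:
        df = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(
            f"{path}: empty file — expected a header with at least "
            "fish_id, sex, total_length, weight, vet_score"
        ) from None

    colmap = sch.get("columns") or {}
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)

    required = ("fish_id", "sex", "total_length", "weight", "vet_score")
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"{path}: missing required column(s) {missing_cols}")

    known = set(CANONICAL_COLUMNS) | {"status"}
    unknown_cols = [c for c in df.columns if c not in known]
    if unknown_cols:
        raise CohortValidationError(
            f"{path}: unknown column(s) {unknown_cols}; analyte codes must be "
            f"one of {list(ANALYTE_CODES)}"
        )

    sex_codes = {"male": "male", "female": "female", "m": "male", "f": "female",
                 "M": "male", "F": "female"}
    sex_codes.update(sch.get("sex_codes") or {})

    def parse_num(cell: str, col: str, fish_id: str) -> float | None:
        cell = cell.strip()
        if cell == "" or cell.upper() in {"NA", "NAN", "ND"}:
            return None
        try:
            return float(cell)
        except ValueError:
            raise CohortValidationError(
                f"non-numeric value {cell!r} in column {col} (fish {fish_id})"
            ) from None

    records: list[FishRecord] = []
    n_rejected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        for _, row in df.iterrows():
            fish_id = str(row["fish_id"]).strip()
            raw_sex = str(row["sex"]).strip()
            if not fish_id or raw_sex not in sex_codes:
                n_rejected += 1
                continue
            core = {c: parse_num(str(row[c]), c, fish_id) for c in
                    ("total_length", "weight", "vet_score")}
            if any(v is None for v in core.values()):
                n_rejected += 1
                continue
            age = parse_num(str(row.get("age", "")), "age", fish_id) if "age" in df.columns else None
            analytes = {
                code: parse_num(str(row[code]), code, fish_id)
                for code in ANALYTE_CODES
                if code in df.columns
            }
            if core["vet_score"] is not None and not _on_half_grid(core["vet_score"]):
                warnings.warn(
                    f"vet_score {core['vet_score']} off the 0.5 grid (fish {fish_id})"
                )
            records.append(
                FishRecord(
                    fish_id=fish_id,
                    sex=sex_codes[raw_sex],
                    total_length=core["total_length"],
                    weight=core["weight"],
                    vet_score=core["vet_score"],
                    age=None if age is None else int(round(age)),
                    analytes=analytes,
                )
            )
    cohort = Cohort(records, provenance=provenance or str(path))
    cohort.n_rows_read = len(df)
    cohort.n_rows_rejected = n_rejected
    return cohort


def save_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write the normalized cohort CSV (canonical column order).

    Missing cells are emitted empty; the written file round-trips through
    :func:`load_cohort` losslessly, including missingness.
    """
    path = Path(path)
    df = cohort.to_frame().drop(columns=["status"])
    df.to_csv(path, index=False)  # default float repr round-trips exactly
    return path
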