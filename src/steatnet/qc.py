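"""Quality-control arithmetic for replicate panels and reference comparisons.

Covers the precision/accuracy bookkeeping done around a benchtop analyzer:
relative standard deviation of replicate runs, symmetric percent
difference, the analyzer's derived globulin, and classification of a
measured mean against a certified/reference confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateSet",
    "ReferenceValue",
    "ReferenceComparison",
    "rsd",
    "percent_difference",
    "derive_glob",
    "compare_to_reference",
    "load_replicates",
    "load_references",
    "qc_report",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Repeated measurements of one analyte on one QC sample."""

    label: str
    analyte: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(not math.isfinite(v) for v in vals):
            raise ValueError(f"{self.label}/{self.analyte}: non-finite replicate value")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ReferenceValue:
    """A certified, reference or comparison value for one analyte."""

    analyte: str
    kind: str  # certified | reference | comparison
    center: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError(f"{self.analyte}: give both CI bounds or neither")
        if self.ci_low is not None and not self.ci_low <= self.center <= self.ci_high:
            raise ValueError(
                f"{self.analyte}: CI [{self.ci_low}, {self.ci_high}] must bracket "
                f"center {self.center}"
            )


@dataclass(frozen=True)
class ReferenceComparison:
    analyte: str
    classification: str  # within | below | above
    percent_difference: float  # signed, relative to the reference center


def rsd(replicates: ReplicateSet) -> float:
    """Relative standard deviation in percent: 100 x sample SD / mean.

    Sample SD uses the n-1 denominator (replicate precision convention).
    Requires at least two replicates and a nonzero mean.
    """
    if replicates.n < 2:
        raise ValueError(f"{replicates.analyte}: need n >= 2 replicates, got {replicates.n}")
    vals = np.asarray(replicates.values, dtype=float)
    mean = vals.mean()
    if mean == 0.0:
        raise ValueError(f"{replicates.analyte}: RSD undefined for zero mean")
    return float(100.0 * vals.std(ddof=1) / abs(mean))


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference: 100 x |a - b| / mean(a, b).

    Symmetric in its arguments and zero iff a == b.
    """
    denom = (a + b) / 2.0
    if denom == 0.0:
        raise ValueError("percent difference undefined when a + b = 0")
    return float(100.0 * abs(a - b) / abs(denom))


def derive_glob(tp: float, alb: float) -> float:
    """Globulin as the analyzer derives it: total protein minus albumin."""
    if alb < 0 or tp < 0:
        raise ValueError("TP and ALB must be non-negative")
    if alb > tp:
        raise ValueError(f"negative globulin: ALB ({alb}) exceeds TP ({tp})")
    return tp - alb


def compare_to_reference(measured_mean: float, ref: ReferenceValue) -> ReferenceComparison:
    """Classify a measured mean against a reference confidence interval.

    The percent difference is signed relative to the reference center
    (positive when measured above it); classification needs CI bounds.
    """
    if ref.ci_low is None:
        raise ValueError(f"{ref.analyte}: classification requires CI bounds")
    if ref.center == 0:
        raise ValueError(f"{ref.analyte}: percent difference undefined for zero center")
    if measured_mean < ref.ci_low:
        cls = "below"
    elif measured_mean > ref.ci_high:
        cls = "above"
    else:
        cls = "within"
    pct = 100.0 * (measured_mean - ref.center) / abs(ref.center)
    return ReferenceComparison(ref.analyte, cls, float(pct))


def load_replicates(path: str | Path) -> list[ReplicateSet]:
    """Read a replicate table CSV with columns label, analyte, value."""
    df = pd.read_csv(path)
    out = []
    for (label, analyte), grp in df.groupby(["label", "analyte"], sort=False):
        out.append(ReplicateSet(str(label), str(analyte), tuple(grp["value"].astype(float))))
    return out


def load_references(path: str | Path) -> list[ReferenceValue]:
    """Read a reference table CSV: analyte, kind, center, ci_low, ci_high."""
    df = pd.read_csv(path)
    refs = []
    for _, row in df.iterrows():
        lo = None if pd.isna(row.get("ci_low")) else float(row["ci_low"])
        hi = None if pd.isna(row.get("ci_high")) else float(row["ci_high"])
        refs.append(ReferenceValue(str(row["analyte"]), str(row["kind"]),
                                   float(row["center"]), lo, hi))
    return refs


def qc_report(
    replicates: list[ReplicateSet],
    references: list[ReferenceValue] | None = None,
    measured_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the QC summary: per-analyte n, mean, SD, RSD%, and — when a
    reference and a measured mean are supplied — the CI classification and
    signed percent difference versus the reference center."""
    refs = {r.analyte: r for r in (references or [])}
    measured = measured_means or {}
    rows = []
    for rep in replicates:
        vals = np.asarray(rep.values, dtype=float)
        row: dict[str, object] = {
            "label": rep.label,
            "analyte": rep.analyte,
            "n": rep.n,
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if rep.n >= 2 else float("nan"),
            "rsd_pct": rsd(rep) if rep.n >= 2 and vals.mean() != 0 else float("nan"),
        }
        mean = measured.get(rep.analyte, float(vals.mean()))
        ref = refs.get(rep.analyte)
        if ref is not None and ref.ci_low is not None:
            cmpres = compare_to_reference(mean, ref)
            row["vs_reference"] = cmpres.classification
            row["signed_pct_diff"] = cmpres.percent_difference
        rows.append(row)
    return pd.DataFrame(rows)
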