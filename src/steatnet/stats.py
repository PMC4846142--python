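"""Univariate healthy-vs-diseased battery with assumption-driven test choice.

Each variable is first screened for sexual dimorphism (male vs female within
each health class); dimorphic variables are compared per sex, the rest with
sexes combined to increase power.  Within each comparison the two groups are
checked for normality (Shapiro-Wilk, per group) and equal variances
(Levene); the comparison runs a classical two-tailed t-test when both hold,
otherwise a two-sided Mann-Whitney U (exact for small untied samples,
normal approximation with tie and continuity corrections otherwise).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .analytes import ANALYTE_CODES, MORPHO_TRAITS
from .cohort import Cohort, HealthStatus

__all__ = [
    "AssumptionCheck",
    "ComparisonResult",
    "DimorphismDecision",
    "ComparisonTable",
    "check_assumptions",
    "compare_groups",
    "dimorphism_screen",
    "build_comparison_table",
    "DEFAULT_VARIABLES",
]

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05

#: Table variables: the ten retained analytes (BA excluded for sporadic
#: non-reporting, UA never detected) plus the morphometric traits.
DEFAULT_VARIABLES: tuple[str, ...] = tuple(
    c for c in ANALYTE_CODES if c not in ("BA", "UA")
) + MORPHO_TRAITS


@dataclass(frozen=True)
class AssumptionCheck:
    parametric_ok: bool
    reason: str  # "ok" | "normality" | "variance" | "insufficient n"
    shapiro_p: tuple[float, float] | None = None
    levene_p: float | None = None


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    stratum: str  # combined | male | female
    test_used: str  # t_test | mann_whitney
    statistic: float
    p_value: float
    significant: bool
    direction: str  # label of the higher group, or "none"
    n1: int
    n2: int
    group_labels: tuple[str, str] = ("healthy", "diseased")


@dataclass(frozen=True)
class DimorphismDecision:
    variable: str
    dimorphic: bool
    evidence: dict[str, float] = field(default_factory=dict)
    undetermined: bool = False


@dataclass
class ComparisonTable:
    """Output of the full battery: one or two rows per variable."""

    results: list[ComparisonResult]
    decisions: dict[str, DimorphismDecision]
    skipped: dict[str, str] = field(default_factory=dict)
    alpha: float = ALPHA_DEFAULT

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": r.variable,
                "stratum": r.stratum,
                "test": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "direction": r.direction,
                "n1": r.n1,
                "n2": r.n2,
            }
            for r in self.results
        ]
        return pd.DataFrame(
            rows,
            columns=["variable", "stratum", "test", "statistic", "p_value",
                     "significant", "direction", "n1", "n2"],
        )

    def to_markdown(self) -> str:
        df = self.to_frame().copy()
        df["p_value"] = df["p_value"].map(lambda p: f"{p:.4g}")
        df["statistic"] = df["statistic"].map(lambda s: f"{s:.4g}")
        lines = ["| " + " | ".join(df.columns) + " |",
                 "|" + "---|" * len(df.columns)]
        for _, row in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        if self.skipped:
            lines.append("")
            for var, why in self.skipped.items():
                lines.append(f"- skipped {var}: {why}")
        return "\n".join(lines)

    def lookup(self, variable: str, stratum: str | None = None) -> list[ComparisonResult]:
        return [
            r for r in self.results
            if r.variable == variable and (stratum is None or r.stratum == stratum)
        ]


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def check_assumptions(group_a, group_b, alpha: float = ALPHA_DEFAULT) -> AssumptionCheck:
    """Gate the parametric path: Shapiro-Wilk per group plus Levene.

    Both groups must pass normality at ``alpha`` and the pair must pass
    Levene's equal-variance test at ``alpha``.  Groups of fewer than three
    observations force the nonparametric path (``reason="insufficient n"``).
    """
    a, b = _clean(group_a), _clean(group_b)
    if len(a) < 3 or len(b) < 3:
        return AssumptionCheck(False, "insufficient n")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        # Shapiro is undefined for constant samples; treat as non-normal.
        return AssumptionCheck(False, "normality")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_a = float(sps.shapiro(a).pvalue)
        p_b = float(sps.shapiro(b).pvalue)
    if p_a < alpha or p_b < alpha:
        return AssumptionCheck(False, "normality", (p_a, p_b))
    p_lev = float(sps.levene(a, b, center="mean").pvalue)
    if p_lev < alpha:
        return AssumptionCheck(False, "variance", (p_a, p_b), p_lev)
    return AssumptionCheck(True, "ok", (p_a, p_b), p_lev)


def compare_groups(
    group_a,
    group_b,
    alpha: float = ALPHA_DEFAULT,
    labels: tuple[str, str] = ("healthy", "diseased"),
    variable: str = "",
    stratum: str = "combined",
    welch: bool = False,
    test: str = "auto",
) -> ComparisonResult:
    """Two-sided comparison of two groups with automatic test selection.

    Missing values are dropped per group.  Direction is the label of the
    group with the higher mean (t-test) or median (Mann-Whitney).
    ``test`` forces a branch (``"t_test"`` / ``"mann_whitney"``) instead of
    gating on :func:`check_assumptions`.
    """
    if test not in ("auto", "t_test", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    a, b = _clean(group_a), _clean(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"{variable or 'comparison'}: a group is empty after "
                         "missing-value removal")
    if test == "auto":
        parametric = check_assumptions(a, b, alpha).parametric_ok
    else:
        parametric = test == "t_test"
    if parametric:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        test_used = "t_test"
        stat, p = float(res.statistic), float(res.pvalue)
        hi_a, hi_b = a.mean(), b.mean()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        test_used = "mann_whitney"
        stat, p = float(res.statistic), float(res.pvalue)
        hi_a, hi_b = np.median(a), np.median(b)
    if np.isnan(p):  # identical constant groups
        p, stat = 1.0, 0.0
    if hi_a > hi_b:
        direction = labels[0]
    elif hi_b > hi_a:
        direction = labels[1]
    else:
        direction = "none"
    return ComparisonResult(
        variable=variable,
        stratum=stratum,
        test_used=test_used,
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha),
        direction=direction,
        n1=len(a),
        n2=len(b),
        group_labels=labels,
    )


def _variable_values(df: pd.DataFrame, variable: str) -> pd.Series:
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    return df[variable].astype(float)


def dimorphism_screen(
    cohort: Cohort, variable: str, alpha: float = ALPHA_DEFAULT
) -> DimorphismDecision:
    """Screen one variable for sexual dimorphism.

    Males vs females are compared within the healthy class and within the
    diseased class; the variable is dimorphic when either comparison is
    significant at ``alpha``.  A missing stratum (e.g. no diseased females)
    yields an undetermined decision with a warning.
    """
    df = cohort.to_frame()
    vals = _variable_values(df, variable)
    evidence: dict[str, float] = {}
    dimorphic = False
    for status in (HealthStatus.HEALTHY.value, HealthStatus.DISEASED.value):
        m = _clean(vals[(df["sex"] == "male") & (df["status"] == status)])
        f = _clean(vals[(df["sex"] == "female") & (df["status"] == status)])
        if len(m) == 0 or len(f) == 0:
            warnings.warn(
                f"{variable}: missing sex stratum within {status}; "
                "dimorphism undetermined"
            )
            return DimorphismDecision(variable, False, evidence, undetermined=True)
        if np.ptp(np.concatenate([m, f])) == 0:
            evidence[status] = 1.0
            continue
        res = compare_groups(m, f, alpha, labels=("male", "female"),
                             variable=variable, stratum=status)
        evidence[status] = res.p_value
        dimorphic = dimorphic or res.significant
    return DimorphismDecision(variable, dimorphic, evidence)


def _benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Step-up FDR-adjusted p-values (monotone, capped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def build_comparison_table(
    cohort: Cohort,
    variables: tuple[str, ...] | list[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    p_adjust: str = "none",
) -> ComparisonTable:
    """Run the whole battery over a cohort.

    For each variable: dimorphism screen first; dimorphic variables get
    per-sex healthy-vs-diseased rows, the rest a single combined-sex row.
    Variables that cannot be tested (all missing in a group) are skipped
    with a logged reason, never aborting the table.  ``p_adjust="bh"``
    applies a Benjamini-Hochberg correction across the table's rows (the
    default reports raw per-test p-values, the convention for these
    panels).
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    if variables is None:
        variables = DEFAULT_VARIABLES
    df = cohort.to_frame()
    results: list[ComparisonResult] = []
    decisions: dict[str, DimorphismDecision] = {}
    skipped: dict[str, str] = {}
    for var in variables:
        try:
            vals = _variable_values(df, var)
        except KeyError as e:
            skipped[var] = str(e)
            continue
        healthy_all = _clean(vals[df["status"] == "healthy"])
        diseased_all = _clean(vals[df["status"] == "diseased"])
        if len(healthy_all) == 0 or len(diseased_all) == 0:
            skipped[var] = "no non-missing values in a health class"
            logger.info("skipping %s: %s", var, skipped[var])
            continue
        decision = dimorphism_screen(cohort, var, alpha)
        decisions[var] = decision
        try:
            if decision.dimorphic:
                for sex in ("male", "female"):
                    sel = df["sex"] == sex
                    results.append(
                        compare_groups(
                            vals[sel & (df["status"] == "healthy")],
                            vals[sel & (df["status"] == "diseased")],
                            alpha, variable=var, stratum=sex,
                        )
                    )
            else:
                results.append(
                    compare_groups(healthy_all, diseased_all, alpha,
                                   variable=var, stratum="combined")
                )
        except ValueError as e:
            skipped[var] = str(e)
            logger.info("skipping %s: %s", var, e)
    if p_adjust == "bh" and results:
        adjusted = _benjamini_hochberg([r.p_value for r in results])
        results = [
            ComparisonResult(
                variable=r.variable, stratum=r.stratum, test_used=r.test_used,
                statistic=r.statistic, p_value=p_adj,
                significant=bool(p_adj < alpha), direction=r.direction,
                n1=r.n1, n2=r.n2, group_labels=r.group_labels,
            )
            for r, p_adj in zip(results, adjusted)
        ]
    return ComparisonTable(results, decisions, skipped, alpha)
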