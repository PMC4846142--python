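"""Registry of the twelve rotor analytes reported by the benchtop analyzer.

Each analyte carries its reporting units and the instrument's detection
range for the avian/reptile rotor.  Globulin (GLOB) is the single derived
quantity on the panel: the analyzer computes it as total protein minus
albumin rather than measuring it directly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AnalyteSpec", "ANALYTES", "ANALYTE_CODES", "MORPHO_TRAITS", "flag_value"]


@dataclass(frozen=True)
class AnalyteSpec:
    """One entry of the analyte registry.

    Parameters
    ----------
    code : str
        Short identifier used in column headers (e.g. ``"TP"``, ``"Na"``).
    name : str
        Full analyte name.
    units : str
        Reporting units as printed by the rotor.
    range_low, range_high : float
        Instrument detection bounds, inclusive at both ends.
    derived : bool
        True only for GLOB, which the analyzer derives as TP - ALB.
    """

    code: str
    name: str
    units: str
    range_low: float
    range_high: float
    derived: bool = False

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError(
                f"{self.code}: range_low ({self.range_low}) must be below "
                f"range_high ({self.range_high})"
            )


ANALYTES: dict[str, AnalyteSpec] = {
    spec.code: spec
    for spec in (
        AnalyteSpec("AST", "aspartate aminotransferase", "U/L", 5.0, 2000.0),
        AnalyteSpec("BA", "bile acids", "umol/L", 35.0, 200.0),
        AnalyteSpec("CK", "creatine kinase", "U/L", 5.0, 14000.0),
        AnalyteSpec("UA", "uric acid", "mg/dL", 0.3, 25.0),
        AnalyteSpec("GLU", "glucose", "mg/dL", 10.0, 700.0),
        AnalyteSpec("PHOS", "inorganic phosphorus", "mg/dL", 0.2, 20.0),
        AnalyteSpec("Ca", "calcium", "mg/dL", 4.0, 16.0),
        AnalyteSpec("TP", "total protein", "g/dL", 2.0, 14.0),
        AnalyteSpec("ALB", "albumin", "g/dL", 1.0, 6.5),
        AnalyteSpec("GLOB", "globulin", "g/dL", 0.0, 13.0, derived=True),
        AnalyteSpec("K", "potassium", "mmol/L", 1.5, 8.5),
        AnalyteSpec("Na", "sodium", "mmol/L", 110.0, 170.0),
    )
}

#: Canonical analyte column order used by cohort I/O.
ANALYTE_CODES: tuple[str, ...] = tuple(ANALYTES)

#: Morphometric traits recorded alongside the blood panel.
MORPHO_TRAITS: tuple[str, ...] = ("total_length", "weight", "age")


def flag_value(code: str, value: float | None) -> str:
    """Flag one analyte value against its instrument range.

    Returns one of ``"below"``, ``"in_range"``, ``"above"`` or ``"missing"``.
    Bounds are inclusive: a value exactly at a detection bound is in range.
    """
    try:
        spec = ANALYTES[code]
    except KeyError:
        raise KeyError(f"unknown analyte code {code!r}") from None
    if value is None or (isinstance(value, float) and value != value):  # NaN
        return "missing"
    if value < spec.range_low:
        return "below"
    if value > spec.range_high:
        return "above"
    return "in_range"
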