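"""Woman-level data model: validation, hypertension classification, descriptives, design.

The unit of analysis is one woman nested in a household. Each record carries the
two continuous outcomes (systolic and diastolic blood pressure, mmHg), a
self-reported ever-told-hypertension flag, a region name, and ten categorical
risk factors. Hypertension is classified by the standard clinical cutoffs:
SBP >= 140 mmHg or DBP >= 90 mmHg (both thresholds inclusive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SBP_THRESHOLD",
    "DBP_THRESHOLD",
    "Factor",
    "CovariateScheme",
    "HypertensionFlags",
    "default_scheme",
    "classify_hypertension",
    "add_hypertension_flags",
    "build_descriptive_table",
    "validate_table",
    "ValidationReport",
    "build_design",
    "drop_incomplete",
    "read_women_csv",
    "write_women_csv",
]

SBP_THRESHOLD = 140.0
DBP_THRESHOLD = 90.0

#: CSV columns that every woman-level table must carry before the factors.
CORE_COLUMNS = ("woman_id", "household_id", "region", "sbp", "dbp", "ever_told")


@dataclass(frozen=True)
class Factor:
    """One categorical risk factor: column name, ordered levels, reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str
    household_level: bool = False

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r}: duplicate levels {self.levels}")
        if self.reference not in self.levels:
            raise ValueError(
                f"factor {self.name!r}: reference {self.reference!r} not among levels"
            )


@dataclass(frozen=True)
class CovariateScheme:
    """Ordered collection of factors defining the design matrix layout."""

    factors: tuple[Factor, ...]

    def __iter__(self):
        return iter(self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def indicator_labels(self) -> list[str]:
        """Labels of the non-reference indicator columns, in design order."""
        out = []
        for f in self.factors:
            out.extend(f"{f.name} {lv}" for lv in f.levels if lv != f.reference)
        return out

    @property
    def n_design_columns(self) -> int:
        return 1 + len(self.indicator_labels())


def default_scheme() -> CovariateScheme:
    """The ten-factor scheme of the study: first listed level is the reference.

    Age, obesity and education vary woman to woman; cooking fuel, wealth,
    water source, toilet type, household size class, wall type and vegetable
    consumption are treated as household attributes shared by co-resident women.
    """
    hh = dict(household_level=True)
    return CovariateScheme(
        factors=(
            Factor("age", ("15–24", "25–34", "35–44", "45–49"), "15–24"),
            Factor("obesity", ("Not obese", "Obese"), "Not obese"),
            Factor("cooking_fuel", ("Advanced", "Transition", "Primitive"), "Advanced", **hh),
            Factor("education", ("Secondary/higher", "No education", "Primary"), "Secondary/higher"),
            Factor("wealth", ("Richer/richest", "Poorer/poorest", "Middle"), "Richer/richest", **hh),
            Factor("water_source", ("Improved", "Unimproved"), "Improved", **hh),
            Factor("toilet_type", ("Improved", "Unimproved"), "Improved", **hh),
            Factor("household_size", (">3 members", "1–3 members"), ">3 members", **hh),
            Factor("wall_type", ("Durable materials", "Non-durable materials"), "Durable materials", **hh),
            Factor("vegetable", ("Ate vegetable at least once", "Didn't eat vegetable"),
                   "Ate vegetable at least once", **hh),
        )
    )


# ---------------------------------------------------------------------------
# Hypertension classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HypertensionFlags:
    sbp_flag: int
    dbp_flag: int
    combined_flag: int


def classify_hypertension(sbp: float, dbp: float) -> HypertensionFlags:
    """Classify one woman's blood pressure against the clinical cutoffs.

    ``sbp_flag`` is set iff SBP >= 140 mmHg, ``dbp_flag`` iff DBP >= 90 mmHg,
    and ``combined_flag`` is their logical OR. Thresholds are inclusive.
    """
    for name, v in (("sbp", sbp), ("dbp", dbp)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive, got {v!r}")
    s = int(sbp >= SBP_THRESHOLD)
    d = int(dbp >= DBP_THRESHOLD)
    return HypertensionFlags(s, d, int(s or d))


def add_hypertension_flags(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification: returns a copy with htn_sbp/htn_dbp/htn_combined."""
    out = records.copy()
    out["htn_sbp"] = (out["sbp"].to_numpy(float) >= SBP_THRESHOLD).astype(int)
    out["htn_dbp"] = (out["dbp"].to_numpy(float) >= DBP_THRESHOLD).astype(int)
    out["htn_combined"] = (out["htn_sbp"] | out["htn_dbp"]).astype(int)
    return out


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed survey tables)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def build_descriptive_table(
    records: pd.DataFrame, scheme: CovariateScheme | None = None
) -> pd.DataFrame:
    """Frequency table (count, percent of N) per hypertension measure and factor level.

    Percentages are 100*count/N rounded half-away-from-zero to one decimal,
    N being the total number of women. Within each characteristic the counts
    sum to N (levels are exhaustive).
    """
    if len(records) == 0:
        raise ValueError("cannot describe an empty table")
    scheme = scheme or default_scheme()
    flagged = add_hypertension_flags(records)
    n = len(flagged)
    rows: list[tuple[str, str, int, float]] = []

    def emit(characteristic: str, level: str, count: int) -> None:
        rows.append((characteristic, level, count, round_half_away(100.0 * count / n)))

    for col, label in (
        ("htn_sbp", "SBP"),
        ("htn_dbp", "DBP"),
        ("htn_combined", "Both SBP and/or DBP"),
        ("ever_told", "Ever told to have hypertension"),
    ):
        pos = int(flagged[col].sum())
        emit(label, "No" if col == "ever_told" else "Not hypertensive", n - pos)
        emit(label, "Yes" if col == "ever_told" else "Hypertensive", pos)

    for f in scheme:
        counts = flagged[f.name].value_counts()
        for lv in f.levels:
            emit(f.name, lv, int(counts.get(lv, 0)))

    return pd.DataFrame(rows, columns=["characteristic", "level", "count", "percent"])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of table QC. Outliers are flagged, never dropped."""

    n_records: int
    category_violations: list[dict] = field(default_factory=list)
    outliers: list[dict] = field(default_factory=list)
    duplicate_woman_ids: list = field(default_factory=list)
    missing_columns: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.category_violations or self.duplicate_woman_ids or self.missing_columns)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_records": self.n_records,
                "ok": self.ok,
                "category_violations": self.category_violations,
                "outliers": self.outliers,
                "duplicate_woman_ids": [str(w) for w in self.duplicate_woman_ids],
                "missing_columns": self.missing_columns,
            },
            indent=2,
        )


def _boxplot_outlier_mask(values: np.ndarray) -> np.ndarray:
    """Tukey boxplot rule; quartiles by linear interpolation between order stats."""
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def validate_table(records: pd.DataFrame, scheme: CovariateScheme | None = None) -> ValidationReport:
    """QC a woman-level table: category membership, boxplot outliers, duplicate ids.

    Categories must be mutually exclusive and exhaustive, so any covariate value
    outside its factor's declared levels is reported. SBP and DBP values outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are flagged for review but retained.
    """
    scheme = scheme or default_scheme()
    report = ValidationReport(n_records=len(records))

    for col in CORE_COLUMNS:
        if col not in records.columns:
            report.missing_columns.append(col)
    for f in scheme:
        if f.name not in records.columns:
            report.missing_columns.append(f.name)
    if report.missing_columns or len(records) == 0:
        return report

    for f in scheme:
        bad = ~records[f.name].isin(f.levels)
        for _, row in records.loc[bad].iterrows():
            report.category_violations.append(
                {"woman_id": str(row["woman_id"]), "factor": f.name, "value": str(row[f.name])}
            )

    for col in ("sbp", "dbp"):
        values = records[col].to_numpy(float)
        mask = _boxplot_outlier_mask(values)
        for idx in np.flatnonzero(mask):
            report.outliers.append(
                {"woman_id": str(records.iloc[idx]["woman_id"]), "variable": col,
                 "value": float(values[idx])}
            )

    dup = records["woman_id"][records["woman_id"].duplicated()]
    report.duplicate_woman_ids = sorted(set(dup.tolist()), key=str)
    return report


def drop_incomplete(records: pd.DataFrame, scheme: CovariateScheme | None = None
                    ) -> tuple[pd.DataFrame, int]:
    """Complete-case filter: drop rows missing an outcome or covariate.

    Returns the retained table and the number of dropped rows (to be logged).
    """
    scheme = scheme or default_scheme()
    cols = ["sbp", "dbp", *scheme.names]
    keep = records[cols].notna().all(axis=1)
    return records.loc[keep].reset_index(drop=True), int((~keep).sum())


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design(
    records: pd.DataFrame, scheme: CovariateScheme | None = None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + one 0/1 indicator per non-reference level, in scheme order.

    A woman at all reference levels has design row (1, 0, ..., 0). With the
    full ten-factor scheme this yields 16 columns. Raises on any covariate
    value that is not a declared level of its factor.
    """
    scheme = scheme or default_scheme()
    n = len(records)
    labels = ["intercept", *scheme.indicator_labels()]
    x = np.zeros((n, len(labels)))
    x[:, 0] = 1.0
    col = 1
    for f in scheme:
        values = records[f.name].to_numpy()
        unknown = set(values) - set(f.levels)
        if unknown:
            raise ValueError(f"factor {f.name!r}: unknown level(s) {sorted(unknown)}")
        for lv in f.levels:
            if lv == f.reference:
                continue
            x[:, col] = (values == lv).astype(float)
            col += 1
    return x, labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_women_csv(path, scheme: CovariateScheme | None = None) -> pd.DataFrame:
    """Read the woman-level CSV schema (core columns then one column per factor)."""
    scheme = scheme or default_scheme()
    df = pd.read_csv(path, dtype={f.name: str for f in scheme})
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return df


def write_women_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, lineterminator="\n")
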