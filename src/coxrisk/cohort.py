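"""Canonical cohort table schema, delimited-text I/O, and eligibility filtering.

A cohort is an ordinary :class:`pandas.DataFrame`, one row per individual,
with a small canonical column dictionary: an opaque ``id``, ``sex``
(``male``/``female``), baseline covariates, ``followup_years`` and a binary
``event`` indicator.  Binary flags are stored as floats (0.0/1.0) with NaN as
the single explicit missing marker; the file sentinel for missing values is
the string ``NA``.  Lipids are carried in mmol/L and systolic blood pressure
in mmHg; converters from mg/dL are provided for files recorded on the US
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError

#: canonical columns and their kinds
ID_COLUMN = "id"
SEX_COLUMN = "sex"
SEXES = ("male", "female")

FLAG_COLUMNS = (
    "smoking_current",
    "bp_medication",
    "statin_use",
    "diabetes_history",
    "cvd_history",
    "gestational_diabetes",
    "family_history_chd",
    "family_history_dm",
    "physical_activity",
    "vegetables_daily",
    "high_glucose_history",
    "event",
)

NUMERIC_COLUMNS = (
    "age_at_baseline",
    "prs",
    "bmi",
    "sbp",
    "hdl",
    "ldl",
    "tg",
    "tc",
    "waist_cm",
    "followup_years",
)

#: columns every cohort must carry
REQUIRED_COLUMNS = (ID_COLUMN, SEX_COLUMN, "age_at_baseline", "followup_years", "event")

MISSING_SENTINEL = "NA"

#: columns defined for women only; structurally missing (not incomplete) in men
WOMEN_ONLY_COLUMNS = ("gestational_diabetes",)

# mg/dL -> mmol/L divisors (cholesterol fractions vs triglycerides)
MGDL_PER_MMOL_CHOL = 38.67
MGDL_PER_MMOL_TG = 88.57

_TRUTHY = {"1", "1.0", "true", "t", "yes", "y"}
_FALSY = {"0", "0.0", "false", "f", "no", "n"}


def mgdl_to_mmol(value, analyte: str):
    """Convert a lipid measurement from mg/dL to mmol/L.

    ``analyte`` is one of ``hdl``, ``ldl``, ``tc`` (cholesterol, factor
    38.67) or ``tg`` (triglycerides, factor 88.57).
    """
    factor = MGDL_PER_MMOL_TG if analyte == "tg" else MGDL_PER_MMOL_CHOL
    return np.asarray(value, dtype=float) / factor


def mmol_to_mgdl(value, analyte: str):
    factor = MGDL_PER_MMOL_TG if analyte == "tg" else MGDL_PER_MMOL_CHOL
    return np.asarray(value, dtype=float) * factor


def _coerce_flag(series: pd.Series, column: str) -> pd.Series:
    out = pd.Series(np.nan, index=series.index, dtype=float)
    as_str = series.astype("string").str.strip().str.lower()
    out[as_str.isin(_TRUTHY)] = 1.0
    out[as_str.isin(_FALSY)] = 0.0
    bad = as_str.notna() & ~as_str.isin(_TRUTHY | _FALSY)
    if bad.any():
        raise SchemaError(
            f"column {column!r}: unparseable boolean values "
            f"{sorted(as_str[bad].unique())[:5]}"
        )
    return out


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(path, renames: dict | None = None, lipid_units: str = "mmol/L"):
    """Read a delimited cohort file into the canonical typed table.

    Parameters
    ----------
    path:
        CSV (comma) or TSV/TXT (tab) file; ``NA`` marks missing cells.
    renames:
        optional mapping of file column name -> canonical column name,
        applied before validation.
    lipid_units:
        ``"mmol/L"`` (canonical) or ``"mg/dL"``; on the latter, hdl/ldl/tc/tg
        are converted to mmol/L on read.

    Returns the typed :class:`~pandas.DataFrame`; a read report (row count
    and missing counts per column) is stored in ``df.attrs["read_report"]``.
    """
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path),
        dtype=str,
        na_values=[MISSING_SENTINEL, ""],
        keep_default_na=False,
    )
    if renames:
        df = df.rename(columns=renames)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if df[ID_COLUMN].duplicated().any():
        dupes = df.loc[df[ID_COLUMN].duplicated(), ID_COLUMN].head(5).tolist()
        raise SchemaError(f"duplicate ids in {path}: {dupes}")

    out = pd.DataFrame(index=df.index)
    out[ID_COLUMN] = df[ID_COLUMN].astype(str)
    sex = df[SEX_COLUMN].astype("string").str.strip().str.lower()
    bad_sex = sex.notna() & ~sex.isin(SEXES)
    if bad_sex.any():
        raise SchemaError(f"unknown sex labels: {sorted(sex[bad_sex].unique())}")
    out[SEX_COLUMN] = sex.astype(object)

    missing_counts: dict[str, int] = {}
    for col in df.columns:
        if col in (ID_COLUMN, SEX_COLUMN):
            continue
        if col in FLAG_COLUMNS:
            out[col] = _coerce_flag(df[col], col)
        else:
            out[col] = pd.to_numeric(df[col], errors="coerce")
        missing_counts[col] = int(out[col].isna().sum())

    if lipid_units == "mg/dL":
        for col in ("hdl", "ldl", "tc", "tg"):
            if col in out.columns:
                out[col] = mgdl_to_mmol(out[col], col)
    elif lipid_units != "mmol/L":
        raise SchemaError(f"unknown lipid_units {lipid_units!r}")

    validate_cohort(out)
    out.attrs["read_report"] = {
        "path": str(path),
        "n_rows": int(len(out)),
        "missing_per_column": missing_counts,
    }
    return out


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Structural checks shared by readers and the generator."""
    for col in REQUIRED_COLUMNS:
        if col not in cohort.columns:
            raise SchemaError(f"required column {col!r} missing")
    fup = cohort["followup_years"]
    if (fup.dropna() <= 0).any():
        raise SchemaError("followup_years must be > 0")
    age = cohort["age_at_baseline"].dropna()
    if len(age) and (age.lt(18).any() or age.gt(100).any()):
        raise SchemaError("age_at_baseline outside plausible range [18, 100]")
    if "gestational_diabetes" in cohort.columns:
        males = cohort[SEX_COLUMN] == "male"
        if cohort.loc[males, "gestational_diabetes"].notna().any():
            raise SchemaError("gestational_diabetes must be missing for males")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort so that :func:`read_cohort` round-trips it losslessly.

    Floats are written at ``repr`` precision; missing cells become ``NA``.
    """
    cohort.to_csv(
        path,
        sep=_delimiter_for(path),
        index=False,
        na_rep=MISSING_SENTINEL,
        float_format=None,
    )


@dataclass
class EligibilitySpec:
    """Sequential eligibility rules for one disease analysis.

    Rows are removed in a fixed order — age bounds, then each prevalent
    condition flag in list order, then missingness in the required columns —
    and the count removed at every step is recorded in the exclusion ledger.
    Follow-up is then administratively truncated at ``horizon`` years: events
    after the horizon become non-events censored at the horizon.
    """

    disease: str
    age_bounds: tuple[float, float] = (30.0, 75.0)
    exclude_prevalent: tuple[str, ...] = ()
    require_complete: tuple[str, ...] = ()
    horizon: float = 10.0

    def __post_init__(self):
        if not self.age_bounds[0] < self.age_bounds[1]:
            raise SchemaError("age_bounds low must be < high")
        if self.horizon <= 0:
            raise SchemaError("horizon must be > 0")


def chd_eligibility(require_complete=(), horizon: float = 10.0) -> EligibilitySpec:
    """CHD analysis rules: drop prevalent CVD, then baseline statin users."""
    return EligibilitySpec(
        disease="CHD",
        exclude_prevalent=("cvd_history", "statin_use"),
        require_complete=tuple(require_complete),
        horizon=horizon,
    )


def t2d_eligibility(require_complete=(), horizon: float = 10.0) -> EligibilitySpec:
    """T2D analysis rules: drop prevalent diabetes."""
    return EligibilitySpec(
        disease="T2D",
        exclude_prevalent=("diabetes_history",),
        require_complete=tuple(require_complete),
        horizon=horizon,
    )


def apply_eligibility(cohort: pd.DataFrame, spec: EligibilitySpec):
    """Apply sequential eligibility filtering and horizon truncation.

    Returns ``(filtered_cohort, ledger)`` where ``ledger`` is an ordered
    mapping of step label -> rows removed at that step.  The operation is
    idempotent and the ledger counts sum to ``len(input) - len(output)``.
    """
    for flag in spec.exclude_prevalent:
        if flag not in cohort.columns:
            raise SchemaError(f"exclusion flag {flag!r} not in cohort")
    for col in spec.require_complete:
        if col not in cohort.columns:
            raise SchemaError(f"required column {col!r} not in cohort")

    ledger: dict[str, int] = {}
    df = cohort

    lo, hi = spec.age_bounds
    keep = df["age_at_baseline"].ge(lo) & df["age_at_baseline"].le(hi)
    ledger["age_bounds"] = int((~keep).sum())
    df = df[keep]

    for flag in spec.exclude_prevalent:
        keep = df[flag].fillna(0.0) != 1.0
        ledger[f"prevalent:{flag}"] = int((~keep).sum())
        df = df[keep]

    if spec.require_complete:
        keep = pd.Series(True, index=df.index)
        for col in spec.require_complete:
            ok = df[col].notna()
            if col in WOMEN_ONLY_COLUMNS:
                ok |= df[SEX_COLUMN] == "male"
            keep &= ok
        ledger["missing_predictors"] = int((~keep).sum())
        df = df[keep]

    df = df.copy()
    late = df["followup_years"] > spec.horizon
    df.loc[late, "event"] = 0.0
    df.loc[late, "followup_years"] = spec.horizon
    df.attrs["exclusion_ledger"] = ledger
    return df, ledger


def format_ledger(ledger: dict[str, int], n_in: int) -> str:
    """Render an exclusion ledger with the sequential percentages."""
    lines = [f"rows in: {n_in}"]
    remaining = n_in
    for step, removed in ledger.items():
        pct = 100.0 * removed / remaining if remaining else math.nan
        lines.append(f"excluded at {step}: {removed} ({pct:.1f}% of remaining)")
        remaining -= removed
    lines.append(f"rows out: {remaining}")
    return "\n".join(lines)
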