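"""Comparator clinical risk calculators and the external-score adapter.

Two calculators are packaged with human-readable, citation-headed
coefficient files:

* the 2013 ACC/AHA Pooled Cohort Equations (PCE) for 10-year atherosclerotic
  cardiovascular disease risk — the white/European coefficient set is the
  default, matching a European-ancestry validation population;
* the Finnish Diabetes Risk Score (FINDRISC), an integer point-based type 2
  diabetes questionnaire, with a first-degree-only family-history mode for
  cohorts where second-degree history is unavailable and a documented
  "no-waist" variant.

Richer proprietary algorithms (QRISK3, QDiabetes) are not reimplemented;
externally computed per-individual risks are attached through
:func:`attach_external_scores` and evaluated like any other risk vector.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SEX_COLUMN, mmol_to_mgdl
from .exceptions import SchemaError
from .riskmodel import RiskModel

PCE_AGE_RANGE = (40.0, 79.0)

_PCE_TERMS = (
    "ln_age",
    "ln_age_sq",
    "ln_tc",
    "ln_age_ln_tc",
    "ln_hdl",
    "ln_age_ln_hdl",
    "ln_sbp_treated",
    "ln_age_ln_sbp_treated",
    "ln_sbp_untreated",
    "ln_age_ln_sbp_untreated",
    "smoker",
    "ln_age_smoker",
    "diabetes",
)


def _data_path(name: str):
    return resources.files("coxrisk.data").joinpath(name)


@dataclass
class PCECoefficients:
    """Published PCE coefficient tables keyed by (group, sex)."""

    tables: dict[tuple[str, str], dict[str, float]]

    @classmethod
    def load(cls, path=None) -> "PCECoefficients":
        path = path or _data_path("pce_coefficients.csv")
        with resources.as_file(path) if not isinstance(path, str) else _noop(path) as p:
            df = pd.read_csv(p, comment="#")
        tables: dict[tuple[str, str], dict[str, float]] = {}
        for (group, sex), sub in df.groupby(["group", "sex"]):
            tables[(group, sex)] = dict(zip(sub["term"], sub["value"].astype(float)))
        for key, tab in tables.items():
            if "baseline_survival" not in tab or "mean_term" not in tab:
                raise SchemaError(f"PCE table {key} lacks baseline or mean term")
            if not 0.0 < tab["baseline_survival"] <= 1.0:
                raise SchemaError(f"PCE table {key} baseline survival out of range")
        return cls(tables)

    def risk_model(self, sex: str, group: str = "white") -> RiskModel:
        """Express one PCE sex/group equation as a :class:`RiskModel` over
        the transformed design columns, so the shared absolute-risk and
        recalibration machinery applies to it."""
        tab = self.tables[(group, sex)]
        coeffs = {t: tab[t] for t in _PCE_TERMS if t in tab}
        return RiskModel(
            disease="ASCVD",
            sex=sex,
            horizon=10.0,
            coefficients=coeffs,
            baseline_survival_at_horizon=tab["baseline_survival"],
            mean_component=tab["mean_term"],
            provenance={"source": "pooled_cohort_equations_2013", "group": group},
        )


class _noop:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def pce_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Transformed PCE predictor columns (lipids converted mmol/L -> mg/dL,
    treated/untreated SBP split, log transforms and age interactions)."""
    required = ("age_at_baseline", "tc", "hdl", "sbp", "bp_medication",
                "diabetes_history", "smoking_current", SEX_COLUMN)
    for col in required:
        if col not in cohort.columns:
            raise SchemaError(f"PCE requires column {col!r}")
    ln_age = np.log(cohort["age_at_baseline"].to_numpy(dtype=float))
    ln_tc = np.log(mmol_to_mgdl(cohort["tc"], "tc"))
    ln_hdl = np.log(mmol_to_mgdl(cohort["hdl"], "hdl"))
    ln_sbp = np.log(cohort["sbp"].to_numpy(dtype=float))
    treated = cohort["bp_medication"].to_numpy(dtype=float)
    smoker = cohort["smoking_current"].to_numpy(dtype=float)
    diabetes = cohort["diabetes_history"].to_numpy(dtype=float)
    design = pd.DataFrame(
        {
            "ln_age": ln_age,
            "ln_age_sq": ln_age**2,
            "ln_tc": ln_tc,
            "ln_age_ln_tc": ln_age * ln_tc,
            "ln_hdl": ln_hdl,
            "ln_age_ln_hdl": ln_age * ln_hdl,
            "ln_sbp_treated": treated * ln_sbp,
            "ln_age_ln_sbp_treated": treated * ln_age * ln_sbp,
            "ln_sbp_untreated": (1.0 - treated) * ln_sbp,
            "ln_age_ln_sbp_untreated": (1.0 - treated) * ln_age * ln_sbp,
            "smoker": smoker,
            "ln_age_smoker": ln_age * smoker,
            "diabetes": diabetes,
        },
        index=cohort.index,
    )
    design[SEX_COLUMN] = cohort[SEX_COLUMN]
    design["id"] = cohort["id"] if "id" in cohort.columns else cohort.index.astype(str)
    return design


def pce_risk(
    cohort: pd.DataFrame,
    coefficients: PCECoefficients | None = None,
    group: str = "white",
    return_flags: bool = False,
):
    """Per-individual 10-year PCE risk, sex-specific.

    Ages outside the published validity range (40-79) are flagged, not
    refused.  With ``return_flags=True`` returns ``(risk, out_of_range)``.
    """
    coefficients = coefficients or PCECoefficients.load()
    design = pce_design(cohort)
    risk = pd.Series(np.nan, index=cohort.index, name="pce_risk", dtype=float)
    for sex in ("male", "female"):
        mask = design[SEX_COLUMN] == sex
        if not mask.any():
            continue
        model = coefficients.risk_model(sex, group=group)
        sub = design.loc[mask]
        lp = sum(
            beta * sub[term].to_numpy() for term, beta in model.coefficients.items()
        )
        risk[mask] = 1.0 - model.baseline_survival_at_horizon ** np.exp(
            lp - model.mean_component
        )
    age = cohort["age_at_baseline"].to_numpy(dtype=float)
    flags = pd.Series(
        (age < PCE_AGE_RANGE[0]) | (age > PCE_AGE_RANGE[1]),
        index=cohort.index,
        name="pce_age_out_of_range",
    )
    risk.attrs["n_age_out_of_range"] = int(flags.sum())
    if return_flags:
        return risk, flags
    return risk


# ---------------------------------------------------------------------------
# FINDRISC


@dataclass
class FindriscTable:
    """Parsed FINDRISC category boundaries and point values."""

    numeric_items: dict[str, dict[str, list[tuple[float, float, int]]]]
    boolean_items: dict[str, tuple[str, int]]  # item -> (polarity, points)
    family_points: dict[str, int]

    @classmethod
    def load(cls, path=None) -> "FindriscTable":
        path = path or _data_path("findrisc_points.csv")
        with resources.as_file(path) if not isinstance(path, str) else _noop(path) as p:
            df = pd.read_csv(p, comment="#")
        numeric: dict[str, dict[str, list]] = {}
        boolean: dict[str, tuple[str, int]] = {}
        family: dict[str, int] = {}
        for _, row in df.iterrows():
            item, kind, sex = row["item"], row["kind"], row["sex"]
            pts = int(row["points"])
            if kind == "numeric":
                lo = -np.inf if pd.isna(row["lower"]) else float(row["lower"])
                hi = np.inf if pd.isna(row["upper"]) else float(row["upper"])
                numeric.setdefault(item, {}).setdefault(sex, []).append((lo, hi, pts))
            elif kind == "boolean":
                boolean[item] = (str(row["value"]), pts)
            elif kind == "family":
                family[str(row["value"])] = pts
            else:
                raise SchemaError(f"unknown FINDRISC row kind {kind!r}")
        for item, per_sex in numeric.items():
            for sex, bins in per_sex.items():
                bins.sort()
                if any(p < 0 for *_, p in bins):
                    raise SchemaError(f"negative points for {item}")
        return cls(numeric, boolean, family)

    def numeric_points(self, item: str, sex: np.ndarray, value: np.ndarray) -> np.ndarray:
        per_sex = self.numeric_items[item]
        out = np.zeros(len(value), dtype=int)
        for i, (s, v) in enumerate(zip(sex, value)):
            bins = per_sex.get(s) or per_sex.get("any")
            for lo, hi, pts in bins:
                if lo <= v < hi:
                    out[i] = pts
                    break
        return out


def findrisc_score(
    cohort: pd.DataFrame,
    table: FindriscTable | None = None,
    first_degree_only: bool = True,
    require_waist: bool = True,
) -> pd.Series:
    """Integer FINDRISC point sum per individual.

    ``first_degree_only=True`` scores family history from the binary
    first-degree flag alone (second-degree points unreachable).  With
    ``require_waist=False`` a documented no-waist variant is computed in
    which the waist item contributes zero points.
    """
    table = table or FindriscTable.load()
    n = len(cohort)
    score = np.zeros(n, dtype=int)
    sex = cohort[SEX_COLUMN].to_numpy()

    for item in ("age", "bmi", "waist_cm"):
        col = "age_at_baseline" if item == "age" else item
        if col not in cohort.columns or cohort[col].isna().any():
            if item == "waist_cm" and not require_waist:
                continue
            raise SchemaError(
                f"FINDRISC requires complete column {col!r} "
                "(use require_waist=False for the no-waist variant)"
                if item == "waist_cm"
                else f"FINDRISC requires complete column {col!r}"
            )
        score += table.numeric_points(item, sex, cohort[col].to_numpy(dtype=float))

    for item, (polarity, pts) in table.boolean_items.items():
        if item not in cohort.columns or cohort[item].isna().any():
            raise SchemaError(f"FINDRISC requires complete column {item!r}")
        flag = cohort[item].to_numpy(dtype=float) == 1.0
        positive = flag if polarity == "positive" else ~flag
        score += np.where(positive, pts, 0)

    if first_degree_only:
        fam = cohort.get("family_history_dm")
        if fam is None or fam.isna().any():
            raise SchemaError("FINDRISC requires complete column 'family_history_dm'")
        score += np.where(fam.to_numpy(dtype=float) == 1.0,
                          table.family_points["first_degree"], 0)
    else:
        fam1 = cohort.get("family_history_dm")
        fam2 = cohort.get("family_history_dm_second_degree")
        if fam1 is None or fam2 is None:
            raise SchemaError(
                "two-degree family-history mode needs 'family_history_dm' and "
                "'family_history_dm_second_degree'"
            )
        first = fam1.to_numpy(dtype=float) == 1.0
        second = (fam2.to_numpy(dtype=float) == 1.0) & ~first
        score += np.where(first, table.family_points["first_degree"], 0)
        score += np.where(second, table.family_points["second_degree"], 0)

    return pd.Series(score, index=cohort.index, name="findrisc")


# ---------------------------------------------------------------------------
# external-score adapter


def attach_external_scores(
    cohort: pd.DataFrame, path, score_name: str
) -> pd.DataFrame:
    """Join an externally computed risk column (file: ``id,risk``) onto the
    cohort under ``score_name``."""
    ext = pd.read_csv(path)
    if ext.shape[1] != 2:
        raise SchemaError("external score file must have exactly two columns")
    ext.columns = ["id", score_name]
    ext["id"] = ext["id"].astype(str)
    vals = pd.to_numeric(ext[score_name], errors="raise")
    if ((vals < 0) | (vals > 1)).any():
        bad = ext.loc[(vals < 0) | (vals > 1), "id"].head(5).tolist()
        raise SchemaError(f"external scores outside [0,1] for ids {bad}")
    unknown = set(ext["id"]) - set(cohort["id"].astype(str))
    if unknown:
        raise SchemaError(f"external score ids not in cohort: {sorted(unknown)[:10]}")
    out = cohort.merge(ext, on="id", how="left")
    out.index = cohort.index
    out.attrs = dict(cohort.attrs)
    return out
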