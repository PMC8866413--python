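"""Discrimination, calibration, reclassification, and stratification metrics.

Conventions:

* AUC point estimates are the Mann-Whitney probability with ties counted as
  one half; variances, confidence intervals and paired comparisons use
  DeLong's structural-components method, two-sided throughout.
* Categorical NRI is reported on the percent scale.  High risk means
  ``risk >= threshold`` (closed lower bound).  The overall NRI is exactly
  the sum of the event and non-event components before any rounding.
* Bootstrap confidence intervals are percentile intervals; resampling is
  stratified by case status by default so every replicate has both
  denominators.
* Observed incidence in calibration deciles is the Kaplan-Meier cumulative
  incidence at the horizon, which reduces to the raw event proportion when
  nothing is censored before the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .exceptions import CoxRiskError, SchemaError


@dataclass
class MetricReport:
    """A labelled point estimate with optional CI / p-value / subgroup."""

    metric: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    subgroup: str | None = None
    n: int | None = None
    note: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and np.isfinite(self.estimate)
            and not (self.ci_low <= self.estimate + 1e-12
                     and self.estimate <= self.ci_high + 1e-12)
        ):
            raise CoxRiskError(
                f"{self.metric}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket estimate {self.estimate}"
            )


def _as_float_array(x, name):
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SchemaError(f"{name} must be one-dimensional")
    return arr


def _event_bool(event):
    e = _as_float_array(event, "event")
    return e == 1.0


def _check_aligned(*series):
    indexes = [s.index for s in series if isinstance(s, pd.Series)]
    for idx in indexes[1:]:
        if not indexes[0].equals(idx):
            raise SchemaError("risk/event vectors are misaligned (index mismatch)")


# ---------------------------------------------------------------------------
# DeLong AUC


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, is_case: np.ndarray):
    """Structural components V10 (per case) and V01 (per non-case)."""
    pos, neg = scores[is_case], scores[~is_case]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise SchemaError("both cases and non-cases are required for AUC")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # one per case
    v01 = 1.0 - (tz[m:] - ty) / m    # one per non-case
    return auc, v10, v01


def auc_delong(risk, event, ci_level: float = 0.95) -> MetricReport:
    """AUC with DeLong variance and a two-sided normal-theory CI."""
    _check_aligned(*(s for s in (risk, event) if isinstance(s, pd.Series)))
    scores = _as_float_array(risk, "risk")
    is_case = _event_bool(event)
    auc, v10, v01 = _delong_components(scores, is_case)
    m, n = is_case.sum(), (~is_case).sum()
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(var)
    return MetricReport(
        metric="auc",
        estimate=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n=int(m + n),
        note="DeLong",
    )


def auc_compare(risk_a, risk_b, event) -> MetricReport:
    """Paired DeLong comparison: estimate is AUC(a) - AUC(b)."""
    a = _as_float_array(risk_a, "risk_a")
    b = _as_float_array(risk_b, "risk_b")
    if len(a) != len(b):
        raise SchemaError("risk vectors differ in length")
    _check_aligned(*(s for s in (risk_a, risk_b, event) if isinstance(s, pd.Series)))
    is_case = _event_bool(event)
    auc_a, v10a, v01a = _delong_components(a, is_case)
    auc_b, v10b, v01b = _delong_components(b, is_case)
    m, n = is_case.sum(), (~is_case).sum()
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = 0.0
    if m > 1:
        var += np.var(d10, ddof=1) / m
    if n > 1:
        var += np.var(d01, ddof=1) / n
    delta = auc_a - auc_b
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
        half = 0.0
    else:
        z = delta / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        half = stats.norm.ppf(0.975) * np.sqrt(var)
    return MetricReport(
        metric="delta_auc",
        estimate=float(delta),
        ci_low=float(delta - half),
        ci_high=float(delta + half),
        p_value=float(p),
        n=int(m + n),
        note="paired DeLong",
    )


# ---------------------------------------------------------------------------
# reclassification and NRI


@dataclass
class ReclassificationTable:
    """Cross-tabulated movement across one risk threshold, cases and
    non-cases separately."""

    threshold: float
    case_up: int
    case_down: int
    case_both_high: int
    case_both_low: int
    noncase_up: int
    noncase_down: int
    noncase_both_high: int
    noncase_both_low: int
    label_old: str = "old"
    label_new: str = "new"

    @property
    def n_cases(self) -> int:
        return self.case_up + self.case_down + self.case_both_high + self.case_both_low

    @property
    def n_noncases(self) -> int:
        return (self.noncase_up + self.noncase_down
                + self.noncase_both_high + self.noncase_both_low)

    def to_frame(self) -> pd.DataFrame:
        """Printable layout: up / both-high / down / both-low counts with
        within-group percentages, for cases, non-cases, and all."""
        rows = []
        for grp, up, bh, dn, bl in (
            ("cases", self.case_up, self.case_both_high,
             self.case_down, self.case_both_low),
            ("non-cases", self.noncase_up, self.noncase_both_high,
             self.noncase_down, self.noncase_both_low),
        ):
            rows.append({"group": grp, "upclassified": up, "both_high": bh,
                         "downclassified": dn, "both_low": bl})
        rows.append({
            "group": "all",
            "upclassified": self.case_up + self.noncase_up,
            "both_high": self.case_both_high + self.noncase_both_high,
            "downclassified": self.case_down + self.noncase_down,
            "both_low": self.case_both_low + self.noncase_both_low,
        })
        df = pd.DataFrame(rows).set_index("group")
        totals = df.sum(axis=1)
        for col in df.columns:
            df[col + "_pct"] = 100.0 * df[col] / totals
        return df


@dataclass
class NRIResult:
    """Event / non-event / overall NRI on the percent scale."""

    event_nri: float
    nonevent_nri: float
    overall_nri: float
    event_ci: tuple[float, float] | None = None
    nonevent_ci: tuple[float, float] | None = None
    overall_ci: tuple[float, float] | None = None
    n_bootstrap: int = 0
    n_redrawn: int = 0

    def __post_init__(self):
        if abs(self.overall_nri - (self.event_nri + self.nonevent_nri)) > 1e-9:
            raise CoxRiskError("overall NRI must equal event + nonevent exactly")


def reclassification(
    risk_old, risk_new, event, threshold: float,
    label_old: str = "old", label_new: str = "new",
) -> ReclassificationTable:
    """Classify everyone as high risk iff ``risk >= threshold`` under each
    model and cross-tabulate movement for cases and non-cases."""
    if not 0.0 < threshold < 1.0:
        raise SchemaError("threshold must be in (0, 1)")
    _check_aligned(*(s for s in (risk_old, risk_new, event)
                     if isinstance(s, pd.Series)))
    old = _as_float_array(risk_old, "risk_old")
    new = _as_float_array(risk_new, "risk_new")
    if len(old) != len(new):
        raise SchemaError("risk vectors differ in length")
    is_case = _event_bool(event)
    high_old = old >= threshold
    high_new = new >= threshold

    def counts(mask):
        up = int((~high_old & high_new & mask).sum())
        down = int((high_old & ~high_new & mask).sum())
        bh = int((high_old & high_new & mask).sum())
        bl = int((~high_old & ~high_new & mask).sum())
        return up, down, bh, bl

    cu, cd, cbh, cbl = counts(is_case)
    nu, nd, nbh, nbl = counts(~is_case)
    return ReclassificationTable(
        threshold=threshold,
        case_up=cu, case_down=cd, case_both_high=cbh, case_both_low=cbl,
        noncase_up=nu, noncase_down=nd, noncase_both_high=nbh, noncase_both_low=nbl,
        label_old=label_old, label_new=label_new,
    )


def categorical_nri(table: ReclassificationTable) -> NRIResult:
    """Point-estimate categorical NRI (percent scale) from a
    reclassification table."""
    if table.n_cases == 0 or table.n_noncases == 0:
        raise SchemaError("categorical NRI needs at least one case and one non-case")
    event = 100.0 * (table.case_up - table.case_down) / table.n_cases
    nonevent = 100.0 * (table.noncase_down - table.noncase_up) / table.n_noncases
    return NRIResult(event_nri=event, nonevent_nri=nonevent,
                     overall_nri=event + nonevent)


def nri_bootstrap_ci(
    risk_old, risk_new, event, threshold: float,
    n_reps: int = 200, seed: int = 0, stratified: bool = True,
) -> NRIResult:
    """Categorical NRI with percentile bootstrap CIs over individuals.

    With ``stratified=True`` (default) cases and non-cases are resampled
    separately, so every replicate has both denominators; otherwise whole
    rows are resampled and any replicate with a missing class is redrawn
    (counted in ``n_redrawn``).
    """
    if n_reps < 2:
        raise SchemaError("n_reps must be >= 2")
    old = _as_float_array(risk_old, "risk_old")
    new = _as_float_array(risk_new, "risk_new")
    is_case = _event_bool(event)
    point = categorical_nri(reclassification(old, new, is_case, threshold))

    # per-individual reclassification direction: +1 up, -1 down, 0 unchanged
    high_old = old >= threshold
    high_new = new >= threshold
    delta = np.where(~high_old & high_new, 1.0,
                     np.where(high_old & ~high_new, -1.0, 0.0))
    d_case = delta[is_case]
    d_non = delta[~is_case]
    rng = np.random.default_rng(seed)
    n_case, n_non = len(d_case), len(d_non)

    redrawn = 0
    if stratified:
        idx_c = rng.integers(0, n_case, size=(n_reps, n_case))
        idx_n = rng.integers(0, n_non, size=(n_reps, n_non))
        ev = 100.0 * d_case[idx_c].mean(axis=1)
        nv = -100.0 * d_non[idx_n].mean(axis=1)
    else:
        n = len(delta)
        ev = np.empty(n_reps)
        nv = np.empty(n_reps)
        for r in range(n_reps):
            while True:
                idx = rng.integers(0, n, size=n)
                cases = is_case[idx]
                if cases.any() and (~cases).any():
                    break
                redrawn += 1
            ev[r] = 100.0 * delta[idx][cases].mean()
            nv[r] = -100.0 * delta[idx][~cases].mean()
    ov = ev + nv

    def ci(samples):
        lo, hi = np.percentile(samples, [2.5, 97.5])
        return (float(lo), float(hi))

    return NRIResult(
        event_nri=point.event_nri,
        nonevent_nri=point.nonevent_nri,
        overall_nri=point.overall_nri,
        event_ci=ci(ev),
        nonevent_ci=ci(nv),
        overall_ci=ci(ov),
        n_bootstrap=n_reps,
        n_redrawn=redrawn,
    )


def continuous_nri(risk_old, risk_new, event) -> MetricReport:
    """Threshold-free NRI (percent scale; exact ties contribute zero)."""
    old = _as_float_array(risk_old, "risk_old")
    new = _as_float_array(risk_new, "risk_new")
    if len(old) != len(new):
        raise SchemaError("risk vectors differ in length")
    is_case = _event_bool(event)
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise SchemaError("continuous NRI needs both classes")
    s = np.sign(new - old)
    event_term = s[is_case].mean()
    nonevent_term = -s[~is_case].mean()
    total = 100.0 * (event_term + nonevent_term)
    return MetricReport(
        metric="continuous_nri",
        estimate=float(total),
        n=int(len(old)),
        note="percent scale; event and nonevent components in extras",
        extras={"event_component": 100.0 * float(event_term),
                "nonevent_component": 100.0 * float(nonevent_term)},
    )


def idi(risk_old, risk_new, event) -> MetricReport:
    """Integrated discrimination improvement: the change in discrimination
    slope (mean risk in cases minus mean risk in non-cases)."""
    old = _as_float_array(risk_old, "risk_old")
    new = _as_float_array(risk_new, "risk_new")
    if len(old) != len(new):
        raise SchemaError("risk vectors differ in length")
    is_case = _event_bool(event)
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise SchemaError("IDI needs both classes")
    slope_new = new[is_case].mean() - new[~is_case].mean()
    slope_old = old[is_case].mean() - old[~is_case].mean()
    return MetricReport(
        metric="idi",
        estimate=float(slope_new - slope_old),
        n=int(len(old)),
        extras={"slope_new": float(slope_new), "slope_old": float(slope_old)},
    )


# ---------------------------------------------------------------------------
# calibration


def km_incidence(followup, event, horizon: float) -> tuple[float, float]:
    """Kaplan-Meier cumulative incidence at ``horizon`` with its Greenwood
    standard error."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(followup, dtype=float), np.asarray(event, dtype=float))
    surv = float(kmf.survival_function_at_times(horizon).iloc[0])
    try:
        ci = kmf.confidence_interval_survival_function_
        idx = ci.index.to_numpy()
        pos = np.searchsorted(idx, horizon, side="right") - 1
        lo, hi = ci.iloc[max(pos, 0)]
        se = abs(hi - lo) / (2 * 1.959964)
    except Exception:
        se = np.nan
    return 1.0 - surv, float(se)


def calibration_deciles(
    risk, event, followup, horizon: float, n_bins: int = 10
) -> pd.DataFrame:
    """Mean predicted risk vs Kaplan-Meier observed incidence within
    equal-count bins of predicted risk (deciles by default).

    Heavy ties can make fewer than ``n_bins`` distinct bins; the result then
    has fewer rows and a ``"reduced_bins"`` note in ``attrs``.
    """
    r = _as_float_array(risk, "risk")
    e = _as_float_array(event, "event")
    f = _as_float_array(followup, "followup")
    if len(r) < n_bins:
        raise SchemaError(f"need at least {n_bins} individuals")
    try:
        bins = pd.qcut(r, n_bins, labels=False, duplicates="drop")
    except ValueError as exc:
        raise SchemaError(f"cannot form risk bins: {exc}") from exc
    rows = []
    for b in np.unique(bins):
        mask = bins == b
        obs, se = km_incidence(f[mask], e[mask], horizon)
        rows.append({
            "bin": int(b),
            "n": int(mask.sum()),
            "events": int(e[mask].sum()),
            "mean_predicted": float(r[mask].mean()),
            "observed_incidence": obs,
            "observed_se": se,
        })
    out = pd.DataFrame(rows)
    if len(out) < n_bins:
        out.attrs["note"] = f"reduced_bins:{len(out)}"
    return out


# ---------------------------------------------------------------------------
# risk stratification


def _percentile_bands(score: np.ndarray, bands) -> np.ndarray:
    """Assign each individual to a percentile band.  Percentiles come from
    the stable (ordinal) rank so ties split deterministically; a value
    sitting exactly on a band edge joins the upper band."""
    n = len(score)
    rank = stats.rankdata(score, method="ordinal")
    pct = 100.0 * (rank - 1) / n  # in [0, 100)
    labels = np.full(n, -1, dtype=int)
    for k, (lo, hi) in enumerate(bands):
        mask = (pct >= lo) & (pct < hi)
        labels[mask] = k
    return labels


def percentile_hazard_ratios(
    score, event, followup,
    bands=((0, 25), (25, 75), (75, 95), (95, 100)),
    reference=(25, 75),
) -> list[MetricReport]:
    """Cox hazard ratios for score-percentile bands against a reference band
    (the interquartile band by default)."""
    s = _as_float_array(score, "score")
    e = _as_float_array(event, "event")
    f = _as_float_array(followup, "followup")
    bands = [tuple(b) for b in bands]
    if tuple(reference) not in bands:
        raise SchemaError("reference band must be one of the bands")
    covered = sorted(bands)
    if covered[0][0] != 0 or covered[-1][1] != 100 or any(
        covered[i][1] != covered[i + 1][0] for i in range(len(covered) - 1)
    ):
        raise SchemaError("bands must partition [0, 100]")
    labels = _percentile_bands(s, bands)
    if (labels < 0).any():
        raise SchemaError("band assignment failed")
    for k, band in enumerate(bands):
        if not (labels == k).any():
            raise SchemaError(f"empty band {band}")

    ref_idx = bands.index(tuple(reference))
    df = pd.DataFrame({"followup": f, "event": e})
    dummy_cols = []
    for k, band in enumerate(bands):
        if k == ref_idx:
            continue
        col = f"band_{band[0]}_{band[1]}"
        df[col] = (labels == k).astype(float)
        dummy_cols.append((k, band, col))
    cph = CoxPHFitter()
    cph.fit(df, duration_col="followup", event_col="event")

    reports = [MetricReport(
        metric="hazard_ratio",
        estimate=1.0,
        subgroup=f"{reference[0]}-{reference[1]}pct",
        n=int((labels == ref_idx).sum()),
        note="reference band",
    )]
    summary = cph.summary
    for k, band, col in dummy_cols:
        row = summary.loc[col]
        reports.append(MetricReport(
            metric="hazard_ratio",
            estimate=float(np.exp(row["coef"])),
            ci_low=float(np.exp(row["coef lower 95%"])),
            ci_high=float(np.exp(row["coef upper 95%"])),
            p_value=float(row["p"]),
            subgroup=f"{band[0]}-{band[1]}pct",
            n=int((labels == k).sum()),
        ))
    return reports


def km_by_band(
    score, event, followup, horizon: float,
    bands=((0, 25), (25, 75), (75, 95), (95, 100)),
) -> pd.DataFrame:
    """Kaplan-Meier cumulative incidence at the horizon per percentile band."""
    s = _as_float_array(score, "score")
    e = _as_float_array(event, "event")
    f = _as_float_array(followup, "followup")
    labels = _percentile_bands(s, [tuple(b) for b in bands])
    rows = []
    for k, band in enumerate(bands):
        mask = labels == k
        inc, se = km_incidence(f[mask], e[mask], horizon)
        rows.append({"band": f"{band[0]}-{band[1]}pct", "n": int(mask.sum()),
                     "events": int(e[mask].sum()),
                     "km_incidence": inc, "km_se": se})
    return pd.DataFrame(rows)


def subgroup_metrics(risk, cohort: pd.DataFrame, splits: dict) -> list[MetricReport]:
    """DeLong AUC within labelled subgroups.

    ``splits`` maps label -> boolean mask (Series/array) or a predicate
    taking the cohort and returning one.  Single-class subgroups are
    reported as not estimable rather than raised."""
    reports = []
    r = _as_float_array(risk, "risk")
    e = _event_bool(cohort["event"])
    for label, pred in splits.items():
        mask = pred(cohort) if callable(pred) else pred
        mask = np.asarray(mask, dtype=bool)
        sub_e = e[mask]
        if sub_e.all() or not sub_e.any():
            reports.append(MetricReport(
                metric="auc", estimate=float("nan"), subgroup=label,
                n=int(mask.sum()), note="not estimable: single class",
            ))
            continue
        rep = auc_delong(r[mask], sub_e)
        rep.subgroup = label
        reports.append(rep)
    return reports


def default_subgroups(cohort: pd.DataFrame, bmi_split: bool = False) -> dict:
    """The standard subgroup battery: sex, age at 55, and optionally BMI at 30."""
    splits = {
        "men": (cohort["sex"] == "male").to_numpy(),
        "women": (cohort["sex"] == "female").to_numpy(),
        "age<55": (cohort["age_at_baseline"] < 55).to_numpy(),
        "age>=55": (cohort["age_at_baseline"] >= 55).to_numpy(),
    }
    if bmi_split and "bmi" in cohort.columns:
        splits["bmi<30"] = (cohort["bmi"] < 30).to_numpy()
        splits["bmi>=30"] = (cohort["bmi"] >= 30).to_numpy()
    return splits
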