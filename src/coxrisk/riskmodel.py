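"""Cox-based 10-year absolute-risk tools: derivation, application,
external-coefficient integration, and recalibration.

A risk tool is a :class:`RiskModel` bundle — per-unit log-hazard-ratio
coefficients beta_j, a baseline survival S0(t) at the horizon t anchored at
the derivation-cohort covariate means, and the mean component
m = sum_j beta_j * xbar_j.  Absolute risk follows the standard Cox/Breslow
composition

    risk_i = 1 - S0(t) ** exp(LP_i - m),        LP_i = sum_j beta_j x_ij.

Derivation fits a sex-stratified Cox proportional-hazards model (partial
likelihood with Efron handling of tied event times, via lifelines); the
baseline cumulative hazard comes from the Breslow estimator and is evaluated
at the covariate means of the derivation data.  Adjustment covariates (for
example ancestry principal components) are included in the fit but excluded
from the exported score; because the baseline is anchored at their means,
predictions implicitly hold them at the derivation average.

Recalibration to an external cohort keeps the coefficients fixed: the linear
predictor enters a proportional-hazards model as an offset with coefficient
one (realised directly through the Breslow estimator with per-subject hazard
multipliers exp(LP_i)), the baseline survival is re-estimated at the target
horizon, and the mean component is recomputed over the target cohort.  The
anchor (S0, m) therefore moves jointly, so predictions are invariant to
where the baseline is centred.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import SEX_COLUMN, SEXES
from .exceptions import FitError, ModelIOError, SchemaError

MODEL_FORMAT_VERSION = "1"


@dataclass
class RiskModel:
    """A portable absolute-risk scoring bundle."""

    disease: str
    sex: str
    horizon: float
    coefficients: dict[str, float]
    baseline_survival_at_horizon: float
    mean_component: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.baseline_survival_at_horizon <= 1.0:
            raise ModelIOError(
                "baseline_survival_at_horizon must be in (0, 1], got "
                f"{self.baseline_survival_at_horizon}"
            )
        if self.horizon <= 0:
            raise ModelIOError("horizon must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["format_version"] = MODEL_FORMAT_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        d = dict(d)
        version = d.pop("format_version", None)
        if version != MODEL_FORMAT_VERSION:
            raise ModelIOError(
                f"unsupported model format version {version!r}; "
                f"supported: [{MODEL_FORMAT_VERSION!r}]"
            )
        try:
            return cls(**d)
        except TypeError as exc:
            raise ModelIOError(f"malformed model bundle: {exc}") from exc


def save_model(model: RiskModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_model(path) -> RiskModel:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelIOError(f"cannot parse model bundle {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ModelIOError(f"model bundle {path} is not a mapping")
    model = RiskModel.from_dict(d)
    if not isinstance(model.coefficients, dict) or not all(
        isinstance(v, (int, float)) for v in model.coefficients.values()
    ):
        raise ModelIOError(f"model bundle {path} has non-numeric coefficients")
    return model


# ---------------------------------------------------------------------------
# scoring


def linear_predictor(model: RiskModel, cohort: pd.DataFrame) -> pd.Series:
    """Uncentred LP_i = sum_j beta_j x_ij for every row of ``cohort``."""
    lp = np.zeros(len(cohort))
    for name, beta in model.coefficients.items():
        if name not in cohort.columns:
            raise SchemaError(f"model covariate {name!r} missing from cohort")
        x = cohort[name].to_numpy(dtype=float)
        if np.isnan(x).any():
            bad = cohort.loc[np.isnan(x), "id"].head(10).tolist()
            raise SchemaError(
                f"missing values in model covariate {name!r} for ids {bad}"
            )
        lp += beta * x
    return pd.Series(lp, index=cohort.index, name="linear_predictor")


def absolute_risk(model: RiskModel, cohort: pd.DataFrame) -> pd.Series:
    """Absolute risk over the model horizon, one probability per row."""
    s0 = model.baseline_survival_at_horizon
    if s0 <= 0.0:
        raise FitError("degenerate baseline: S0(t) = 0")
    lp = linear_predictor(model, cohort)
    risk = 1.0 - s0 ** np.exp(lp - model.mean_component)
    out = pd.Series(np.clip(risk, 0.0, 1.0), index=cohort.index, name="risk")
    out.attrs["model"] = f"{model.disease}/{model.sex}"
    return out


# ---------------------------------------------------------------------------
# Breslow baseline


def breslow_cumulative_hazard(
    time: np.ndarray, event: np.ndarray, exp_lp: np.ndarray, t: float
) -> float:
    """Breslow estimate of the baseline cumulative hazard at ``t`` for fixed
    per-subject hazard multipliers ``exp_lp`` (LP coefficient constrained to
    one):  H0(t) = sum_{event times t_k <= t} d_k / sum_{i at risk} exp_lp_i.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    exp_lp = np.asarray(exp_lp, dtype=float)
    order = np.argsort(time, kind="mergesort")
    ts, es, ws = time[order], event[order], exp_lp[order]
    # suffix sums give the risk-set denominator at each sorted position;
    # tied times share the denominator taken at the first index of the tie
    riskset = np.cumsum(ws[::-1])[::-1]
    _, first, inverse = np.unique(ts, return_index=True, return_inverse=True)
    denom = riskset[first[inverse]]
    contrib = np.where((es > 0) & (ts <= t), es / denom, 0.0)
    return float(contrib.sum())


# ---------------------------------------------------------------------------
# derivation


def _check_design(design: pd.DataFrame) -> None:
    for col in design.columns:
        vals = design[col]
        if vals.isna().any():
            raise FitError(f"missing values in predictor {col!r}; "
                           "apply eligibility filtering first")
        if vals.nunique() <= 1:
            raise FitError(f"predictor {col!r} is constant in this stratum")


def fit_risk_model(
    cohort: pd.DataFrame,
    predictors: list[str],
    adjustment: list[str] | tuple = (),
    horizon: float = 10.0,
    disease: str = "",
) -> dict[str, RiskModel]:
    """Fit sex-specific Cox absolute-risk tools on a derivation cohort.

    Returns ``{"male": RiskModel, "female": RiskModel}``.  Exported
    coefficients cover ``predictors`` only; ``adjustment`` covariates are
    fitted but recorded solely in provenance.  Covariates that are entirely
    missing within a sex stratum (for example women-only flags in the male
    stratum) are dropped from that stratum's model and noted in provenance.
    """
    if not predictors:
        raise FitError("predictors must be non-empty")
    models: dict[str, RiskModel] = {}
    for sex in SEXES:
        sub = cohort[cohort[SEX_COLUMN] == sex]
        if len(sub) == 0 or sub["event"].sum() == 0:
            raise FitError(f"zero events in the {sex} stratum")
        preds = [p for p in predictors if not sub[p].isna().all()]
        adjs = [a for a in adjustment if not sub[a].isna().all()]
        dropped = sorted(set(predictors) - set(preds))
        cols = preds + adjs
        design = sub[cols + ["followup_years", "event"]].astype(float)
        _check_design(design[cols])

        cph = CoxPHFitter()
        try:
            cph.fit(design, duration_col="followup_years", event_col="event")
        except Exception as exc:  # lifelines raises ConvergenceError et al.
            raise FitError(f"Cox fit failed in the {sex} stratum: {exc}") from exc

        betas = cph.params_
        ses = cph.standard_errors_
        lp_full = design[cols].to_numpy() @ betas.to_numpy()
        h0 = breslow_cumulative_hazard(
            design["followup_years"].to_numpy(),
            design["event"].to_numpy(),
            np.exp(lp_full),
            horizon,
        )
        means = design[cols].mean()
        m_full = float((betas * means).sum())
        m_pred = float(sum(betas[p] * means[p] for p in preds))
        s0 = math.exp(-h0 * math.exp(m_full))

        models[sex] = RiskModel(
            disease=disease,
            sex=sex,
            horizon=horizon,
            coefficients={p: float(betas[p]) for p in preds},
            baseline_survival_at_horizon=s0,
            mean_component=m_pred,
            provenance={
                "derivation": "cox_ph/efron_ties/breslow_baseline",
                "n": int(len(sub)),
                "events": int(design["event"].sum()),
                "standard_errors": {p: float(ses[p]) for p in preds},
                "adjustment": {a: float(betas[a]) for a in adjs},
                "dropped_all_missing": dropped,
                "covariate_means": {c: float(means[c]) for c in cols},
            },
        )
    return models


def integrate_external_coefficients(
    model: RiskModel,
    extra: dict[str, float],
    extra_means: dict[str, float],
    source: str = "external",
) -> RiskModel:
    """Extend a model with externally derived coefficients.

    The added terms enter centred at the supplied means: the mean component
    grows by ``sum(beta * mean)`` while the baseline survival anchor stays
    fixed, so an individual at the supplied means keeps their original risk.
    """
    collisions = set(extra) & set(model.coefficients)
    if collisions:
        raise SchemaError(f"coefficient name collision: {sorted(collisions)}")
    missing = set(extra) - set(extra_means)
    if missing:
        raise SchemaError(f"no mean supplied for external betas: {sorted(missing)}")
    coeffs = dict(model.coefficients)
    m = model.mean_component
    for name, beta in extra.items():
        coeffs[name] = float(beta)
        m += float(beta) * float(extra_means[name])
    provenance = dict(model.provenance)
    provenance.setdefault("integrated", []).append(
        {"source": source, "covariates": sorted(extra)}
    )
    return RiskModel(
        disease=model.disease,
        sex=model.sex,
        horizon=model.horizon,
        coefficients=coeffs,
        baseline_survival_at_horizon=model.baseline_survival_at_horizon,
        mean_component=m,
        provenance=provenance,
    )


def recalibrate(model: RiskModel, cohort: pd.DataFrame) -> RiskModel:
    """Re-anchor a model's baseline survival and mean component in a target
    cohort, keeping every coefficient fixed.

    The model LP enters as a unit-coefficient offset: the Breslow baseline
    hazard is estimated with per-subject multipliers exp(LP_i), evaluated at
    the model horizon, and re-anchored at the target-cohort mean component.
    """
    if "followup_years" not in cohort.columns or "event" not in cohort.columns:
        raise SchemaError("target cohort needs followup_years and event")
    if cohort["event"].sum() == 0:
        raise FitError("no events in the target cohort")
    lp = linear_predictor(model, cohort).to_numpy()
    h0 = breslow_cumulative_hazard(
        cohort["followup_years"].to_numpy(dtype=float),
        cohort["event"].to_numpy(dtype=float),
        np.exp(lp),
        model.horizon,
    )
    means = {
        name: float(cohort[name].astype(float).mean())
        for name in model.coefficients
    }
    m_new = float(sum(model.coefficients[k] * means[k] for k in means))
    s0_new = math.exp(-h0 * math.exp(m_new))
    provenance = dict(model.provenance)
    provenance["recalibration"] = {
        "method": "unit_offset_breslow",
        "n": int(len(cohort)),
        "events": int(cohort["event"].sum()),
        "target_means": means,
    }
    return RiskModel(
        disease=model.disease,
        sex=model.sex,
        horizon=model.horizon,
        coefficients=dict(model.coefficients),
        baseline_survival_at_horizon=s0_new,
        mean_component=m_new,
        provenance=provenance,
    )


def score_by_sex(models: dict[str, RiskModel], cohort: pd.DataFrame) -> pd.Series:
    """Apply sex-specific models, returning one combined risk vector."""
    risk = pd.Series(np.nan, index=cohort.index, name="risk")
    for sex, model in models.items():
        mask = cohort[SEX_COLUMN] == sex
        if mask.any():
            risk[mask] = absolute_risk(model, cohort[mask])
    if risk.isna().any():
        raise SchemaError("cohort contains sexes not covered by the models")
    return risk


def recalibrate_by_sex(
    models: dict[str, RiskModel], cohort: pd.DataFrame
) -> dict[str, RiskModel]:
    return {
        sex: recalibrate(model, cohort[cohort[SEX_COLUMN] == sex])
        for sex, model in models.items()
    }
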