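"""End-to-end orchestration: derive -> integrate -> recalibrate -> score ->
evaluate, from one structured config.

Three nested predictor tiers are first class — ``baseline`` (PRS + age, plus
BMI for T2D), ``genomic`` (adding questionnaire factors), ``genomic_plus``
(adding SBP and lipid measurements).  Each tier is derived per sex on the
derivation cohort, recalibrated in the validation cohort, and evaluated
against the comparator scores (Pooled Cohort Equations for CHD — also
recalibrated — the FINDRISC point score for T2D, and any externally
supplied risk columns).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, cohort as cohort_io, metrics, riskmodel, simulate
from .exceptions import ConfigError, SchemaError

log = logging.getLogger("coxrisk.pipeline")

DEFAULT_THRESHOLDS = {"CHD": 0.075, "T2D": 0.056}


@dataclass
class PipelineConfig:
    """Resolved configuration for one full run."""

    disease: str
    derivation: str | simulate.GeneratorConfig
    validation: str | simulate.GeneratorConfig
    tiers: dict[str, list[str]] = field(default_factory=dict)
    threshold: float | None = None
    bootstrap_reps: int = 200
    seed: int = 0
    output_dir: str = "coxrisk_output"
    external_betas: str | None = None  # JSON: {covariate: {beta, mean}}
    external_scores: dict[str, str] = field(default_factory=dict)
    comparators: list[str] | None = None

    def __post_init__(self):
        if self.disease not in ("CHD", "T2D"):
            raise ConfigError(f"unknown disease {self.disease!r}")
        if not self.tiers:
            self.tiers = simulate.predictor_tiers(self.disease)
        names = list(self.tiers)
        for smaller, larger in zip(names, names[1:]):
            if not set(self.tiers[smaller]) <= set(self.tiers[larger]):
                raise ConfigError(
                    f"predictor tiers must be nested: {smaller!r} is not a "
                    f"subset of {larger!r}"
                )
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLDS[self.disease]
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must be in (0, 1)")
        if self.comparators is None:
            self.comparators = ["pce"] if self.disease == "CHD" else ["findrisc"]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("derivation", "validation"):
            val = raw.get(key)
            if isinstance(val, dict):
                raw[key] = simulate.GeneratorConfig.from_dict(val)
        return cls(**raw)


def _load_cohort(source, seed_offset: int, seed: int) -> pd.DataFrame:
    if isinstance(source, simulate.GeneratorConfig):
        cfg = dataclasses.replace(source, seed=seed + seed_offset)
        return simulate.generate_cohort(cfg)
    return cohort_io.read_cohort(source)


def _eligibility(disease: str, predictors, horizon: float):
    required = [p for p in predictors if p not in ("",)]
    if disease == "CHD":
        return cohort_io.chd_eligibility(require_complete=required, horizon=horizon)
    return cohort_io.t2d_eligibility(require_complete=required, horizon=horizon)


def _report_to_dict(rep: metrics.MetricReport) -> dict:
    d = dataclasses.asdict(rep)
    return {k: v for k, v in d.items() if v not in (None, "", {})}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the report bundle and writes every
    table under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    horizon = 10.0
    run_log: list[str] = []

    def stage(msg):
        log.info(msg)
        run_log.append(msg)

    stage(f"disease={config.disease} seed={config.seed} "
          f"threshold={config.threshold} bootstrap_reps={config.bootstrap_reps}")

    deriv = _load_cohort(config.derivation, 1, config.seed)
    valid = _load_cohort(config.validation, 2, config.seed)
    all_predictors = sorted(set().union(*config.tiers.values()))
    spec_d = _eligibility(config.disease, all_predictors, horizon)
    comparator_cols = []
    if "pce" in config.comparators:
        comparator_cols = ["tc", "hdl", "sbp", "bp_medication",
                          "diabetes_history", "smoking_current"]
    spec_v = _eligibility(
        config.disease, sorted(set(all_predictors + comparator_cols)), horizon
    )
    deriv, ledger_d = cohort_io.apply_eligibility(deriv, spec_d)
    valid, ledger_v = cohort_io.apply_eligibility(valid, spec_v)
    stage("derivation eligibility: " + json.dumps(ledger_d))
    stage("validation eligibility: " + json.dumps(ledger_v))
    (out / "exclusion_ledgers.txt").write_text(
        "derivation\n" + json.dumps(ledger_d, indent=2)
        + "\nvalidation\n" + json.dumps(ledger_v, indent=2) + "\n"
    )

    external = None
    if config.external_betas:
        with open(config.external_betas) as fh:
            external = json.load(fh)

    bundle: dict = {"config": {"disease": config.disease, "seed": config.seed,
                               "threshold": config.threshold},
                    "tiers": {}, "comparators": {}}
    risks: dict[str, pd.Series] = {}
    event = valid["event"].to_numpy(dtype=float)
    followup = valid["followup_years"].to_numpy(dtype=float)

    for tier, predictors in config.tiers.items():
        fit_predictors = list(predictors)
        extra = {}
        if external:
            extra = {k: v for k, v in external.items() if k in predictors}
            fit_predictors = [p for p in predictors if p not in extra]
        models = riskmodel.fit_risk_model(
            deriv, fit_predictors, horizon=horizon, disease=config.disease
        )
        if extra:
            models = {
                sex: riskmodel.integrate_external_coefficients(
                    m,
                    {k: v["beta"] for k, v in extra.items()
                     if not (sex == "male" and k in cohort_io.WOMEN_ONLY_COLUMNS)},
                    {k: v["mean"] for k, v in extra.items()},
                    source=str(config.external_betas),
                )
                for sex, m in models.items()
            }
        for sex, m in models.items():
            riskmodel.save_model(m, out / f"model_{tier}_{sex}.json")
        pre_risk = riskmodel.score_by_sex(models, valid)
        recal = riskmodel.recalibrate_by_sex(models, valid)
        for sex, m in recal.items():
            riskmodel.save_model(m, out / f"model_{tier}_{sex}_recalibrated.json")
        post_risk = riskmodel.score_by_sex(recal, valid)
        risks[tier] = post_risk
        stage(f"tier {tier}: derived and recalibrated "
              f"({len(models['male'].coefficients)} male coefficients)")

        cal_pre = metrics.calibration_deciles(pre_risk, event, followup, horizon)
        cal_post = metrics.calibration_deciles(post_risk, event, followup, horizon)
        cal_pre.to_csv(out / f"calibration_{tier}_pre.csv", index=False)
        cal_post.to_csv(out / f"calibration_{tier}_post.csv", index=False)

        auc = metrics.auc_delong(post_risk.to_numpy(), event)
        sub = metrics.subgroup_metrics(
            post_risk.to_numpy(), valid,
            metrics.default_subgroups(valid, bmi_split=config.disease == "T2D"),
        )
        hrs = metrics.percentile_hazard_ratios(post_risk.to_numpy(), event, followup)
        km = metrics.km_by_band(post_risk.to_numpy(), event, followup, horizon)
        km.to_csv(out / f"km_bands_{tier}.csv", index=False)
        bundle["tiers"][tier] = {
            "auc": _report_to_dict(auc),
            "subgroup_auc": [_report_to_dict(r) for r in sub],
            "hazard_ratios": [_report_to_dict(r) for r in hrs],
            "mean_risk_pre_recalibration": float(pre_risk.mean()),
            "mean_risk_post_recalibration": float(post_risk.mean()),
        }

    # comparator scores on the validation cohort
    comparator_risks: dict[str, np.ndarray] = {}
    for comp in config.comparators:
        if comp == "pce":
            coeffs = clinical.PCECoefficients.load()
            models = {
                sex: coeffs.risk_model(sex) for sex in ("male", "female")
            }
            design = clinical.pce_design(valid)
            design["followup_years"] = valid["followup_years"].to_numpy()
            design["event"] = valid["event"].to_numpy()
            recal = {
                sex: riskmodel.recalibrate(
                    m, design[design[cohort_io.SEX_COLUMN] == sex]
                )
                for sex, m in models.items()
            }
            comparator_risks["pce"] = riskmodel.score_by_sex(recal, design).to_numpy()
            stage("comparator pce: recalibrated in validation cohort")
        elif comp == "findrisc":
            score = clinical.findrisc_score(valid, require_waist="waist_cm" in valid)
            comparator_risks["findrisc"] = score.to_numpy(dtype=float)
            stage("comparator findrisc: integer point score (not recalibrated)")
        else:
            raise ConfigError(f"unknown comparator {comp!r}")
    for name, path in config.external_scores.items():
        valid = clinical.attach_external_scores(valid, path, name)
        comparator_risks[name] = valid[name].to_numpy(dtype=float)
        stage(f"comparator {name}: attached external scores from {path}")

    probability_comparators = {
        k: v for k, v in comparator_risks.items() if k != "findrisc"
    }
    for name, comp_risk in comparator_risks.items():
        auc = metrics.auc_delong(comp_risk, event)
        entry = {"auc": _report_to_dict(auc), "delta_auc": {}}
        for tier, tier_risk in risks.items():
            cmp = metrics.auc_compare(tier_risk.to_numpy(), comp_risk, event)
            entry["delta_auc"][tier] = _report_to_dict(cmp)
        hrs = metrics.percentile_hazard_ratios(comp_risk, event, followup)
        entry["hazard_ratios"] = [_report_to_dict(r) for r in hrs]
        bundle["comparators"][name] = entry

    # reclassification battery against probability-scale comparators
    reclass_rows = []
    for name, comp_risk in probability_comparators.items():
        for tier, tier_risk in risks.items():
            if tier == "baseline":
                continue
            table = metrics.reclassification(
                comp_risk, tier_risk.to_numpy(), event, config.threshold,
                label_old=name, label_new=tier,
            )
            nri = metrics.nri_bootstrap_ci(
                comp_risk, tier_risk.to_numpy(), event, config.threshold,
                n_reps=config.bootstrap_reps, seed=config.seed,
            )
            cnri = metrics.continuous_nri(comp_risk, tier_risk.to_numpy(), event)
            didi = metrics.idi(comp_risk, tier_risk.to_numpy(), event)
            frame = table.to_frame()
            frame.insert(0, "comparison", f"{tier}_vs_{name}")
            reclass_rows.append(frame.reset_index())
            bundle.setdefault("reclassification", {})[f"{tier}_vs_{name}"] = {
                "event_nri": nri.event_nri,
                "event_ci": list(nri.event_ci),
                "nonevent_nri": nri.nonevent_nri,
                "nonevent_ci": list(nri.nonevent_ci),
                "overall_nri": nri.overall_nri,
                "overall_ci": list(nri.overall_ci),
                "continuous_nri": _report_to_dict(cnri),
                "idi": _report_to_dict(didi),
            }
    if reclass_rows:
        pd.concat(reclass_rows, ignore_index=True).to_csv(
            out / "reclassification.csv", index=False
        )

    risk_table = valid[["id"]].copy()
    for tier, r in risks.items():
        risk_table[f"risk_{tier}"] = r.to_numpy()
    for name, r in comparator_risks.items():
        risk_table[f"risk_{name}"] = r
    risk_table.to_csv(out / "risk_vectors.csv", index=False)

    (out / "summary.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    (out / "run_log.txt").write_text("\n".join(run_log) + "\n")
    bundle["output_dir"] = str(out)
    return bundle
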