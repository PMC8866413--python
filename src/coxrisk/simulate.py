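"""Synthetic biobank-like cohort generation.

The generator emulates the statistical structure a 10-year incident-disease
analysis assumes: sex-stratified correlated baseline risk factors, a
standard-normal polygenic score, proportional-hazards event times with a
Weibull baseline, independent exponential dropout, administrative censoring
at the horizon, and prevalence flags that drive eligibility exclusions.

Covariates are drawn through a Gaussian copula: one latent multivariate
normal per individual with the configured pairwise correlations; continuous
covariates are obtained by scaling (normal) or exponentiating (lognormal)
the latent value, binary covariates by thresholding it at the quantile of
the configured prevalence.  Event times are inverted analytically from the
Weibull cumulative hazard scaled by exp(linear predictor), so the output has
exact proportional-hazards structure and Cox-fit parameter recovery is a
valid oracle.  The linear predictor is centred at the theoretical covariate
means, which are recorded (with the effects and baseline) in a
:class:`TrueParameters` sidecar for parameter-recovery and calibration
tests.

All randomness flows through a single :func:`numpy.random.default_rng`
stream, so an identical config + seed reproduces the table byte for byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import SEX_COLUMN, validate_cohort
from .exceptions import ConfigError

_DISTRIBUTIONS = ("normal", "lognormal", "bernoulli")


@dataclass
class CovariateSpec:
    """Marginal distribution of one covariate.

    ``params`` are ``(mean, sd)`` for ``normal``, ``(mean_log, sd_log)`` for
    ``lognormal`` and ``(p,)`` for ``bernoulli``; either a single tuple or a
    ``{"male": ..., "female": ...}`` mapping for sex-specific marginals.
    ``women_only`` covariates are missing (NaN) for men.
    """

    dist: str
    params: tuple | dict
    women_only: bool = False

    def __post_init__(self):
        if self.dist not in _DISTRIBUTIONS:
            raise ConfigError(f"unknown distribution {self.dist!r}")
        if isinstance(self.params, dict):
            self.params = {s: tuple(v) for s, v in self.params.items()}
        else:
            self.params = tuple(self.params)
        for p in self._per_sex().values():
            if self.dist == "bernoulli":
                if not 0.0 <= p[0] <= 1.0:
                    raise ConfigError(f"bernoulli p must be in [0,1], got {p[0]}")
            elif p[1] <= 0:
                raise ConfigError(f"{self.dist} sd must be > 0, got {p[1]}")

    def _per_sex(self) -> dict:
        if isinstance(self.params, dict):
            return {s: tuple(v) for s, v in self.params.items()}
        return {"male": tuple(self.params), "female": tuple(self.params)}

    def theoretical_mean(self, sex_fraction_female: float) -> float:
        """Population mean implied by the marginals (women-only covariates
        averaged over women only)."""
        per_sex = self._per_sex()
        means = {}
        for sex, p in per_sex.items():
            if self.dist == "normal":
                means[sex] = p[0]
            elif self.dist == "lognormal":
                means[sex] = math.exp(p[0] + p[1] ** 2 / 2.0)
            else:
                means[sex] = p[0]
        if self.women_only:
            return means["female"]
        f = sex_fraction_female
        return f * means["female"] + (1.0 - f) * means["male"]


@dataclass
class GeneratorConfig:
    """Full recipe for one synthetic cohort."""

    n_individuals: int
    disease: str
    seed: int = 0
    sex_fraction_female: float = 0.5
    age_range: tuple[float, float] = (40.0, 70.0)
    prs_effect: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    covariate_distributions: dict[str, CovariateSpec] = field(default_factory=dict)
    correlation_spec: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_weibull: tuple[float, float] = (1.3, 150.0)  # (shape, scale years)
    censor_rate: float = 0.0  # exponential dropout events per year
    horizon: float = 10.0
    prevalence_rates: dict[str, float] = field(default_factory=dict)
    derive_total_cholesterol: bool = True

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ConfigError("sex_fraction_female must be in [0,1]")
        shape, scale = self.baseline_weibull
        if shape <= 0 or scale <= 0:
            raise ConfigError("Weibull shape and scale must be > 0")
        if self.horizon <= 0:
            raise ConfigError("horizon must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range low must be < high")
        for p in self.prevalence_rates.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigError("prevalence rates must be in [0,1]")
        for name in self.prevalence_rates:
            if name in self.covariate_distributions:
                raise ConfigError(
                    f"prevalence flag {name!r} collides with a covariate"
                )
        known = set(self.covariate_distributions) | {"prs", "age_at_baseline"}
        for name in self.covariate_effects:
            if name not in known:
                raise ConfigError(f"unknown covariate in covariate_effects: {name!r}")
        self._correlation_matrix()  # raises on invalid structure

    def _copula_order(self) -> list[str]:
        return list(self.covariate_distributions)

    def _correlation_matrix(self) -> np.ndarray:
        names = self._copula_order()
        index = {n: i for i, n in enumerate(names)}
        r = np.eye(len(names))
        for a, b, rho in self.correlation_spec:
            if a not in index or b not in index:
                raise ConfigError(f"correlation names unknown covariate: ({a}, {b})")
            if a == b:
                raise ConfigError(f"self-correlation not allowed: ({a}, {b})")
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"correlation out of range for pair ({a}, {b})")
            r[index[a], index[b]] = rho
            r[index[b], index[a]] = rho
        if len(names) and np.linalg.eigvalsh(r).min() < -1e-10:
            raise ConfigError(
                "correlation_spec is not positive semi-definite; "
                f"pairs: {[(a, b) for a, b, _ in self.correlation_spec]}"
            )
        return r

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_distributions"] = {
            k: dataclasses.asdict(v) for k, v in self.covariate_distributions.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["covariate_distributions"] = {
            k: CovariateSpec(**v) if not isinstance(v, CovariateSpec) else v
            for k, v in d.get("covariate_distributions", {}).items()
        }
        d["age_range"] = tuple(d.get("age_range", (40.0, 70.0)))
        d["baseline_weibull"] = tuple(d.get("baseline_weibull", (1.3, 150.0)))
        d["correlation_spec"] = [tuple(t) for t in d.get("correlation_spec", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrueParameters:
    """Generating truth recorded alongside a synthetic cohort."""

    covariate_effects: dict[str, float]
    covariate_means: dict[str, float]
    baseline_weibull: tuple[float, float]
    censor_rate: float
    horizon: float

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["baseline_weibull"] = list(self.baseline_weibull)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrueParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["baseline_weibull"] = tuple(d["baseline_weibull"])
        return cls(**d)

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        """Centred generating linear predictor for each row (women-only
        covariates contribute zero for men)."""
        lp = np.zeros(len(cohort))
        for name, beta in self.covariate_effects.items():
            x = cohort[name].to_numpy(dtype=float)
            mu = self.covariate_means[name]
            lp += beta * (np.where(np.isnan(x), mu, x) - mu)
        return lp

    def cumulative_baseline_hazard(self, t: float) -> float:
        shape, scale = self.baseline_weibull
        return (t / scale) ** shape

    def true_risk(self, cohort: pd.DataFrame, t: float | None = None) -> np.ndarray:
        """Exact event probability by time ``t`` under the generating model
        (ignoring dropout), per individual."""
        t = self.horizon if t is None else t
        h0 = self.cumulative_baseline_hazard(t)
        return 1.0 - np.exp(-h0 * np.exp(self.linear_predictor(cohort)))

    def marginal_survival(self, t: float) -> float:
        """Baseline (reference-individual) survival including dropout-free
        Weibull only; useful for null-effect checks."""
        return math.exp(-self.cumulative_baseline_hazard(t))


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort table from the configured generative model.

    The returned frame carries the :class:`TrueParameters` record in
    ``df.attrs["true_parameters"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    df = pd.DataFrame(
        {"id": [f"S{i:07d}" for i in range(n)]},
    )
    female = rng.random(n) < config.sex_fraction_female
    df[SEX_COLUMN] = np.where(female, "female", "male")
    lo, hi = config.age_range
    df["age_at_baseline"] = rng.uniform(lo, hi, size=n)
    df["prs"] = rng.standard_normal(n)

    # latent Gaussian copula over the configured covariates
    names = config._copula_order()
    if names:
        corr = config._correlation_matrix()
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
        z = rng.standard_normal((n, len(names))) @ chol.T
        for j, name in enumerate(names):
            spec = config.covariate_distributions[name]
            col = np.full(n, np.nan)
            for sex, p in spec._per_sex().items():
                mask = female if sex == "female" else ~female
                if spec.women_only and sex == "male":
                    continue
                zj = z[mask, j]
                if spec.dist == "normal":
                    col[mask] = p[0] + p[1] * zj
                elif spec.dist == "lognormal":
                    col[mask] = np.exp(p[0] + p[1] * zj)
                else:  # bernoulli via latent threshold
                    col[mask] = (stats.norm.cdf(zj) > 1.0 - p[0]).astype(float)
            df[name] = col

    if (
        config.derive_total_cholesterol
        and {"hdl", "ldl", "tg"} <= set(df.columns)
        and "tc" not in df.columns
    ):
        # Friedewald composition keeps TC consistent with the fractions
        df["tc"] = df["hdl"] + df["ldl"] + df["tg"] / 2.2

    # prevalence flags (independent of the event process)
    for flag, rate in config.prevalence_rates.items():
        df[flag] = (rng.random(n) < rate).astype(float)

    # generating truth: effects over prs + age + configured covariates
    effects = dict(config.covariate_effects)
    if config.prs_effect:
        effects["prs"] = effects.get("prs", 0.0) + config.prs_effect
    means = {}
    for name in effects:
        if name == "prs":
            means[name] = 0.0
        elif name == "age_at_baseline":
            means[name] = (lo + hi) / 2.0
        else:
            spec = config.covariate_distributions[name]
            means[name] = spec.theoretical_mean(config.sex_fraction_female)
    truth = TrueParameters(
        covariate_effects=effects,
        covariate_means=means,
        baseline_weibull=tuple(config.baseline_weibull),
        censor_rate=config.censor_rate,
        horizon=config.horizon,
    )

    # analytic inversion of the Weibull cumulative hazard under PH
    shape, scale = config.baseline_weibull
    lp = truth.linear_predictor(df)
    e = rng.exponential(1.0, size=n)
    t_event = scale * (e / np.exp(lp)) ** (1.0 / shape)
    if config.censor_rate > 0:
        t_censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    observed = np.minimum.reduce([t_event, t_censor, np.full(n, config.horizon)])
    df["followup_years"] = np.maximum(observed, 1e-8)
    df["event"] = ((t_event <= t_censor) & (t_event <= config.horizon)).astype(float)

    validate_cohort(df)
    df.attrs["true_parameters"] = truth
    return df


# ---------------------------------------------------------------------------
# default study conditions


def chd_predictor_tiers() -> dict[str, list[str]]:
    """Nested predictor tiers for the CHD risk tools (sex handled by
    stratification, not as a covariate)."""
    baseline = ["prs", "age_at_baseline"]
    genomic = baseline + [
        "smoking_current",
        "bmi",
        "bp_medication",
        "diabetes_history",
        "family_history_chd",
    ]
    genomic_plus = genomic + ["sbp", "hdl", "ldl"]
    return {"baseline": baseline, "genomic": genomic, "genomic_plus": genomic_plus}


def t2d_predictor_tiers() -> dict[str, list[str]]:
    baseline = ["prs", "age_at_baseline", "bmi"]
    genomic = baseline + [
        "smoking_current",
        "bp_medication",
        "statin_use",
        "cvd_history",
        "gestational_diabetes",
        "family_history_dm",
    ]
    genomic_plus = genomic + ["sbp", "hdl", "tg"]
    return {"baseline": baseline, "genomic": genomic, "genomic_plus": genomic_plus}


def predictor_tiers(disease: str) -> dict[str, list[str]]:
    if disease == "CHD":
        return chd_predictor_tiers()
    if disease == "T2D":
        return t2d_predictor_tiers()
    raise ConfigError(f"unknown disease label {disease!r}")


def default_config(disease: str, n_individuals: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """Documented default generator for a CHD- or T2D-like cohort.

    Marginal moments are chosen to resemble a middle-aged European biobank
    sample (current smoking ~10-12%, BMI ~27 +/- 4 kg/m^2, SBP ~138 +/- 18
    mmHg, HDL higher in women); log-hazard-ratio effects are plausible
    literature-scale values.  Risk-factor correlations are illustrative
    placeholders, not estimates of any particular cohort.
    """
    if disease == "CHD":
        dists = {
            "smoking_current": CovariateSpec("bernoulli", (0.12,)),
            "bmi": CovariateSpec("normal", (27.2, 4.2)),
            "bp_medication": CovariateSpec("bernoulli", (0.12,)),
            "diabetes_history": CovariateSpec("bernoulli", (0.025,)),
            "family_history_chd": CovariateSpec("bernoulli", (0.40,)),
            "sbp": CovariateSpec("normal", (138.0, 18.0)),
            "hdl": CovariateSpec(
                "lognormal", {"male": (0.22, 0.25), "female": (0.44, 0.25)}
            ),
            "ldl": CovariateSpec("normal", (3.6, 0.85)),
            "tg": CovariateSpec("lognormal", (0.40, 0.50)),
        }
        effects = {
            "age_at_baseline": 0.075,
            "smoking_current": 0.65,
            "bmi": 0.025,
            "bp_medication": 0.35,
            "diabetes_history": 0.65,
            "family_history_chd": 0.35,
            "sbp": 0.010,
            "hdl": -0.45,
            "ldl": 0.22,
        }
        corr = [
            ("bmi", "sbp", 0.25),
            ("bmi", "tg", 0.30),
            ("bmi", "hdl", -0.25),
            ("hdl", "tg", -0.40),
            ("sbp", "tg", 0.10),
            ("bmi", "bp_medication", 0.20),
            ("sbp", "bp_medication", 0.30),
            ("bmi", "diabetes_history", 0.25),
        ]
        return GeneratorConfig(
            n_individuals=n_individuals,
            disease="CHD",
            seed=seed,
            sex_fraction_female=0.55,
            age_range=(40.0, 70.0),
            prs_effect=math.log(1.6),
            covariate_effects=effects,
            covariate_distributions=dists,
            correlation_spec=corr,
            baseline_weibull=(1.3, 147.0),
            censor_rate=0.02,
            horizon=10.0,
            prevalence_rates={"cvd_history": 0.07, "statin_use": 0.12},
        )
    if disease == "T2D":
        dists = {
            "bmi": CovariateSpec("normal", (27.5, 4.5)),
            "smoking_current": CovariateSpec("bernoulli", (0.11,)),
            "bp_medication": CovariateSpec("bernoulli", (0.18,)),
            "statin_use": CovariateSpec("bernoulli", (0.14,)),
            "cvd_history": CovariateSpec("bernoulli", (0.06,)),
            "gestational_diabetes": CovariateSpec(
                "bernoulli", (0.02,), women_only=True
            ),
            "family_history_dm": CovariateSpec("bernoulli", (0.20,)),
            "sbp": CovariateSpec("normal", (139.0, 18.0)),
            "hdl": CovariateSpec(
                "lognormal", {"male": (0.22, 0.25), "female": (0.44, 0.25)}
            ),
            "tg": CovariateSpec("lognormal", (0.40, 0.50)),
            "waist_cm": CovariateSpec(
                "normal", {"male": (97.0, 11.0), "female": (85.0, 12.0)}
            ),
            "physical_activity": CovariateSpec("bernoulli", (0.65,)),
            "vegetables_daily": CovariateSpec("bernoulli", (0.45,)),
            "high_glucose_history": CovariateSpec("bernoulli", (0.04,)),
        }
        effects = {
            "age_at_baseline": 0.045,
            "bmi": 0.09,
            "smoking_current": 0.30,
            "bp_medication": 0.30,
            "statin_use": 0.30,
            "cvd_history": 0.30,
            "gestational_diabetes": 1.10,
            "family_history_dm": 0.55,
            "sbp": 0.008,
            "hdl": -0.50,
            "tg": 0.18,
            "high_glucose_history": 0.90,
            "physical_activity": -0.15,
        }
        corr = [
            ("bmi", "waist_cm", 0.80),
            ("bmi", "sbp", 0.25),
            ("bmi", "tg", 0.30),
            ("bmi", "hdl", -0.25),
            ("hdl", "tg", -0.40),
            ("bmi", "bp_medication", 0.20),
            ("bmi", "high_glucose_history", 0.20),
        ]
        return GeneratorConfig(
            n_individuals=n_individuals,
            disease="T2D",
            seed=seed,
            sex_fraction_female=0.54,
            age_range=(40.0, 70.0),
            prs_effect=math.log(1.75),
            covariate_effects=effects,
            covariate_distributions=dists,
            correlation_spec=corr,
            baseline_weibull=(1.5, 116.0),
            censor_rate=0.02,
            horizon=10.0,
            prevalence_rates={"diabetes_history": 0.05},
        )
    raise ConfigError(f"unknown disease label {disease!r}")
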