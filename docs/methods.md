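# Methods

## Absolute-risk model

A risk tool is a sex-specific Cox proportional-hazards linear predictor
converted to 10-year absolute risk by the standard Breslow composition

    risk_i = 1 − S₀(t)^exp(LP_i − m),   LP_i = Σ_j β_j x_ij,   m = Σ_j β_j x̄_j.

The three components are carried together in a `RiskModel` bundle
(JSON, versioned, lossless round trip): per-unit log hazard ratios β, the
baseline survival S₀(t) at the horizon, and the mean component m. Because
S₀ and m are anchored jointly, predictions are invariant to where the
baseline is centred — whether a derivation pipeline evaluated its baseline
at covariate means or at zero does not matter so long as the pair moves
together, and every operation here preserves that.

**Fitting.** The partial likelihood is maximised by lifelines'
`CoxPHFitter` with Efron handling of tied event times (ties in the Breslow
*estimator* itself share the risk-set denominator at the tie, the common
convention). The baseline cumulative hazard is the Breslow estimator with
per-subject multipliers exp(LP) over all fitted covariates, evaluated at
the horizon and anchored at the covariate means of the derivation stratum.
Constant predictors raise an error rather than being silently dropped; a
covariate that is *entirely* missing in one sex stratum (women-only flags
such as gestational diabetes in the male stratum) is excluded from that
stratum's model and recorded in provenance.

**Adjustment covariates** (e.g. ancestry principal components) are included
in the fit but excluded from the exported score. Exporting them would make
the tool non-portable across cohorts; because the baseline is anchored at
their derivation means, predictions implicitly hold them at the average.
Their fitted betas are kept in provenance.

**External coefficient integration.** Coefficients estimated elsewhere
(family history, clinical measurements) are merged into a tool without
refitting: each added term enters centred at a supplied mean, incrementing
m by β·mean while the baseline anchor stays fixed. An individual sitting at
the supplied means keeps their original risk exactly; no joint
individual-level data is required.

**Recalibration.** To transport a tool to a new cohort the coefficients are
frozen and only the anchor moves: the model LP enters a proportional-
hazards model as an offset with coefficient one — realised directly as the
Breslow estimator with multipliers exp(LP_i) — giving a target-cohort
baseline cumulative hazard; m is recomputed over the target covariate
means and S₀(t) re-anchored there. Applied to the tool's own derivation
cohort (without adjustment covariates) this is an exact fixed point.

## Comparator scores

The 2013 Pooled Cohort Equations are evaluated from a packaged,
citation-headed coefficient file (white/European set by default, the other
published group included) over the published transformed design (log age,
log lipids in mg/dL, treated/untreated log SBP, smoking and diabetes terms
with age interactions). The equation has exactly the absolute-risk form
above, so the PCE is represented internally as a `RiskModel` over the
transformed columns and shares the scoring and recalibration code path.
Ages outside the published 40–79 validity range are flagged per individual,
not refused. FINDRISC is the full 8-item integer point table (0–26);
numeric categories use the convention lower ≤ x < upper, a first-degree-only
family-history mode makes second-degree points unreachable where that item
is unavailable, and a documented no-waist variant scores the waist item as
zero. Richer proprietary algorithms (QRISK3, QDiabetes) are consumed as
externally computed per-individual risks through a two-column adapter.

## Evaluation battery

* **AUC**: Mann–Whitney probability with ties counted ½; variance, CIs and
  paired model comparisons by DeLong's structural-components method,
  two-sided. The point estimate is exactly the O(n²) pair-count value
  (tested to 1e-12).
* **Categorical NRI** at a closed-lower-bound threshold (risk ≥ 7.5% CHD,
  ≥ 5.6% T2D), reported on the percent scale; overall = event + non-event
  exactly, enforced structurally. Bootstrap CIs are percentile intervals
  over 200 replicates, stratified by case status by default so each
  replicate has both denominators (a flag restores unstratified resampling,
  in which caseless replicates are redrawn and counted).
* **Continuous NRI** (sign-based, ties contribute zero, percent scale) and
  **IDI** (difference of discrimination slopes).
* **Calibration deciles**: equal-count bins of predicted risk vs
  Kaplan–Meier observed incidence at the horizon — KM rather than raw
  proportions because follow-up is censored; with no censoring the two
  coincide (tested). Heavy ties reduce the bin count with a recorded note.
* **Percentile hazard ratios**: score percentiles from stable (ordinal)
  ranks, boundary values joining the upper band; Cox fit on band indicators
  with the interquartile band as reference; KM incidence per band
  exportable.
* **Subgroups**: AUC within men/women, age split at 55, BMI split at 30
  (T2D); single-class subgroups are reported as not estimable rather than
  raised.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes: sex (Bernoulli),
age (uniform over a configured range), a standard-normal PRS, correlated
baseline covariates, proportional-hazards event times, independent
exponential dropout, administrative censoring at the 10-year horizon, and
prevalence flags that drive eligibility exclusions. Covariates are drawn
through a Gaussian copula: a latent multivariate normal with the configured
pairwise correlations; normal and lognormal margins by transformation,
binary covariates by thresholding the latent value at the prevalence
quantile. `correlation_spec` therefore specifies *latent* (copula)
correlations; monotone marginal transforms attenuate raw Pearson values, so
correlation checks are made on the latent scale. Event times are inverted
analytically from the Weibull cumulative hazard scaled by exp(LP), so the
output has exact proportional-hazards structure and Cox recovery is a valid
oracle; the LP is centred at theoretical covariate means, recorded with the
effects and baseline in a `TrueParameters` sidecar that round-trips through
YAML. All draws flow through a single seeded generator stream, so identical
config + seed reproduces the table byte for byte. Total cholesterol, when
not supplied, is composed from the fractions (HDL + LDL + TG/2.2) so the
lipid panel stays internally consistent.

**Defaults.** The shipped CHD and T2D configurations use marginal moments
resembling a middle-aged European biobank sample (current smoking 11–12%,
BMI 27 ± 4 kg/m², SBP ~138 ± 18 mmHg, HDL higher in women, 40–70 years at
baseline), literature-scale log hazard ratios (PRS ln 1.6 per SD for CHD,
ln 1.75 for T2D; BMI 0.09 per kg/m² for T2D), Weibull baselines giving
roughly 3% (CHD) and 2.5% (T2D) 10-year incidence at the reference point
with mildly increasing hazard (shapes 1.3 / 1.5), and 2%/year dropout,
which reproduces the heavily right-truncated follow-up pattern (median 10
years) of a mature biobank. Risk-factor correlation magnitudes are
illustrative placeholders — plausible confounding (BMI–SBP 0.25, BMI–waist
0.8, HDL–TG −0.4) — not estimates of any particular cohort.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: genotype/LD structure behind the PRS (only
its standardised marginal), registry-code phenotyping error,
non-proportional hazards, competing risks, informative censoring,
measurement error in questionnaire items, and secular or age-cohort trends.
Tests on generated data validate the *machinery* (estimators, identities,
calibration logic), not cohort-specific effect sizes.

## Eligibility and schema

Cohorts are plain CSV/TSV with a canonical column dictionary; `NA` is the
file missing sentinel and NaN the only internal missing marker. Lipids are
mmol/L and SBP mmHg, with mg/dL converters (38.67 cholesterol, 88.57
triglycerides). Exclusions apply in a fixed order — age bounds, prevalent
conditions in spec order (prevalent CVD then baseline statins for CHD;
prevalent diabetes for T2D), then missing predictors — with the count
removed at each step recorded in a ledger, making the order auditable.
Follow-up is then truncated at the horizon: events after 10 years become
non-events censored at 10. Analysis is complete-case; no imputation.
Gestational diabetes is defined for women only and is never treated as
"incomplete" in men.

## Numerical choices and problem sizes

Bootstrap and simulation outputs are seed-reproducible throughout. The test
suite uses cohorts of 20k–100k rows where a distributional property is
asserted (3-SE bands) and small hand-enumerable fixtures for exact
arithmetic. The bootstrap-coverage study uses samples of n = 8000 (~1000
cases) per repeat, 200 repeats × 200 bootstrap replicates, with the
population NRI evaluated on 4 million draws of the same model; percentile
intervals for the NRI are known to undercover at much smaller sample
sizes, so the study is sized where nominal coverage is attainable. The
parameter-recovery study uses 20 cohorts of n = 50,000. Degenerate inputs
raise typed errors (`ConfigError`, `SchemaError`, `FitError`,
`ModelIOError`) naming the offending column, pair, or stratum.

## Known limitations

Single-event, single-horizon tools only: no time-varying covariates, no
competing-risk (Fine–Gray) absolute risk, no lifetime risk. The PCE
implementation covers the two published race groups only, and FINDRISC
category boundary conventions (half-open intervals) place boundary values
such as BMI = 30.0 in the upper category. The shipped model weights are
synthetic-derived demonstrations; user-supplied published coefficient
bundles are loaded through the same `RiskModel` format.
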