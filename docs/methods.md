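# Methods

## Pharmacokinetic features

For each patient and a fixed window `[start, end]` in months
post-transplant (default `[6, 12]`, both boundaries included), every
visit with a recorded trough C0 (ng/mL) and a positive total daily dose
TDD (mg/day) contributes one dose-normalized trough C0/D = C0 / TDD
(ng/mL/mg).  The intrapatient variability is the coefficient of
variation of those values,

    IPV% = SD(C0/D) / mean(C0/D) × 100 ,

with the sample (n−1) standard deviation.  The sample convention is the
usual one for therapeutic-drug-monitoring IPV; the population SD
(`ddof=0`) is available for sensitivity analysis.  Only SD/mean is
offered: the inverted ratio is not a variability measure, and exposing
it would invite silent misuse.  At least two windowed visits are
required; patients below that raise (or are skipped with their ids
recorded), and the validator warns below four, the lower end of the
per-patient sample counts this pipeline is designed around.

Metabolizer class uses the C0/D of the visit nearest month 3 within
±1 month: fast < 1.05 ≤ intermediate < 1.55 ≤ slow (ng/mL/mg).  The
upper cut is implemented as `< 1.55` vs `≥ 1.55`, which closes the gap a
"1.05–1.54 vs ≥1.55" reading would leave on (1.54, 1.55).  With no
visit near month 3 the class is `undetermined`.

## Renal function

The 4-variable MDRD study equation,

    eGFR = k · (Scr/88.4)^(−1.154) · age^(−0.203) · 0.742[female] ,

with creatinine Scr in µmol/L (converted to mg/dL by /88.4) and no race
term.  `k` defaults to 186 (original calibration); 175 (IDMS-traceable)
is a parameter because laboratory calibration varies between centers and
is rarely reported.  Window aggregation is the arithmetic mean of values
inside the closed window.

## The outcome model

A five-predictor linear model for the per-patient mean eGFR in months
13–36:

    y = 11.256 + 0.764·eGFR6 − 0.103·IPV% + 1.439·Sex + 1.676·C0/D − 10.112·AR

Sex is male = 1 / female = 0; AR (acute rejection within year one) is
yes = 1 / no = 0.  These codings are enforced by `ModelInputs` because a
silent flip corrupts every downstream number while leaving the pipeline
superficially plausible.  The model is affine, so the prediction at the
mean of any input set equals the mean of the predictions — a property
the Monte Carlo tests exploit exactly.

`EgfrLinearModel` either carries this fixed coefficient set
(`coef="published"`) or re-estimates the same specification by OLS
(statsmodels), returning 95% confidence intervals, standardized betas
(b·SD(x)/SD(y)) and R².  Age can be added as a covariate to mirror the
wider multivariable analysis; the default specification excludes it (its
effect is null in that analysis, p ≈ 0.66).  The outcome is the
per-patient window mean; per-observation fitting is possible by passing
one row per examination, but the per-patient mean is the default
aggregation.

Auxiliary statistics follow the nonparametric conventions of this
literature: Mann–Whitney U with the tie-corrected normal-approximation
Z (cohort group sizes make exact enumeration unnecessary), Pearson
chi-square without continuity correction on 2×2 tables, and Spearman
rank correlation by default (Pearson by flag).

## Monte Carlo engine

Each scenario fixes sex and AR and assigns independent distributions to
eGFR6, IPV and C0/D ("randomly combined" inputs).  The published grid is
the full factorial: 2 eGFR6 bands (30–44, 45–59 mL/min/1.73 m²) × 2 IPV
bands (15–29.99, 30–59.99%) × 2 genotype C0/D spreads (expresser \*1/\*3:
1.30 ± 0.54; non-expresser \*3/\*3: 1.92 ± 0.98 ng/mL/mg) × 2 sexes × 2
AR states = 32 cells, 1000 draws per cell by default (draws are
allocated per cell, not shared).

Sampling assumptions, since only ranges are stated for the banded
inputs:

* eGFR6 and IPV are uniform over their band — the minimal-assumption
  reading of "values generated from these ranges".  A truncated-normal
  alternative (centered at the band midpoint, SD = width/4, truncated to
  the band) is available via `band_mode` for sensitivity analysis.
* C0/D is uniform on [mean − SD, mean + SD] ("within one standard
  deviation of the mean"), truncated to positive values by rejection;
  `c0d_mode="truncated_normal"` substitutes a Normal(mean, SD) truncated
  to (0, mean + 6 SD).  This choice materially affects the
  below-threshold fractions and is deliberately a top-level knob.

"Below threshold" is strict (`y < t`); ties have probability zero under
continuous sampling.  Per-scenario seeds are `base_seed + CRC32(label)`
(mod 2³¹−1), so adding scenarios never perturbs existing ones, and a
shared seed makes paired contrasts exact: with identical seeds the AR=1
draws equal the AR=0 draws minus exactly 10.112.

### Deterministic oracle

`analytic_fraction_below` computes P(y < t) without sampling.  Because
the model is affine, y = const + Σ aᵢXᵢ with independent Xᵢ.  Each
continuous term aᵢXᵢ is discretized into exact cell masses (CDF
differences) on a shared grid (default 4096 cells per term); the masses
are FFT-convolved; the CDF at the threshold is read off with cell-center
placement and midpoint interpolation.  Against closed forms (single
uniform; inclusion–exclusion for three uniforms) the oracle is accurate
to ≲5·10⁻⁴, an order of magnitude below the 3σ binomial band of the
sampler at n = 100,000, which is what it is used to check.

## Synthetic cohort generator

Defaults encode the target cohort structure: 103 patients, 64% male,
expresser fraction 15/103, AR rate 4.9%, DGF 12.6%, once-daily
formulation 25/103, age log-normal matched to median 39 (IQR 31–47),
4–11 troughs per patient uniformly spaced in months 6–12 plus one visit
at month 3.  Per-patient latent mean C0/D is log-normal, moment-matched
to the genotype mean ± SD (log-normality enforces positivity and the
right skew typical of dose-normalized troughs); the per-visit C0/D is
the latent mean times unit-mean log-normal noise whose CV equals the
patient's target IPV, itself drawn from Normal(22.51, 9.71) truncated at
zero.  The daily dose is titrated per patient so the expected trough
sits at the 8 ng/mL monitoring target; C0 is reconstructed as
C0/D × dose.  IPV and C0/D are generated independently (their joint
distribution in real cohorts is not established; a correlation hook can
be added at the latent layer).  AR is independent of all covariates and
its rate is configurable up to 0.5 so AR-stratified tests have power at
small n.

Month-6 eGFR is generated directly (log-normal matched to median 47.48,
IQR 40.32–57.09) because the outcome model consumes eGFR6, not
creatinine; `egfr_mode="creatinine"` instead writes the implied
creatinine (inverse MDRD) into the visit nearest month 6 so the renal
module is exercised end-to-end.  The late outcome is the linear model
evaluated at each patient's *realized* features plus Gaussian noise —
realized, not latent, so that refitting the same specification is
unbiased by construction and confidence-interval coverage is nominal.

The default residual SD is 8.9 mL/min/1.73 m², chosen once by solving
Var(signal)·(1−R²)/R² = σ² for R² ≈ 0.574 under the generator's
covariate distributions; the refit R² at n = 103 then averages ≈0.58
across replicates.

Replicates in which no AR case is drawn (probability ≈0.6% at rate
0.049, n = 103) have a singular design; coverage checks condition on an
estimable design and skip them, which is the standard conditional view
of OLS interval coverage.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: dose-titration dynamics and
dose changes within the window (IPV is computed across whatever doses
occur), adherence behaviour, drug–drug interactions, correlated
covariates, irregular visit schedules, and measurement error in
creatinine.  Tests against this generator validate the *pipeline
mathematics*, not the clinical effect sizes.

## Problem sizes and numerical choices

Unit and property tests run at n ≤ a few thousand draws; oracle-
equivalence and the no-rejection floor checks run the full 32-cell grid
at 100,000 draws per cell (vectorized, a few seconds); coefficient-
recovery coverage uses 500 OLS replicates at n = 103.  All randomness is
`numpy.random.default_rng` seeded explicitly; per-stage seeds in the
pipeline derive from a single base seed and are recorded in the run log,
making full runs byte-reproducible.  Windows are closed intervals on
both ends; degenerate inputs (empty windows, <2 usable visits, zero-
margin tables, singular designs) raise typed errors rather than
returning NaN.

## Known limitations

* The coefficients are treated as fixed in the simulation; estimation
  uncertainty of the model itself is not propagated (scenario inputs
  only).
* The exact sampling distribution behind the original scenario figures
  is not documented; under the uniform reading the below-threshold
  fractions land within a few percentage points of the published values,
  and the uniform/truncated-normal switch brackets the assumption.
* The MDRD calibration constant of the source laboratory is unknown;
  186 is assumed.
* Survival/time-to-event outcomes, AUC-based exposure metrics and
  mixed-effects longitudinal models are out of scope.
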