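# Methods

## Scientific setting

`lcsem` implements the longitudinal analysis used to ask whether a blood
biomarker (serum S100β, a glial calcium-binding protein, μg/L) tracks
brain structural aging across two measurement waves roughly 3–4 years
apart in a narrow-age older cohort. Per participant the data comprise
serum S100β at both waves, volumetric MRI (white matter hyperintensity
volume WMH, total brain TB, gray matter GM, intracranial volume ICV;
cm³), tract-averaged fractional anisotropy (FA) and mean diffusivity (MD)
for 12 white matter tracts per wave, a 5-level visual rating of
perivascular-space (PVS) change, and demographic/vascular covariates.
Because no participant-level data ship with the package, a synthetic
cohort generator with the same statistical structure is a first-class
module: every downstream stage is exercised against data whose true
parameters are known.

## The model family

### Latent change scores

For a construct measured at waves 2 and 3, the latent change score (LCS)
parameterization sets

    y2 = η,      y3 = η + Δ,

with unit loadings and zero measurement residual for single-indicator
constructs, so η is the baseline level and Δ the 3-year change. Level
mean/variance, change mean/variance, and the level–change covariance are
free. With a single indicator and two waves, Δ is essentially a
difference score: the model reproduces `mean(y3 − y2)` and
`var(y3 − y2)` exactly (a unit-test identity).

### General white-matter factors

FA and MD are summarized by latent general factors (gFA, gMD) measured by
7 indicators per wave: genu and splenium of the corpus callosum plus
left–right averages of the anterior thalamic radiation, cingulum,
uncinate, arcuate, and inferior longitudinal fasciculi (12 raw tracts;
averaging of bilateral tracts uses the available side when one is
missing). Identification is by marker variable (genu loading fixed to 1,
intercept to 0 at both waves), leaving the latent wave-2 mean free.
Strong factorial invariance constrains each indicator's loading and
intercept to equality across waves; residual variances are free per wave,
same-indicator residuals covary across waves, and additional tract–tract
residual pairs are configurable (a helper proposes pairs by the largest
standardized residual covariance of a fitted configural model — the
specific pairs used in any given cohort cannot be derived a priori, so
they are a configuration input, default empty).

### Bivariate models and the reported associations

A bivariate LCS model joins the serum construct with one MRI construct
and freely estimates all six covariances among {serum level, serum
change, MRI level, MRI change}. Only covariances (no level→change
regressions) are included, because the reported quantities are
standardized correlations: the level–level ("cross-sectional") and
change–change ("longitudinal") covariances carry reserved labels that the
reporting pipeline standardizes, tests, and bootstrap-brackets. For PVS
only a change rating exists, so the observed rating replaces the latent
MRI change and correlates with the serum level and change directly.

### Covariates and the auxiliary variable

Manifest variables are regressed on exogenous observed covariates: serum
manifests on the age at serum draw of their wave and sex; MRI manifests
on the age at MRI of their wave, sex, and diabetes/hypertension flags.
Covariates get free means, variances and mutual covariances, and point
only at manifests. Because returners have systematically larger baseline
GM (the attrition model below), baseline GM enters every model that does
not already contain it as a saturated-correlates auxiliary variable: it
covaries freely with all exogenous latent variables, all exogenous
observed covariates, and the residuals of indicators with free residual
variance. This leaves all substantive parameters untouched with complete
data (verified to 1e-5 in tests) while letting FIML exploit the
GM–missingness association under MAR.

## Estimation

Models are specified in RAM form (directed-path matrix A, symmetric
covariance S, mean vector M); implied moments are
Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, μ = F(I−A)⁻¹M. The casewise full-information
maximum likelihood sums each case's observed-subvector normal
log-density; pattern grouping is an optimization only and equals the
case-by-case computation exactly. Optimization is L-BFGS-B with an
analytic gradient obtained by accumulating per-pattern derivatives with
respect to (μ, Σ) and chaining through the RAM structure, followed by a
bounded polish stage at tighter tolerance (relative log-likelihood change
1e-14, gradient tolerance 1e-8) so saturated identities and nested
comparisons hold sharply. Start values are deterministic data moments:
exogenous observed moments at their sample values, loadings from marker
regressions, and change-latent moments seeded from marker difference
scores — the last is what keeps the optimizer in the correct basin for
latent-factor change models. Variances are unconstrained (Heywood cases
are allowed but flagged in warnings). Non-PD implied covariances return a
penalized objective value.

Because FA (~0.03 SD), serum (~0.035 SD) and raw volumes (~90 SD) live on
wildly different scales, the pipeline rescales each construct's two waves
by the wave-2 sample SD before fitting (binary covariates keep their
coding). Standardized estimates, χ² and fit indices are invariant to
these affine changes of units; the rescaling exists purely for optimizer
conditioning, and a test verifies χ² invariance under a ×1000 rescaling
of one indicator.

Standard errors come from the observed information (central differences
of the analytic gradient); the two association p-values are two-sided
Wald tests on the unstandardized covariances. The headline inferential
surface is the bias-corrected percentile bootstrap (resample
participants, refit warm-started from the point estimates, drop and count
non-converged replicates): z₀ = Φ⁻¹(fraction of replicate estimates below
the point estimate), interval endpoints at Φ(2z₀ ± z_{(1+conf)/2})
percentiles; 1000 replicates by default (tests use fewer).

### Fit evaluation

The χ² statistic is the likelihood-ratio 2(ℓ_sat − ℓ_model) with
N-scaling. The saturated model is the unstructured MVN MLE on the same
cases — closed-form sample moments with complete data, an EM algorithm
under missingness. The independence baseline (free means/variances, zero
covariances) factorizes casewise, so its FIML MLE is the per-variable
univariate fit. RMSEA uses the (n−1) divisor; CFI/TLI use the
noncentrality forms; SRMR is the RMS of covariance residuals
(diagonal included, means excluded) standardized by the saturated-model
SDs, which keeps it defined under missing data.

## The synthetic cohort generator

The generator mirrors the model family exactly, so parameter recovery is
well-defined: per construct a joint-normal latent (level, change) pair;
wave-3 score = level + change. The default calibration
(`lcsem/calibration/default.yaml`) fixes:

* Serum: wave means 0.085/0.092 μg/L, SDs 0.035/0.040, wave-to-wave
  stability r = 0.585, which imply level variance 0.001225, change
  variance 0.001187, and level–change covariance −0.000406 in closed form.
* WMH: the published summary is a median/IQR, so the log-cm³ latent is
  calibrated lognormally (log-median 2.087, log-SD 0.972 at wave 2); the
  wave-to-wave log stability is not published and is set to 0.8 (WMH
  ranking is highly stable in aging cohorts).
* TB/GM: published means/SDs; 3-year change means −15.0/−6.5 cm³; change
  SDs 20/12 cm³ and level–change correlations −0.2 are design choices in
  the plausible range for 3-year volumetric change in the eighth decade.
* Cross-construct correlations: serum↔MRI level–level and change–change
  correlations are set to the published standardized estimates
  (e.g. serum–gFA level −0.150); MRI↔MRI correlations are set to
  moderate, sign-correct values; cross-construct level↔change
  correlations default to zero but are configurable
  (`level_change_correlations`), which the MAR simulation uses.
* Tract measurement: FA intercepts 0.38–0.55, loadings 0.022–0.032 (≈60%
  reliability), equal loadings/intercepts across waves (so strong
  invariance holds by construction), cross-wave residual correlation 0.6,
  inter-hemisphere residual correlation 0.7 for bilateral tracts.
* Per-tract serum couplings: the published per-tract FA associations
  (anterior thalamic −0.155, cingulum −0.111, splenium/arcuate −0.087)
  exceed or undershoot what a pure factor structure can produce, so each
  configured tract's wave-2 residual is additionally correlated with the
  serum level to hit its target observed correlation exactly. The
  remaining tracts (genu/uncinate/ILF ≈ −0.108) are solved numerically —
  by fitting the factor model to a very large (n = 300,000) generated
  cohort — so that the general-factor model's pseudo-true level
  association equals the calibrated −0.150 despite the per-tract
  heterogeneity.
* Covariate effects are added to manifests mean-centered (age minus wave
  mean, sex minus the male proportion, flags minus prevalence), so
  manifest means remain at the calibrated latent means; effect sizes are
  small and realistic (e.g. sex difference in serum −0.009 μg/L).
* Missingness: wave-3 non-return is Bernoulli with probability
  logistic(−1.37 − 0.35·zGM) (≈20%, returners have more baseline GM);
  each wave's MRI block is additionally missing completely at random at
  rate 0.20; the wave-2 serum value is never removed. Dropout is sampled
  from baseline GM only, so missingness is MAR by construction.
* Artifacts: assay outliers are placed strictly above mean + 4 SD at
  rate 0.008; wave-3 floor values are uniform on [0, 0.02) μg/L at rate
  0.011; an audit log records every injected cell.

### Cohort table column dictionary

One row per participant; missing values are empty cells (NaN). `w ∈ {2, 3}`
indexes the wave.

| column | meaning |
|---|---|
| `participant_id` | integer identifier |
| `sex` | 1 = male, 0 = female |
| `icv` | intracranial volume, cm³ (constant across waves) |
| `age_serum_w`, `age_mri_w` | age in years at serum draw / MRI scan |
| `s100b_w` | serum S100β, μg/L |
| `mmse_w` | Mini-Mental State Examination score, 0–30 |
| `dementia_w`, `melanoma_w` | self-reported diagnosis flags (0/1) |
| `diabetes_w`, `hypertension_w` | vascular risk flags (0/1) |
| `wmh_w`, `tb_w`, `gm_w` | WMH / total brain / gray matter volume, cm³ |
| `fa_<tract>_w`, `md_<tract>_w` | tract-averaged FA (unitless) and MD (10⁻³ mm²/s); `<tract>` ∈ genu, splenium, atr_l/r, cing_l/r, unc_l/r, arc_l/r, ilf_l/r |
| `pvs_change` | visual PVS change rating, −2…+2 (one per participant) |

`preprocess.average_bilateral` adds `fa_<tract>_w` / `md_<tract>_w`
left–right averages (e.g. `fa_atr_2`) for the five bilateral tracts.

What the generator does *not* emulate: non-normal latent distributions,
scanner or batch effects, more than two waves, nonlinear change,
non-ignorable missingness, and the discreteness of real MMSE/PVS beyond
rounding/thresholding. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the assumed model, not
robustness to violations of it.

## Preprocessing rules

Participants with self-reported dementia or MMSE < 24 at either wave are
excluded, then participants reporting melanoma at either wave (melanoma
cells secrete S100β). Serum cells more than 4 SD *above* their wave's
mean are set missing — one-sided, per wave, non-iterative, with the mean
and SD computed once before any removal; wave-3 cells below the 0.02 μg/L
assay sensitivity floor are set missing. Cell-level (not row-level)
removal keeps the participant's other wave usable under FIML. WMH is
natural-log transformed; optionally WMH/TB/GM are divided by ICV before
any transform (the main analysis path; an uncorrected run is a
robustness check). A transform flag makes re-application an error.

## Multiple testing

The association suite collects the level and change p-values of all
converged outcome models into one Benjamini–Hochberg family per suite
(global outcomes and the per-tract suite are corrected separately) at
q = 0.05. `bh_fdr` is backed by statsmodels' step-up implementation and
is tested against a literal brute-force oracle, including the published
worked example in which exactly one of twelve tests survives.

## Problem sizes used in verification

Simulation-based tests use deliberately chosen sizes: 10–25 replicates of
n = 600 for calibrated recovery (Monte-Carlo SE of the replicate mean
≈ 0.01 on a correlation of 0.15), one n = 10,000 cohort for generator
calibration, 150 replicates of n = 400 for the MAR-correction and
FDR-control simulations. The MAR simulation uses a deliberately harsher
attrition scenario (logit slope −1.5 on zGM, with nonzero GM-level ↔
change correlations) than the default calibration, because the mechanism
check needs a bias large enough to measure against Monte-Carlo noise; the
auxiliary-variable correction it demonstrates is the same one the default
pipeline applies.

## Known limitations

* No robust (sandwich) or scaled χ² variants; the PVS rating enters as an
  observed numeric variable, so its Wald test leans on normality it does
  not fully satisfy (the bootstrap interval is the better surface there).
* Two waves only; no proportional-change (dual) extensions, latent growth
  curves, or lead–lag models.
* The optimizer expects construct-scaled data; `scale_for_fit` is applied
  by the pipeline but callers using `Sem` directly on badly mixed scales
  may see slow or premature convergence.
* Numeric parity with any particular SEM package's χ² scaling or
  optimizer is not claimed.
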