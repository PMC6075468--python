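# Default calibration for the two-wave synthetic cohort generator.
#
# Latent level/change moments per construct, cross-construct correlations,
# tract measurement parameters, covariate distributions and effects,
# missingness and artifact-injection rates.  Serum is in ug/L, volumes in
# cm^3 (WMH modelled on the log-cm^3 scale and exponentiated on output),
# FA unitless, MD in 1e-3 mm^2/s, ages in years.
version: 1

constructs:
  s100b:   {baseline_mean: 0.085,   baseline_var: 0.001225, change_mean: 0.007,
            change_var: 0.001187,   level_change_cov: -0.000406}
  gfa:     {baseline_mean: 0.0,     baseline_var: 1.0,      change_mean: -0.15,
            change_var: 0.25,       level_change_cov: -0.1}
  gmd:     {baseline_mean: 0.0,     baseline_var: 1.0,      change_mean: 0.15,
            change_var: 0.25,       level_change_cov: -0.1}
  wmh:     {baseline_mean: 2.087,   baseline_var: 0.9456,   change_mean: 0.3105,
            change_var: 0.3783,     level_change_cov: -0.1885}
  tb:      {baseline_mean: 991.176, baseline_var: 8194.23,  change_mean: -14.997,
            change_var: 400.0,      level_change_cov: -362.09}
  gm:      {baseline_mean: 472.862, baseline_var: 2012.42,  change_mean: -6.541,
            change_var: 144.0,      level_change_cov: -107.66}

# correlations between latent levels (upper-triangle pairs; omitted -> 0)
level_correlations:
  s100b: {gfa: -0.150, gmd: 0.003, wmh: -0.019, gm: 0.061, tb: 0.045}
  gfa:   {gmd: -0.40,  gm: 0.15,  tb: 0.15}
  gmd:   {gm: -0.15,   tb: -0.15}
  wmh:   {gfa: -0.35,  gmd: 0.35, gm: -0.20, tb: -0.20}
  gm:    {tb: 0.75}

# correlations between latent changes
change_correlations:
  s100b: {wmh: 0.082, gfa: -0.083, gmd: -0.019, gm: -0.050, tb: -0.044}
  gfa:   {gmd: -0.30}
  wmh:   {gfa: -0.20, gmd: 0.20}
  gm:    {tb: 0.50}

# per-tract measurement: loading (indicator units per latent SD), intercept,
# residual variance, same-tract cross-wave residual covariance
fa_tracts:
  genu:     {loading: 0.030, intercept: 0.47, residual_var: 0.0005, cross_wave_residual_cov: 0.0003}
  splenium: {loading: 0.028, intercept: 0.55, residual_var: 0.0005, cross_wave_residual_cov: 0.0003}
  atr:      {loading: 0.030, intercept: 0.40, residual_var: 0.0005, cross_wave_residual_cov: 0.0003}
  cing:     {loading: 0.025, intercept: 0.42, residual_var: 0.0005, cross_wave_residual_cov: 0.0003}
  unc:      {loading: 0.027, intercept: 0.38, residual_var: 0.0005, cross_wave_residual_cov: 0.0003}
  arc:      {loading: 0.026, intercept: 0.41, residual_var: 0.0005, cross_wave_residual_cov: 0.0003}
  ilf:      {loading: 0.028, intercept: 0.44, residual_var: 0.0005, cross_wave_residual_cov: 0.0003}
md_tracts:
  genu:     {loading: 0.030, intercept: 0.75, residual_var: 0.0004, cross_wave_residual_cov: 0.00024}
  splenium: {loading: 0.032, intercept: 0.72, residual_var: 0.0004, cross_wave_residual_cov: 0.00024}
  atr:      {loading: 0.026, intercept: 0.70, residual_var: 0.0004, cross_wave_residual_cov: 0.00024}
  cing:     {loading: 0.022, intercept: 0.68, residual_var: 0.0004, cross_wave_residual_cov: 0.00024}
  unc:      {loading: 0.025, intercept: 0.72, residual_var: 0.0004, cross_wave_residual_cov: 0.00024}
  arc:      {loading: 0.024, intercept: 0.69, residual_var: 0.0004, cross_wave_residual_cov: 0.00024}
  ilf:      {loading: 0.026, intercept: 0.71, residual_var: 0.0004, cross_wave_residual_cov: 0.00024}

interhemisphere_corr: 0.7

# target observed wave-2 correlation between the serum level and the
# (left-right averaged) tract indicator; reached by coupling the tract's
# wave-2 residual to the serum latent level on top of the factor path.
# The genu/unc/ilf values are solved so that the strong-invariance
# general-factor model's population-level (pseudo-true) level association
# equals the calibrated latent correlation (-0.150) despite the per-tract
# heterogeneity introduced by the named couplings above.
tract_level_coupling:
  fa: {atr: -0.155, cing: -0.111, splenium: -0.087, arc: -0.087,
       genu: -0.1075, unc: -0.1071, ilf: -0.1085}
  md: {}

covariate_effects:
  s100b: {age: 0.003, sex: -0.009}
  wmh:   {age: 0.05,  sex: 0.05,  diabetes: 0.20,  hypertension: 0.25}
  tb:    {age: -3.0,  sex: 40.0,  diabetes: -5.0,  hypertension: -4.0}
  gm:    {age: -1.5,  sex: 25.0,  diabetes: -3.0,  hypertension: -2.0}
  fa:    {age: -0.002, sex: 0.003, diabetes: -0.004, hypertension: -0.004}
  md:    {age: 0.003,  sex: -0.003, diabetes: 0.005, hypertension: 0.005}

covariate_dists:
  age2_mean: 72.493
  age2_sd: 0.716
  wave_lag_mean: 3.77
  wave_lag_sd: 0.28
  mri_lag2_mean_days: 65.39
  mri_lag2_sd_days: 34.69
  mri_lag3_mean_days: 38.69
  mri_lag3_sd_days: 28.37
  sex_p_male: 0.509
  diabetes_prev: 0.10
  hypertension_prev: 0.40

icv_mean: 1450.0
icv_sd: 130.0

# probabilities over PVS change ratings -2..+2; the cohort exhibits only
# "no change" and "worse"
pvs_change_probs: [0.0, 0.0, 0.910256, 0.089744, 0.0]
pvs_coupling: 0.0

health:
  mmse_mean: 28.8
  mmse_sd: 1.29
  mmse_cross_wave_corr: 0.6
  mmse_tail_rate: 0.01
  dementia_prev: 0.015
  dementia_incidence_w3: 0.01
  melanoma_prev_w2: 0.02
  melanoma_incidence_w3: 0.01

missingness:
  attrition_intercept: -1.37
  attrition_slope_on_gm: -0.35
  scan_missing_rate: 0.20

artifact_injection:
  outlier_rate: 0.008
  outlier_magnitude_sd: 1.0
  floor_rate: 0.011
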