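"""Synthetic cohort generator: calibration, determinism, missingness, artifacts."""

import copy

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lcsem.cohort import (ConfigurationError, default_config, generate_cohort,
                          apply_missingness, inject_artifacts, schema_columns,
                          latent_moments, implied_s100b_stability, TRACTS,
                          MIDLINE_TRACTS)


def test_empty_cohort_has_full_schema():
    cfg = default_config(n_participants=0, seed=1)
    df = generate_cohort(cfg)
    assert len(df) == 0
    assert list(df.columns) == schema_columns()


def test_determinism_same_seed_identical_tables():
    cfg = default_config(n_participants=300, seed=11)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(cfg, seed=12)
    assert not a["s100b_2"].equals(c["s100b_2"])


def test_zero_residual_indicators_are_exact_factor_transforms():
    """With residual variances 0 (and no coupling), every tract indicator is
    an exact affine transform of the latent factor: the factor score
    back-solved from any indicator agrees across indicators to 1e-9."""
    cfg = default_config(n_participants=2000, seed=3)
    for t in cfg.fa_tracts.values():
        t.residual_var = 0.0
        t.cross_wave_residual_cov = 0.0
    cfg.tract_level_coupling = {"fa": {}, "md": {}}
    cfg.covariate_effects = {}
    df = generate_cohort(cfg)
    f_from_genu = (df["fa_genu_2"] - cfg.fa_tracts["genu"].intercept) \
        / cfg.fa_tracts["genu"].loading
    for t in TRACTS:
        col = f"fa_{t}_2" if t in MIDLINE_TRACTS else f"fa_{t}_l_2"
        f = (df[col] - cfg.fa_tracts[t].intercept) / cfg.fa_tracts[t].loading
        assert np.allclose(f, f_from_genu, atol=1e-9)
    # sample mean identity: mean(ind) == intercept + loading * mean(factor)
    assert np.allclose(df["fa_genu_2"].mean(),
                       cfg.fa_tracts["genu"].intercept
                       + cfg.fa_tracts["genu"].loading * f_from_genu.mean(),
                       atol=1e-9)


def test_s100b_calibration_large_sample(big_cohort):
    df = big_cohort
    n = len(df)
    se2 = df["s100b_2"].std() / np.sqrt(n)
    se3 = df["s100b_3"].std() / np.sqrt(n)
    assert abs(df["s100b_2"].mean() - 0.085) < 3 * se2
    assert abs(df["s100b_3"].mean() - 0.092) < 3 * se3
    r = df["s100b_2"].corr(df["s100b_3"])
    cfg = default_config(n_participants=1, seed=0)
    r_implied = implied_s100b_stability(cfg)
    se_r = (1 - r_implied ** 2) / np.sqrt(n)
    assert abs(r - r_implied) < 3 * se_r


def test_latent_covariance_recovery_without_covariate_noise():
    """Manifest single-indicator constructs reproduce the configured latent
    covariance entrywise within Monte-Carlo error (n=50,000)."""
    cfg = default_config(n_participants=50000, seed=19)
    cfg.covariate_effects = {}
    df = generate_cohort(cfg)
    mean, cov = latent_moments(cfg)
    names = [(c, p) for c in ("s100b", "gfa", "gmd", "wmh", "tb", "gm")
             for p in ("lv", "ch")]
    obs = {
        ("s100b", "lv"): df["s100b_2"],
        ("s100b", "ch"): df["s100b_3"] - df["s100b_2"],
        ("wmh", "lv"): np.log(df["wmh_2"]),
        ("wmh", "ch"): np.log(df["wmh_3"]) - np.log(df["wmh_2"]),
        ("tb", "lv"): df["tb_2"], ("tb", "ch"): df["tb_3"] - df["tb_2"],
        ("gm", "lv"): df["gm_2"], ("gm", "ch"): df["gm_3"] - df["gm_2"],
    }
    n = len(df)
    for a, xa in obs.items():
        for b, xb in obs.items():
            i, j = names.index(a), names.index(b)
            target = cov[i, j]
            sample = np.cov(xa, xb, ddof=0)[0, 1]
            mc_se = np.sqrt((cov[i, i] * cov[j, j] + target ** 2) / n)
            assert abs(sample - target) < 4 * mc_se, (a, b)


def test_tract_level_coupling_targets(big_cohort):
    df = big_cohort
    cfg = default_config(n_participants=1, seed=0)
    n = len(df)
    for tract, rho in (("atr", -0.155), ("cing", -0.111)):
        avg = (df[f"fa_{tract}_l_2"] + df[f"fa_{tract}_r_2"]) / 2
        r = np.corrcoef(df["s100b_2"], avg)[0, 1]
        # covariate effects perturb the pure latent target slightly
        assert abs(r - rho) < 3 * (1 - rho ** 2) / np.sqrt(n) + 0.01


def test_missingness_off_leaves_table_unchanged():
    cfg = default_config(n_participants=500, seed=2)
    cfg.missingness = {"attrition_intercept": -np.inf,
                       "attrition_slope_on_gm": 0.0, "scan_missing_rate": 0.0}
    df = generate_cohort(cfg)
    out = apply_missingness(df, cfg)
    pd.testing.assert_frame_equal(df, out)


def test_attrition_depends_on_gm_direction():
    cfg = default_config(n_participants=10000, seed=23)
    df = generate_cohort(cfg)
    out = apply_missingness(df, cfg)
    dropped = out["s100b_3"].isna()
    assert 0.05 < dropped.mean() < 0.5
    assert df.loc[~dropped, "gm_2"].mean() > df.loc[dropped, "gm_2"].mean()


def test_attrition_logit_slope_recovery_and_mar():
    """Logistic regression of dropout on standardized baseline GM recovers
    the configured slope; conditional on GM the (pre-deletion) wave-3 serum
    value carries no information about dropout (MAR by construction)."""
    cfg = default_config(n_participants=10000, seed=29)
    complete = generate_cohort(cfg)
    out = apply_missingness(complete, cfg)
    drop = out["s100b_3"].isna().astype(float).to_numpy()
    z = (complete["gm_2"] - complete["gm_2"].mean()) / complete["gm_2"].std(ddof=0)
    X = sm.add_constant(np.column_stack(
        [z, (complete["s100b_3"] - complete["s100b_3"].mean())
         / complete["s100b_3"].std()]))
    fit = sm.Logit(drop, X).fit(disp=0)
    slope, slope_se = fit.params[1], fit.bse[1]
    assert abs(slope - cfg.missingness["attrition_slope_on_gm"]) < 3 * slope_se
    assert abs(fit.params[2]) < 3 * fit.bse[2]


def test_wave2_serum_never_removed():
    cfg = default_config(n_participants=2000, seed=31)
    cfg.missingness["scan_missing_rate"] = 0.5
    out = apply_missingness(generate_cohort(cfg), cfg)
    assert out["s100b_2"].notna().all()


def test_artifacts_zero_rates_noop():
    cfg = default_config(n_participants=400, seed=5)
    cfg.artifact_injection = {"outlier_rate": 0.0, "floor_rate": 0.0,
                              "outlier_magnitude_sd": 1.0}
    df = generate_cohort(cfg)
    out, audit = inject_artifacts(df, cfg)
    assert audit == []
    pd.testing.assert_frame_equal(df, out)


def test_artifact_construction_and_audit():
    cfg = default_config(n_participants=3000, seed=13)
    cfg.artifact_injection = {"outlier_rate": 0.01, "floor_rate": 0.01,
                              "outlier_magnitude_sd": 1.0}
    df = generate_cohort(cfg)
    out, audit = inject_artifacts(df, cfg)
    outliers = [a for a in audit if a["rule"] == "outlier"]
    floors = [a for a in audit if a["rule"] == "floor"]
    assert outliers and floors
    for a in outliers:
        col = f"s100b_{a['wave']}"
        clean = df[col]
        assert a["injected"] > clean.mean() + 4 * clean.std(ddof=0)
        assert out.loc[out["participant_id"] == a["participant_id"],
                       col].iloc[0] == pytest.approx(a["injected"])
    for a in floors:
        assert 0.0 <= a["injected"] < 0.02
    # cells not in the audit are untouched
    touched = {(a["participant_id"], a["wave"]) for a in audit}
    for w in (2, 3):
        ids = ~df["participant_id"].isin([p for p, ww in touched if ww == w])
        pd.testing.assert_series_equal(df.loc[ids, f"s100b_{w}"],
                                       out.loc[ids, f"s100b_{w}"])


def test_pvs_distribution_and_coupling():
    cfg = default_config(n_participants=20000, seed=37)
    df = generate_cohort(cfg)
    counts = df["pvs_change"].value_counts(normalize=True)
    assert set(counts.index) <= {0.0, 1.0}
    assert counts[1.0] == pytest.approx(0.0897, abs=0.01)
    cfg2 = copy.deepcopy(cfg)
    cfg2.pvs_coupling = -0.5
    df2 = generate_cohort(cfg2)
    d = df2["s100b_3"] - df2["s100b_2"]
    assert np.corrcoef(d, df2["pvs_change"])[0, 1] < -0.05


@pytest.mark.parametrize("mutate, match", [
    (lambda c: c.constructs["gfa"].__setattr__("baseline_var", -1.0), "negative variance"),
    (lambda c: c.__setattr__("pvs_change_probs", (0.5, 0.5, 0.5, 0, 0)), "summing to 1"),
    (lambda c: c.missingness.__setitem__("scan_missing_rate", 1.5), "outside"),
    (lambda c: c.artifact_injection.__setitem__("outlier_rate", -0.1), "outside"),
    (lambda c: c.level_correlations.update(
        {"gm": {"tb": 0.99}, "gfa": {"gm": 0.9, "tb": -0.9}}), "positive semidefinite"),
])
def test_configuration_errors(mutate, match):
    cfg = default_config(n_participants=10, seed=1)
    mutate(cfg)
    with pytest.raises(ConfigurationError, match=match):
        cfg.validate()


def test_config_yaml_round_trip(tmp_path):
    from lcsem.cohort import GeneratorConfig, load_config
    cfg = default_config(n_participants=50, seed=9)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    back = load_config(str(p))
    assert back.to_dict() == cfg.to_dict()
    pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(back))
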