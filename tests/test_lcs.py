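"""LCS model builders: identities, hand-enumerated counts, recovery."""

import copy

import numpy as np
import pandas as pd
import pytest

from lcsem.cohort import default_config, generate_cohort
from lcsem.preprocess import average_bilateral
from lcsem.model import Sem
from lcsem.pipeline import scale_for_fit, build_outcome_model
from lcsem.ram import SpecificationError
from lcsem.lcs import (ChangeScoreSpec, LEVEL_ASSOC, CHANGE_ASSOC,
                       build_univariate_lcs, build_latent_factor_lcs,
                       build_bivariate_lcs, build_pvs_variant,
                       add_covariates, add_auxiliary, propose_residual_pairs)


def _uni(name="y"):
    return ChangeScoreSpec(name, {name: (f"{name}_2", f"{name}_3")})


def _factor(name="g", keys=("genu", "splenium", "atr"), metric="fa", **kw):
    return ChangeScoreSpec(name, {k: (f"{metric}_{k}_2", f"{metric}_{k}_3")
                                  for k in keys}, **kw)


def test_difference_score_identity(rng):
    lv = rng.normal(10.0, 2.0, 700)
    d = rng.normal(-0.5, 1.0, 700) - 0.3 * (lv - 10)
    df = pd.DataFrame({"y_2": lv, "y_3": lv + d})
    res = Sem(build_univariate_lcs(_uni()), df).fit()
    diff = df["y_3"] - df["y_2"]
    assert res.params["y_ch_mean"] == pytest.approx(diff.mean(), abs=1e-6)
    assert res.params["y_ch_var"] == pytest.approx(diff.var(ddof=0), abs=1e-6)
    assert res.params["y_lv_mean"] == pytest.approx(df["y_2"].mean(), abs=1e-6)
    assert res.params["y_lv_var"] == pytest.approx(df["y_2"].var(ddof=0), abs=1e-6)


def test_calibrated_serum_change_mean_recovery(big_cohort):
    """The generator's serum increase (0.092 - 0.085) is recovered by the
    univariate change score model at large n."""
    spec = ChangeScoreSpec("s100b", {"s100b": ("s100b_2", "s100b_3")})
    res = Sem(build_univariate_lcs(spec), big_cohort).fit()
    se = res.bse["s100b_ch_mean"]
    assert abs(res.params["s100b_ch_mean"] - 0.007) < 3 * se


def test_bivariate_free_parameter_count_is_14():
    ps = build_bivariate_lcs(_uni("a"), _uni("b"))
    # 4 means + 4 variances + 6 covariances, per the path-diagram hand count
    assert ps.compile().npar == 14
    labels = ps.free_labels()
    assert LEVEL_ASSOC in labels and CHANGE_ASSOC in labels


def test_bivariate_rejects_shared_variables():
    with pytest.raises(SpecificationError, match="share variable"):
        build_bivariate_lcs(_uni("a"), _uni("a"))


def test_latent_factor_df_hand_enumeration(small_cohort):
    """7 indicators/wave: 14 observed -> 119 moments; strong invariance
    gives 6 loadings + 6 intercepts + 14 residual vars + 7 cross-wave
    residual covs + 3 latent (co)variances + 2 latent means = 38 free;
    df = 81."""
    keys = ("genu", "splenium", "atr", "cing", "unc", "arc", "ilf")
    ps = build_latent_factor_lcs(_factor(keys=keys))
    m = Sem(ps, small_cohort)
    assert m.npar == 38
    assert m.df_model == 14 * 17 // 2 - 38 == 81


def test_configural_nests_strong_invariance(small_cohort):
    """The strong-invariance model can never beat the configural model in
    likelihood; breaking invariance in the data produces a large positive
    LR difference with df equal to the number of tied parameters."""
    keys = ("genu", "splenium", "atr")
    strong = build_latent_factor_lcs(_factor(keys=keys))
    config = build_latent_factor_lcs(_factor(keys=keys, invariance="configural"))
    df = small_cohort[strong.observed].copy()
    groups = [[f"fa_{k}_2", f"fa_{k}_3"] for k in keys]
    d, _ = scale_for_fit(df, strong.observed, groups)
    rs = Sem(strong, d).fit(compute_se=False)
    rc = Sem(config, d).fit(compute_se=False)
    # on-model data: tiny LR difference, correct df gap (2 loadings + 2 ints)
    lr = rs.chi2 - rc.chi2
    assert rc.df == rs.df - 4
    assert -1e-3 < lr < 25.0
    # break invariance: rescale one non-marker indicator at wave 3 only
    d2 = d.copy()
    d2["fa_splenium_3"] = d2["fa_splenium_3"] * 1.5
    rs2 = Sem(strong, d2).fit(compute_se=False)
    rc2 = Sem(config, d2).fit(compute_se=False)
    assert rs2.chi2 - rc2.chi2 > 100.0


def test_extra_residual_pairs_and_proposer(small_cohort):
    keys = ("genu", "splenium", "atr", "cing")
    base = build_latent_factor_lcs(_factor(keys=keys))
    groups = [[f"fa_{k}_2", f"fa_{k}_3"] for k in keys]
    df, _ = scale_for_fit(small_cohort[base.observed], base.observed, groups)
    res = Sem(base, df).fit(compute_se=False)
    pairs = propose_residual_pairs(res, _factor(keys=keys), k=3)
    assert len(pairs) == 3
    assert all(p[0][0] != p[1][0] for p in pairs)
    augmented = build_latent_factor_lcs(_factor(keys=keys,
                                                extra_residual_pairs=pairs))
    assert augmented.compile().npar == base.compile().npar + 3
    r2 = Sem(augmented, df).fit(compute_se=False)
    assert r2.chi2 <= res.chi2 + 1e-6
    with pytest.raises(SpecificationError, match="unknown indicator"):
        _factor(keys=keys, extra_residual_pairs=[(("nope", 2), ("genu", 3))])


def test_pvs_variant_structure_and_null_recovery():
    cfg = default_config(n_participants=4000, seed=61)
    df = generate_cohort(cfg)  # pvs independent of serum by default
    ps = build_pvs_variant(_uni("s100b").__class__(
        "s100b", {"s100b": ("s100b_2", "s100b_3")}), "pvs_change")
    assert LEVEL_ASSOC in ps.free_labels() and CHANGE_ASSOC in ps.free_labels()
    groups = [["s100b_2", "s100b_3"], ["pvs_change"]]
    d, _ = scale_for_fit(df, ps.observed, groups)
    res = Sem(ps, d).fit()
    for lab in (LEVEL_ASSOC, CHANGE_ASSOC):
        assert abs(res.standardized[lab]) < 3 / np.sqrt(len(df))
    with pytest.raises(SpecificationError):
        build_pvs_variant(ChangeScoreSpec(
            "s100b", {"s100b": ("s100b_2", "s100b_3")}), "")


def test_pvs_coupling_recovered_in_sign_and_bounded():
    cfg = default_config(n_participants=6000, seed=67)
    cfg.pvs_coupling = -0.4
    df = generate_cohort(cfg)
    ps = build_pvs_variant(ChangeScoreSpec(
        "s100b", {"s100b": ("s100b_2", "s100b_3")}), "pvs_change")
    d, _ = scale_for_fit(df, ps.observed,
                         [["s100b_2", "s100b_3"], ["pvs_change"]])
    res = Sem(ps, d).fit()
    est = res.standardized[CHANGE_ASSOC]
    se = 1 / np.sqrt(len(df))
    assert est < -3 * se                      # clearly negative
    assert abs(est) < 0.4 + 3 * se            # thresholding only attenuates


def test_add_covariates_unknown_manifest_errors():
    ps = build_univariate_lcs(_uni())
    with pytest.raises(SpecificationError, match="unknown manifest"):
        add_covariates(ps, {"nope": ["sex"]})


def test_covariate_adjustment_removes_confounding():
    """A shared age effect on serum and tract FA biases the unadjusted
    level association; covariate adjustment recovers the latent truth."""
    cfg = default_config(n_participants=4000, seed=71)
    cfg.covariate_effects = {"s100b": {"age": 0.02}, "fa": {"age": -0.015}}
    df = average_bilateral(generate_cohort(cfg))
    truth = cfg.tract_level_coupling["fa"]["atr"]
    ps_adj, groups = build_outcome_model("tract:atr:fa", covariates=True,
                                         auxiliary=None)
    d, _ = scale_for_fit(df, ps_adj.observed, groups)
    adj = Sem(ps_adj, d).fit(compute_se=False).standardized[LEVEL_ASSOC]
    ps_raw, groups_raw = build_outcome_model("tract:atr:fa", covariates=False,
                                             auxiliary=None)
    d2, _ = scale_for_fit(df, ps_raw.observed, groups_raw)
    raw = Sem(ps_raw, d2).fit(compute_se=False).standardized[LEVEL_ASSOC]
    se = 1 / np.sqrt(len(df))
    assert abs(adj - truth) < 4 * se
    assert abs(raw - truth) > abs(adj - truth)
    assert raw < truth  # negative confounding pushes it further negative


def test_auxiliary_no_missingness_invariance(small_cohort):
    """With complete data the saturated-correlates auxiliary leaves every
    substantive estimate unchanged (within numerical tolerance)."""
    ps, groups = build_outcome_model("wmh", covariates=False, auxiliary=None)
    from lcsem.preprocess import transform_mri
    df = transform_mri(small_cohort, icv_correct=True)
    d, _ = scale_for_fit(df, ps.observed + ["gm_2"], groups + [["gm_2"]])
    r0 = Sem(ps, d).fit(compute_se=False, compute_fit_indices=False)
    ps_aux = add_auxiliary(ps, "gm_2")
    r1 = Sem(ps_aux, d).fit(compute_se=False, compute_fit_indices=False)
    for lab in ps.free_labels():
        assert r1.params[lab] == pytest.approx(r0.params[lab], abs=1e-5)
    with pytest.raises(SpecificationError, match="already in model"):
        add_auxiliary(ps_aux, "gm_2")


def test_auxiliary_df_bookkeeping():
    """Adding the auxiliary adds 13 moments and 13 parameters to the
    covariate-adjusted single-construct model, leaving df unchanged."""
    ps, _ = build_outcome_model("wmh", covariates=True, auxiliary=None)
    ps_aux = add_auxiliary(ps, "gm_2")
    p0, p1 = len(ps.observed), len(ps_aux.observed)
    m0 = p0 * (p0 + 3) // 2
    m1 = p1 * (p1 + 3) // 2
    added_par = ps_aux.compile().npar - ps.compile().npar
    assert added_par == m1 - m0 == 13


def test_builder_round_trips_through_serialization(small_cohort):
    from lcsem.ram import PathSpec
    for ps, _ in (build_outcome_model("gfa", covariates=False, auxiliary=None),
                  build_outcome_model("wmh", covariates=True, auxiliary="gm_2"),
                  build_outcome_model("pvs", covariates=True, auxiliary="gm_2")):
        back = PathSpec.from_json(ps.to_json())
        assert back.to_dict() == ps.to_dict()


def test_single_indicator_bivariate_equals_pearson(small_cohort):
    """Without covariates, the standardized level-level estimate equals the
    Pearson correlation of the wave-2 observations."""
    ps, groups = build_outcome_model("tract:cing:fa", covariates=False,
                                     auxiliary=None)
    d, _ = scale_for_fit(small_cohort, ps.observed, groups)
    res = Sem(ps, d).fit(compute_se=False)
    r = np.corrcoef(small_cohort["s100b_2"], small_cohort["fa_cing_2"])[0, 1]
    assert res.standardized[LEVEL_ASSOC] == pytest.approx(r, abs=0.01)
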