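"""Two-wave synthetic cohort generation.

The generator emulates a longitudinal aging-cohort design: serum S100β
(μg/L) sampled at two waves three to four years apart, volumetric MRI
(WMH, total brain, gray matter, ICV; cm³), tract-averaged FA and MD for 12
white matter tracts per wave, a 5-level visual rating of perivascular-space
change, demographics and vascular-risk flags, GM-dependent attrition, and
assay artifacts (extreme outliers and values at the assay floor).

The generative model matches the analysis model family: per construct a
joint-normal latent (level, change) pair, wave-2 score = level, wave-3
score = level + change; tract indicators load on general white-matter
factors (gFA, gMD) with per-tract intercepts/loadings shared across waves,
cross-wave correlated residuals, and an inter-hemisphere residual
correlation for bilateral tracts.  Covariate effects are added to the
manifest variables mean-centered, so manifest means stay at the calibrated
latent means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "CONSTRUCTS", "TRACTS", "BILATERAL_TRACTS", "MIDLINE_TRACTS", "RAW_TRACTS",
    "ConfigurationError", "LatentSpec", "TractSpec", "GeneratorConfig",
    "default_config", "load_config", "generate_cohort", "apply_missingness",
    "inject_artifacts", "schema_columns", "latent_moments",
    "implied_s100b_stability",
]

CONSTRUCTS = ("s100b", "gfa", "gmd", "wmh", "tb", "gm")
MIDLINE_TRACTS = ("genu", "splenium")
BILATERAL_TRACTS = ("atr", "cing", "unc", "arc", "ilf")
TRACTS = MIDLINE_TRACTS + BILATERAL_TRACTS
#: raw per-hemisphere tract keys as stored in the cohort table
RAW_TRACTS = MIDLINE_TRACTS + tuple(
    f"{t}_{s}" for t in BILATERAL_TRACTS for s in ("l", "r"))
ASSAY_FLOOR = 0.02  # μg/L, assay sensitivity threshold


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class LatentSpec:
    """Joint-normal latent (level, change) moments for one construct."""
    baseline_mean: float
    baseline_var: float
    change_mean: float
    change_var: float
    level_change_cov: float

    def validate(self, name: str) -> None:
        if self.baseline_var < 0 or self.change_var < 0:
            raise ConfigurationError(f"negative variance in construct {name!r}")
        block = np.array([[self.baseline_var, self.level_change_cov],
                          [self.level_change_cov, self.change_var]])
        if np.linalg.eigvalsh(block).min() < -1e-12:
            raise ConfigurationError(
                f"level/change covariance of construct {name!r} is not PSD")


@dataclass
class TractSpec:
    """Measurement parameters for one tract indicator (shared across sides)."""
    loading: float
    intercept: float
    residual_var: float
    cross_wave_residual_cov: float

    def validate(self, name: str) -> None:
        if self.residual_var < 0:
            raise ConfigurationError(f"negative residual variance for tract {name!r}")
        if abs(self.cross_wave_residual_cov) > self.residual_var + 1e-15:
            raise ConfigurationError(
                f"cross-wave residual covariance exceeds residual variance "
                f"for tract {name!r}")


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_participants: int
    seed: int = 0
    constructs: dict = field(default_factory=dict)        # name -> LatentSpec
    level_correlations: dict = field(default_factory=dict)
    change_correlations: dict = field(default_factory=dict)
    #: corr(level of A, change of B) across constructs: {A: {B: rho}}
    level_change_correlations: dict = field(default_factory=dict)
    fa_tracts: dict = field(default_factory=dict)          # tract -> TractSpec
    md_tracts: dict = field(default_factory=dict)
    interhemisphere_corr: float = 0.7
    tract_level_coupling: dict = field(default_factory=lambda: {"fa": {}, "md": {}})
    covariate_effects: dict = field(default_factory=dict)
    covariate_dists: dict = field(default_factory=dict)
    icv_mean: float = 1450.0
    icv_sd: float = 130.0
    pvs_change_probs: tuple = (0.0, 0.0, 1.0, 0.0, 0.0)
    pvs_coupling: float = 0.0
    health: dict = field(default_factory=dict)
    missingness: dict = field(default_factory=dict)
    artifact_injection: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        for name, c in self.constructs.items():
            c.validate(name)
        for name, t in {**self.fa_tracts, **self.md_tracts}.items():
            t.validate(name)
        p = np.asarray(self.pvs_change_probs, float)
        if p.size != 5 or (p < 0).any() or (p > 1).any() or abs(p.sum() - 1) > 1e-9:
            raise ConfigurationError(
                "pvs_change_probs must be 5 probabilities summing to 1")
        if not -1 < self.interhemisphere_corr < 1:
            raise ConfigurationError("interhemisphere_corr must be in (-1, 1)")
        if not -1 <= self.pvs_coupling <= 1:
            raise ConfigurationError("pvs_coupling must be in [-1, 1]")
        for key in ("scan_missing_rate",):
            v = self.missingness.get(key, 0.0)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"missingness rate {key}={v} outside [0, 1]")
        for key in ("outlier_rate", "floor_rate"):
            v = self.artifact_injection.get(key, 0.0)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"artifact rate {key}={v} outside [0, 1]")
        R = latent_moments(self)[1]
        sd = np.sqrt(np.diag(R))
        corr = R / np.outer(sd, sd)
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError(
                "cross_construct covariance (latent level/change block) is not "
                "positive semidefinite")

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pvs_change_probs"] = list(self.pvs_change_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d.pop("version", None)
        d["constructs"] = {k: LatentSpec(**v) for k, v in d.get("constructs", {}).items()}
        d["fa_tracts"] = {k: TractSpec(**v) for k, v in d.get("fa_tracts", {}).items()}
        d["md_tracts"] = {k: TractSpec(**v) for k, v in d.get("md_tracts", {}).items()}
        d["pvs_change_probs"] = tuple(d.get("pvs_change_probs", (0, 0, 1, 0, 0)))
        d.setdefault("n_participants", 0)
        d["interhemisphere_corr"] = d.pop("interhemisphere_corr",
                                          d.pop("interhemi_corr", 0.7))
        return cls(**d)

    def to_yaml(self, path=None):
        s = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return s
        with open(path, "w") as fh:
            fh.write(s)


def load_config(path: str, n_participants: int | None = None,
                seed: int | None = None) -> GeneratorConfig:
    """Load a generator configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    cfg = GeneratorConfig.from_dict(d)
    if n_participants is not None:
        cfg.n_participants = n_participants
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    return cfg


def default_config(n_participants: int = 600, seed: int = 0) -> GeneratorConfig:
    """The shipped default calibration (two-wave aging cohort)."""
    text = importlib.resources.files("lcsem").joinpath(
        "calibration/default.yaml").read_text()
    cfg = GeneratorConfig.from_dict(yaml.safe_load(text))
    cfg.n_participants = n_participants
    cfg.seed = seed
    cfg.validate()
    return cfg


# --------------------------------------------------------------------- moments
def _latent_index():
    return [(c, p) for c in CONSTRUCTS for p in ("lv", "ch")]


def latent_moments(config: GeneratorConfig):
    """Mean vector and covariance of the 12 latent (level, change) variables,
    ordered (construct, lv/ch) over s100b, gfa, gmd, wmh, tb, gm."""
    idx = _latent_index()
    n = len(idx)
    mean = np.empty(n)
    sd = np.empty(n)
    for k, (c, p) in enumerate(idx):
        spec = config.constructs[c]
        mean[k] = spec.baseline_mean if p == "lv" else spec.change_mean
        sd[k] = np.sqrt(spec.baseline_var if p == "lv" else spec.change_var)

    def corr_lookup(table, a, b):
        return table.get(a, {}).get(b, table.get(b, {}).get(a, 0.0))

    C = np.eye(n)
    for i, (ci, pi) in enumerate(idx):
        for j in range(i + 1, n):
            cj, pj = idx[j]
            if ci == cj:
                spec = config.constructs[ci]
                denom = np.sqrt(spec.baseline_var * spec.change_var)
                r = spec.level_change_cov / denom if denom > 0 else 0.0
            elif pi == "lv" and pj == "lv":
                r = corr_lookup(config.level_correlations, ci, cj)
            elif pi == "ch" and pj == "ch":
                r = corr_lookup(config.change_correlations, ci, cj)
            elif pi == "lv":   # level of ci with change of cj
                r = config.level_change_correlations.get(ci, {}).get(cj, 0.0)
            else:              # change of ci with level of cj
                r = config.level_change_correlations.get(cj, {}).get(ci, 0.0)
            C[i, j] = C[j, i] = r
    cov = C * np.outer(sd, sd)
    return mean, cov


def implied_s100b_stability(config: GeneratorConfig) -> float:
    """Closed-form manifest Pearson correlation between the two serum waves,
    including the variance contributed by the (centered) covariate effects."""
    s = config.constructs["s100b"]
    cov = s.baseline_var + s.level_change_cov
    v2 = s.baseline_var
    v3 = s.baseline_var + s.change_var + 2 * s.level_change_cov
    eff = config.covariate_effects.get("s100b", {})
    cd = config.covariate_dists
    b_age = eff.get("age", 0.0)
    b_sex = eff.get("sex", 0.0)
    va2 = cd.get("age2_sd", 0.0) ** 2
    vlag = cd.get("wave_lag_sd", 0.0) ** 2
    p = cd.get("sex_p_male", 0.5)
    vsex = p * (1 - p)
    # age3 = age2 + lag, so cov(age2, age3) = var(age2); sex is shared
    cov += b_age ** 2 * va2 + b_sex ** 2 * vsex
    v2 += b_age ** 2 * va2 + b_sex ** 2 * vsex
    v3 += b_age ** 2 * (va2 + vlag) + b_sex ** 2 * vsex
    return float(cov / np.sqrt(v2 * v3))


# ---------------------------------------------------------------------- schema
def schema_columns() -> list[str]:
    cols = ["participant_id", "sex", "icv", "pvs_change"]
    for w in (2, 3):
        cols += [f"age_serum_{w}", f"age_mri_{w}", f"s100b_{w}", f"mmse_{w}",
                 f"dementia_{w}", f"melanoma_{w}", f"diabetes_{w}",
                 f"hypertension_{w}", f"wmh_{w}", f"tb_{w}", f"gm_{w}"]
        cols += [f"fa_{t}_{w}" for t in RAW_TRACTS]
        cols += [f"md_{t}_{w}" for t in RAW_TRACTS]
    return cols


def _residual_block_order():
    """Residual dimensions per metric: for each tract, its per-side wave-2
    dims then wave-3 dims (midline: [w2, w3]; bilateral: [L2, R2, L3, R3])."""
    order = []
    for t in TRACTS:
        sides = ("",) if t in MIDLINE_TRACTS else ("l", "r")
        for w in (2, 3):
            for s in sides:
                order.append((t, s, w))
    return order


def _metric_residual_cov(config, tracts: dict):
    """Covariance of the stacked residual vector for one metric."""
    order = _residual_block_order()
    n = len(order)
    V = np.zeros((n, n))
    rho = config.interhemisphere_corr
    pos = {k: i for i, k in enumerate(order)}
    for t in TRACTS:
        spec = tracts[t]
        s2, c = spec.residual_var, spec.cross_wave_residual_cov
        sides = ("",) if t in MIDLINE_TRACTS else ("l", "r")
        for w1 in (2, 3):
            for w2 in (2, 3):
                base = s2 if w1 == w2 else c
                for a in sides:
                    for b in sides:
                        f = 1.0 if a == b else rho
                        V[pos[(t, a, w1)], pos[(t, b, w2)]] = base * f
    return order, V


def _coupling_vector(config, metric: str, order, tracts: dict):
    """Covariance of each residual dim with the serum latent level, chosen so
    configured tracts hit their target observed wave-2 correlation."""
    targets = config.tract_level_coupling.get(metric, {})
    s = config.constructs["s100b"]
    sigma_s = np.sqrt(s.baseline_var)
    factor = {"fa": "gfa", "md": "gmd"}[metric]
    f = config.constructs[factor]
    sigma_f = np.sqrt(f.baseline_var)
    r_sf = config.level_correlations.get("s100b", {}).get(
        factor, config.level_correlations.get(factor, {}).get("s100b", 0.0))
    cov_sf = r_sf * sigma_s * sigma_f
    rho = config.interhemisphere_corr
    out = np.zeros(len(order))
    for t, rho_t in targets.items():
        spec = tracts[t]
        lam = spec.loading
        if t in MIDLINE_TRACTS:
            var_bar = spec.residual_var
        else:
            var_bar = spec.residual_var * (1 + rho) / 2.0
        var_x = lam ** 2 * f.baseline_var + var_bar
        c_e = rho_t * sigma_s * np.sqrt(var_x) - lam * cov_sf
        for k, (tt, side, w) in enumerate(order):
            if tt == t and w == 2:
                out[k] = c_e
    return out


def _joint_draw(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """One Cholesky draw of [latents, FA residuals, MD residuals]."""
    mean_l, cov_l = latent_moments(config)
    idx = _latent_index()
    s_lv_pos = idx.index(("s100b", "lv"))
    order_fa, V_fa = _metric_residual_cov(config, config.fa_tracts)
    order_md, V_md = _metric_residual_cov(config, config.md_tracts)
    k_l, k_f, k_m = len(idx), len(order_fa), len(order_md)
    dim = k_l + k_f + k_m
    cov = np.zeros((dim, dim))
    cov[:k_l, :k_l] = cov_l
    cov[k_l:k_l + k_f, k_l:k_l + k_f] = V_fa
    cov[k_l + k_f:, k_l + k_f:] = V_md
    c_fa = _coupling_vector(config, "fa", order_fa, config.fa_tracts)
    c_md = _coupling_vector(config, "md", order_md, config.md_tracts)
    cov[s_lv_pos, k_l:k_l + k_f] = c_fa
    cov[k_l:k_l + k_f, s_lv_pos] = c_fa
    cov[s_lv_pos, k_l + k_f:] = c_md
    cov[k_l + k_f:, s_lv_pos] = c_md
    mean = np.concatenate([mean_l, np.zeros(k_f + k_m)])
    ev = np.linalg.eigvalsh(cov)
    if ev.min() < -1e-8 * max(ev.max(), 1.0):
        raise ConfigurationError(
            "joint latent/residual covariance is not PSD; check the "
            "tract_level_coupling block against the residual variances")
    # dims with exactly zero variance (e.g. residual_var = 0) stay at their
    # mean; factorize only the positive-variance block so no jitter leaks
    pos = np.diag(cov) > 0
    sub = cov[np.ix_(pos, pos)]
    try:
        L = np.linalg.cholesky(sub)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(sub + 1e-10 * np.mean(np.diag(sub))
                               * np.eye(sub.shape[0]))
    Z = rng.standard_normal((n, int(pos.sum())))
    draws = np.tile(mean, (n, 1))
    draws[:, pos] += Z @ L.T
    return draws, idx, order_fa, order_md, k_l, k_f


def _truncnorm(rng, mean, sd, n, nsd=3.0):
    x = rng.normal(mean, sd, size=n)
    return np.clip(x, mean - nsd * sd, mean + nsd * sd)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a complete (pre-missingness) cohort table.

    Deterministic given the configuration and seed (``config.seed`` unless
    overridden).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    cols = schema_columns()
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    cd = config.covariate_dists
    p_male = cd.get("sex_p_male", 0.5)
    sex = (rng.random(n) < p_male).astype(float)
    age2 = _truncnorm(rng, cd.get("age2_mean", 72.5), cd.get("age2_sd", 0.7), n)
    lag = _truncnorm(rng, cd.get("wave_lag_mean", 3.77), cd.get("wave_lag_sd", 0.28), n)
    age3 = age2 + lag
    mri_lag2 = _truncnorm(rng, cd.get("mri_lag2_mean_days", 65.0),
                          cd.get("mri_lag2_sd_days", 35.0), n) / 365.25
    mri_lag3 = _truncnorm(rng, cd.get("mri_lag3_mean_days", 39.0),
                          cd.get("mri_lag3_sd_days", 28.0), n) / 365.25
    age_mri2 = age2 + np.abs(mri_lag2)
    age_mri3 = age3 + np.abs(mri_lag3)
    diabetes = (rng.random(n) < cd.get("diabetes_prev", 0.1)).astype(float)
    hypertension = (rng.random(n) < cd.get("hypertension_prev", 0.4)).astype(float)
    icv = np.maximum(rng.normal(config.icv_mean, config.icv_sd, n), 800.0)

    h = config.health
    mmse_mu, mmse_sd = h.get("mmse_mean", 28.8), h.get("mmse_sd", 1.29)
    r_mmse = h.get("mmse_cross_wave_corr", 0.6)
    z1 = rng.standard_normal(n)
    z2 = r_mmse * z1 + np.sqrt(1 - r_mmse ** 2) * rng.standard_normal(n)
    mmse2 = np.clip(np.rint(mmse_mu + mmse_sd * z1), 0, 30)
    mmse3 = np.clip(np.rint(mmse_mu + mmse_sd * z2), 0, 30)
    tail = rng.random(n) < h.get("mmse_tail_rate", 0.0)
    mmse2[tail] = rng.integers(20, 26, size=int(tail.sum()))
    dementia2 = (rng.random(n) < h.get("dementia_prev", 0.0)).astype(float)
    dementia3 = np.maximum(
        dementia2, (rng.random(n) < h.get("dementia_incidence_w3", 0.0)).astype(float))
    melanoma2 = (rng.random(n) < h.get("melanoma_prev_w2", 0.0)).astype(float)
    melanoma3 = np.maximum(
        melanoma2, (rng.random(n) < h.get("melanoma_incidence_w3", 0.0)).astype(float))

    draws, idx, order_fa, order_md, k_l, k_f = _joint_draw(config, n, rng)
    lat = {key: draws[:, i] for i, key in enumerate(idx)}
    res_fa = {key: draws[:, k_l + i] for i, key in enumerate(order_fa)}
    res_md = {key: draws[:, k_l + k_f + i] for i, key in enumerate(order_md)}

    eff = config.covariate_effects
    sex_c = sex - p_male
    diab_c = diabetes - cd.get("diabetes_prev", 0.1)
    hyp_c = hypertension - cd.get("hypertension_prev", 0.4)
    age2_c = age2 - cd.get("age2_mean", 72.5)
    age3_c = age3 - (cd.get("age2_mean", 72.5) + cd.get("wave_lag_mean", 3.77))
    agem2_c = age_mri2 - (cd.get("age2_mean", 72.5)
                          + cd.get("mri_lag2_mean_days", 65.0) / 365.25)
    agem3_c = age_mri3 - (cd.get("age2_mean", 72.5) + cd.get("wave_lag_mean", 3.77)
                          + cd.get("mri_lag3_mean_days", 39.0) / 365.25)

    def manifest_effect(group, age_c):
        e = eff.get(group, {})
        return (e.get("age", 0.0) * age_c + e.get("sex", 0.0) * sex_c
                + e.get("diabetes", 0.0) * diab_c
                + e.get("hypertension", 0.0) * hyp_c)

    out = {
        "participant_id": np.arange(1, n + 1),
        "sex": sex, "icv": icv,
        "age_serum_2": age2, "age_serum_3": age3,
        "age_mri_2": age_mri2, "age_mri_3": age_mri3,
        "mmse_2": mmse2, "mmse_3": mmse3,
        "dementia_2": dementia2, "dementia_3": dementia3,
        "melanoma_2": melanoma2, "melanoma_3": melanoma3,
        "diabetes_2": diabetes, "diabetes_3": diabetes.copy(),
        "hypertension_2": hypertension, "hypertension_3": hypertension.copy(),
    }
    out["s100b_2"] = lat[("s100b", "lv")] + manifest_effect("s100b", age2_c)
    out["s100b_3"] = (lat[("s100b", "lv")] + lat[("s100b", "ch")]
                      + manifest_effect("s100b", age3_c))
    out["wmh_2"] = np.exp(lat[("wmh", "lv")] + manifest_effect("wmh", agem2_c))
    out["wmh_3"] = np.exp(lat[("wmh", "lv")] + lat[("wmh", "ch")]
                          + manifest_effect("wmh", agem3_c))
    for c in ("tb", "gm"):
        out[f"{c}_2"] = lat[(c, "lv")] + manifest_effect(c, agem2_c)
        out[f"{c}_3"] = (lat[(c, "lv")] + lat[(c, "ch")]
                         + manifest_effect(c, agem3_c))

    for metric, tracts, res, factor in (("fa", config.fa_tracts, res_fa, "gfa"),
                                        ("md", config.md_tracts, res_md, "gmd")):
        f2 = lat[(factor, "lv")]
        f3 = f2 + lat[(factor, "ch")]
        e2 = manifest_effect(metric, agem2_c)
        e3 = manifest_effect(metric, agem3_c)
        for t in TRACTS:
            spec = tracts[t]
            sides = ("",) if t in MIDLINE_TRACTS else ("l", "r")
            for s in sides:
                key = t if s == "" else f"{t}_{s}"
                v2 = spec.intercept + spec.loading * f2 + res[(t, s, 2)] + e2
                v3 = spec.intercept + spec.loading * f3 + res[(t, s, 3)] + e3
                if metric == "fa":
                    v2, v3 = np.clip(v2, 0.0, 1.0), np.clip(v3, 0.0, 1.0)
                out[f"{metric}_{key}_2"] = v2
                out[f"{metric}_{key}_3"] = v3

    # PVS change rating, optionally coupled to the serum latent change
    probs = np.asarray(config.pvs_change_probs, float)
    rho = config.pvs_coupling
    cum = np.cumsum(probs)
    from scipy.stats import norm
    thresholds = norm.ppf(np.clip(cum[:-1], 1e-12, 1 - 1e-12))
    ch = lat[("s100b", "ch")]
    ch_sd = np.sqrt(config.constructs["s100b"].change_var)
    z_ch = (ch - config.constructs["s100b"].change_mean) / max(ch_sd, 1e-12)
    z = rho * z_ch + np.sqrt(max(1 - rho ** 2, 0.0)) * rng.standard_normal(n)
    out["pvs_change"] = (np.searchsorted(thresholds, z, side="right") - 2).astype(float)

    df = pd.DataFrame(out)[cols]
    return df


# ---------------------------------------------------------------- missingness
def apply_missingness(table: pd.DataFrame, config: GeneratorConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """MAR attrition plus MCAR scan missingness.

    Wave-3 fields are removed for non-returners sampled with probability
    ``logistic(intercept + slope * standardized baseline GM)``; each wave's
    MRI block is additionally removed with ``scan_missing_rate`` (MCAR).
    The wave-2 serum value is never removed.  Deterministic given seed.
    """
    m = config.missingness
    rate = m.get("scan_missing_rate", 0.0)
    if not 0 <= rate <= 1:
        raise ConfigurationError(f"scan_missing_rate={rate} outside [0, 1]")
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    df = table.copy()
    n = len(df)
    if n == 0:
        return df
    gm = df["gm_2"].to_numpy(float)
    sd = np.nanstd(gm)
    z = (gm - np.nanmean(gm)) / (sd if sd > 0 else 1.0)
    p_drop = expit(m.get("attrition_intercept", -np.inf)
                   + m.get("attrition_slope_on_gm", 0.0) * z)
    dropout = rng.random(n) < p_drop

    mri_cols = {w: [f"wmh_{w}", f"tb_{w}", f"gm_{w}", f"age_mri_{w}"]
                + [f"fa_{t}_{w}" for t in RAW_TRACTS]
                + [f"md_{t}_{w}" for t in RAW_TRACTS] for w in (2, 3)}
    wave3_cols = ([f"{v}_3" for v in ("s100b", "age_serum", "mmse", "dementia",
                                      "melanoma", "diabetes", "hypertension")]
                  + mri_cols[3])
    df.loc[dropout, wave3_cols] = np.nan

    scan_missing = {}
    for w in (2, 3):
        miss = rng.random(n) < rate
        scan_missing[w] = miss
        df.loc[miss, mri_cols[w]] = np.nan
    no_pvs = dropout | scan_missing[2] | scan_missing[3]
    df.loc[no_pvs, "pvs_change"] = np.nan
    return df


# ------------------------------------------------------------------- artifacts
def inject_artifacts(table: pd.DataFrame, config: GeneratorConfig,
                     seed: int | None = None):
    """Inject assay artifacts into the serum columns.

    Outliers (either wave) are placed strictly above mean + 4 SD of the
    uncontaminated wave distribution; floor artifacts (wave 3 only) are
    uniform draws in [0, 0.02).  Returns ``(table, audit)`` where the audit
    is a JSON-able list of the injected cells.
    """
    a = config.artifact_injection
    out_rate = a.get("outlier_rate", 0.0)
    floor_rate = a.get("floor_rate", 0.0)
    mag = a.get("outlier_magnitude_sd", 1.0)
    for key, v in (("outlier_rate", out_rate), ("floor_rate", floor_rate)):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{key}={v} outside [0, 1]")
    rng = np.random.default_rng((config.seed + 2) if seed is None else seed)
    df = table.copy()
    audit: list[dict] = []
    for w in (2, 3):
        col = f"s100b_{w}"
        vals = df[col].to_numpy(float)
        obs = np.where(~np.isnan(vals))[0]
        if obs.size == 0:
            continue
        mean, sd = vals[obs].mean(), vals[obs].std()
        hit = obs[rng.random(obs.size) < out_rate]
        for i in hit:
            new = mean + (4.0 + 0.05 + abs(rng.standard_normal()) * mag) * sd
            audit.append({"rule": "outlier", "wave": w,
                          "participant_id": int(df["participant_id"].iloc[i]),
                          "original": float(vals[i]), "injected": float(new)})
            df.iat[i, df.columns.get_loc(col)] = new
    col = "s100b_3"
    vals = df[col].to_numpy(float)
    obs = np.where(~np.isnan(vals))[0]
    hit = obs[rng.random(obs.size) < floor_rate] if obs.size else np.array([], int)
    for i in hit:
        new = rng.uniform(0.0, ASSAY_FLOOR)
        audit.append({"rule": "floor", "wave": 3,
                      "participant_id": int(df["participant_id"].iloc[i]),
                      "original": float(vals[i]), "injected": float(new)})
        df.iat[i, df.columns.get_loc(col)] = new
    return df, audit
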