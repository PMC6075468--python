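"""Builders for latent change score (LCS) model families.

A two-wave LCS model represents the wave-3 score as the wave-2 latent
level plus a latent change:

    y2 = eta,        y3 = eta + Delta        (unit loadings, zero residual)

so that for single-indicator constructs the latent change is essentially a
difference score.  Multi-indicator constructs replace y2/y3 by a latent
factor measured by several indicators per wave under strong factorial
invariance (loadings and intercepts constrained equal across waves, with
same-indicator residuals allowed to correlate across waves).

Bivariate models combine two constructs and freely estimate the six
covariances among the two levels and two changes; the level-level
("cross-sectional") and change-change ("longitudinal") covariances carry
the reserved labels :data:`LEVEL_ASSOC` and :data:`CHANGE_ASSOC` used by
the reporting pipeline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .ram import PathSpec, SpecificationError

__all__ = [
    "LEVEL_ASSOC", "CHANGE_ASSOC", "ChangeScoreSpec",
    "build_univariate_lcs", "build_latent_factor_lcs", "build_bivariate_lcs",
    "build_pvs_variant", "add_covariates", "add_auxiliary",
    "propose_residual_pairs",
]

#: reserved label for the cross-sectional (level-level) association
LEVEL_ASSOC = "level_level"
#: reserved label for the longitudinal (change-change) association
CHANGE_ASSOC = "change_change"


@dataclass
class ChangeScoreSpec:
    """Declarative description of one construct's measurement across waves.

    ``indicators`` maps an indicator key to its (wave-2 column, wave-3
    column) pair; one entry yields a single-indicator construct, several
    yield a latent factor.  ``extra_residual_pairs`` adds residual
    covariances between different indicators, each endpoint given as
    ``(indicator_key, wave)`` with wave in {2, 3}.
    """

    name: str
    indicators: dict[str, tuple[str, str]]
    invariance: str = "strong"              # 'strong' | 'configural'
    extra_residual_pairs: list = field(default_factory=list)
    marker: str | None = None               # defaults to the first indicator

    def __post_init__(self) -> None:
        if not self.indicators:
            raise SpecificationError(f"construct {self.name!r} has no indicators")
        if self.invariance not in ("strong", "configural"):
            raise SpecificationError(f"unknown invariance level {self.invariance!r}")
        if self.marker is None:
            self.marker = next(iter(self.indicators))
        if self.marker not in self.indicators:
            raise SpecificationError(f"marker {self.marker!r} is not an indicator")
        for (a, wa), (b, wb) in self.extra_residual_pairs:
            for ind, w in ((a, wa), (b, wb)):
                if ind not in self.indicators:
                    raise SpecificationError(
                        f"extra residual pair references unknown indicator {ind!r}")
                if w not in (2, 3):
                    raise SpecificationError(f"wave must be 2 or 3, got {w!r}")

    @property
    def level(self) -> str:
        return f"{self.name}_lv"

    @property
    def change(self) -> str:
        return f"{self.name}_ch"

    @property
    def wave3_factor(self) -> str:
        return f"{self.name}_f3"

    def columns(self) -> list[str]:
        cols = []
        for c2, c3 in self.indicators.values():
            cols.extend([c2, c3])
        return cols


def build_univariate_lcs(spec: ChangeScoreSpec) -> PathSpec:
    """Univariate LCS model; dispatches to the latent-factor builder for
    multi-indicator constructs."""
    if len(spec.indicators) > 1:
        return build_latent_factor_lcs(spec)
    n = spec.name
    (c2, c3) = next(iter(spec.indicators.values()))
    ps = PathSpec(observed=[c2, c3], latent=[spec.level, spec.change])
    ps.add_path(spec.level, c2, value=1.0)
    ps.add_path(spec.level, c3, value=1.0)
    ps.add_path(spec.change, c3, value=1.0)
    ps.add_cov(spec.level, label=f"{n}_lv_var")
    ps.add_cov(spec.change, label=f"{n}_ch_var")
    ps.add_cov(spec.level, spec.change, label=f"{n}_lv_ch_cov")
    ps.add_mean(spec.level, label=f"{n}_lv_mean")
    ps.add_mean(spec.change, label=f"{n}_ch_mean")
    return ps


def build_latent_factor_lcs(spec: ChangeScoreSpec) -> PathSpec:
    """Multi-indicator LCS with a latent factor per wave.

    Identification is by marker variable: the marker's loading is fixed at
    1 and its intercept at 0 at both waves, leaving the latent wave-2 mean
    free.  Under strong invariance all other loadings and intercepts share
    a label across waves; under configural invariance they are wave
    specific.  Same-indicator residuals covary across waves; extra
    residual pairs come from the ChangeScoreSpec.
    """
    n = spec.name
    strong = spec.invariance == "strong"
    w2cols = {k: v[0] for k, v in spec.indicators.items()}
    w3cols = {k: v[1] for k, v in spec.indicators.items()}
    observed = [w2cols[k] for k in spec.indicators] + \
               [w3cols[k] for k in spec.indicators]
    lv, ch, f3 = spec.level, spec.change, spec.wave3_factor
    ps = PathSpec(observed=observed, latent=[lv, ch, f3])
    ps.add_path(lv, f3, value=1.0)
    ps.add_path(ch, f3, value=1.0)
    for k in spec.indicators:
        if k == spec.marker:
            ps.add_path(lv, w2cols[k], value=1.0)
            ps.add_path(f3, w3cols[k], value=1.0)
        elif strong:
            lab = f"{n}_load_{k}"
            ps.add_path(lv, w2cols[k], label=lab)
            ps.add_path(f3, w3cols[k], label=lab)
        else:
            ps.add_path(lv, w2cols[k], label=f"{n}_load_{k}_w2")
            ps.add_path(f3, w3cols[k], label=f"{n}_load_{k}_w3")
        # intercepts (marker fixed at 0 -> latent mean identified)
        if k != spec.marker:
            if strong:
                lab = f"{n}_int_{k}"
                ps.add_mean(w2cols[k], label=lab)
                ps.add_mean(w3cols[k], label=lab)
            else:
                ps.add_mean(w2cols[k], label=f"{n}_int_{k}_w2")
                ps.add_mean(w3cols[k], label=f"{n}_int_{k}_w3")
        # residual variances (free at both waves) and cross-wave covariance
        ps.add_cov(w2cols[k], label=f"{n}_res_{k}_w2")
        ps.add_cov(w3cols[k], label=f"{n}_res_{k}_w3")
        ps.add_cov(w2cols[k], w3cols[k], label=f"{n}_rescov_{k}")
    for (a, wa), (b, wb) in spec.extra_residual_pairs:
        ca = w2cols[a] if wa == 2 else w3cols[a]
        cb = w2cols[b] if wb == 2 else w3cols[b]
        ps.add_cov(ca, cb, label=f"{n}_rescov_{a}w{wa}_{b}w{wb}")
    ps.add_cov(lv, label=f"{n}_lv_var")
    ps.add_cov(ch, label=f"{n}_ch_var")
    ps.add_cov(lv, ch, label=f"{n}_lv_ch_cov")
    ps.add_mean(lv, label=f"{n}_lv_mean")
    ps.add_mean(ch, label=f"{n}_ch_mean")
    return ps


def _merge(a: PathSpec, b: PathSpec) -> PathSpec:
    overlap = set(a.variables) & set(b.variables)
    if overlap:
        raise SpecificationError(f"constructs share variable names: {sorted(overlap)}")
    return PathSpec(observed=a.observed + b.observed,
                    latent=a.latent + b.latent,
                    entries=list(a.entries) + list(b.entries))


def build_bivariate_lcs(x_spec: ChangeScoreSpec, y_spec: ChangeScoreSpec) -> PathSpec:
    """Bivariate LCS: two constructs with all six level/change covariances.

    The level-level covariance carries :data:`LEVEL_ASSOC` and the
    change-change covariance :data:`CHANGE_ASSOC`.
    """
    ps = _merge(build_univariate_lcs(x_spec), build_univariate_lcs(y_spec))
    ps.add_cov(x_spec.level, y_spec.level, label=LEVEL_ASSOC)
    ps.add_cov(x_spec.change, y_spec.change, label=CHANGE_ASSOC)
    ps.add_cov(x_spec.level, y_spec.change,
               label=f"{x_spec.name}_lv_{y_spec.name}_ch_cov")
    ps.add_cov(x_spec.change, y_spec.level,
               label=f"{x_spec.name}_ch_{y_spec.name}_lv_cov")
    return ps


def build_pvs_variant(s100b_spec: ChangeScoreSpec, pvs_change_variable: str) -> PathSpec:
    """Observed-change variant: a visual change rating (no level measure)
    enters as a manifest variable correlated with the biomarker's latent
    level and latent change.  The two covariances reuse the reserved
    association labels so reporting is uniform across outcomes."""
    if not pvs_change_variable:
        raise SpecificationError("pvs_change_variable is required")
    ps = build_univariate_lcs(s100b_spec)
    if pvs_change_variable in ps.variables:
        raise SpecificationError(f"{pvs_change_variable!r} already in model")
    ps.observed.append(pvs_change_variable)
    ps.add_mean(pvs_change_variable, label="pvs_mean")
    ps.add_cov(pvs_change_variable, label="pvs_var")
    ps.add_cov(s100b_spec.level, pvs_change_variable, label=LEVEL_ASSOC)
    ps.add_cov(s100b_spec.change, pvs_change_variable, label=CHANGE_ASSOC)
    return ps


def add_covariates(model: PathSpec, covariate_map: dict[str, list[str]]) -> PathSpec:
    """Regress manifest variables on exogenous observed covariates.

    ``covariate_map`` maps a manifest (observed model variable) to its
    covariate columns.  Covariates get free means, variances, and mutual
    covariances, and a free regression path onto each mapped manifest;
    substantive labels are untouched.  Returns a new PathSpec.
    """
    ps = copy.deepcopy(model)
    covs: list[str] = []
    for manifest, cvars in covariate_map.items():
        if manifest not in ps.observed:
            raise SpecificationError(f"unknown manifest {manifest!r} in covariate map")
        for c in cvars:
            if c not in covs:
                covs.append(c)
    for c in covs:
        if c in ps.variables:
            raise SpecificationError(f"covariate {c!r} already in model")
    ps.observed.extend(covs)
    for i, c in enumerate(covs):
        ps.add_mean(c, label=f"{c}_mean")
        ps.add_cov(c, label=f"{c}_var")
        for d in covs[:i]:
            ps.add_cov(c, d, label=f"cov_{d}_{c}")
    for manifest, cvars in covariate_map.items():
        for c in cvars:
            ps.add_path(c, manifest, label=f"b_{c}_{manifest}")
    return ps


def _exogenous_latents(ps: PathSpec) -> list[str]:
    with_incoming = {e.row for e in ps.entries if e.matrix == "A"}
    return [v for v in ps.latent if v not in with_incoming]


def add_auxiliary(model: PathSpec, aux_variable: str) -> PathSpec:
    """Saturated-correlates auxiliary-variable augmentation.

    The auxiliary covaries freely with every exogenous latent, every
    exogenous observed variable, and the residual of every manifest with a
    free residual variance; its own mean and variance are free.  This
    makes FIML draw on the auxiliary's association with missingness
    without touching the substantive parameters.
    """
    if model.has_variable(aux_variable):
        raise SpecificationError(f"auxiliary {aux_variable!r} already in model")
    ps = copy.deepcopy(model)
    with_incoming = {e.row for e in ps.entries if e.matrix == "A"}
    free_resid = {e.row for e in ps.entries
                  if e.matrix == "S" and e.row == e.col and e.is_free
                  and e.row in ps.observed}
    partners = _exogenous_latents(ps)
    partners += [v for v in ps.observed
                 if v not in with_incoming or v in free_resid]
    ps.observed.append(aux_variable)
    ps.add_mean(aux_variable, label=f"aux_{aux_variable}_mean")
    ps.add_cov(aux_variable, label=f"aux_{aux_variable}_var")
    for v in partners:
        ps.add_cov(aux_variable, v, label=f"aux_{aux_variable}_{v}_cov")
    return ps


def propose_residual_pairs(results, spec: ChangeScoreSpec, k: int = 5):
    """Rank unmodelled cross-indicator residual pairs of a fitted factor
    model by absolute standardized covariance residual.

    Intended use: fit the configural (or invariant) model first, then pass
    the top pairs back in via ``extra_residual_pairs``.  Returns a list of
    ``((indicator, wave), (indicator, wave))`` tuples, largest residual
    first.
    """
    mu_s, S_s = results.sample_moments
    if S_s is None:
        raise ValueError("results carry no sample moments; fit with "
                         "compute_fit_indices=True")
    Sigma_hat, _ = results.implied_moments()
    obs = results.model.spec.observed
    sd = np.sqrt(np.diag(S_s))
    R = (S_s - Sigma_hat) / np.outer(sd, sd)
    colmap = {}
    for key, (c2, c3) in spec.indicators.items():
        colmap[c2] = (key, 2)
        colmap[c3] = (key, 3)
    declared = set()
    for e in results.model.spec.entries:
        if e.matrix == "S" and e.row != e.col:
            declared.add(frozenset((e.row, e.col)))
    scored = []
    for i, a in enumerate(obs):
        for j in range(i + 1, len(obs)):
            b = obs[j]
            if a not in colmap or b not in colmap:
                continue
            if colmap[a][0] == colmap[b][0]:
                continue  # same indicator across waves is always modelled
            if frozenset((a, b)) in declared:
                continue
            scored.append((abs(R[i, j]), colmap[a], colmap[b]))
    scored.sort(key=lambda t: -t[0])
    return [(p, q) for _, p, q in scored[:k]]
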