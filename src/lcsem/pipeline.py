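"""End-to-end analysis orchestration.

Builds the right model family per outcome (single-indicator change score
for volumetrics and single tracts, latent white-matter factor for gFA/gMD,
observed-change variant for the PVS rating), adds covariate correction and
the auxiliary variable, fits by FIML, standardizes, bootstraps the two
reserved associations, and applies Benjamini–Hochberg FDR within the
suite.  Also provides the descriptive statistics used to characterize the
cohort and its attrition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import lcs
from .cohort import TRACTS
from .lcs import ChangeScoreSpec, LEVEL_ASSOC, CHANGE_ASSOC
from .model import Sem

__all__ = [
    "DescriptivesResult", "AssociationRow", "compare_groups", "pearson_r",
    "bh_fdr", "build_outcome_model", "run_association_suite",
    "attrition_report", "descriptives_table", "GLOBAL_OUTCOMES",
    "TRACT_OUTCOMES", "plot_associations",
]

GLOBAL_OUTCOMES = ("wmh", "pvs", "gfa", "gmd", "gm", "tbv")
TRACT_OUTCOMES = tuple(f"tract:{t}:{m}" for m in ("fa", "md") for t in TRACTS)


# ------------------------------------------------------------- descriptives
@dataclass
class DescriptivesResult:
    """Two-group comparison: Welch t, Satterthwaite df, pooled-SD Cohen's d."""
    label: str
    mean_x: float
    sd_x: float
    n_x: int
    mean_y: float
    sd_y: float
    n_y: int
    t: float
    df_welch: float
    p: float
    cohens_d: float

    def to_dict(self) -> dict:
        return asdict(self)


def compare_groups(x, y, label: str = "") -> DescriptivesResult:
    """Welch two-sample comparison with pooled-SD Cohen's d."""
    x = np.asarray(pd.Series(x).dropna(), float)
    y = np.asarray(pd.Series(y).dropna(), float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"each group needs >= 2 non-missing values "
                         f"(got {x.size} and {y.size}) for {label or 'comparison'}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            t, df, p = 0.0, float(x.size + y.size - 2), 1.0
        else:
            t, df, p = np.inf if x.mean() > y.mean() else -np.inf, \
                float(x.size + y.size - 2), 0.0
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    pooled = np.sqrt(((x.size - 1) * vx + (y.size - 1) * vy)
                     / max(x.size + y.size - 2, 1))
    d = (x.mean() - y.mean()) / pooled if pooled > 0 else \
        (0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean()))
    return DescriptivesResult(label, float(x.mean()), float(x.std(ddof=1)),
                              int(x.size), float(y.mean()), float(y.std(ddof=1)),
                              int(y.size), t, df, p, float(d))


def pearson_r(x, y):
    """Pearson correlation on pairwise-complete cases; (nan, nan) when a
    margin is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini–Hochberg step-up: adjusted p-values and rejection flags."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def descriptives_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-wave mean/SD/N for the headline cohort variables."""
    rows = []
    for w in (2, 3):
        for var, col in [("age_serum", f"age_serum_{w}"), ("s100b", f"s100b_{w}"),
                         ("mmse", f"mmse_{w}"), ("wmh", f"wmh_{w}"),
                         ("tb", f"tb_{w}"), ("gm", f"gm_{w}")]:
            if col not in table.columns:
                continue
            x = table[col].dropna()
            rows.append({"variable": var, "wave": w, "mean": x.mean(),
                         "sd": x.std(ddof=1), "n": int(x.size)})
        if "sex" in table.columns:
            present = table[f"s100b_{w}"].notna() if f"s100b_{w}" in table.columns \
                else pd.Series(True, index=table.index)
            sex = table.loc[present, "sex"]
            rows.append({"variable": "n_male", "wave": w,
                         "mean": float(sex.sum()), "sd": np.nan,
                         "n": int(sex.size)})
    return pd.DataFrame(rows)


def attrition_report(table: pd.DataFrame):
    """Baseline comparisons of wave-3 returners vs non-returners (serum,
    TB, WMH, GM; Welch) plus a sex-by-MRI-participation chi-square per wave.

    A participant is a returner if the wave-3 serum value is present.
    """
    returner = table["s100b_3"].notna()
    results = []
    for var in ("s100b_2", "tb_2", "wmh_2", "gm_2"):
        grp_r = table.loc[returner, var]
        grp_n = table.loc[~returner, var]
        if grp_r.dropna().size < 2 or grp_n.dropna().size < 2:
            raise ValueError(
                f"degenerate group for {var}: returners n={grp_r.dropna().size}, "
                f"non-returners n={grp_n.dropna().size}")
        results.append(compare_groups(grp_r, grp_n, label=var))
    chi2_tests = {}
    for w in (2, 3):
        has_serum = table[f"s100b_{w}"].notna()
        sub = table.loc[has_serum]
        mri = sub[f"gm_{w}"].notna()
        tab = pd.crosstab(sub["sex"], mri)
        if tab.shape == (2, 2):
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
            chi2_tests[f"sex_by_mri_wave{w}"] = {"chi2": float(chi2), "p": float(p)}
    return results, chi2_tests


# ------------------------------------------------------------ model assembly
def _s100b_spec() -> ChangeScoreSpec:
    return ChangeScoreSpec("s100b", {"s100b": ("s100b_2", "s100b_3")})


def _factor_spec(metric: str, extra_residual_pairs=None) -> ChangeScoreSpec:
    name = {"fa": "gfa", "md": "gmd"}[metric]
    indicators = {t: (f"{metric}_{t}_2", f"{metric}_{t}_3") for t in TRACTS}
    return ChangeScoreSpec(name, indicators,
                           extra_residual_pairs=list(extra_residual_pairs or []))


def outcome_spec(outcome: str, extra_residual_pairs=None) -> ChangeScoreSpec:
    """The ChangeScoreSpec for a named outcome (``wmh``, ``gm``, ``tbv``,
    ``gfa``, ``gmd``, or ``tract:<tract>:<fa|md>``)."""
    if outcome in ("wmh", "gm"):
        return ChangeScoreSpec(outcome, {outcome: (f"{outcome}_2", f"{outcome}_3")})
    if outcome == "tbv":
        return ChangeScoreSpec("tbv", {"tbv": ("tb_2", "tb_3")})
    if outcome in ("gfa", "gmd"):
        return _factor_spec("fa" if outcome == "gfa" else "md",
                            extra_residual_pairs)
    if outcome.startswith("tract:"):
        _, tract, metric = outcome.split(":")
        if tract not in TRACTS or metric not in ("fa", "md"):
            raise ValueError(f"unknown tract outcome {outcome!r}")
        return ChangeScoreSpec(f"{tract}_{metric}",
                               {tract: (f"{metric}_{tract}_2", f"{metric}_{tract}_3")})
    raise ValueError(f"unknown outcome {outcome!r}")


def _covariate_map(spec_x: ChangeScoreSpec, outcome_spec_, pvs: bool):
    cmap = {"s100b_2": ["age_serum_2", "sex"], "s100b_3": ["age_serum_3", "sex"]}
    mri_cov = {2: ["age_mri_2", "sex", "diabetes_2", "hypertension_2"],
               3: ["age_mri_3", "sex", "diabetes_2", "hypertension_2"]}
    if pvs:
        cmap["pvs_change"] = ["age_mri_2", "sex", "diabetes_2", "hypertension_2"]
    elif outcome_spec_ is not None:
        for (c2, c3) in outcome_spec_.indicators.values():
            cmap[c2] = mri_cov[2]
            cmap[c3] = mri_cov[3]
    return cmap


def build_outcome_model(outcome: str, covariates: bool = True,
                        auxiliary: str | None = "gm_2",
                        extra_residual_pairs=None):
    """Assemble the full PathSpec for one outcome.

    Returns ``(path_spec, scaling_groups)``, where ``scaling_groups`` lists
    column groups that must share one scale factor when standardizing the
    data for optimization (both waves of a construct).
    """
    sspec = _s100b_spec()
    groups = [["s100b_2", "s100b_3"]]
    if outcome == "pvs":
        ps = lcs.build_pvs_variant(sspec, "pvs_change")
        ospec = None
        groups.append(["pvs_change"])
    else:
        ospec = outcome_spec(outcome, extra_residual_pairs)
        ps = lcs.build_bivariate_lcs(sspec, ospec)
        groups.append(ospec.columns())
    if covariates:
        ps = lcs.add_covariates(ps, _covariate_map(sspec, ospec, outcome == "pvs"))
    if auxiliary and not ps.has_variable(auxiliary):
        ps = lcs.add_auxiliary(ps, auxiliary)
    return ps, groups


def scale_for_fit(table: pd.DataFrame, spec_observed, groups):
    """Rescale observed columns for optimizer conditioning.

    Columns in the same group (the two waves of one construct) share a
    factor — the wave-2 sample SD — so the change-score structure is
    preserved; remaining non-binary columns are scaled by their own SD.
    Standardized estimates, chi-square and fit indices are invariant to
    these affine changes of units.
    """
    df = table.copy()
    scaled: dict[str, float] = {}
    for grp in groups:
        base = df[grp[0]].std(skipna=True)
        if not np.isfinite(base) or base <= 0:
            base = 1.0
        for c in grp:
            if c in df.columns:
                df[c] = df[c] / base
                scaled[c] = base
    for c in spec_observed:
        if c in scaled or c not in df.columns:
            continue
        vals = df[c].dropna().unique()
        if len(vals) <= 2:        # binary covariates keep their coding
            scaled[c] = 1.0
            continue
        sd = df[c].std(skipna=True)
        if np.isfinite(sd) and sd > 0:
            df[c] = df[c] / sd
            scaled[c] = sd
    return df, scaled


# ------------------------------------------------------------------- reporting
@dataclass
class AssociationRow:
    """One outcome's standardized cross-sectional and longitudinal
    associations with p-values, bootstrap CIs and FDR flags."""
    outcome_name: str
    level_r: float = np.nan
    level_p: float = np.nan
    level_ci_low: float = np.nan
    level_ci_high: float = np.nan
    change_r: float = np.nan
    change_p: float = np.nan
    change_ci_low: float = np.nan
    change_ci_high: float = np.nan
    level_p_fdr: float = np.nan
    change_p_fdr: float = np.nan
    fdr_flag_level: bool = False
    fdr_flag_change: bool = False
    chi2: float = np.nan
    df: int = 0
    rmsea: float = np.nan
    cfi: float = np.nan
    tli: float = np.nan
    srmr: float = np.nan
    n_used: int = 0
    converged: bool = False
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def fit_outcome(table: pd.DataFrame, outcome: str, covariates: bool = True,
                auxiliary: str | None = "gm_2", extra_residual_pairs=None,
                compute_se: bool = True, compute_fit_indices: bool = True):
    """Build, scale and fit the model for one outcome; returns SemResults."""
    ps, groups = build_outcome_model(outcome, covariates=covariates,
                                     auxiliary=auxiliary,
                                     extra_residual_pairs=extra_residual_pairs)
    df, _ = scale_for_fit(table, ps.observed, groups)
    model = Sem(ps, df)
    return model.fit(compute_se=compute_se,
                     compute_fit_indices=compute_fit_indices)


def run_association_suite(table: pd.DataFrame, outcomes=None, q: float = 0.05,
                          n_boot: int = 1000, seed: int = 0,
                          covariates: bool = True,
                          auxiliary: str | None = "gm_2",
                          extra_residual_pairs: dict | None = None,
                          compute_se: bool = True):
    """Fit every outcome's model and report FDR-corrected associations.

    Returns ``(rows, fits)``: a DataFrame with one AssociationRow per
    outcome (FDR applied jointly to all level/change p-values of converged
    fits in this suite) and the dict of SemResults for audit.
    """
    outcomes = list(outcomes if outcomes is not None else GLOBAL_OUTCOMES)
    extra_residual_pairs = extra_residual_pairs or {}
    rows: list[AssociationRow] = []
    fits: dict = {}
    for i, outcome in enumerate(outcomes):
        row = AssociationRow(outcome_name=outcome)
        try:
            res = fit_outcome(table, outcome, covariates=covariates,
                              auxiliary=auxiliary,
                              extra_residual_pairs=extra_residual_pairs.get(outcome),
                              compute_se=compute_se)
        except Exception as exc:  # emit a row; exclude from the FDR family
            row.warnings = [f"fit failed: {exc}"]
            rows.append(row)
            continue
        fits[outcome] = res
        row.converged = res.converged
        row.n_used = res.n_used
        row.chi2, row.df = res.chi2, res.df
        row.rmsea, row.cfi = res.rmsea, res.cfi
        row.tli, row.srmr = res.tli, res.srmr
        row.warnings = list(res.warnings)
        if res.converged:
            row.level_r = float(res.standardized[LEVEL_ASSOC])
            row.change_r = float(res.standardized[CHANGE_ASSOC])
            if compute_se:
                row.level_p = float(res.pvalues[LEVEL_ASSOC])
                row.change_p = float(res.pvalues[CHANGE_ASSOC])
            if n_boot > 0:
                ci = res.bootstrap_ci([LEVEL_ASSOC, CHANGE_ASSOC],
                                      n_boot=n_boot, seed=seed + i)
                row.level_ci_low = float(ci.loc[LEVEL_ASSOC, "lower"])
                row.level_ci_high = float(ci.loc[LEVEL_ASSOC, "upper"])
                row.change_ci_low = float(ci.loc[CHANGE_ASSOC, "lower"])
                row.change_ci_high = float(ci.loc[CHANGE_ASSOC, "upper"])
                row.warnings += ci.attrs.get("warnings", [])
        rows.append(row)

    # one FDR family: all level+change tests of converged fits in the suite
    family = [(i, which) for i, r in enumerate(rows) if r.converged
              for which in ("level", "change")
              if np.isfinite(getattr(r, f"{which}_p"))]
    if family:
        ps = [getattr(rows[i], f"{which}_p") for i, which in family]
        adjusted, reject = bh_fdr(ps, q=q)
        for (i, which), adj, rej in zip(family, adjusted, reject):
            setattr(rows[i], f"{which}_p_fdr", float(adj))
            setattr(rows[i], f"fdr_flag_{which}", bool(rej))
    out = pd.DataFrame([r.to_dict() for r in rows])
    return out, fits


def plot_associations(rows: pd.DataFrame, path: str | None = None):
    """Forest-style plot of standardized level/change associations with
    bootstrap CIs; FDR-surviving estimates are filled."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 1.5))
    ypos = np.arange(len(rows))[::-1]
    for offset, which, color in ((0.15, "level", "tab:blue"),
                                 (-0.15, "change", "tab:green")):
        r = rows[f"{which}_r"]
        lo, hi = rows[f"{which}_ci_low"], rows[f"{which}_ci_high"]
        flags = rows[f"fdr_flag_{which}"]
        ax.errorbar(r, ypos + offset, xerr=[r - lo, hi - r], fmt="none",
                    ecolor=color, alpha=0.7)
        ax.scatter(r, ypos + offset, c=[color if f else "white" for f in flags],
                   edgecolors=color, zorder=3,
                   label=f"{which} ({'cross-sectional' if which == 'level' else 'longitudinal'})")
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(rows["outcome_name"])
    ax.set_xlabel("standardized association (r)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
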