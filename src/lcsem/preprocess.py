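"""Cohort exclusion, serum filtering, and MRI transformation rules.

Three stages, each with an audit trail:

1. ``exclude_participants`` — remove participants with self-reported
   dementia or MMSE < 24 at either wave, and participants reporting
   melanoma at either wave (melanoma is an extracranial source of serum
   S100β).
2. ``filter_s100b`` — per wave, set serum cells more than 4 SDs *above*
   the wave mean to missing (one-sided, mean/SD computed once on the
   wave's non-missing values), and set wave-3 cells below the assay
   sensitivity threshold (0.02 μg/L) to missing.  Rows are retained so the
   participant's other wave stays usable under FIML.
3. ``transform_mri`` — log-transform WMH volume; optionally express WMH,
   total brain and gray matter as proportions of intracranial volume
   before any transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import ASSAY_FLOOR, BILATERAL_TRACTS, MIDLINE_TRACTS

__all__ = ["ExclusionLog", "exclude_participants", "filter_s100b",
           "transform_mri", "average_bilateral", "MMSE_CUTOFF"]

MMSE_CUTOFF = 24
OUTLIER_SD = 4.0


@dataclass
class ExclusionLog:
    """Audit trail of removed rows/cells for one preprocessing stage."""
    rules: list = field(default_factory=list)

    def add(self, rule_name: str, participant_ids, wave=None, values=None):
        self.rules.append({
            "rule": rule_name,
            "participant_ids": [int(i) for i in participant_ids],
            "wave": wave,
            "values": None if values is None else [float(v) for v in values],
            "count": len(list(participant_ids)),
        })

    def add_warning(self, rule_name: str, message: str):
        self.rules.append({"rule": rule_name, "warning": message,
                           "participant_ids": [], "count": 0})

    def count(self, rule_name: str | None = None) -> int:
        return sum(r["count"] for r in self.rules
                   if rule_name is None or r["rule"] == rule_name)

    def to_dict(self) -> dict:
        return asdict(self)


def _flagged(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df.columns:
        return pd.Series(False, index=df.index)
    return df[col].fillna(0).astype(float) > 0


def exclude_participants(table: pd.DataFrame):
    """Remove dementia/MMSE<24 participants, then melanoma reporters.

    Missing flags count as not-flagged.  Returns ``(table, ExclusionLog)``.
    """
    log = ExclusionLog()
    df = table
    mmse_low = pd.Series(False, index=df.index)
    for w in (2, 3):
        col = f"mmse_{w}"
        if col in df.columns:
            mmse_low |= df[col].astype(float) < MMSE_CUTOFF
    dementia = _flagged(df, "dementia_2") | _flagged(df, "dementia_3")
    rule1 = dementia | mmse_low
    log.add("dementia_or_mmse", df.loc[rule1, "participant_id"])
    df = df.loc[~rule1]
    melanoma = _flagged(df, "melanoma_2") | _flagged(df, "melanoma_3")
    log.add("melanoma", df.loc[melanoma, "participant_id"])
    df = df.loc[~melanoma].reset_index(drop=True)
    return df, log


def filter_s100b(table: pd.DataFrame):
    """Assay-level cell filters on the serum columns (see module docstring).

    The outlier rule is one-sided (above the mean only), per wave, and
    non-iterative: the wave mean and SD are computed once, on all of that
    wave's non-missing values, before any removal.
    """
    log = ExclusionLog()
    df = table.copy()
    for w in (2, 3):
        col = f"s100b_{w}"
        x = df[col].astype(float)
        obs = x.dropna()
        if len(obs) < 2:
            log.add_warning(f"outlier_4sd_wave{w}",
                            f"fewer than 2 non-missing values at wave {w}; "
                            "filter skipped")
            continue
        cut = obs.mean() + OUTLIER_SD * obs.std()
        high = x > cut
        log.add(f"outlier_4sd_wave{w}", df.loc[high, "participant_id"],
                wave=w, values=x[high])
        df.loc[high, col] = np.nan
    x = df["s100b_3"].astype(float)
    low = x < ASSAY_FLOOR
    log.add("assay_floor_wave3", df.loc[low, "participant_id"], wave=3,
            values=x[low])
    df.loc[low, "s100b_3"] = np.nan
    return df, log


def transform_mri(table: pd.DataFrame, icv_correct: bool = True) -> pd.DataFrame:
    """Log-transform WMH; optionally proportion volumes by ICV first.

    Only volumetric columns change; FA/MD are untouched.  The returned
    table carries ``attrs['mri_transformed'] = True`` and a second
    application raises.
    """
    if table.attrs.get("mri_transformed"):
        raise ValueError("MRI volumes already transformed on this table")
    df = table.copy()
    vol_cols = [c for c in ("wmh_2", "wmh_3", "tb_2", "tb_3", "gm_2", "gm_3")
                if c in df.columns]
    for c in vol_cols:
        neg = df[c] < 0
        if neg.any():
            raise ValueError(f"negative volume in column {c!r}")
    if icv_correct:
        icv = df["icv"].astype(float)
        for c in vol_cols:
            df[c] = df[c].astype(float) / icv
    for c in ("wmh_2", "wmh_3"):
        if c not in df.columns:
            continue
        x = df[c].astype(float)
        zero = x == 0
        if zero.any():
            df.loc[zero, c] = np.nan
        df[c] = np.log(df[c].astype(float))
    df.attrs["mri_transformed"] = True
    df.attrs["icv_corrected"] = bool(icv_correct)
    return df


def average_bilateral(table: pd.DataFrame) -> pd.DataFrame:
    """Add left-right tract averages (``fa_atr_2`` from ``fa_atr_l_2`` /
    ``fa_atr_r_2`` etc.), using the available side if one is missing.
    Midline tracts already have a single column."""
    df = table.copy()
    for metric in ("fa", "md"):
        for t in BILATERAL_TRACTS:
            for w in (2, 3):
                lcol, rcol = f"{metric}_{t}_l_{w}", f"{metric}_{t}_r_{w}"
                if lcol in df.columns and rcol in df.columns:
                    df[f"{metric}_{t}_{w}"] = df[[lcol, rcol]].mean(axis=1)
    return df
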