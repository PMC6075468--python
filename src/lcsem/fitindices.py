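"""Model-adequacy indices: RMSEA, CFI, TLI, SRMR.

All four are computed from the likelihood-ratio chi-square of the fitted
model, the chi-square of the independence baseline (free means and
variances, all covariances fixed at zero, fit on the same cases), and —
for SRMR — the residual between the saturated-model covariance estimate
and the model-implied covariance.  Canonical definitions:

* ``rmsea = sqrt(max(0, (chi2 - df) / (df * (n - 1))))`` (0 when df = 0)
* ``cfi   = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)``
* ``tli   = ((chi2_b/df_b) - (chi2/df)) / ((chi2_b/df_b) - 1)``
* ``srmr``: root mean square over the lower triangle (diagonal included)
  of the covariance residuals standardized by the sample SDs.

Under FIML the "sample" covariance entering SRMR is the saturated-model
estimate, so SRMR remains defined with missing data.  Mean residuals are
excluded from SRMR.
"""

from __future__ import annotations

import numpy as np

__all__ = ["indices", "rmsea", "cfi", "tli", "srmr"]


def rmsea(chi2: float, df: int, n: int) -> float:
    if df <= 0:
        # saturated model: chi2 must vanish up to optimizer tolerance
        if chi2 > 1e-2:
            raise ValueError(f"df = 0 but chi2 = {chi2:.4g} > 0")
        return 0.0
    if n < 2:
        raise ValueError("rmsea requires n >= 2")
    return float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))


def cfi(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def tli(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    """Tucker-Lewis index; NaN when a ratio is undefined (df or df_b zero)."""
    if df <= 0 or df_b <= 0:
        return np.nan
    rb = chi2_b / df_b
    if abs(rb - 1.0) < 1e-12:
        return np.nan
    return float((rb - chi2 / df) / (rb - 1.0))


def srmr(S_sample: np.ndarray, Sigma_hat: np.ndarray) -> float:
    S = np.asarray(S_sample, float)
    Sh = np.asarray(Sigma_hat, float)
    if S.shape != Sh.shape:
        raise ValueError("sample and implied covariance shapes differ")
    sd = np.sqrt(np.diag(S))
    if (sd <= 0).any():
        raise ValueError("non-positive sample variance; srmr undefined")
    D = (S - Sh) / np.outer(sd, sd)
    il, jl = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(D[il, jl] ** 2)))


def indices(chi2: float, df: int, chi2_b: float, df_b: int, n: int,
            S_sample: np.ndarray | None = None,
            Sigma_hat: np.ndarray | None = None) -> dict:
    """All four indices as a dict; srmr NaN when moments are not supplied."""
    out = {
        "rmsea": rmsea(chi2, df, n),
        "cfi": cfi(chi2, df, chi2_b, df_b),
        "tli": tli(chi2, df, chi2_b, df_b),
        "srmr": np.nan,
    }
    if S_sample is not None and Sigma_hat is not None:
        out["srmr"] = srmr(S_sample, Sigma_hat)
    return out
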