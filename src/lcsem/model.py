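"""FIML structural equation model estimation.

``Sem`` is the model object (a :class:`~lcsem.ram.PathSpec` bound to a
pandas DataFrame); ``Sem.fit`` maximizes the casewise full-information
maximum likelihood and returns a :class:`SemResults` carrying estimates,
standard errors, the likelihood-ratio chi-square against the saturated
model, fit indices, the standardized solution, and bias-corrected bootstrap
confidence intervals on request.

Each case contributes the log-density of its observed subvector under the
pattern-marginal multivariate normal, so cases with partially missing rows
are retained (valid under MAR).  Cases are grouped by missingness pattern
purely as an optimization; the result equals the case-by-case sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .ram import PathSpec, SpecificationError
from . import fitindices

__all__ = ["Sem", "SemResults", "mvn_em"]

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12  # objective penalty for non-PD implied covariances


def _pattern_split(X: np.ndarray):
    """Group rows of X (with NaN) by missingness pattern.

    Returns a list of (observed-column index array, data block) pairs; rows
    with no observed values are rejected upstream.
    """
    obs = ~np.isnan(X)
    patterns = {}
    for i in range(X.shape[0]):
        key = obs[i].tobytes()
        patterns.setdefault(key, []).append(i)
    out = []
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        cols = np.where(mask)[0]
        out.append((cols, X[np.ix_(rows, cols)]))
    return out


def _mvn_block_loglik(Xp: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Sum of MVN log-densities for the rows of a complete block."""
    n, k = Xp.shape
    try:
        c, low = linalg.cho_factor(Sigma, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    resid = Xp - mu
    z = linalg.cho_solve((c, low), resid.T, check_finite=False)
    quad = np.sum(resid.T * z)
    return -0.5 * (n * k * _LOG2PI + n * logdet + quad)


def mvn_em(X: np.ndarray, max_iter: int = 2000, tol: float = 1e-10):
    """Saturated-model (unstructured) MVN MLE under missing data by EM.

    Returns ``(mu, Sigma, loglik, n_iter)`` with the 1/n covariance
    divisor.  With complete data this reduces to the sample moments in one
    step.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("every case must observe at least one variable")
    if obs.all():
        mu = X.mean(axis=0)
        Sigma = np.cov(X, rowvar=False, ddof=0).reshape(p, p)
        return mu, Sigma, _mvn_block_loglik(X, mu, Sigma), 0

    # init: available-case means, pairwise covariances (ridge to PD)
    mu = np.nanmean(X, axis=0)
    Xc = X - mu
    Sigma = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            m = obs[:, i] & obs[:, j]
            if m.sum() >= 2:
                Sigma[i, j] = Sigma[j, i] = np.mean(Xc[m, i] * Xc[m, j])
    ev = np.linalg.eigvalsh(Sigma)
    if ev.min() < 1e-8 * max(ev.max(), 1.0):
        Sigma += (1e-6 * max(np.trace(Sigma) / p, 1.0)
                  - min(ev.min(), 0.0)) * np.eye(p)

    blocks = _pattern_split(X)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for cols, Xp in blocks:
            npat = Xp.shape[0]
            miss = np.setdiff1d(np.arange(p), cols)
            Soo = Sigma[np.ix_(cols, cols)]
            ll += _mvn_block_loglik(Xp, mu[cols], Soo)
            if miss.size == 0:
                T1[cols] += Xp.sum(axis=0)
                T2[np.ix_(cols, cols)] += Xp.T @ Xp
                continue
            Smo = Sigma[np.ix_(miss, cols)]
            try:
                K = np.linalg.solve(Soo, Smo.T).T   # regression of miss on obs
            except np.linalg.LinAlgError:
                K = Smo @ np.linalg.pinv(Soo)
            cond_cov = Sigma[np.ix_(miss, miss)] - K @ Smo.T
            Em = mu[miss] + (Xp - mu[cols]) @ K.T    # (npat, n_miss)
            T1[cols] += Xp.sum(axis=0)
            T1[miss] += Em.sum(axis=0)
            T2[np.ix_(cols, cols)] += Xp.T @ Xp
            T2[np.ix_(miss, cols)] += Em.T @ Xp
            T2[np.ix_(cols, miss)] += Xp.T @ Em
            T2[np.ix_(miss, miss)] += Em.T @ Em + npat * cond_cov
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        if np.isfinite(ll) and abs(ll - ll_old) <= tol * (abs(ll) + 1.0):
            ll_old = ll
            break
        ll_old = ll
    # final loglik at converged moments
    ll = sum(_mvn_block_loglik(Xp, mu[cols], Sigma[np.ix_(cols, cols)])
             for cols, Xp in blocks)
    return mu, Sigma, ll, it


class Sem:
    """A RAM path model bound to data, estimated by FIML.

    Parameters
    ----------
    spec : PathSpec
        Model specification; its observed variables must be columns of
        ``data``.
    data : pandas.DataFrame
        One row per case; missing values as NaN.  Rows observing none of
        the model variables are dropped (counted in ``n_dropped``).
    """

    def __init__(self, spec: PathSpec, data: pd.DataFrame):
        self.spec = spec
        self.compiled = spec.compile()
        missing_cols = [c for c in spec.observed if c not in data.columns]
        if missing_cols:
            raise SpecificationError(f"data lacks model columns: {missing_cols}")
        X = data[spec.observed].to_numpy(dtype=float)
        keep = ~np.isnan(X).all(axis=1)
        self.n_dropped = int((~keep).sum())
        self.X = X[keep]
        self.data = data.loc[keep].reset_index(drop=True)
        if self.X.shape[0] == 0:
            raise ValueError("no cases observe any model variable")
        self.nobs = self.X.shape[0]
        self._blocks = _pattern_split(self.X)
        self.n_patterns = len(self._blocks)

    # ------------------------------------------------------------------ core
    @property
    def param_names(self) -> list[str]:
        return self.compiled.labels

    @property
    def npar(self) -> int:
        return self.compiled.npar

    @property
    def df_model(self) -> int:
        p = self.compiled.n_obs
        return p * (p + 3) // 2 - self.npar

    def implied_moments(self, params, include_latent: bool = False):
        """Model-implied covariance and mean (observed block by default)."""
        return self.compiled.implied_moments(np.asarray(params, float),
                                             include_latent=include_latent)

    def loglike(self, params) -> float:
        """Casewise FIML log-likelihood; -inf if implied Sigma is not PD."""
        try:
            Sigma, mu = self.implied_moments(params)
        except np.linalg.LinAlgError:
            return -np.inf
        ll = 0.0
        for cols, Xp in self._blocks:
            li = _mvn_block_loglik(Xp, mu[cols], Sigma[np.ix_(cols, cols)])
            if not np.isfinite(li):
                return -np.inf
            ll += li
        return ll

    def score(self, params) -> np.ndarray:
        """Analytic gradient of the FIML log-likelihood."""
        return self.loglike_and_score(params)[1]

    def loglike_and_score(self, params):
        """FIML log-likelihood and its exact gradient via RAM algebra.

        The per-pattern derivatives with respect to the pattern-marginal
        (mu, Sigma) are accumulated into full observed-block matrices and
        chained through Sigma = F B S B' F', mu = F B M with B = (I-A)^-1.
        """
        comp = self.compiled
        theta = np.asarray(params, float)
        A, S, M = comp.matrices(theta)
        nv = comp.nv
        try:
            B = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(comp.npar)
        C = B @ S @ B.T                      # full implied covariance
        mu_all = B @ M
        p = comp.n_obs
        Sigma = 0.5 * (C[:p, :p] + C[:p, :p].T)
        mu = mu_all[:p]

        ll = 0.0
        G = np.zeros((p, p))                 # dll/dSigma (observed block)
        g = np.zeros(p)                      # dll/dmu
        for cols, Xp in self._blocks:
            k = cols.size
            So = Sigma[np.ix_(cols, cols)]
            try:
                cf = linalg.cho_factor(So, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return -np.inf, np.zeros(comp.npar)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            r = Xp - mu[cols]
            z = linalg.cho_solve(cf, r.T, check_finite=False)   # (k, n_p)
            n_p = Xp.shape[0]
            ll += -0.5 * (n_p * k * _LOG2PI + n_p * logdet + np.sum(r.T * z))
            Sinv = linalg.cho_solve(cf, np.eye(k), check_finite=False)
            g[cols] += z.sum(axis=1)
            G[np.ix_(cols, cols)] += 0.5 * (z @ z.T - n_p * Sinv)
        if not np.isfinite(ll):
            return -np.inf, np.zeros(comp.npar)

        G = 0.5 * (G + G.T)
        # embed into full-variable space (observed variables come first)
        G_full = np.zeros((nv, nv))
        G_full[:p, :p] = G
        g_full = np.zeros(nv)
        g_full[:p] = g

        P = B.T @ G_full @ B                 # for S entries
        a = B.T @ g_full                     # for M and A mean chain
        Q = 2.0 * (B.T @ G_full @ C)         # for A covariance chain
        b = B @ M

        grad = np.zeros(comp.npar)
        for kk, i, j in comp.s_free:
            grad[kk] += P[i, j] * (1.0 if i == j else 2.0)
        for kk, i in comp.m_free:
            grad[kk] += a[i]
        for kk, i, j in comp.a_free:
            grad[kk] += Q[i, j] + a[i] * b[j]
        return ll, grad

    # ---------------------------------------------------------------- starts
    def _marker_of(self, latent: str) -> str | None:
        """First observed variable reached from a latent via fixed paths."""
        comp = self.compiled
        idx = comp.index
        seen = set()
        frontier = [latent]
        while frontier:
            v = frontier.pop(0)
            if v in seen:
                continue
            seen.add(v)
            j = idx[v]
            children = [comp.names[i] for i in np.where(comp.A0[:, j] != 0)[0]]
            for c in sorted(children, key=lambda c: comp.A0[idx[c], j] != 1.0):
                if c in self.spec.observed:
                    return c
                frontier.append(c)
        return None

    def start_params(self) -> np.ndarray:
        """Deterministic start values (data moments; loadings from marker
        regressions; covariances zero)."""
        comp = self.compiled
        col_mean = np.nanmean(self.X, axis=0)
        col_var = np.nanvar(self.X, axis=0)
        col_var = np.where(col_var > 0, col_var, 1.0)
        obs_idx = {v: i for i, v in enumerate(self.spec.observed)}
        theta = np.zeros(comp.npar)
        assigned = np.zeros(comp.npar, dtype=bool)

        def put(k, val):
            if not assigned[k]:
                theta[k] = val
                assigned[k] = True

        # builder-provided starts take priority
        for lab, st in comp.starts.items():
            put(comp.label_index[lab], st)

        # observed variables with no incoming directed path are exogenous:
        # start their moments at the sample moments
        has_incoming = {comp.names[i] for _, i, _ in comp.a_free}
        has_incoming |= {comp.names[i] for i in np.where(comp.A0.any(axis=1))[0]}
        exog_obs = {v for v in self.spec.observed if v not in has_incoming}

        for k, i, j in comp.s_free:
            vi, vj = comp.names[i], comp.names[j]
            if i == j:
                if vi in exog_obs:
                    put(k, col_var[obs_idx[vi]])
                elif vi in obs_idx:
                    put(k, 0.5 * col_var[obs_idx[vi]])
                else:
                    m = self._marker_of(vi)
                    put(k, 0.5 * col_var[obs_idx[m]] if m else 1.0)
            elif vi in exog_obs and vj in exog_obs:
                a, b = obs_idx[vi], obs_idx[vj]
                both = ~np.isnan(self.X[:, a]) & ~np.isnan(self.X[:, b])
                if both.sum() >= 3:
                    put(k, float(np.cov(self.X[both, a], self.X[both, b],
                                        ddof=0)[0, 1]))
                else:
                    put(k, 0.0)
            else:
                put(k, 0.0)
        for k, i in comp.m_free:
            vi = comp.names[i]
            if vi in obs_idx:
                put(k, col_mean[obs_idx[vi]])
            else:
                m = self._marker_of(vi)
                put(k, col_mean[obs_idx[m]] if m else 0.0)
        for k, i, j in comp.a_free:
            dst, src = comp.names[i], comp.names[j]
            if src in self.spec.latent and dst in obs_idx:
                m = self._marker_of(src)
                if m is not None and m != dst:
                    a, b = obs_idx[dst], obs_idx[m]
                    both = ~np.isnan(self.X[:, a]) & ~np.isnan(self.X[:, b])
                    if both.sum() >= 3:
                        xa = self.X[both, a] - self.X[both, a].mean()
                        xb = self.X[both, b] - self.X[both, b].mean()
                        denom = np.dot(xb, xb)
                        put(k, float(np.dot(xa, xb) / denom) if denom > 0 else 1.0)
                        continue
                put(k, 1.0)
            else:
                put(k, 0.0)
        self._adjust_change_latent_starts(theta, assigned, obs_idx,
                                          col_mean, col_var)
        return theta

    def _adjust_change_latent_starts(self, theta, assigned, obs_idx,
                                     col_mean, col_var):
        """Seed change-latent moments from marker difference scores.

        A latent whose fixed-path children are a proper subset of another
        latent's children is a change variable riding on that level (the
        LCS topology); starting its variance at half the sample variance of
        the marker difference, its mean at the marker mean difference, and
        the level-change covariance accordingly keeps the optimizer in the
        right basin.
        """
        comp = self.compiled
        children = {}
        for v in self.spec.latent:
            j = comp.index[v]
            children[v] = set(np.where(comp.A0[:, j] != 0)[0])
        pairs = []
        for ch, cch in children.items():
            for lv, clv in children.items():
                if ch != lv and cch and cch < clv:
                    pairs.append((ch, lv))
        for ch, lv in pairs:
            m_ch, m_lv = self._marker_of(ch), self._marker_of(lv)
            if m_ch is None or m_lv is None or m_ch == m_lv:
                continue
            a, b = obs_idx[m_ch], obs_idx[m_lv]
            both = ~np.isnan(self.X[:, a]) & ~np.isnan(self.X[:, b])
            if both.sum() < 3:
                continue
            d = self.X[both, a] - self.X[both, b]
            lvv = self.X[both, b]
            for k, i, j in comp.s_free:
                vi, vj = comp.names[i], comp.names[j]
                if vi == ch and vj == ch:
                    theta[k] = max(0.5 * d.var(), 1e-3 * col_var[b])
                elif {vi, vj} == {ch, lv}:
                    theta[k] = 0.5 * float(np.cov(lvv, d, ddof=0)[0, 1])
            for k, i in comp.m_free:
                if comp.names[i] == ch:
                    theta[k] = d.mean()

    # ------------------------------------------------------------------- fit
    def fit(self, start_params=None, maxiter: int = 10000,
            compute_se: bool = True, compute_fit_indices: bool = True,
            gtol: float = 1e-5, ftol: float = 1e-9,
            polish: bool = True) -> "SemResults":
        """Maximize the FIML likelihood; deterministic given data/options."""
        if self.df_model < 0:
            raise SpecificationError(
                f"model is not identified: df = {self.df_model} < 0 "
                f"({self.npar} free parameters)"
            )
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self.start_params()
        # pairwise-moment starts can be jointly non-PD under missing data:
        # shrink free covariance starts toward zero until feasible
        if not np.isfinite(self.loglike(x0)):
            offdiag = [k for k, i, j in self.compiled.s_free if i != j]
            for _ in range(30):
                x0[offdiag] *= 0.7
                if np.isfinite(self.loglike(x0)):
                    break

        def objective(th):
            ll, grad = self.loglike_and_score(th)
            if not np.isfinite(ll):
                return _BIG, np.zeros_like(th)
            return -ll, -grad

        opts = {"maxiter": maxiter, "maxfun": 10 * maxiter,
                "gtol": gtol, "ftol": ftol, "maxcor": 100}
        res = optimize.minimize(objective, x0, method="L-BFGS-B", jac=True,
                                options=opts)
        if not res.success:
            res2 = optimize.minimize(objective, res.x, method="L-BFGS-B",
                                     jac=True, options=opts)
            if res2.fun <= res.fun:
                res = res2
        converged = bool(res.success) and np.isfinite(res.fun)
        if converged and polish:
            # polish: a bounded second stage at much tighter tolerance so
            # nested-model comparisons and saturated identities hold sharply
            res2 = optimize.minimize(objective, res.x, method="L-BFGS-B",
                                     jac=True,
                                     options={"maxiter": min(3000, maxiter),
                                              "maxfun": 30000, "maxcor": 100,
                                              "gtol": 1e-8, "ftol": 1e-14})
            if np.isfinite(res2.fun) and res2.fun <= res.fun:
                res2.nit += res.nit
                res2.success = True
                res = res2
        warns: list[str] = []
        if not converged:
            warns.append(f"optimizer did not converge: {res.message}")
        theta = res.x
        loglik = -res.fun

        estimates = pd.Series(theta, index=self.param_names, name="estimate")

        # Heywood screening: negative free variances
        for k, i, j in self.compiled.s_free:
            if i == j and theta[k] < 0:
                warns.append(
                    f"negative variance estimate for '{self.compiled.labels[k]}' "
                    f"({theta[k]:.4g}); Heywood case"
                )

        bse = pd.Series(np.nan, index=self.param_names, name="se")
        if compute_se and converged:
            try:
                H = _hessian_from_score(lambda t: -self.score(t), theta)
                cov = np.linalg.inv(H)
                d = np.diag(cov)
                if (d < 0).any():
                    warns.append("observed information not positive definite; "
                                 "some standard errors undefined")
                bse = pd.Series(np.sqrt(np.where(d > 0, d, np.nan)),
                                index=self.param_names, name="se")
            except np.linalg.LinAlgError:
                warns.append("observed information singular; standard errors unavailable")

        loglik_sat = chi2 = p_chi2 = np.nan
        indices = {}
        S_sample = mu_sample = None
        if compute_fit_indices:
            mu_sat, S_sat, ll_sat, _ = self.fit_saturated()
            loglik_sat = ll_sat
            S_sample, mu_sample = S_sat, mu_sat
            chi2 = max(2.0 * (loglik_sat - loglik), 0.0)
            df = self.df_model
            p_chi2 = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
            chi2_b, df_b, _ = self.fit_baseline()
            Sigma_hat, _ = self.implied_moments(theta)
            indices = fitindices.indices(chi2, df, chi2_b, df_b, self.nobs,
                                         S_sample=S_sat, Sigma_hat=Sigma_hat)
            indices["chi2_baseline"] = chi2_b
            indices["df_baseline"] = df_b

        std, std_warns = self._standardize(theta)
        warns.extend(std_warns)

        return SemResults(
            model=self, params=estimates, bse=bse, loglik=loglik,
            loglik_saturated=loglik_sat, chi2=chi2, df=self.df_model,
            p_chi2=p_chi2, indices=indices, standardized=std,
            converged=converged, n_iterations=int(res.nit),
            n_used=self.nobs, n_patterns=self.n_patterns,
            n_dropped=self.n_dropped, warnings=warns,
            sample_moments=(mu_sample, S_sample),
        )

    # ----------------------------------------------------- reference models
    def fit_saturated(self):
        """Unstructured MVN fit on the same cases (closed form / EM)."""
        return mvn_em(self.X)

    def fit_baseline(self):
        """Independence model: free means and variances, covariances zero.

        Under a diagonal covariance the casewise likelihood factorizes over
        variables, so the FIML MLE is the per-variable univariate normal
        MLE on that variable's observed values.
        """
        p = self.X.shape[1]
        ll_b = 0.0
        for j in range(p):
            x = self.X[:, j]
            x = x[~np.isnan(x)]
            if x.size < 1:
                raise ValueError(f"variable {self.spec.observed[j]!r} has no data")
            v = x.var()
            if v <= 0:
                v = 1e-12
            ll_b += -0.5 * x.size * (_LOG2PI + np.log(v) + 1.0)
        _, _, ll_sat, _ = self.fit_saturated()
        chi2_b = max(2.0 * (ll_sat - ll_b), 0.0)
        df_b = p * (p + 3) // 2 - 2 * p
        return chi2_b, df_b, ll_b

    # --------------------------------------------------------- standardization
    def _standardize(self, theta: np.ndarray):
        """Correlation-metric solution: covariances / products of implied SDs,
        loadings and paths rescaled by source/destination implied SDs."""
        comp = self.compiled
        warns: list[str] = []
        try:
            Sigma_all, _ = self.implied_moments(theta, include_latent=True)
        except np.linalg.LinAlgError:
            return pd.Series(np.nan, index=self.param_names), \
                ["standardization unavailable: singular (I - A)"]
        var = np.diag(Sigma_all)
        sd = np.sqrt(np.where(var > 0, var, np.nan))
        if np.isnan(sd).any():
            bad = [comp.names[i] for i in np.where(~(var > 0))[0]]
            warns.append(f"zero/negative implied variance for {bad}; "
                         "standardized entries undefined")
        std = pd.Series(np.nan, index=self.param_names, name="std")
        for k, i, j in comp.s_free:
            lab = comp.labels[k]
            if i == j:
                # exogenous variance -> proportion of total implied variance
                std[lab] = theta[k] / var[i] if var[i] > 0 else np.nan
            else:
                std[lab] = theta[k] / (sd[i] * sd[j])
        for k, i, j in comp.a_free:
            lab = comp.labels[k]
            if np.isnan(std[lab]):
                std[lab] = theta[k] * sd[j] / sd[i]
        for k, i in comp.m_free:
            lab = comp.labels[k]
            if np.isnan(std[lab]):
                std[lab] = theta[k] / sd[i]
        return std, warns


def _hessian_from_score(score, x, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of an analytic gradient."""
    x = np.asarray(x, float)
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.empty((p, p))
    for i in range(p):
        xp = x.copy(); xp[i] += h[i]
        xm = x.copy(); xm[i] -= h[i]
        H[i] = (score(xp) - score(xm)) / (2 * h[i])
    return 0.5 * (H + H.T)


def _numerical_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-parameter relative steps."""
    x = np.asarray(x, float)
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-2)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            if i == j:
                fpp = f(x + 2 * h[i] * _e(p, i))
                fp = f(x + h[i] * _e(p, i))
                fm = f(x - h[i] * _e(p, i))
                fmm = f(x - 2 * h[i] * _e(p, i))
                f0 = f(x)
                H[i, i] = (-fpp + 16 * fp - 30 * f0 + 16 * fm - fmm) / (12 * h[i] ** 2)
            else:
                fpp = f(x + h[i] * _e(p, i) + h[j] * _e(p, j))
                fpm = f(x + h[i] * _e(p, i) - h[j] * _e(p, j))
                fmp = f(x - h[i] * _e(p, i) + h[j] * _e(p, j))
                fmm = f(x - h[i] * _e(p, i) - h[j] * _e(p, j))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return 0.5 * (H + H.T)


def _e(p, i):
    v = np.zeros(p)
    v[i] = 1.0
    return v


@dataclass
class SemResults:
    """Estimation results for a :class:`Sem` model."""

    model: Sem
    params: pd.Series
    bse: pd.Series
    loglik: float
    loglik_saturated: float
    chi2: float
    df: int
    p_chi2: float
    indices: dict
    standardized: pd.Series
    converged: bool
    n_iterations: int
    n_used: int
    n_patterns: int
    n_dropped: int
    warnings: list = field(default_factory=list)
    sample_moments: tuple = (None, None)

    # -------------------------------------------------------------- inference
    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided Wald p-values on the unstandardized estimates."""
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index, name="p")

    @property
    def npar(self) -> int:
        return self.model.npar

    @property
    def rmsea(self):
        return self.indices.get("rmsea", np.nan)

    @property
    def cfi(self):
        return self.indices.get("cfi", np.nan)

    @property
    def tli(self):
        return self.indices.get("tli", np.nan)

    @property
    def srmr(self):
        return self.indices.get("srmr", np.nan)

    def implied_moments(self, include_latent: bool = False):
        return self.model.implied_moments(self.params.to_numpy(),
                                          include_latent=include_latent)

    # -------------------------------------------------------------- bootstrap
    def bootstrap_ci(self, labels, n_boot: int = 1000, conf: float = 0.95,
                     seed: int | None = None, standardized: bool = True):
        """Bias-corrected percentile bootstrap CIs for labelled parameters.

        Participants (rows) are resampled with replacement and the model is
        refit from the point estimates; non-converged replicates are dropped
        and counted.  Returns a DataFrame indexed by label with columns
        ``lower``/``upper``/``n_failed``, plus a ``warnings`` attribute entry
        if more than 20% of replicates failed.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        labels = list(labels)
        rng = np.random.default_rng(seed)
        point = (self.standardized if standardized else self.params)[labels]
        draws = np.full((n_boot, len(labels)), np.nan)
        n_failed = 0
        data = self.model.data
        n = len(data)
        warm = self.params.to_numpy()
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                m = Sem(self.model.spec, data.iloc[idx])
                r = m.fit(start_params=warm, compute_se=False,
                          compute_fit_indices=False, ftol=1e-8,
                          polish=False)
            except (ValueError, np.linalg.LinAlgError):
                n_failed += 1
                continue
            if not r.converged:
                n_failed += 1
                continue
            draws[b] = (r.standardized if standardized else r.params)[labels]
        ok = ~np.isnan(draws).any(axis=1)
        draws = draws[ok]
        warns = []
        if n_failed > 0.2 * n_boot:
            warns.append(f"{n_failed}/{n_boot} bootstrap replicates failed")
        alpha = 1.0 - conf
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        rows = []
        for k, lab in enumerate(labels):
            th = draws[:, k]
            B = th.size
            if B == 0 or np.allclose(th, th[0], atol=0):
                lo = hi = float(point[lab]) if B == 0 else float(th[0])
                rows.append((lo, hi))
                continue
            prop = np.mean(th < point[lab])
            prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1))
            z0 = stats.norm.ppf(prop)
            plo = stats.norm.cdf(2 * z0 - zcrit)
            phi = stats.norm.cdf(2 * z0 + zcrit)
            lo, hi = np.percentile(th, [100 * plo, 100 * phi])
            rows.append((float(lo), float(hi)))
        out = pd.DataFrame(rows, index=labels, columns=["lower", "upper"])
        out["n_failed"] = n_failed
        out.attrs["warnings"] = warns
        out.attrs["n_boot"] = n_boot
        out.attrs["draws"] = pd.DataFrame(draws, columns=labels)
        return out

    # ----------------------------------------------------------------- output
    def to_dict(self) -> dict:
        return {
            "estimates": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "standardized": self.standardized.to_dict(),
            "loglik": self.loglik,
            "loglik_saturated": self.loglik_saturated,
            "chi2": self.chi2,
            "df": self.df,
            "p_chi2": self.p_chi2,
            "npar": self.npar,
            "n_used": self.n_used,
            "n_patterns": self.n_patterns,
            "fit_indices": {k: (None if v is None or not np.isfinite(v) else float(v))
                            for k, v in self.indices.items()},
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "warnings": list(self.warnings),
        }

    def summary(self) -> str:
        lines = []
        lines.append("FIML structural equation model")
        lines.append("=" * 70)
        lines.append(f"Cases used: {self.n_used}  (patterns: {self.n_patterns}, "
                     f"dropped empty rows: {self.n_dropped})")
        lines.append(f"Free parameters: {self.npar}   df: {self.df}   "
                     f"converged: {self.converged} ({self.n_iterations} iters)")
        lines.append(f"loglik: {self.loglik:.4f}   saturated: "
                     f"{self.loglik_saturated:.4f}")
        if np.isfinite(self.chi2):
            lines.append(f"chi2({self.df}) = {self.chi2:.3f}, p = {self.p_chi2:.4f}")
            lines.append(f"RMSEA = {self.rmsea:.3f}  CFI = {self.cfi:.3f}  "
                         f"TLI = {self.tli:.3f}  SRMR = {self.srmr:.3f}")
        lines.append("-" * 70)
        lines.append(f"{'parameter':<28}{'est':>10}{'se':>10}{'z':>8}"
                     f"{'p':>8}{'std':>8}")
        for lab in self.params.index:
            est = self.params[lab]
            se = self.bse[lab]
            z = est / se if np.isfinite(se) and se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            std = self.standardized[lab]
            lines.append(f"{lab:<28}{est:>10.4f}{se:>10.4f}{z:>8.2f}"
                         f"{p:>8.3f}{std:>8.3f}")
        for w in self.warnings:
            lines.append(f"[warning] {w}")
        return "\n".join(lines)
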