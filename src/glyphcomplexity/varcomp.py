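"""Linear mixed models with independent random intercepts (variance components).

The model is

    y = X β + Σ_k Z_k b_k + ε,   b_k ~ N(0, σ²_k I),   ε ~ N(0, σ²_e I)

where each Z_k is the indicator matrix of one grouping factor.  Crossed and
nested designs are both expressed by supplying the appropriate factor
codings (nesting = a factor whose levels are the nested combinations).

Estimation profiles β and σ²_e out of the (RE)ML criterion and optimizes
over the variance ratios λ_k = σ²_k/σ²_e on the log scale.  All linear
algebra runs in the q-dimensional random-effect space via the Woodbury
identity, so cost is independent of n beyond the initial cross-products.

Fixed-effect t-tests use Satterthwaite-style approximate degrees of
freedom: df_j = 2·g_j² / Var(g_j), where g_j = Var(β̂_j) as a function of
the variance parameters, its gradient is taken by central finite
differences, and the covariance of the variance-parameter estimates comes
from the observed REML information (finite-difference Hessian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

_LOG_LAM_MIN, _LOG_LAM_MAX = -15.0, 15.0
_SINGULAR_TOL = 1e-6  # λ below this flags a ~zero variance component


class SingularFitWarning(UserWarning):
    pass


@dataclass
class ModelFit:
    """Result of one random-intercept fit."""

    fe_params: pd.Series            # fixed-effect estimates
    se: pd.Series
    df: pd.Series                   # Satterthwaite-style approximate df
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame          # 95% CI, columns low/high
    vcomp: dict[str, float]         # variance per grouping factor
    sigma2_resid: float
    loglik: float
    aic: float
    method: str                     # "REML" or "ML"
    nobs: int
    singular: bool
    model: "VarCompModel" = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "estimate": self.fe_params,
                "se": self.se,
                "df": self.df,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": self.conf_int["low"],
                "ci_high": self.conf_int["high"],
            }
        )
        return tab


class VarCompModel:
    """Variance-components mixed model for one outcome vector."""

    def __init__(self, y, X, factors: dict[str, np.ndarray], fe_names=None):
        self.y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        n, p = X.shape
        if self.y.shape != (n,):
            raise ValueError("y and X have incompatible shapes")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.fe_names = list(fe_names) if fe_names is not None else [f"x{j}" for j in range(p)]
        self.factor_names = list(factors)
        if not self.factor_names:
            raise ValueError("at least one grouping factor is required")
        blocks = []
        self.slices: dict[str, slice] = {}
        start = 0
        for name in self.factor_names:
            codes = np.asarray(factors[name])
            _, codes = np.unique(codes, return_inverse=True)
            q_k = codes.max() + 1
            if q_k < 2:
                raise ValueError(f"grouping factor {name!r} has a single level")
            Z_k = np.zeros((n, q_k))
            Z_k[np.arange(n), codes] = 1.0
            blocks.append(Z_k)
            self.slices[name] = slice(start, start + q_k)
            start += q_k
        self.Z = np.hstack(blocks)
        self.q = start
        self.n, self.p = n, p
        # cross-products reused at every objective evaluation
        self.ZtZ = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ self.X
        self.Zty = self.Z.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    # -- core algebra -------------------------------------------------------

    def _lam_vector(self, lam_by_factor: np.ndarray) -> np.ndarray:
        out = np.empty(self.q)
        for k, name in enumerate(self.factor_names):
            out[self.slices[name]] = lam_by_factor[k]
        return out

    def _parts(self, lam_by_factor: np.ndarray):
        """GLS pieces for W = I + Z Λ Z' at the given variance ratios."""
        lam = self._lam_vector(np.maximum(lam_by_factor, 0.0))
        g = np.sqrt(lam)
        M = np.eye(self.q) + (g[:, None] * self.ZtZ) * g[None, :]
        L = np.linalg.cholesky(M)
        logdetW = 2.0 * float(np.log(np.diag(L)).sum())

        GZtX = g[:, None] * self.ZtX
        GZty = g * self.Zty
        u_X = np.linalg.solve(L, GZtX)      # L⁻¹ G Z'X
        u_y = np.linalg.solve(L, GZty)
        XtWX = self.XtX - u_X.T @ u_X
        XtWy = self.Xty - u_X.T @ u_y
        ytWy = self.yty - float(u_y @ u_y)
        cF = np.linalg.cholesky(XtWX)
        logdetXtWX = 2.0 * float(np.log(np.diag(cF)).sum())
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - float(beta @ XtWy), 1e-300)
        XtWX_inv = np.linalg.inv(XtWX)
        return beta, rss, logdetW, logdetXtWX, XtWX_inv

    def _neg2_profiled(self, log_lam: np.ndarray, reml: bool) -> float:
        try:
            _, rss, logdetW, logdetXtWX, _ = self._parts(np.exp(log_lam))
        except np.linalg.LinAlgError:
            return 1e12
        if reml:
            return (self.n - self.p) * np.log(rss) + logdetW + logdetXtWX
        return self.n * np.log(rss) + logdetW

    def neg2_reml_full(self, theta: np.ndarray) -> float:
        """−2·restricted log-likelihood at natural-scale θ = (σ²_k…, σ²_e)."""
        sig2 = np.maximum(theta[:-1], 0.0)
        sig2e = max(theta[-1], 1e-12)
        lam = sig2 / sig2e
        _, rss, logdetW, logdetXtWX, _ = self._parts(lam)
        n, p = self.n, self.p
        return (
            (n - p) * np.log(2 * np.pi)
            + (n - p) * np.log(sig2e)
            + logdetW
            + logdetXtWX
            + rss / sig2e
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, reml: bool = True) -> ModelFit:
        k = len(self.factor_names)
        best = None
        for x0 in (np.zeros(k), np.full(k, -4.0), np.full(k, 2.0)):
            res = optimize.minimize(
                self._neg2_profiled,
                x0,
                args=(reml,),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        log_lam = np.clip(best.x, _LOG_LAM_MIN, _LOG_LAM_MAX)
        lam = np.exp(log_lam)
        beta, rss, logdetW, logdetXtWX, XtWX_inv = self._parts(lam)
        n, p = self.n, self.p
        dof = (n - p) if reml else n
        sigma2e = rss / dof
        vcomp = {name: float(lam[k_] * sigma2e) for k_, name in enumerate(self.factor_names)}
        saturated = any(
            (self.slices[name].stop - self.slices[name].start) >= self.n
            for name in self.factor_names
        )  # one level per observation: σ²_k and σ²_e are not separable
        singular = bool((lam < _SINGULAR_TOL).any()) or saturated

        if reml:
            loglik = -0.5 * (
                (n - p) * np.log(2 * np.pi)
                + (n - p) * np.log(sigma2e)
                + logdetW
                + logdetXtWX
                + (n - p)
            )
        else:
            loglik = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2e) + logdetW + n)
        n_params = p + len(self.factor_names) + 1
        aic = -2.0 * loglik + 2.0 * n_params

        se = np.sqrt(sigma2e * np.diag(XtWX_inv))
        df = self._satterthwaite(np.array(list(vcomp.values()) + [sigma2e]))
        tvals = beta / se
        pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
        tcrit = sps.t.ppf(0.975, df)
        names = self.fe_names
        return ModelFit(
            fe_params=pd.Series(beta, index=names),
            se=pd.Series(se, index=names),
            df=pd.Series(df, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            conf_int=pd.DataFrame(
                {"low": beta - tcrit * se, "high": beta + tcrit * se}, index=names
            ),
            vcomp=vcomp,
            sigma2_resid=float(sigma2e),
            loglik=float(loglik),
            aic=float(aic),
            method="REML" if reml else "ML",
            nobs=n,
            singular=singular,
            model=self,
        )

    # -- Satterthwaite machinery -------------------------------------------

    def _varbeta_diag(self, theta: np.ndarray) -> np.ndarray:
        sig2 = np.maximum(theta[:-1], 0.0)
        sig2e = max(theta[-1], 1e-12)
        _, _, _, _, XtWX_inv = self._parts(sig2 / sig2e)
        return sig2e * np.diag(XtWX_inv)

    def _satterthwaite(self, theta: np.ndarray) -> np.ndarray:
        n, p = self.n, self.p
        fallback = np.full(p, float(n - p))
        # variance components estimated at the zero boundary are treated as
        # known zeros: including them leaves the information matrix nearly
        # singular and collapses the df spuriously
        active = [i for i in range(len(theta) - 1) if theta[i] > 1e-4 * theta[-1]]
        active.append(len(theta) - 1)
        scale = np.maximum(np.abs(theta), theta[-1])
        h_full = 1e-4 * scale + 1e-10
        m = len(active)
        h = h_full[active]
        try:
            # gradient of Var(β̂_j) wrt the active θ (forward diff at bounds)
            grads = np.zeros((m, p))
            for ii, i in enumerate(active):
                tp = theta.copy()
                tm = theta.copy()
                tp[i] += h[ii]
                if theta[i] - h[ii] > 0:
                    tm[i] -= h[ii]
                    grads[ii] = (self._varbeta_diag(tp) - self._varbeta_diag(tm)) / (2 * h[ii])
                else:
                    grads[ii] = (self._varbeta_diag(tp) - self._varbeta_diag(theta)) / h[ii]
            # observed REML information (central FD Hessian of −2ℓ_R)/2
            H = np.zeros((m, m))
            f0 = self.neg2_reml_full(theta)
            interior = np.array([theta[i] - h[ii] > 0 for ii, i in enumerate(active)])
            for ii, i in enumerate(active):
                for jj, j in enumerate(active):
                    if jj < ii:
                        continue
                    if ii == jj:
                        if interior[ii]:
                            fpp = self.neg2_reml_full(_pert(theta, i, h[ii]))
                            fmm = self.neg2_reml_full(_pert(theta, i, -h[ii]))
                            H[ii, ii] = (fpp - 2 * f0 + fmm) / h[ii] ** 2
                        else:
                            f1 = self.neg2_reml_full(_pert(theta, i, h[ii]))
                            f2 = self.neg2_reml_full(_pert(theta, i, 2 * h[ii]))
                            H[ii, ii] = (f2 - 2 * f1 + f0) / h[ii] ** 2
                    else:
                        if interior[ii] and interior[jj]:
                            fpp = self.neg2_reml_full(_pert(theta, i, h[ii], j, h[jj]))
                            fpm = self.neg2_reml_full(_pert(theta, i, h[ii], j, -h[jj]))
                            fmp = self.neg2_reml_full(_pert(theta, i, -h[ii], j, h[jj]))
                            fmm = self.neg2_reml_full(_pert(theta, i, -h[ii], j, -h[jj]))
                            H[ii, jj] = H[jj, ii] = (fpp - fpm - fmp + fmm) / (
                                4 * h[ii] * h[jj]
                            )
                        else:
                            H[ii, jj] = H[jj, ii] = 0.0
            cov = 2.0 * np.linalg.pinv(H)
            g0 = self._varbeta_diag(theta)
            df = np.empty(p)
            for jdx in range(p):
                gr = grads[:, jdx]
                denom = float(gr @ cov @ gr)
                if denom <= 0 or not np.isfinite(denom):
                    df[jdx] = n - p
                else:
                    df[jdx] = 2.0 * g0[jdx] ** 2 / denom
            return np.clip(df, 1.0, n - p)
        except (np.linalg.LinAlgError, FloatingPointError):
            return fallback


def _pert(theta, i, hi, j=None, hj=None):
    t = theta.copy()
    t[i] += hi
    if j is not None:
        t[j] += hj
    return t


def fit_varcomp(
    data: pd.DataFrame,
    outcome: str,
    fixed: list[str] | None,
    groups: list[str],
    reml: bool = True,
) -> ModelFit:
    """Fit a random-intercept model from a tidy DataFrame.

    ``fixed`` columns must be numeric (dummy-code categoricals upstream);
    an intercept is always included.  ``groups`` are column names whose
    values define the random-intercept factors.
    """
    fixed = list(fixed or [])
    cols = [outcome] + fixed + list(groups)
    d = data.dropna(subset=[c for c in cols if c in data.columns])
    y = d[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d))] + [d[c].to_numpy(dtype=float) for c in fixed])
    factors = {g: d[g].to_numpy() for g in groups}
    model = VarCompModel(y, X, factors, fe_names=["intercept"] + fixed)
    return model.fit(reml=reml)


def delta_aic(null_fit: ModelFit, test_fit: ModelFit) -> float:
    """AIC(null) − AIC(test) after refitting both with ML; positive favors test.

    Requires both fits to model the same outcome vector.
    """
    m0, m1 = null_fit.model, test_fit.model
    if m0 is None or m1 is None:
        raise ValueError("fits must carry their models to be refit")
    if m0.n != m1.n or not np.allclose(m0.y, m1.y):
        raise ValueError("models were fit to different outcome data")
    a0 = m0.fit(reml=False).aic if null_fit.method != "ML" else null_fit.aic
    a1 = m1.fit(reml=False).aic if test_fit.method != "ML" else test_fit.aic
    return float(a0 - a1)
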