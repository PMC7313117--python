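"""Gaussian linear mixed models with a by-individual random intercept.

Used for trip descriptors and trip-level ODBA against tactic (SF/DF).  The
REML fit is delegated to ``statsmodels.MixedLM``; per-coefficient F tests use
Satterthwaite denominator degrees of freedom computed from this module's own
closed-form REML criterion (block/Woodbury algebra for the compound-symmetric
covariance), and marginal/conditional R^2 follow the variance-partition form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .glmm import _group_index


def _xt_omega_inv_x(X, y, code, n_groups, s2_b, s2_e):
    """(X' O^-1 X, X' O^-1 y, y' O^-1 y, log|O|) with O = s2_e I + s2_b Z Z'."""
    p = X.shape[1]
    XtOX = np.zeros((p, p))
    XtOy = np.zeros(p)
    ytOy = 0.0
    logdet = 0.0
    for g in range(n_groups):
        ix = code == g
        Xg, yg = X[ix], y[ix]
        n = len(yg)
        lam = s2_b / (s2_e * (s2_e + n * s2_b))
        XtOX += (Xg.T @ Xg) / s2_e - lam * np.outer(Xg.sum(0), Xg.sum(0))
        XtOy += (Xg.T @ yg) / s2_e - lam * Xg.sum(0) * yg.sum()
        ytOy += (yg @ yg) / s2_e - lam * yg.sum() ** 2
        logdet += (n - 1) * np.log(s2_e) + np.log(s2_e + n * s2_b)
    return XtOX, XtOy, ytOy, logdet


def reml_loglik(theta, y, X, code, n_groups):
    """Restricted log-likelihood at variance components theta = (s2_b, s2_e)."""
    s2_b, s2_e = max(theta[0], 0.0), max(theta[1], 1e-12)
    XtOX, XtOy, ytOy, logdet = _xt_omega_inv_x(X, y, code, n_groups, s2_b, s2_e)
    beta = np.linalg.solve(XtOX, XtOy)
    quad = ytOy - beta @ XtOy
    sign, logdet_x = np.linalg.slogdet(XtOX)
    n, p = len(y), X.shape[1]
    return float(-0.5 * (logdet + logdet_x + quad + (n - p) * np.log(2.0 * np.pi)))


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma2_id: float
    sigma2_res: float
    loglik: float          # restricted log-likelihood
    f_stat: np.ndarray     # per-coefficient Wald F (1, df_satterthwaite)
    df_denom: np.ndarray
    p_values: np.ndarray
    r2_marginal: float
    r2_conditional: float
    singular: bool
    n_obs: int
    n_groups: int


def fit_lmm(y, X, groups, names=None) -> LMMFit:
    """REML fit of ``y = X beta + b_individual + e`` with Satterthwaite tests."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    code, levels = _group_index(groups)
    n_groups = len(levels)

    import warnings

    s2_b = s2_e = None
    loglik = None
    model = sm.MixedLM(y, X, groups=np.asarray(code))
    for method in ("lbfgs", "powell"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method)
            s2_b = float(np.asarray(res.cov_re)[0, 0])
            s2_e = float(res.scale)
            loglik = float(res.llf)
            break
        except np.linalg.LinAlgError:
            continue
    if s2_b is None:
        # boundary-singular data: optimize the closed-form REML criterion
        from scipy import optimize

        var_y = float(np.var(y, ddof=1))
        opt = optimize.minimize(
            lambda th: -reml_loglik(th, y, X, code, n_groups),
            x0=np.array([0.1 * var_y, 0.9 * var_y]),
            method="L-BFGS-B",
            bounds=[(0.0, None), (1e-10 * var_y, None)],
        )
        s2_b, s2_e = float(opt.x[0]), float(opt.x[1])
        loglik = -float(opt.fun)
    singular = s2_b < 1e-10
    s2_b = max(s2_b, 0.0)

    # GLS fixed effects and covariance at the REML variance estimates
    XtOX, XtOy, _, _ = _xt_omega_inv_x(X, y, code, n_groups, s2_b, s2_e)
    cov_beta = np.linalg.inv(XtOX)
    beta = cov_beta @ XtOy
    se = np.sqrt(np.diag(cov_beta))

    df_denom = _satterthwaite_df(y, X, code, n_groups, s2_b, s2_e)
    f_stat = (beta / se) ** 2
    p_values = stats.f.sf(f_stat, 1, df_denom)

    var_f = float(np.var(X @ beta, ddof=0))
    denom = var_f + s2_b + s2_e
    return LMMFit(
        beta=beta,
        se=se,
        names=list(names),
        sigma2_id=s2_b,
        sigma2_res=s2_e,
        loglik=loglik,
        f_stat=f_stat,
        df_denom=df_denom,
        p_values=p_values,
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + s2_b) / denom,
        singular=singular,
        n_obs=len(y),
        n_groups=n_groups,
    )


def _satterthwaite_df(y, X, code, n_groups, s2_b, s2_e):
    """Satterthwaite denominator df per coefficient.

    df_j = 2 v_j^2 / (g_j' A g_j) where v_j = Var(beta_j) as a function of the
    variance components, g_j its gradient (finite differences) and A the
    inverse observed information of the REML criterion.
    """
    theta = np.array([s2_b, s2_e])

    def var_beta(th):
        XtOX, _, _, _ = _xt_omega_inv_x(X, y, code, n_groups, max(th[0], 0.0),
                                        max(th[1], 1e-12))
        return np.diag(np.linalg.inv(XtOX))

    eps = np.maximum(1e-6, 1e-4 * np.abs(theta))
    grads = []
    for j in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps[j]
        tm[j] = max(tm[j] - eps[j], 0.0)
        grads.append((var_beta(tp) - var_beta(tm)) / (tp[j] - tm[j]))
    G = np.column_stack(grads)  # (p, 2)

    def negll(th):
        return -reml_loglik(th, y, X, code, n_groups)

    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(theta, negll)
    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(H)
    v = var_beta(theta)
    denom = np.einsum("pj,jk,pk->p", G, A, G)
    denom = np.clip(denom, 1e-300, None)
    df = 2.0 * v**2 / denom
    # cap at the residual df of the fixed-effects-only model
    return np.clip(df, 1.0, len(y) - X.shape[1])
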