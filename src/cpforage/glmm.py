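"""Binomial (logit) generalized linear mixed models with an individual-level
random intercept, fitted by maximum likelihood with adaptive Gauss-Hermite
quadrature, plus the derived quantities used throughout the analysis:

* Wald confidence intervals and single-step backward pruning of weak
  interactions;
* likelihood-ratio tests of variance components (boundary-conservative);
* adjusted repeatability on the latent scale via the delta-method
  observation-level variance 1 / (pbar * (1 - pbar));
* marginal / conditional R^2 (variance-partition form) and per-covariate
  effect sizes r;
* conditional modes of the random effect (GLMM analogue of BLUPs) with
  simulation-based SDs;
* random-slope ("behavioural reaction norm") models via the Laplace
  approximation, one environmental covariate at a time.

The random intercept b_i ~ N(0, sigma_id^2) is integrated out per individual;
Laplace is the one-node special case of the adaptive quadrature, so both
model families share one likelihood code path where possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit

_SIGMA_EPS = 1e-8
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def standardize_columns(df: pd.DataFrame, cols) -> pd.DataFrame:
    """Return a copy with ``cols`` z-scored (mean 0, SD 1)."""
    out = df.copy()
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd <= 0:
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (x - x.mean()) / sd
    return out


def build_design(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Build a fixed-effects design matrix with an intercept.

    ``terms`` are column names; ``"a:b"`` denotes the elementwise product of
    two columns (an interaction).
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float))
        else:
            cols.append(df[term].to_numpy(dtype=float))
        names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _group_index(groups) -> tuple[np.ndarray, list]:
    groups = pd.Series(list(groups))
    levels = list(pd.unique(groups))
    code = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    return code, levels


# ---------------------------------------------------------------------------
# Likelihood machinery (random intercept)
# ---------------------------------------------------------------------------

def _bernoulli_ll(y, eta):
    # log p(y | eta), numerically safe
    return y * eta - np.logaddexp(0.0, eta)


def _group_mode(y, eta_fix, sigma2, b0=0.0, max_iter=50, tol=1e-10):
    """Newton maximization of the conditional log-density of one individual's
    random intercept; returns (mode, negative curvature)."""
    b = b0
    for _ in range(max_iter):
        p = expit(eta_fix + b)
        g = np.sum(y - p) - b / sigma2
        h = -np.sum(p * (1.0 - p)) - 1.0 / sigma2
        step = g / h
        b_new = b - step
        # dampen absurd steps
        if abs(step) > 10.0:
            b_new = b - np.sign(step) * 10.0
        b = b_new
        if abs(step) < tol:
            break
    p = expit(eta_fix + b)
    h = np.sum(p * (1.0 - p)) + 1.0 / sigma2
    return b, h


def _agq_group_ll(y, eta_fix, sigma, nodes, weights, return_mode=False):
    """Adaptive Gauss-Hermite log-likelihood contribution of one individual."""
    sigma2 = sigma * sigma
    bhat, h = _group_mode(y, eta_fix, sigma2)
    tau = 1.0 / np.sqrt(h)
    z = bhat + np.sqrt(2.0) * tau * nodes
    # log integrand: Bernoulli terms + normal prior density
    ll_pts = (
        np.array([np.sum(_bernoulli_ll(y, eta_fix + b)) for b in z])
        - 0.5 * z * z / sigma2
        - 0.5 * np.log(sigma2)
        - 0.5 * _LOG2PI
    )
    logsum = ll_pts + np.log(weights) + nodes * nodes
    m = logsum.max()
    ll = m + np.log(np.sum(np.exp(logsum - m))) + 0.5 * np.log(2.0) + np.log(tau)
    if return_mode:
        return ll, bhat, tau
    return ll


def glmm_loglik(beta, sigma, y, X, code, n_groups, nodes, weights):
    """Marginal log-likelihood of the random-intercept binomial GLMM."""
    eta = X @ beta
    if sigma < _SIGMA_EPS:
        return float(np.sum(_bernoulli_ll(y, eta)))
    ll = 0.0
    for g in range(n_groups):
        ix = code == g
        ll += _agq_group_ll(y[ix], eta[ix], sigma, nodes, weights)
    return float(ll)


@dataclass
class GLMMFit:
    """Fitted binomial random-intercept GLMM."""

    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    names: list[str]
    sigma_id: float
    loglik: float
    fitted_p: np.ndarray            # conditional on the estimated modes
    fitted_p_marginal: np.ndarray   # fixed effects only
    phi: float
    conditional_mode: np.ndarray
    mode_sd: np.ndarray
    group_levels: list
    converged: bool
    n_obs: int
    n_groups: int
    quadrature_nodes: int
    y: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    group_code: np.ndarray = field(repr=False, default=None)

    @property
    def sigma2_id(self) -> float:
        return self.sigma_id ** 2

    def ci_contains_zero(self, term: str) -> bool:
        j = self.names.index(term)
        return bool(self.ci_low[j] <= 0.0 <= self.ci_high[j])


def fit_glmm_binomial(
    y,
    X,
    groups,
    names=None,
    quadrature_nodes: int = 15,
    n_sim: int = 10_000,
    seed: int | None = 0,
) -> GLMMFit:
    """ML fit of a binomial GLMM with a by-group random intercept.

    ``X`` must already contain the intercept column.  ``quadrature_nodes=1``
    gives the Laplace approximation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    code, levels = _group_index(groups)
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("at least 2 individuals are required")
    nodes, weights = hermgauss(quadrature_nodes)

    def negll(theta):
        return -glmm_loglik(theta[:-1], theta[-1], y, X, code, n_groups, nodes, weights)

    # warm start at the plain-logistic solution
    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    x0 = np.append(glm.params, 0.5)
    bounds = [(None, None)] * X.shape[1] + [(0.0, None)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    beta = res.x[:-1]
    sigma = float(res.x[-1])
    loglik = -float(res.fun)

    # Wald covariance from the numerical Hessian at the optimum
    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(res.x, negll)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(len(res.x), np.nan)
    se = se_all[:-1]
    zcrit = stats.norm.ppf(0.975)

    eta_fix = X @ beta
    modes = np.zeros(n_groups)
    taus = np.zeros(n_groups)
    if sigma >= _SIGMA_EPS:
        for g in range(n_groups):
            ix = code == g
            b, h = _group_mode(y[ix], eta_fix[ix], sigma * sigma)
            modes[g] = b
            taus[g] = 1.0 / np.sqrt(h)
    rng = np.random.default_rng(seed)
    if sigma >= _SIGMA_EPS:
        draws = rng.standard_normal((n_sim, n_groups)) * taus + modes
        mode_sd = draws.std(axis=0, ddof=1)
    else:
        mode_sd = np.zeros(n_groups)

    fitted_cond = expit(eta_fix + modes[code])
    fitted_marg = expit(eta_fix)
    resid_df = max(len(y) - X.shape[1] - 1, 1)
    pearson = np.sum((y - fitted_cond) ** 2 / (fitted_cond * (1.0 - fitted_cond)))
    phi = float(pearson / resid_df)

    return GLMMFit(
        beta=beta,
        se=se,
        ci_low=beta - zcrit * se,
        ci_high=beta + zcrit * se,
        names=list(names),
        sigma_id=sigma,
        loglik=loglik,
        fitted_p=fitted_cond,
        fitted_p_marginal=fitted_marg,
        phi=phi,
        conditional_mode=modes,
        mode_sd=mode_sd,
        group_levels=levels,
        converged=bool(res.success),
        n_obs=len(y),
        n_groups=n_groups,
        quadrature_nodes=quadrature_nodes,
        y=y,
        X=X,
        group_code=code,
    )


# ---------------------------------------------------------------------------
# Inference on the fitted model
# ---------------------------------------------------------------------------

def fit_glm_binomial(y, X, names=None):
    """Plain logistic regression (the sigma_id = 0 reduced model)."""
    import statsmodels.api as sm

    glm = sm.GLM(np.asarray(y, float), np.asarray(X, float),
                 family=sm.families.Binomial()).fit()
    return {
        "beta": np.asarray(glm.params),
        "se": np.asarray(glm.bse),
        "loglik": float(glm.llf),
        "names": list(names) if names is not None else None,
    }


def lrt_random_effect(loglik_full: float, loglik_reduced: float, df: int = 1):
    """Likelihood-ratio test of a variance component.

    ``df`` is the number of (co)variance parameters added by the full model:
    1 for a random intercept, 2 for a random slope plus its covariance.  The
    naive chi-square reference is conservative at the boundary sigma = 0.
    """
    chi2 = 2.0 * (loglik_full - loglik_reduced)
    if chi2 < -1e-6:
        raise ValueError("full model has lower log-likelihood than the reduced model")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return float(chi2), df, p


@dataclass
class RepeatabilityEstimate:
    r_adj: float
    sigma2_id: float
    sigma2_dist: float
    lrt_chi2: float = np.nan
    lrt_df: int = 1
    p: float = np.nan


def adjusted_repeatability(fit: GLMMFit, use: str = "conditional") -> RepeatabilityEstimate:
    """Adjusted repeatability on the latent (logit) scale.

    The observation-level variance is obtained via the delta method,
    sigma2_dist = 1 / (pbar (1 - pbar)), with pbar the mean fitted
    probability (conditional fitted values by default; ``use="marginal"``
    switches to fixed-effects-only fitted values).
    """
    p = fit.fitted_p if use == "conditional" else fit.fitted_p_marginal
    pbar = float(np.mean(p))
    if pbar <= 0.0 or pbar >= 1.0:
        raise ValueError("mean fitted probability at the boundary; R_adj undefined")
    sigma2_dist = 1.0 / (pbar * (1.0 - pbar))
    s2 = fit.sigma2_id
    return RepeatabilityEstimate(
        r_adj=s2 / (s2 + sigma2_dist), sigma2_id=s2, sigma2_dist=sigma2_dist
    )


def sigma_id_for_repeatability(r_adj: float, pbar: float = 0.5) -> float:
    """Latent intercept SD implying a target adjusted repeatability.

    Inverts R_adj = s2 / (s2 + 1/(pbar(1-pbar))); used to parameterize
    simulations by a repeatability target rather than a raw variance.
    """
    if not 0.0 <= r_adj < 1.0:
        raise ValueError("r_adj must be in [0, 1)")
    sigma2_dist = 1.0 / (pbar * (1.0 - pbar))
    return float(np.sqrt(r_adj / (1.0 - r_adj) * sigma2_dist))


def r2_nakagawa(fit: GLMMFit) -> tuple[float, float]:
    """Variance-partition marginal and conditional R^2 on the latent scale."""
    eta_fix = fit.X @ fit.beta
    var_f = float(np.var(eta_fix, ddof=0))
    sigma2_dist = adjusted_repeatability(fit).sigma2_dist
    denom = var_f + fit.sigma2_id + sigma2_dist
    return var_f / denom, (var_f + fit.sigma2_id) / denom


def effect_size_r(fit: GLMMFit, term: str) -> float:
    """Per-covariate effect size |r| from a variance-partition semi-partial R^2."""
    j = fit.names.index(term)
    var_x = float(np.var(fit.X[:, j], ddof=0))
    sigma2_dist = adjusted_repeatability(fit).sigma2_dist
    eta_fix = fit.X @ fit.beta
    denom = float(np.var(eta_fix, ddof=0)) + fit.sigma2_id + sigma2_dist
    return float(np.sqrt(fit.beta[j] ** 2 * var_x / denom))


def conditional_modes(fit: GLMMFit) -> pd.DataFrame:
    """Per-individual tendency (conditional mode) and simulation SD."""
    return pd.DataFrame(
        {
            "individual_id": fit.group_levels,
            "mode": fit.conditional_mode,
            "sd": fit.mode_sd,
        }
    )


def backward_prune_interactions(
    df: pd.DataFrame,
    y_col: str,
    base_terms: list[str],
    interactions: list[str],
    groups_col: str,
    **fit_kwargs,
) -> tuple[GLMMFit, list[str]]:
    """Single-step backward pruning of weak interactions.

    Fits the model with all ``interactions``, removes simultaneously every
    interaction whose Wald 95% CI covers zero, and refits.  Returns the final
    fit and the list of retained interactions.
    """
    terms = base_terms + interactions
    X, names = build_design(df, terms)
    full = fit_glmm_binomial(df[y_col], X, df[groups_col], names=names, **fit_kwargs)
    kept = [t for t in interactions if not full.ci_contains_zero(t)]
    if kept == interactions:
        return full, kept
    X2, names2 = build_design(df, base_terms + kept)
    final = fit_glmm_binomial(df[y_col], X2, df[groups_col], names=names2, **fit_kwargs)
    return final, kept


# ---------------------------------------------------------------------------
# Random-slope (reaction norm) models, Laplace approximation
# ---------------------------------------------------------------------------

def _slope_group_mode(y, eta_fix, z, prec, max_iter=50, tol=1e-10):
    """2-D Newton mode of one individual's (intercept, slope) deviation."""
    b = np.zeros(2)
    Z = np.column_stack([np.ones_like(z), z])
    for _ in range(max_iter):
        eta = eta_fix + Z @ b
        p = expit(eta)
        g = Z.T @ (y - p) - prec @ b
        w = p * (1.0 - p)
        H = -(Z.T * w) @ Z - prec
        step = np.linalg.solve(H, g)
        if np.linalg.norm(step) > 10.0:
            step = step / np.linalg.norm(step) * 10.0
        b = b - step
        if np.linalg.norm(step) < tol:
            break
    eta = eta_fix + Z @ b
    w = expit(eta) * (1.0 - expit(eta))
    H = (Z.T * w) @ Z + prec
    return b, H


def _slope_loglik(beta, chol_params, y, X, z, code, n_groups):
    l11, l21, l22 = chol_params
    L = np.array([[l11, 0.0], [l21, l22]])
    cov = L @ L.T + 1e-10 * np.eye(2)
    sign, logdet = np.linalg.slogdet(cov)
    prec = np.linalg.inv(cov)
    eta_fix = X @ beta
    ll = 0.0
    for g in range(n_groups):
        ix = code == g
        yg, ef, zg = y[ix], eta_fix[ix], z[ix]
        b, H = _slope_group_mode(yg, ef, zg, prec)
        Zg = np.column_stack([np.ones_like(zg), zg])
        eta = ef + Zg @ b
        h_val = (
            np.sum(_bernoulli_ll(yg, eta))
            - 0.5 * b @ prec @ b
            - 0.5 * logdet
            - _LOG2PI
        )
        _, logdetH = np.linalg.slogdet(H)
        ll += h_val + _LOG2PI - 0.5 * logdetH
    return float(ll)


@dataclass
class RandomSlopeResult:
    term: str
    loglik_full: float
    loglik_reduced: float
    lrt_chi2: float
    lrt_df: int
    p: float
    sigma_int: float
    sigma_slope: float
    cov_int_slope: float
    converged: bool


def random_slope_model(
    df: pd.DataFrame,
    y_col: str,
    base_terms: list[str],
    slope_term: str,
    groups_col: str,
) -> RandomSlopeResult:
    """Reaction-norm model for one environmental covariate.

    Full model: random intercept + random slope on ``slope_term`` with their
    covariance (Laplace).  Reduced: random intercept only (one-node
    quadrature, i.e. Laplace, for a like-for-like likelihood comparison).
    LRT df = 2 (slope variance + covariance).
    """
    if slope_term not in base_terms:
        raise ValueError("slope_term must be one of the fixed terms")
    X, names = build_design(df, base_terms)
    y = df[y_col].to_numpy(dtype=float)
    z = df[slope_term].to_numpy(dtype=float)
    code, levels = _group_index(df[groups_col])
    n_groups = len(levels)

    reduced = fit_glmm_binomial(y, X, df[groups_col], names=names, quadrature_nodes=1)

    def negll(theta):
        return -_slope_loglik(theta[: X.shape[1]], theta[X.shape[1]:], y, X, z, code, n_groups)

    x0 = np.concatenate([reduced.beta, [max(reduced.sigma_id, 0.1), 0.0, 0.1]])
    bounds = [(None, None)] * X.shape[1] + [(0.0, None), (None, None), (0.0, None)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 400, "ftol": 1e-12})
    l11, l21, l22 = res.x[X.shape[1]:]
    cov = np.array([[l11, 0.0], [l21, l22]]) @ np.array([[l11, l21], [0.0, l22]])
    ll_full = -float(res.fun)
    chi2, dfree, p = lrt_random_effect(max(ll_full, reduced.loglik), reduced.loglik, df=2)
    return RandomSlopeResult(
        term=slope_term,
        loglik_full=ll_full,
        loglik_reduced=reduced.loglik,
        lrt_chi2=chi2,
        lrt_df=dfree,
        p=p,
        sigma_int=float(np.sqrt(cov[0, 0])),
        sigma_slope=float(np.sqrt(cov[1, 1])),
        cov_int_slope=float(cov[0, 1]),
        converged=bool(res.success),
    )
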