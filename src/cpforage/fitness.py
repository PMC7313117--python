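"""Condition and fitness proxies, and their association with the individual
tendency to perform dynamic-foraging trips.

* SMI — scaled mass index: body mass standardized to the mean skeletal size
  via the standardized-major-axis (SMA) allometric slope of ln(mass) on
  ln(keel length).
* DBMI — daily body mass increase: brood mean of each nestling's daily
  relative mass gain between two measurement days.
* Weighted Pearson correlations (weights = inverse SD of the individual
  tendency) with permutation p-values: exhaustive enumeration for n <= 7,
  otherwise Monte-Carlo with the +1 smoothing p = (1 + #extreme) / (B + 1).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Condition / growth indices
# ---------------------------------------------------------------------------

def sma_slope(x, y) -> float:
    """Standardized-major-axis slope of y on x: b_OLS / r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r) or r == 0.0:
        raise ValueError("zero correlation: SMA slope undefined")
    b_ols = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    return float(b_ols / r)


def scaled_mass_index(mass, keel) -> np.ndarray:
    """SMI_i = M_i * (L0 / L_i)^b with L0 the mean keel and b the SMA slope
    of ln(mass) on ln(keel).  When keel lengths are all equal, SMI == mass."""
    mass = np.asarray(mass, dtype=float)
    keel = np.asarray(keel, dtype=float)
    if len(mass) < 3:
        raise ValueError("at least 3 individuals are required")
    if np.any(mass <= 0) or np.any(keel <= 0):
        raise ValueError("mass and keel must be positive")
    l0 = keel.mean()
    if np.allclose(keel, keel[0]):
        return mass.copy()
    b = sma_slope(np.log(keel), np.log(mass))
    return mass * (l0 / keel) ** b


def dbmi(brood: pd.DataFrame) -> float:
    """Brood-level daily body mass increase.

    ``brood`` rows are nestlings with columns ``bm_first`` (g), ``bm_second``
    (g, NaN when the nestling died before the second visit) and ``i_days``
    (days between the two measurements).  The average runs over the m
    survivors that have both measurements.
    """
    ok = brood.dropna(subset=["bm_second"])
    m = len(ok)
    if m < 1:
        raise ValueError("no nestlings with both measurements")
    gains = (
        (ok["bm_second"].to_numpy(dtype=float) - ok["bm_first"].to_numpy(dtype=float))
        / ok["bm_first"].to_numpy(dtype=float)
        / ok["i_days"].to_numpy(dtype=float)
    )
    return float(gains.mean())


def residualize(y, predictors: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of y on an intercept plus predictor columns."""
    y = np.asarray(y, dtype=float)
    P = np.asarray(predictors, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    X = np.column_stack([np.ones(len(y)), P])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("predictor matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def feeding_frequency(n_trips: int, tracked_hours: float) -> float:
    """Foraging trips per device-on hour (nestling-rearing birds only)."""
    if tracked_hours <= 0:
        raise ValueError("tracked hours must be positive")
    return float(n_trips) / float(tracked_hours)


# ---------------------------------------------------------------------------
# Weighted correlation + randomization
# ---------------------------------------------------------------------------

def weighted_corr(x, y, w) -> float:
    """Weighted Pearson correlation with weighted means and variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if len(x) < 3:
        raise ValueError("at least 3 pairs are required")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    cov = np.sum(w * (x - xm) * (y - ym))
    vx = np.sum(w * (x - xm) ** 2)
    vy = np.sum(w * (y - ym) ** 2)
    if not (np.isfinite(vx) and np.isfinite(vy)) or vx <= 0 or vy <= 0:
        raise ValueError("zero or undefined weighted variance")
    return float(cov / math.sqrt(vx * vy))


def randomization_test(x, y, w, n_perm: int = 9999, seed: int | None = 0) -> float:
    """Two-sided permutation p-value for the weighted correlation.

    ``y`` is shuffled while (x, w) stay paired.  For n <= 7 all n! pairings
    are enumerated exactly; otherwise ``n_perm`` random shuffles are drawn
    and p = (1 + #{|r*| >= |r_obs|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    r_obs = abs(weighted_corr(x, y, w))
    n = len(y)
    if n <= 7:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(weighted_corr(x, y[list(perm)], w))
            count += r >= r_obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    yy = y.copy()
    for _ in range(n_perm):
        rng.shuffle(yy)
        if abs(weighted_corr(x, yy, w)) >= r_obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def correlate_tendency(
    adults: pd.DataFrame,
    targets: dict[str, str] | None = None,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Weighted correlations between individual DF tendency and fitness proxies.

    ``adults`` must hold ``tendency`` (conditional mode, logit scale),
    ``tendency_sd`` and the target columns.  Weights are 1/SD.  Relative
    device load (``device_load``) is analysed separately per sex.  Targets
    with fewer than 3 complete pairs are skipped.
    """
    if targets is None:
        targets = {
            "residual_smi": "residual_smi",
            "breeding_success": "breeding_success",
            "residual_dbmi": "residual_dbmi",
            "residual_feeding_freq": "residual_feeding_freq",
        }
    rows = []
    for name, col in targets.items():
        if col not in adults.columns:
            continue
        sub = adults.dropna(subset=["tendency", "tendency_sd", col])
        if len(sub) < 3:
            continue
        w = 1.0 / np.maximum(sub["tendency_sd"].to_numpy(dtype=float), 1e-8)
        x = sub["tendency"].to_numpy(dtype=float)
        y = sub[col].to_numpy(dtype=float)
        try:
            r = weighted_corr(x, y, w)
            p = randomization_test(x, y, w, n_perm=n_perm, seed=seed)
        except ValueError:
            continue
        rows.append({"target": name, "n": len(sub), "r_w": r, "p_rand": p})
    if "device_load" in adults.columns and "sex" in adults.columns:
        for sex, sub in adults.groupby("sex"):
            sub = sub.dropna(subset=["tendency", "tendency_sd", "device_load"])
            if len(sub) < 3:
                continue
            w = 1.0 / np.maximum(sub["tendency_sd"].to_numpy(dtype=float), 1e-8)
            try:
                r = weighted_corr(sub["tendency"], sub["device_load"], w)
                p = randomization_test(sub["tendency"], sub["device_load"], w,
                                       n_perm=n_perm, seed=seed)
            except ValueError:
                continue
            rows.append(
                {"target": f"device_load_sex{sex}", "n": len(sub), "r_w": r, "p_rand": p}
            )
    return pd.DataFrame(rows, columns=["target", "n", "r_w", "p_rand"])
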