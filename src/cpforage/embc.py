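"""Binary expectation-maximization clustering of GPS fixes into four
behavioural modes from instantaneous velocity and absolute turning angle.

A 4-component bivariate Gaussian mixture is fitted in (speed, |turn|) space,
initialized from the four quadrants of the per-axis medians.  After
convergence each axis is split at the midpoint between its two "low" and two
"high" component means, and components are mapped to modes by the side of the
splits their means fall on:

* low speed, low turn   -> ``perch``
* low speed, high turn  -> ``intensive_search``
* high speed, low turn  -> ``relocation``
* high speed, high turn -> ``extensive_search``

A post-hoc temporal smoothing pass corrects isolated, uncertain labels inside
runs of a predominant mode (the mixture itself ignores temporal order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODES = ("perch", "intensive_search", "extensive_search", "relocation")

# quadrant order used internally for the 4 mixture components:
# (low s, low t), (low s, high t), (high s, low t), (high s, high t)
_QUADRANT_MODES = ("perch", "intensive_search", "relocation", "extensive_search")

_COV_FLOOR = 1e-8


@dataclass
class EMbCModel:
    means: np.ndarray          # (4, 2) component means in (speed, turn)
    covs: np.ndarray           # (4, 2, 2)
    weights: np.ndarray        # (4,)
    speed_split: float
    turn_split: float
    loglik: float
    n_iter: int
    converged: bool
    component_mode: tuple      # mode name per component
    loglik_trace: np.ndarray = None


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = x - mean
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
    maha = np.einsum("ni,ij,nj->n", diff, inv, diff)
    return -0.5 * (maha + np.log(det) + 2.0 * np.log(2.0 * np.pi))


def _floor_cov(cov: np.ndarray) -> np.ndarray:
    cov = cov.copy()
    cov[0, 0] = max(cov[0, 0], _COV_FLOOR)
    cov[1, 1] = max(cov[1, 1], _COV_FLOOR)
    # keep positive definite: cap correlation magnitude
    lim = 0.999 * np.sqrt(cov[0, 0] * cov[1, 1])
    cov[0, 1] = np.clip(cov[0, 1], -lim, lim)
    cov[1, 0] = cov[0, 1]
    return cov


def embc_fit(points: np.ndarray, max_iter: int = 200, tol: float = 1e-6,
             seed: int | None = None) -> EMbCModel:
    """Fit the 4-mode binary clustering model to (speed, turn) pairs.

    ``seed`` is accepted for interface symmetry; the quadrant-median
    initialization makes the fit deterministic.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be (n, 2): speed and absolute turn")
    if not np.all(np.isfinite(x)):
        raise ValueError("points must be finite")
    n = len(x)
    if n < 50:
        raise ValueError("at least 50 points are required")
    if np.ptp(x[:, 0]) <= 0 or np.ptp(x[:, 1]) <= 0:
        raise ValueError("degenerate input: an axis has zero range")

    med = np.median(x, axis=0)
    low_s = x[:, 0] <= med[0]
    low_t = x[:, 1] <= med[1]
    quadrants = [low_s & low_t, low_s & ~low_t, ~low_s & low_t, ~low_s & ~low_t]

    means = np.zeros((4, 2))
    covs = np.zeros((4, 2, 2))
    weights = np.zeros(4)
    global_cov = _floor_cov(np.cov(x.T) + _COV_FLOOR * np.eye(2))
    for k, mask in enumerate(quadrants):
        if mask.sum() >= 4:
            means[k] = x[mask].mean(axis=0)
            covs[k] = _floor_cov(np.cov(x[mask].T) + _COV_FLOOR * np.eye(2))
            weights[k] = mask.sum() / n
        else:  # sparse quadrant: fall back to global spread
            means[k] = med + 0.1 * (k - 1.5) * np.sqrt(np.diag(global_cov))
            covs[k] = global_cov
            weights[k] = max(mask.sum(), 1) / n
    weights /= weights.sum()

    loglik = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        logp = np.stack(
            [np.log(weights[k]) + _mvn_logpdf(x, means[k], covs[k]) for k in range(4)],
            axis=1,
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        new_loglik = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        # M step
        nk = resp.sum(axis=0)
        weights = nk / n
        for k in range(4):
            if nk[k] < 1e-10:
                continue
            means[k] = resp[:, k] @ x / nk[k]
            diff = x - means[k]
            covs[k] = _floor_cov((resp[:, k][:, None] * diff).T @ diff / nk[k])

    speed_split, turn_split = _delimiters(means)
    component_mode = tuple(
        _quadrant_mode(means[k], speed_split, turn_split) for k in range(4)
    )
    return EMbCModel(
        means=means,
        covs=covs,
        weights=weights,
        speed_split=speed_split,
        turn_split=turn_split,
        loglik=loglik,
        n_iter=it,
        converged=converged,
        component_mode=component_mode,
        loglik_trace=np.array(trace),
    )


def _delimiters(means: np.ndarray) -> tuple[float, float]:
    """Per-axis split: midpoint between the 2nd and 3rd sorted component means."""
    s = np.sort(means[:, 0])
    t = np.sort(means[:, 1])
    return 0.5 * (s[1] + s[2]), 0.5 * (t[1] + t[2])


def _quadrant_mode(mean: np.ndarray, speed_split: float, turn_split: float) -> str:
    low_s = mean[0] < speed_split
    low_t = mean[1] < turn_split
    return _QUADRANT_MODES[(0 if low_s else 2) + (0 if low_t else 1)]


def embc_posteriors(model: EMbCModel, points: np.ndarray) -> np.ndarray:
    """Posterior mode probabilities, columns ordered as :data:`MODES`."""
    x = np.asarray(points, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(x)):
        raise ValueError("points must be finite")
    logp = np.stack(
        [
            np.log(model.weights[k]) + _mvn_logpdf(x, model.means[k], model.covs[k])
            for k in range(4)
        ],
        axis=1,
    )
    m = logp.max(axis=1, keepdims=True)
    resp = np.exp(logp - m)
    resp /= resp.sum(axis=1, keepdims=True)
    # aggregate components sharing a mode (possible in degenerate fits)
    post = np.zeros((len(x), 4))
    for k, mode in enumerate(model.component_mode):
        post[:, MODES.index(mode)] += resp[:, k]
    return post


def embc_label(model: EMbCModel, points: np.ndarray) -> tuple[list, np.ndarray]:
    """Label points with their maximum-posterior behavioural mode.

    Returns ``(labels, posteriors)`` with posterior columns in :data:`MODES`
    order.
    """
    post = embc_posteriors(model, points)
    labels = [MODES[i] for i in post.argmax(axis=1)]
    return labels, post


def smooth_labels(labels, posteriors, window: int = 5):
    """Margin-gated majority smoothing of a time-ordered label sequence.

    A fix's label is replaced by the strict-majority label of the centred
    ``window`` when that majority differs from the current label and the fix's
    posterior margin (top minus second probability) is below 0.5.  A single
    pass over the original labels; ties leave labels unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    labels = list(labels)
    post = np.asarray(posteriors, dtype=float)
    if len(labels) != len(post):
        raise ValueError("labels and posteriors differ in length")
    srt = np.sort(post, axis=1)
    margin = srt[:, -1] - srt[:, -2]
    half = window // 2
    out = list(labels)
    n = len(labels)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = labels[lo:hi]
        values, counts = np.unique(win, return_counts=True)
        best = counts.max()
        if best <= len(win) / 2.0:
            continue  # no strict majority
        if (counts == best).sum() > 1:
            continue  # tie
        maj = values[counts.argmax()]
        if maj != labels[i] and margin[i] < 0.5:
            out[i] = maj
    return out
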