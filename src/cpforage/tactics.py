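"""Foraging-tactic classification at the trip level.

Each trip is summarized by the proportions of the four behavioural modes
among its (smoothed) fix labels.  The number of clusters is chosen by a
majority consensus over several cluster-validity indices (including two that
can vote for "no clustering", k = 1), after which K-means with k = 2
partitions trips into a static-foraging (SF, perch-dominated) and a
dynamic-foraging (DF, flight-dominated) tactic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .embc import MODES

PROFILE_COLUMNS = ("p_perch", "p_intensive", "p_extensive", "p_relocation")
_PROFILE_MODES = ("perch", "intensive_search", "extensive_search", "relocation")

_W_FLOOR = 1e-12


def trip_profile(labels) -> np.ndarray:
    """Behaviour composition of a trip: proportions of the four modes.

    Order: perch, intensive search, extensive search, relocation.
    """
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("trip has no labelled fixes")
    unknown = set(labels) - set(MODES)
    if unknown:
        raise ValueError(f"unknown behaviour labels: {unknown}")
    n = float(len(labels))
    return np.array([labels.count(m) / n for m in _PROFILE_MODES])


def _wss(x: np.ndarray, k: int, seed, n_init: int = 5) -> tuple[float, np.ndarray]:
    if k == 1:
        centre = x.mean(axis=0)
        return float(((x - centre) ** 2).sum()), np.zeros(len(x), dtype=int)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return float(km.inertia_), km.labels_


def _gap_vote(x: np.ndarray, ks, seed, n_ref: int = 10) -> int:
    """Gap statistic (uniform reference over the feature bounding box).

    Votes for the smallest k with Gap(k) >= Gap(k+1) - s(k+1); may vote 1.
    """
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    log_w = np.array([np.log(max(_wss(x, k, seed)[0], _W_FLOOR)) for k in ks])
    ref_log_w = np.zeros((n_ref, len(ks)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_log_w[b] = [np.log(max(_wss(ref, k, seed)[0], _W_FLOOR)) for k in ks]
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return ks[i]
    return ks[-1]


def _hartigan_vote(x: np.ndarray, ks, seed, threshold: float = 10.0) -> int:
    """Hartigan's rule: smallest k with H(k) <= 10, H(k) = (W_k/W_{k+1}-1)(n-k-1)."""
    n = len(x)
    w = [max(_wss(x, k, seed)[0], _W_FLOOR) for k in list(ks) + [ks[-1] + 1]]
    for i, k in enumerate(ks):
        h = (w[i] / w[i + 1] - 1.0) * max(n - k - 1, 1)
        if h <= threshold:
            return k
    return ks[-1]


def select_k(profiles: np.ndarray, k_max: int = 8, seed: int | None = 0) -> tuple[int, dict]:
    """Consensus number of clusters over five validity indices.

    Gap and Hartigan can assess "no clustering" (k = 1); silhouette,
    Calinski-Harabasz and Davies-Bouldin only rank k >= 2.  The decision is
    hierarchical: first the k = 1-capable indices vote on whether any
    structure exists (ties broken toward the smaller k, i.e. toward no
    clustering); if structure is supported, the winner is the plurality vote
    of all five indices over k >= 2, ties again toward the smaller k.

    Returns ``(k_star, votes)`` where ``votes`` maps index name -> voted k.
    """
    x = np.asarray(profiles, dtype=float)
    if len(x) < 10:
        raise ValueError("at least 10 profiles are required")
    if len(x) <= k_max:
        k_max = max(2, len(x) - 1)
    ks_all = list(range(1, k_max + 1))
    ks_multi = list(range(2, k_max + 1))

    votes = {}
    votes["gap"] = _gap_vote(x, ks_all, seed)
    votes["hartigan"] = _hartigan_vote(x, ks_all, seed)

    sil, ch, db = {}, {}, {}
    for k in ks_multi:
        _, lab = _wss(x, k, seed)
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = silhouette_score(x, lab)
        ch[k] = calinski_harabasz_score(x, lab)
        db[k] = davies_bouldin_score(x, lab)
    votes["silhouette"] = max(sorted(sil), key=lambda k: sil[k])
    votes["calinski_harabasz"] = max(sorted(ch), key=lambda k: ch[k])
    votes["davies_bouldin"] = min(sorted(db), key=lambda k: db[k])

    # stage 1: is there any clustering at all?
    gate = [votes["gap"], votes["hartigan"]]
    n_one = sum(1 for v in gate if v == 1)
    if n_one * 2 >= len(gate):  # majority or tie -> no clustering
        return 1, votes
    # stage 2: plurality over the k >= 2 votes of all five indices
    multi_votes = [v for v in votes.values() if v >= 2]
    tally = pd.Series(multi_votes).value_counts()
    best = tally.max()
    k_star = int(min(k for k, c in tally.items() if c == best))
    return k_star, votes


def kmeans_tactics(
    profiles: np.ndarray,
    k: int = 2,
    n_restarts: int = 100,
    max_iter: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """K-means partition of trip profiles, mapped to SF/DF tactics.

    The 10,000-iteration budget is spent as ``n_restarts`` random restarts of
    at most ``max_iter`` Lloyd iterations each; the lowest-inertia solution is
    kept.  The cluster whose centroid has the higher perching proportion is
    labelled SF, the other DF (only for k = 2).

    Returns a DataFrame with ``cluster_id``, ``tactic`` and
    ``distance_to_centroid`` rows aligned with ``profiles``.
    """
    x = np.asarray(profiles, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(x) < k:
        raise ValueError("fewer profiles than clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter, random_state=seed)
    cluster = km.fit_predict(x)
    centroids = km.cluster_centers_
    dist = np.linalg.norm(x - centroids[cluster], axis=1)
    out = pd.DataFrame({"cluster_id": cluster, "distance_to_centroid": dist})
    if k == 2:
        sf_cluster = int(np.argmax(centroids[:, PROFILE_COLUMNS.index("p_perch")]))
        out["tactic"] = np.where(cluster == sf_cluster, "SF", "DF")
    else:
        out["tactic"] = [f"cluster_{c}" for c in cluster]
    out.attrs["centroids"] = centroids
    out.attrs["inertia"] = float(km.inertia_)
    return out
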