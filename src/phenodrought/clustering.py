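"""Minimum within-group-sum-of-squares clustering of trait time profiles.

Traits are grouped by the shape of a per-day profile (mean drought
effect, genetic correlation, or correlation with a post-harvest trait)
using Lloyd-style k-means minimizing

    WSS = sum over clusters, sum over members ||profile - centroid||^2,

best-of-restarts with k-means++ seeding, for k = 1..k_max (default 10).
The number of groups is chosen from the scree of WSS values; the
automated stand-in for choosing the elbow by eye is the k maximizing the
second difference of the (non-increasing) curve, always overridable.

Profiles are clustered unscaled — drought effects are already on a
common percent scale and correlations on [-1, 1]; a z-scaling switch
exists for heterogeneous inputs.  Missing profile entries (days where a
genetic correlation is undefined) are ignored in distance sums, with
each profile-centroid distance normalized by the number of available
days so short profiles are not favoured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_K_MAX = 10
DEFAULT_RESTARTS = 100


def _scaled_sq_dist_matrix(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Profile-to-centroid squared distances, missing-aware.

    Sum over days available in both, rescaled by n_days / n_available;
    infinite where no day overlaps.
    """
    diff = X[:, None, :] - centroids[None, :, :]
    avail = np.isfinite(diff)
    sq = np.where(avail, diff * diff, 0.0).sum(axis=2)
    n_avail = avail.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sq * (X.shape[1] / n_avail)
    out[n_avail == 0] = np.inf
    return out


def _scaled_sq_dist(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return _scaled_sq_dist_matrix(x[None, :], centroids)[0]


def _wss(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    d = _scaled_sq_dist_matrix(X, centroids)
    return float(d[np.arange(X.shape[0]), labels].sum())


def _centroids(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    cents = np.full((k, X.shape[1]), np.nan)
    for j in range(k):
        members = X[labels == j]
        if len(members):
            avail = np.isfinite(members)
            n = avail.sum(axis=0)
            s = np.where(avail, members, 0.0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cents[j] = np.where(n > 0, s / n, np.nan)
    return cents


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    first = rng.integers(n)
    idx = [first]
    d2 = _scaled_sq_dist_matrix(X, X[[first]]).min(axis=1)
    for _ in range(1, k):
        probs = d2.copy()
        if not np.isfinite(probs).all() or probs.sum() <= 0:
            cand = rng.integers(n)
        else:
            cand = rng.choice(n, p=probs / probs.sum())
        idx.append(int(cand))
        d2 = np.minimum(d2, _scaled_sq_dist_matrix(X, X[[cand]]).min(axis=1))
    return X[idx].copy()


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    cents = _kmeanspp_init(X, k, rng)
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d = _scaled_sq_dist_matrix(X, cents)
        new_labels = d.argmin(axis=1)
        # re-seed empty clusters with the worst-fitted profile
        for j in range(k):
            if not (new_labels == j).any():
                worst = int(d[np.arange(len(new_labels)), new_labels].argmax())
                new_labels[worst] = j
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        cents = _centroids(X, labels, k)
    return labels, cents, _wss(X, labels, cents)


@dataclass
class ProfileClustering:
    """Partition of trait profiles for one k."""

    labels: pd.Series          # trait -> 1-based cluster label
    centroids: pd.DataFrame    # cluster label x day
    wss: float
    k: int

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cluster_profiles(profiles: pd.DataFrame, k: int,
                     restarts: int = DEFAULT_RESTARTS, seed: int = 0,
                     scale: bool = False) -> ProfileClustering:
    """Best-of-restarts WSS clustering of a trait-by-day profile matrix.

    Rows with no finite entry are rejected; ``scale`` optionally
    z-scores each day column first (off by default).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(profiles)})")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).any(axis=1).all():
        bad = profiles.index[~np.isfinite(X).any(axis=1)].tolist()
        raise ValueError(f"profiles with no finite entries: {bad[:10]}")
    if scale:
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    if k == len(profiles):
        labels = np.arange(k)
        cents = X.copy()
        best = (labels, cents, _wss(X, labels, cents))
    elif k == 1:
        labels = np.zeros(len(X), dtype=int)
        cents = _centroids(X, labels, 1)
        best = (labels, cents, _wss(X, labels, cents))
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(restarts):
            cand = _lloyd(X, k, rng)
            if best is None or cand[2] < best[2]:
                best = cand
    labels, cents, wss = best
    # canonical labelling: clusters numbered by first appearance
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    mapped = np.array([order[lab] for lab in labels])
    cent_rows = {order[j]: cents[j] for j in set(labels)}
    centroids = pd.DataFrame.from_dict(cent_rows, orient="index",
                                       columns=profiles.columns).sort_index()
    return ProfileClustering(
        labels=pd.Series(mapped, index=profiles.index, name="cluster"),
        centroids=centroids, wss=wss, k=k,
    )


def wss_curve(profiles: pd.DataFrame, k_max: int = DEFAULT_K_MAX,
              restarts: int = DEFAULT_RESTARTS, seed: int = 0,
              scale: bool = False) -> np.ndarray:
    """WSS for k = 1..min(k_max, n profiles), forced non-increasing."""
    k_top = min(k_max, len(profiles))
    vals = [cluster_profiles(profiles, k, restarts, seed, scale).wss
            for k in range(1, k_top + 1)]
    return np.minimum.accumulate(np.asarray(vals))


@dataclass
class KSelection:
    k: int
    ambiguous: bool
    second_differences: np.ndarray


def choose_k(wss: np.ndarray, fallback_k: int = 2,
             rel_tol: float = 1e-6) -> KSelection:
    """Automated scree-elbow: k maximizing the second difference of the
    *log* WSS curve, log WSS(k-1) - 2 log WSS(k) + log WSS(k+1), over
    2 <= k <= k_max - 1.

    The log scale makes the elbow scale-free: a geometric (elbow-less)
    decay is exactly linear in log and yields the configured fallback
    with the ambiguity flag set, while the k after which the curve
    flattens maximizes the log second difference regardless of how
    unequal the cluster separations are.  Degenerate cases: an
    all-(near-)zero curve means identical profiles (k = 1); a WSS
    reaching ~0 at some k means exactly that many distinct profiles.
    """
    wss = np.minimum.accumulate(np.asarray(wss, dtype=float))
    k_max = wss.size
    if wss[0] <= rel_tol * max(1.0, abs(wss[0])):
        return KSelection(1, False, np.array([]))
    tiny = wss <= rel_tol * wss[0]
    if tiny.any():
        return KSelection(int(np.argmax(tiny)) + 1, False, np.array([]))
    if k_max < 3:
        return KSelection(1, False, np.array([]))
    lw = np.log(wss)
    second = lw[:-2] - 2.0 * lw[1:-1] + lw[2:]  # indexed by k = 2..k_max-1
    if second.max() <= rel_tol:
        return KSelection(fallback_k, True, second)
    k = int(np.argmax(second)) + 2
    return KSelection(k, False, second)


@dataclass
class JointClassification:
    """Simultaneous classification of traits under two clusterings."""

    pairs: pd.Series           # trait -> (labelA, labelB)
    crosstab: pd.DataFrame     # A label x B label counts

    @property
    def n_combined(self) -> int:
        """Number of non-empty cells, i.e. distinct combined clusters."""
        return int((self.crosstab.to_numpy() > 0).sum())

    def category_of(self, trait) -> tuple:
        return self.pairs.loc[trait]


def merge_labels(labels: pd.Series, merge_map: dict) -> pd.Series:
    """Collapse cluster labels by a mapping {old: merged}; labels not in
    the map keep their value.  The merged labels must partition the set."""
    return labels.map(lambda v: merge_map.get(v, v))


def joint_classification(labels_a: pd.Series, labels_b: pd.Series,
                         merge_map_a: dict | None = None,
                         merge_map_b: dict | None = None) -> JointClassification:
    """Cross-tabulate two clusterings of the same trait set."""
    only_a = set(labels_a.index) - set(labels_b.index)
    only_b = set(labels_b.index) - set(labels_a.index)
    if only_a or only_b:
        raise ValueError(
            f"trait sets differ between labelings (only in A: {sorted(only_a)[:5]}, "
            f"only in B: {sorted(only_b)[:5]})"
        )
    a = merge_labels(labels_a, merge_map_a) if merge_map_a else labels_a
    b = merge_labels(labels_b, merge_map_b) if merge_map_b else labels_b
    b = b.reindex(a.index)
    pairs = pd.Series(list(zip(a, b)), index=a.index, name="joint")
    crosstab = pd.crosstab(a, b)
    return JointClassification(pairs=pairs, crosstab=crosstab)
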