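"""Two-step k-means profiling of participants on the four model parameters.

k-means is run for k = 2..7 under three distances (euclidean, cityblock,
correlation) with seeded multi-restart greedy (k-means++-style) seeding;
the solution maximizing the mean silhouette — computed under the same
distance — is selected. The largest cluster of the winning solution is
then re-clustered with the identical procedure, yielding combined labels
such as 1, 2a, 2b, 2c, 3. Stability is assessed by resampling participants
with replacement, re-running the two-step procedure, and matching
resampled cluster profiles to the original ones by maximal Pearson
correlation.

Centroid updates follow the distance: coordinate-wise mean for euclidean,
coordinate-wise median for cityblock (the L1 minimizer), and the
row-standardized mean for correlation distance (1 - Pearson across the
four parameters). Parameters are z-standardized by default before
clustering, because the learning rates live on [0, 1] while the exponents
live on [0, 5] and would otherwise dominate; a raw-scale mode is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterSolution",
    "TwoStepSolution",
    "kmeans",
    "select_clustering",
    "two_step_cluster",
    "cluster_profiles",
    "bootstrap_validate",
    "METRICS",
]

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "cityblock", "correlation")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def _update_centers(X: np.ndarray, labels: np.ndarray, k: int, metric: str, rng) -> np.ndarray:
    centers = np.empty((k, X.shape[1]))
    for c in range(k):
        members = X[labels == c]
        if len(members) == 0:  # re-seed empty cluster at a random point
            centers[c] = X[rng.integers(len(X))]
        elif metric == "cityblock":
            centers[c] = np.median(members, axis=0)
        elif metric == "correlation":
            centers[c] = _standardize_rows(members).mean(axis=0)
        else:
            centers[c] = members.mean(axis=0)
    return centers


def _greedy_seed(X: np.ndarray, k: int, metric: str, rng) -> np.ndarray:
    """k-means++-style seeding under the chosen metric."""
    centers = [X[rng.integers(len(X))]]
    while len(centers) < k:
        dist = cdist(X, np.array(centers), metric=metric).min(axis=1)
        total = dist.sum()
        if total <= 0:
            centers.append(X[rng.integers(len(X))])
            continue
        centers.append(X[rng.choice(len(X), p=dist / total)])
    return np.array(centers)


def kmeans(
    X: np.ndarray,
    k: int,
    metric: str = "euclidean",
    n_restarts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Lloyd iterations under the given distance; returns (labels, inertia).

    Inertia is the summed point-to-assigned-center distance under the same
    metric; the best of ``n_restarts`` seeded restarts is returned.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        centers = _greedy_seed(X, k, metric, rng)
        labels = None
        for _it in range(max_iter):
            dist = cdist(X, centers, metric=metric)
            new_labels = dist.argmin(axis=1)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centers = _update_centers(X, labels, k, metric, rng)
        inertia = float(cdist(X, centers, metric=metric)[np.arange(len(X)), labels].sum())
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels.copy()
    return best_labels, best_inertia


@dataclass
class ClusterSolution:
    labels: np.ndarray
    k: int
    metric: str
    silhouette: float
    selection_table: pd.DataFrame  # one row per (k, metric) tried
    warnings: list[str] = field(default_factory=list)


def select_clustering(
    X: np.ndarray,
    k_range: Sequence[int] = range(2, 8),
    metrics: Sequence[str] = METRICS,
    n_restarts: int = 20,
    seed: int = 0,
    standardize: bool = True,
) -> ClusterSolution:
    """Pick (k, metric) by maximal mean silhouette under the same metric."""
    X = np.asarray(X, dtype=float)
    if standardize:
        X = _zscore_columns(X)
    if len(X) <= max(k_range):
        raise ValueError("need more participants than the largest k")
    warns: list[str] = []
    usable = []
    for metric in metrics:
        if metric == "correlation" and np.any(X.std(axis=1) == 0):
            warns.append("correlation distance skipped: zero-variance rows present")
            logger.warning(warns[-1])
            continue
        usable.append(metric)
    rows = []
    best = None
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(usable) * len(list(k_range))))
    for metric in usable:
        for k in k_range:
            labels, inertia = kmeans(X, k, metric, n_restarts=n_restarts, seed=next(seeds))
            if len(np.unique(labels)) < 2:
                sil = -1.0
            else:
                sil = float(silhouette_score(X, labels, metric=metric))
            rows.append({"k": k, "metric": metric, "silhouette": sil, "inertia": inertia})
            if best is None or sil > best[0]:
                best = (sil, k, metric, labels)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no usable distance metric for these data")
    sil, k, metric, labels = best
    if sil < 0.5:  # Kaufman-Rousseeuw banding: below 0.5 = weak/no substantial structure
        warns.append(f"weak cluster structure: best mean silhouette {sil:.3f}")
        logger.warning(warns[-1])
    return ClusterSolution(labels=labels, k=k, metric=metric, silhouette=sil,
                           selection_table=table, warnings=warns)


@dataclass
class TwoStepSolution:
    first: ClusterSolution
    second: ClusterSolution | None
    refined_cluster: int | None  # first-level label that was re-clustered
    labels: np.ndarray  # combined string labels, e.g. "1", "2a", "2b"
    warnings: list[str] = field(default_factory=list)


def two_step_cluster(
    X: np.ndarray,
    k_range: Sequence[int] = range(2, 8),
    metrics: Sequence[str] = METRICS,
    n_restarts: int = 20,
    seed: int = 0,
    standardize: bool = True,
) -> TwoStepSolution:
    """First-level selection, then re-cluster the largest cluster.

    Combined labels number first-level clusters 1..k and suffix the
    re-clustered one with letters (``2a``, ``2b``, ...). If the largest
    cluster is too small for the second step it is skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    if standardize:
        X = _zscore_columns(X)
    first = select_clustering(X, k_range, metrics, n_restarts, seed=seed, standardize=False)
    sizes = np.bincount(first.labels, minlength=first.k)
    target = int(np.argmax(sizes))
    combined = np.array([str(l + 1) for l in first.labels], dtype=object)
    warns: list[str] = []
    second = None
    if sizes[target] <= max(k_range):
        warns.append(
            f"largest cluster has {sizes[target]} members <= max k {max(k_range)}; second step skipped"
        )
        logger.warning(warns[-1])
        return TwoStepSolution(first, None, None, combined.astype(str), warns)
    sub_idx = np.flatnonzero(first.labels == target)
    second = select_clustering(X[sub_idx], k_range, metrics, n_restarts, seed=seed + 1, standardize=False)
    letters = "abcdefghij"
    for pos, i in enumerate(sub_idx):
        combined[i] = f"{target + 1}{letters[second.labels[pos]]}"
    return TwoStepSolution(first, second, target, combined.astype(str), warns)


def cluster_profiles(labels: Sequence[str], table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.e.m. of every column of ``table`` per cluster label.

    The same code path serves model parameters and WCST scores.
    """
    df = table.copy()
    df["_cluster"] = list(labels)
    g = df.groupby("_cluster", sort=True)
    mean = g.mean()
    sem = g.sem(ddof=1)
    n = g.size()
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    out["n"] = n
    return out


def _match_profiles(orig: pd.DataFrame, new: pd.DataFrame) -> list[tuple[str, str, float]]:
    """Greedy matching of new to original cluster profiles by Pearson r."""
    pairs = []
    remaining_o = list(orig.index)
    remaining_n = list(new.index)
    cors = {}
    for o in remaining_o:
        for m in remaining_n:
            a, b = orig.loc[o].to_numpy(float), new.loc[m].to_numpy(float)
            if np.std(a) == 0 or np.std(b) == 0:
                cors[(o, m)] = -np.inf
            else:
                cors[(o, m)] = float(np.corrcoef(a, b)[0, 1])
    while remaining_o and remaining_n:
        o, m = max(((o, m) for o in remaining_o for m in remaining_n), key=lambda t: cors[t])
        pairs.append((o, m, cors[(o, m)]))
        remaining_o.remove(o)
        remaining_n.remove(m)
    return pairs


def bootstrap_validate(
    param_table: pd.DataFrame,
    score_table: pd.DataFrame | None = None,
    n_boot: int = 1000,
    frac: float = 0.5,
    k_range: Sequence[int] = range(2, 8),
    metrics: Sequence[str] = METRICS,
    n_restarts: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Cluster-stability check by resampling with replacement.

    Each resample draws ``round(frac * n)`` participants with replacement,
    re-runs the two-step clustering, and matches the resampled cluster
    mean-parameter profiles to the original solution's by maximal Pearson
    correlation. Returns one row per (resample, matched cluster) with the
    matched correlation; strong, replicable structure shows correlations
    near 1.
    """
    X = param_table.to_numpy(dtype=float)
    Xc = _zscore_columns(X) if standardize else X
    orig = two_step_cluster(Xc, k_range, metrics, n_restarts, seed=seed, standardize=False)
    orig_prof = cluster_profiles(orig.labels, param_table).loc[:, "mean"]
    rng = np.random.default_rng(seed)
    n_draw = int(round(frac * len(X)))
    rows = []
    for b in range(n_boot):
        idx = rng.integers(0, len(X), size=n_draw)
        Xb = Xc[idx]
        try:
            sol = two_step_cluster(Xb, k_range, metrics, n_restarts, seed=int(rng.integers(2**31)),
                                   standardize=False)
        except ValueError as exc:
            logger.warning("bootstrap resample %d failed: %s", b, exc)
            continue
        prof = cluster_profiles(sol.labels, param_table.iloc[idx].reset_index(drop=True)).loc[:, "mean"]
        for o, m, c in _match_profiles(orig_prof, prof):
            rows.append({"resample": b, "orig_cluster": o, "matched_cluster": m, "profile_correlation": c})
    return pd.DataFrame(rows)


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return (X - mu) / np.where(sd > 0, sd, 1.0)
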