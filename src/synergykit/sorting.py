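"""Sorting synergies into reference modules.

Synergy vectors from the reference (healthy) group are pooled into a
matrix D (muscles x k_total) and clustered with K-means (Lloyd
iterations on squared Euclidean distance, best of many random
initializations). The cluster count is chosen by maximizing the mean
silhouette coefficient, and the resulting centroids serve as the
reference synergies. Every subject's synergy vectors — both groups — are
then classified against the centroids by Pearson correlation: a synergy
is assigned to the best-correlated centroid when r > 0.6, otherwise it
stays unclassified. Activation-coefficient rows inherit the assignment
of their synergy vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import DataError


# ---------------------------------------------------------------------------
# K-means (Lloyd) with distortion monitoring


def _distortion(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    d = X - centroids[labels]
    return float(np.sum(d * d))


def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared Euclidean distance; ties broken toward the lowest cluster index
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def kmeans_cluster(
    D: np.ndarray,
    i: int,
    seed: int | None = None,
    n_init: int = 50,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cluster the columns of D (points = synergy vectors) into ``i`` groups.

    Lloyd iterations: assign each point to its nearest centroid, recompute
    centroids as cluster means, repeat until the distortion J changes by
    less than ``tol``. The best (lowest-J) of ``n_init`` random
    initializations is returned. An emptied cluster is re-seeded at the
    point farthest from its current centroid.

    Returns
    -------
    assignment : (k_total,) int array of cluster ids
    centroids : (m, i) array, one reference synergy per column
    J : float, final distortion
    """
    D = np.asarray(D, dtype=float)
    X = D.T  # points x features
    n_pts = X.shape[0]
    if not 1 <= i <= n_pts:
        raise DataError(f"cluster count {i} outside 1..{n_pts}")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        init = X[rng.choice(n_pts, size=i, replace=False)].copy()
        labels, centroids, J, _trace = _lloyd(X, init, max_iter, tol)
        if best is None or J < best[0]:
            best = (J, labels, centroids)
    J, labels, centroids = best
    return labels, centroids.T, J


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One Lloyd run from given centroids; returns the distortion trace.

    The trace is non-increasing except possibly at an empty-cluster
    re-seed (which strictly lowers J on the following assignment).
    """
    centroids = centroids.copy()
    i = centroids.shape[0]
    labels = _assign(X, centroids)
    J = _distortion(X, centroids, labels)
    trace = [J]
    for _it in range(max_iter):
        for c in range(i):
            members = labels == c
            if members.any():
                centroids[c] = X[members].mean(axis=0)
            else:
                # re-seed an emptied cluster at the farthest point
                far = np.argmax(((X - centroids[labels]) ** 2).sum(axis=1))
                centroids[c] = X[far]
        labels = _assign(X, centroids)
        J_new = _distortion(X, centroids, labels)
        trace.append(J_new)
        if J - J_new <= tol:
            J = J_new
            break
        J = J_new
    return labels.copy(), centroids, J, trace


def silhouette_mean(D: np.ndarray, assignment: np.ndarray) -> float:
    """Mean silhouette coefficient of a clustering of D's columns.

    Per point: s = (b - a) / max(a, b) with a the mean distance to other
    points in its own cluster and b the smallest mean distance to the
    points of any other cluster. Points in singleton clusters score 0, as
    do points where a = b = 0 (coincident data).
    """
    D = np.asarray(D, dtype=float)
    X = D.T
    labels = np.asarray(assignment)
    ids = np.unique(labels)
    if ids.size < 2:
        raise DataError("silhouette needs at least 2 clusters")
    dist = np.sqrt(np.maximum(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2), 0.0))
    scores = np.zeros(X.shape[0])
    for p in range(X.shape[0]):
        own = labels == labels[p]
        n_own = own.sum()
        if n_own == 1:
            scores[p] = 0.0
            continue
        a = dist[p, own].sum() / (n_own - 1)
        b = min(dist[p, labels == c].mean() for c in ids if c != labels[p])
        denom = max(a, b)
        scores[p] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


@dataclass
class ReferenceSynergySet:
    """Reference synergies: centroids of the clustered healthy-group pool."""

    centroids: np.ndarray  # (m, i)
    assignment: np.ndarray  # cluster id per pooled synergy vector
    distortion: float
    silhouette: float
    i: int
    silhouette_by_i: dict[int, float] = field(default_factory=dict)
    muscle_names: tuple[str, ...] | None = None

    @property
    def n_refs(self) -> int:
        return self.centroids.shape[1]


def select_cluster_number(
    D: np.ndarray,
    i_range=range(2, 9),
    seed: int | None = None,
    n_init: int = 50,
    muscle_names: tuple[str, ...] | None = None,
) -> ReferenceSynergySet:
    """Pick the cluster count maximizing the mean silhouette coefficient.

    Runs :func:`kmeans_cluster` for every i in ``i_range`` (default 2..8)
    and keeps the silhouette-optimal clustering; ties go to the smallest
    i. Deterministic for a fixed seed.
    """
    D = np.asarray(D, dtype=float)
    sil_by_i: dict[int, float] = {}
    runs: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    rng = np.random.default_rng(seed)
    for i in i_range:
        if i >= D.shape[1]:
            continue
        sub_seed = int(rng.integers(2**31))
        labels, centroids, J = kmeans_cluster(D, i, seed=sub_seed, n_init=n_init)
        sil_by_i[i] = silhouette_mean(D, labels)
        runs[i] = (labels, centroids, J)
    if not sil_by_i:
        raise DataError("i_range produced no admissible cluster counts")
    best_i = max(sorted(sil_by_i), key=lambda i: sil_by_i[i])
    labels, centroids, J = runs[best_i]
    return ReferenceSynergySet(
        centroids=centroids,
        assignment=labels,
        distortion=J,
        silhouette=sil_by_i[best_i],
        i=best_i,
        silhouette_by_i=sil_by_i,
        muscle_names=muscle_names,
    )


# ---------------------------------------------------------------------------
# Pearson-correlation classification against the reference set


@dataclass
class SynergyMatch:
    """Classification of one subject synergy against the reference set."""

    subject_id: str | None
    group: str | None
    synergy_index: int
    r_values: np.ndarray  # r against every centroid
    best_ref: int  # argmax-r centroid id
    classified: bool  # max r > r_min
    weights: np.ndarray  # the synergy vector (m,)
    coefficients: np.ndarray | None = None  # matching activation-coefficient row

    @property
    def r(self) -> float:
        return float(self.r_values[self.best_ref])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0:
        return np.nan
    return float(xs @ ys / denom)


def match_to_reference(
    W_subject: np.ndarray,
    refs: ReferenceSynergySet,
    r_min: float = 0.6,
    C_subject: np.ndarray | None = None,
    subject_id: str | None = None,
    group: str | None = None,
) -> list[SynergyMatch]:
    """Classify each subject synergy column by Pearson r to the centroids.

    A synergy is assigned to its best-correlated centroid iff r > r_min
    (default 0.6), else left unclassified. Zero-variance vectors have
    undefined r and are unclassified with a warning. Activation
    coefficient rows (``C_subject``) travel with their synergy.
    """
    W_subject = np.asarray(W_subject, dtype=float)
    if W_subject.shape[0] != refs.centroids.shape[0]:
        raise DataError("subject synergies and centroids disagree on muscle count")
    matches = []
    for j in range(W_subject.shape[1]):
        w = W_subject[:, j]
        r = np.array([_pearson(w, refs.centroids[:, c]) for c in range(refs.n_refs)])
        if np.all(np.isnan(r)):
            warnings.warn(
                f"synergy {j} of subject {subject_id!r} has zero variance; unclassified",
                stacklevel=2,
            )
            best, ok = 0, False
        else:
            best = int(np.nanargmax(r))
            ok = bool(r[best] > r_min)
        matches.append(
            SynergyMatch(
                subject_id=subject_id,
                group=group,
                synergy_index=j,
                r_values=r,
                best_ref=best,
                classified=ok,
                weights=w,
                coefficients=None if C_subject is None else C_subject[j],
            )
        )
    return matches


def similarity_rate(matches: list[SynergyMatch]) -> float:
    """Percentage of synergies classified (r above threshold), per group.

    Computed per synergy (not per subject): 100 * classified / total.
    """
    if not matches:
        raise DataError("no matches given")
    return 100.0 * sum(m.classified for m in matches) / len(matches)
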