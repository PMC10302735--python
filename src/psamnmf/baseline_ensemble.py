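"""The eight baseline partitioners behind one uniform contract.

Fuzzy C-means, K-means, a 1 x k self-organizing map, Gaussian mixtures,
DBSCAN, Ward hierarchical, spectral and OPTICS clustering each produce a
hard Partition with labels in [0, k).  Soft methods are hardened by maximum
membership; density methods, which do not take k, are repaired to exactly k
clusters (eps scan + noise reassignment + largest-cluster splitting).
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import (
    DBSCAN,
    OPTICS,
    AgglomerativeClustering,
    KMeans,
    SpectralClustering,
)
from sklearn.mixture import GaussianMixture

from .motion_io import ValidationError
from .preprocessing import FeatureMatrix

METHODS = (
    "fuzzy_cmeans",
    "kmeans",
    "som",
    "gmm",
    "dbscan",
    "hierarchical",
    "spectral",
    "optics",
)


class DegenerateInputError(ValueError):
    """The feature matrix has no variance to cluster."""


@dataclass
class Partition:
    """A hard labeling of n instances into k clusters by one method."""

    labels: np.ndarray
    k: int
    method: str
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D vector")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValidationError(
                f"labels outside [0, {self.k}) in partition from {self.method!r}"
            )

    @property
    def n(self) -> int:
        return self.labels.shape[0]


@dataclass
class PartitionEnsemble:
    """T partitions of the same n instances, one per baseline method."""

    partitions: list[Partition]

    def __post_init__(self) -> None:
        if len({p.n for p in self.partitions}) > 1:
            raise ValidationError("ensemble members disagree on n")

    @property
    def n(self) -> int:
        return self.partitions[0].n

    @property
    def T(self) -> int:
        return len(self.partitions)

    def require_consensus_ready(self) -> None:
        if self.T < 2:
            raise ValidationError("consensus needs >= 2 ensemble members")


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D instance x feature matrix")
    return X


# ---------------------------------------------------------------------------
# Hand-rolled soft partitioners
# ---------------------------------------------------------------------------


def _fuzzy_cmeans_labels(
    X: np.ndarray, k: int, seed: int, m: float = 2.0,
    max_iter: int = 300, tol: float = 1e-6,
) -> np.ndarray:
    """Fuzzy C-means with fuzziness m, hardened by maximum membership.

    Alternates membership and centroid updates of the weighted within-cluster
    sum of squares until memberships stabilize.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    U = rng.random((n, k)) + 1e-3
    U /= U.sum(axis=1, keepdims=True)
    expo = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        Um = U**m
        centroids = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d = cdist(X, centroids) + 1e-12
        inv = d ** (-expo)
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(U_new - U)) < tol:
            U = U_new
            break
        U = U_new
    return np.argmax(U, axis=1)


def _som_labels(
    X: np.ndarray, k: int, seed: int, n_epochs: int = 20,
    lr0: float = 0.5, sigma0: float | None = None,
) -> np.ndarray:
    """Online SOM on a 1 x k node grid; the best-matching node is the label.

    Learning rate and (Gaussian) neighborhood width decay exponentially over
    epochs; weights start at randomly drawn data points.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    W = X[rng.choice(n, size=k, replace=False)].astype(float).copy()
    sigma0 = sigma0 if sigma0 is not None else max(k / 2.0, 1.0)
    grid = np.arange(k, dtype=float)
    total = n_epochs * n
    step = 0
    for _ in range(n_epochs):
        for i in rng.permutation(n):
            frac = step / total
            lr = lr0 * np.exp(-3.0 * frac)
            sigma = sigma0 * np.exp(-3.0 * frac) + 1e-9
            x = X[i]
            bmu = np.argmin(np.linalg.norm(W - x, axis=1))
            h = np.exp(-((grid - bmu) ** 2) / (2 * sigma**2))
            W += lr * h[:, None] * (x - W)
            step += 1
    return np.argmin(cdist(X, W), axis=1)


# ---------------------------------------------------------------------------
# Density-method repair
# ---------------------------------------------------------------------------


def _repair_to_k(labels: np.ndarray, X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Force an arbitrary labeling (noise = -1 allowed) to exactly k clusters.

    Noise points join the nearest non-noise cluster centroid; if more than k
    clusters remain, all but the k largest are merged into their nearest kept
    centroid; if fewer, the largest cluster is split by seeded 2-means until
    k is reached.
    """
    labels = labels.copy()
    if np.all(labels == -1):
        labels[:] = 0
    # noise -> nearest cluster centroid
    if np.any(labels == -1):
        ids = np.unique(labels[labels != -1])
        centroids = np.vstack([X[labels == c].mean(axis=0) for c in ids])
        noise = np.where(labels == -1)[0]
        nearest = np.argmin(cdist(X[noise], centroids), axis=1)
        labels[noise] = ids[nearest]
    # too many clusters -> keep k largest, merge the rest
    ids, counts = np.unique(labels, return_counts=True)
    if len(ids) > k:
        keep = ids[np.argsort(-counts, kind="stable")[:k]]
        centroids = np.vstack([X[labels == c].mean(axis=0) for c in keep])
        for c in ids:
            if c not in keep:
                members = labels == c
                labels[members] = keep[
                    np.argmin(cdist(X[members], centroids), axis=1)
                ]
    # too few -> split the largest via 2-means
    while len(np.unique(labels)) < k:
        ids, counts = np.unique(labels, return_counts=True)
        big = ids[np.argmax(counts)]
        members = np.where(labels == big)[0]
        sub = KMeans(n_clusters=2, n_init=5, random_state=seed).fit_predict(X[members])
        new_id = labels.max() + 1
        labels[members[sub == 1]] = new_id
    # compact to 0..k-1 in order of first appearance
    remap = {c: i for i, c in enumerate(dict.fromkeys(labels.tolist()))}
    return np.array([remap[c] for c in labels])


def _density_labels(X: np.ndarray, k: int, seed: int, method: str) -> np.ndarray:
    """DBSCAN/OPTICS with eps selected to yield k non-noise clusters.

    eps is scanned over a geometric grid of pairwise-distance quantiles
    (MinPts = 5); the first eps producing exactly k non-noise clusters wins,
    otherwise the scan result closest to k is repaired.
    """
    d = pdist(X)
    positive = d[d > 0]
    if positive.size == 0:
        raise DegenerateInputError("all pairwise distances are zero")
    quantiles = np.geomspace(0.02, 0.98, 25)
    eps_grid = np.unique(np.quantile(positive, quantiles))
    min_samples = min(5, max(2, X.shape[0] // 10))
    best_labels, best_gap = None, np.inf
    for eps in eps_grid:
        if method == "dbscan":
            raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
        else:
            raw = OPTICS(
                min_samples=min_samples, max_eps=eps,
                cluster_method="dbscan", eps=eps,
            ).fit_predict(X)
        n_found = len(set(raw.tolist()) - {-1})
        gap = abs(n_found - k)
        if gap < best_gap or (gap == best_gap and n_found > 0):
            best_labels, best_gap = raw, gap
        if n_found == k:
            break
    return _repair_to_k(best_labels, X, k, seed)


# ---------------------------------------------------------------------------
# Uniform contract
# ---------------------------------------------------------------------------


def fit_partition(X, method: str, k: int, seed: int) -> Partition:
    """Run one baseline method and return a hard Partition with k clusters.

    Feature columns are scaled to unit variance first (no centering, so
    nonnegativity is preserved) — otherwise columns in physical units
    dominate the unit-norm spectral columns in every distance computation.
    """
    X = _as_array(X)
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    if np.allclose(X, X[0]):
        raise DegenerateInputError("feature matrix has zero variance")
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    X = X / scale

    if method == "kmeans":
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    elif method == "fuzzy_cmeans":
        labels = _fuzzy_cmeans_labels(X, k, seed)
    elif method == "som":
        labels = _som_labels(X, k, seed)
    elif method == "gmm":
        gmm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed,
            reg_covar=1e-6, n_init=3,
        )
        labels = gmm.fit_predict(X)
    elif method == "hierarchical":
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    elif method == "spectral":
        d = squareform(pdist(X))
        bandwidth = np.median(d[d > 0]) if np.any(d > 0) else 1.0
        affinity = np.exp(-(d**2) / (2 * bandwidth**2))
        labels = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=seed,
            assign_labels="kmeans",
        ).fit_predict(affinity)
    else:  # dbscan / optics
        labels = _density_labels(X, k, seed, method)

    labels = _repair_to_k(np.asarray(labels), X, k, seed)
    return Partition(labels=labels, k=k, method=method, seed=seed)


def child_seed(master: int, index: int) -> int:
    """Deterministic per-method seed derived from the master seed."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def build_ensemble(X, methods, k: int, seed: int) -> PartitionEnsemble:
    """One Partition per requested method, seeds derived by method index."""
    methods = list(methods)
    if len(methods) < 2:
        raise ValidationError("an ensemble needs >= 2 methods")
    partitions = []
    for m in methods:
        try:
            partitions.append(fit_partition(X, m, k, child_seed(seed, METHODS.index(m))))
        except Exception as exc:
            raise type(exc)(f"[{m}] {exc}") from exc
    return PartitionEnsemble(partitions)


__all__ = [
    "METHODS", "Partition", "PartitionEnsemble", "DegenerateInputError",
    "fit_partition", "build_ensemble", "child_seed",
]
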