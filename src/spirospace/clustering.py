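"""Chemical-space mapping: PCA projection, PAM k-medoids, silhouette selection.

The pruned, standardized descriptor matrix is projected by principal-component
analysis; clustering runs on the leading scores.  k-medoids is implemented as
classic PAM — a greedy BUILD phase followed by best-improvement SWAP local
search — rather than the faster Voronoi iteration, because PAM is
deterministic, needs no random restarts, and its solution quality can be
checked against exhaustive enumeration on small instances.  The number of
clusters is chosen by maximizing the mean silhouette width.

All tie-breaks (equal distances, equal costs, equal silhouettes) resolve to
the lowest index / smallest k so every routine is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .feature_prep import DescriptorMatrix

__all__ = [
    "PCAModel",
    "ClusterModel",
    "ClusteringError",
    "fit_pca",
    "pairwise_distances",
    "kmedoids_pam",
    "silhouette",
    "select_k",
]


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Eigendecomposition of the sample covariance of a standardized matrix."""

    loadings: np.ndarray  # p x c, orthonormal columns
    explained_variance: np.ndarray  # c eigenvalues, non-increasing
    explained_fraction: np.ndarray  # eigenvalue / total variance
    scores: np.ndarray  # n x c
    center: np.ndarray  # column means removed before projection
    descriptor_names: list[str] = field(default_factory=list)
    scaffold_ids: list[str] = field(default_factory=list)
    total_variance: float = 0.0

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.center) @ self.loadings


def fit_pca(m: DescriptorMatrix, n_components: int | None = None) -> PCAModel:
    """PCA of a standardized descriptor matrix via covariance eigendecomposition.

    Covariance uses the sample convention (divisor n−1).  Sign convention:
    within each loading column the entry of largest magnitude is positive,
    which pins down the otherwise arbitrary eigenvector signs.
    """
    if not m.standardized:
        raise ClusteringError("fit_pca expects a standardized matrix")
    n, p = m.values.shape
    if n < 3:
        raise ClusteringError("PCA needs at least 3 samples")
    max_c = min(n - 1, p)
    if n_components is None:
        n_components = max_c
    if not 1 <= n_components <= max_c:
        raise ClusteringError(f"n_components must be in [1, {max_c}], got {n_components}")
    center = m.values.mean(axis=0)
    xc = m.values - center
    cov = (xc.T @ xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    total = float(np.trace(cov))
    # deterministic sign: largest-magnitude entry of each loading positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    loadings = eigvecs[:, :n_components]
    return PCAModel(
        loadings=loadings,
        explained_variance=eigvals[:n_components],
        explained_fraction=eigvals[:n_components] / total if total > 0 else eigvals[:n_components],
        scores=xc @ loadings,
        center=center,
        descriptor_names=list(m.descriptor_names),
        scaffold_ids=list(m.scaffold_ids),
        total_variance=total,
    )


def components_for_variance(model: PCAModel, fraction: float = 0.90) -> int:
    """Smallest number of leading components whose cumulative share ≥ fraction."""
    cum = np.cumsum(model.explained_fraction)
    idx = int(np.searchsorted(cum, fraction - 1e-12)) + 1
    return min(idx, len(cum))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distances(scores: np.ndarray) -> np.ndarray:
    """Euclidean n×n distance matrix from an n×c score array."""
    scores = np.asarray(scores, float)
    if scores.ndim != 2:
        raise ClusteringError("scores must be 2-D")
    return squareform(pdist(scores, metric="euclidean"))


def _as_distance_matrix(d_or_scores: np.ndarray) -> np.ndarray:
    d = np.asarray(d_or_scores, float)
    if d.ndim == 2 and d.shape[0] == d.shape[1] and np.allclose(np.diag(d), 0.0):
        if not np.allclose(d, d.T, atol=1e-10):
            raise ClusteringError("distance matrix must be symmetric")
        if d.min() < -1e-12:
            raise ClusteringError("distances must be non-negative")
        return d
    return pairwise_distances(d)


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """A fitted k-medoids partition with its silhouette profile."""

    k: int
    medoid_indices: list[int]
    assignments: np.ndarray  # n labels in [0, k)
    silhouette_per_sample: np.ndarray
    mean_silhouette: float
    total_cost: float


def _assign(d: np.ndarray, medoids: list[int]) -> np.ndarray:
    """Nearest-medoid labels; ties go to the lowest medoid index; medoids to themselves."""
    med = sorted(medoids)
    labels = np.argmin(d[:, med], axis=1)
    for lab, m_idx in enumerate(med):
        labels[m_idx] = lab
    return labels


def _cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, sorted(medoids)].min(axis=1).sum())


def kmedoids_pam(d_or_scores: np.ndarray, k: int) -> ClusterModel:
    """PAM: greedy BUILD then best-improvement SWAP, fully deterministic.

    Accepts either a symmetric zero-diagonal distance matrix or an n×c score
    array (Euclidean distances are computed).  BUILD seeds the first medoid
    with the point minimizing total distance and adds each next medoid for the
    largest cost decrease; SWAP repeatedly applies the single best improving
    (medoid, non-medoid) exchange until none improves, so the final cost is a
    local optimum under single swaps.
    """
    d = _as_distance_matrix(d_or_scores)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ClusteringError(f"k must be in [1, {n}], got {k}")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, None
        for c in range(n):
            if c in medoids:
                continue
            gain = float(np.maximum(nearest - d[:, c], 0.0).sum())
            if gain > best_gain + 1e-12:
                best_gain, best_c = gain, c
        medoids.append(best_c)

    # SWAP
    current = _cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best_delta, best_pair = -1e-12, None
        for m in sorted(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = [x for x in medoids if x != m] + [h]
                delta = current - _cost(d, trial)
                if delta > best_delta + 1e-12:
                    best_delta, best_pair = delta, (m, h)
        if best_pair is not None:
            m, h = best_pair
            medoids = [x for x in medoids if x != m] + [h]
            current -= best_delta
            improved = True

    medoids = sorted(medoids)
    labels = _assign(d, medoids)
    if k >= 2 and len(np.unique(labels)) >= 2:
        per_sample, mean_sil = silhouette(d, labels)
    else:
        per_sample, mean_sil = np.zeros(n), 0.0
    return ClusterModel(
        k=k,
        medoid_indices=medoids,
        assignments=labels,
        silhouette_per_sample=per_sample,
        mean_silhouette=mean_sil,
        total_cost=_cost(d, medoids),
    )


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def silhouette(d_or_scores: np.ndarray, assignments: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample silhouette s(i) = (b−a)/max(a,b) and its unweighted mean.

    a(i) is the mean distance to the other members of i's cluster; b(i) the
    smallest mean distance to any other cluster.  Members of singleton
    clusters get s(i) = 0 by convention, as do points with a = b = 0.
    """
    d = _as_distance_matrix(d_or_scores)
    labels = np.asarray(assignments)
    n = d.shape[0]
    if labels.shape != (n,):
        raise ClusteringError("assignments must label every sample")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ClusteringError("silhouette needs at least 2 clusters")
    s = np.zeros(n)
    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = d[i, own[own != i]].mean()
        b = min(d[i, members[lab]].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_k(
    d_or_scores: np.ndarray, k_range: tuple[int, int] = (2, 10)
) -> tuple[int, ClusterModel, dict[int, float]]:
    """Fit PAM for each k in [k_min, k_max]; keep the best mean silhouette.

    Ties resolve to the smaller k.  Returns the winning k, its fitted model
    and the full silhouette curve for reporting.
    """
    d = _as_distance_matrix(d_or_scores)
    n = d.shape[0]
    k_min, k_max = k_range
    k_max = min(k_max, n - 1)
    if k_min < 2 or k_min > k_max:
        raise ClusteringError(f"invalid k_range {k_range} for n={n}")
    curve: dict[int, float] = {}
    best_k, best_model = None, None
    for k in range(k_min, k_max + 1):
        model = kmedoids_pam(d, k)
        curve[k] = model.mean_silhouette
        if best_model is None or model.mean_silhouette > best_model.mean_silhouette + 1e-12:
            best_k, best_model = k, model
    return best_k, best_model, curve
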