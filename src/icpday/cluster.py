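"""K-medoids (PAM) clustering of normalized ICP series with Davies-Bouldin
model selection.

The partition is built on Euclidean distances between the 24-point rows.
Medoids are seeded with the classical PAM BUILD phase (greedy cost-reduction
placement, fully deterministic) and refined by the swap phase: the
(medoid, candidate) swap with the largest cost reduction is applied until no
swap lowers the total within-cluster distance to medoid.  The number of
clusters is chosen over k = 2..7 by minimizing the Davies-Bouldin index,
with ties broken toward smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ClusterSolution", "kmedoids", "davies_bouldin", "select_k", "size_ordered_labels"]


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray           # n ints in [0, k)
    medoid_indices: np.ndarray   # k row indices into the input matrix
    cost: float                  # total distance of points to their medoid
    db_index: float | None = None
    per_k_db: dict[int, float] = field(default_factory=dict)


def _build_init(D: np.ndarray, k: int) -> np.ndarray:
    """Classical PAM BUILD: greedily add the medoid that most reduces the
    total distance-to-nearest-medoid.  Deterministic (ties to lowest index)."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[:, medoids[0]].copy()
    for _ in range(1, k):
        gain = np.maximum(d_near[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        h = int(np.argmax(gain))
        medoids.append(h)
        d_near = np.minimum(d_near, D[:, h])
    return np.asarray(sorted(medoids), dtype=int)


def _nearest_two(D: np.ndarray, medoids: np.ndarray):
    sub = D[:, medoids]
    order = np.argsort(sub, axis=1, kind="stable")
    d1 = sub[np.arange(len(D)), order[:, 0]]
    d2 = sub[np.arange(len(D)), order[:, 1]] if len(medoids) > 1 else np.full(len(D), np.inf)
    return order[:, 0], d1, d2


def kmedoids(
    matrix: np.ndarray, k: int, seed: int = 0, max_iter: int = 200, n_restarts: int = 4
) -> ClusterSolution:
    """PAM partition of the rows of ``matrix`` into ``k`` clusters.

    Runs the swap phase from the deterministic BUILD seeding plus
    ``n_restarts`` random seedings (drawn from ``seed``) and keeps the
    lowest-cost local optimum; greedy swap alone can stall on small inputs.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n]; got k={k}, n={n}")
    D = cdist(X, X)
    rng = np.random.default_rng(seed)
    best: ClusterSolution | None = None
    for r in range(n_restarts + 1):
        init = _build_init(D, k) if r == 0 else np.sort(rng.choice(n, size=k, replace=False))
        sol = _pam_swap(D, init, k, max_iter)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    return best


def _pam_swap(D: np.ndarray, medoids: np.ndarray, k: int, max_iter: int) -> ClusterSolution:
    n = D.shape[0]
    medoids = np.asarray(medoids, dtype=int).copy()
    for _ in range(max_iter):
        nearest, d1, d2 = _nearest_two(D, medoids)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        best_delta, best_pair = -1e-12, None
        for mi, m in enumerate(medoids):
            assigned = nearest == mi
            # cost change of swapping medoid m for each candidate column h
            reassign = np.minimum(d2[:, None], D) - d1[:, None]
            keep = np.minimum(0.0, D - d1[:, None])
            delta = np.where(assigned[:, None], reassign, keep).sum(axis=0)
            delta[is_medoid] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_pair = float(delta[h]), (mi, h)
        if best_pair is None:
            break
        medoids = medoids.copy()
        medoids[best_pair[0]] = best_pair[1]
        medoids.sort()
    nearest, d1, _ = _nearest_two(D, medoids)
    return ClusterSolution(k=k, labels=nearest, medoid_indices=medoids, cost=float(d1.sum()))


def davies_bouldin(matrix: np.ndarray, labels: np.ndarray, dispersion: str = "centroid") -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (S_i + S_j) / M_ij ratio; lower is better.

    ``dispersion='centroid'`` uses the classical definition (mean distance to
    the cluster centroid, centroid separation); ``'medoid'`` measures both
    against the in-cluster medoid instead.  Coincident cluster centers make
    the ratio undefined and raise.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    centers, S = [], []
    for u in uniq:
        pts = X[labels == u]
        if len(pts) == 0:
            raise ValueError("empty cluster")
        if dispersion == "centroid":
            c = pts.mean(axis=0)
        elif dispersion == "medoid":
            d_in = cdist(pts, pts)
            c = pts[int(np.argmin(d_in.sum(axis=1)))]
        else:
            raise ValueError(f"unknown dispersion {dispersion!r}")
        centers.append(c)
        S.append(float(np.linalg.norm(pts - c, axis=1).mean()))
    centers = np.asarray(centers)
    M = cdist(centers, centers)
    ratios = np.empty(k)
    for i in range(k):
        r = -np.inf
        for j in range(k):
            if i == j:
                continue
            if M[i, j] == 0:
                raise ValueError("coincident cluster centers: Davies-Bouldin undefined")
            r = max(r, (S[i] + S[j]) / M[i, j])
        ratios[i] = r
    return float(ratios.mean())


def select_k(
    matrix: np.ndarray,
    k_range: range = range(2, 8),
    seed: int = 0,
    dispersion: str = "centroid",
) -> ClusterSolution:
    """Run PAM over ``k_range`` and keep the partition with minimal
    Davies-Bouldin index (ties toward smaller k)."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    kmax = max(k_range)
    if X.shape[0] <= kmax:
        raise ValueError(f"need n > {kmax} rows; got {X.shape[0]}")
    best: ClusterSolution | None = None
    per_k: dict[int, float] = {}
    for k in k_range:
        sol = kmedoids(X, k, seed=seed)
        try:
            db = davies_bouldin(X, sol.labels, dispersion=dispersion)
        except ValueError:  # degenerate partition (coincident centers)
            db = np.inf
        per_k[k] = db
        if best is None or db < best.db_index:
            sol.db_index = db
            best = sol
    assert best is not None
    best.per_k_db = per_k
    return best


def size_ordered_labels(labels: np.ndarray) -> np.ndarray:
    """Map integer cluster labels to Roman numerals by descending cluster
    size (I = largest), the convention used in the cohort report."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    romans = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    mapping = {int(u): romans[i] for i, u in enumerate(order)}
    return np.asarray([mapping[int(l)] for l in labels])
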