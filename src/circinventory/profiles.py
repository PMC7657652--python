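"""Stage-profile clustering of top-expressed circles.

Expression *shapes* rather than magnitudes drive the grouping: rows are
log2(RPM+1)-transformed and z-scored before a k-means (k = 5 by default)
partition chosen by within-cluster sum of squares (WCSS). k-means is
implemented in-repo (kmeans++ seeding + Lloyd iterations, best of many
restarts) so that the iteration-level monotonicity of the objective is
assertable and results are bit-reproducible for a fixed seed; an external
backend can be swapped in for cross-checks but this implementation is
canonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class ClusterResult:
    k: int
    assignments: Dict[str, int]     # row label -> canonical cluster id
    centroids: np.ndarray           # (k, n_stages), canonical order
    wcss: float
    seed: int
    restarts: int
    iterations: int                 # iterations of the winning restart
    wcss_history: Tuple[float, ...]  # per-iteration objective of the winner


def transform_profiles(matrix: pd.DataFrame, mode: str = "log_zscore") -> pd.DataFrame:
    """log2(RPM+1) then per-row z-scoring (``log_zscore``), or identity (``raw``).

    Rows with zero variance after the log transform become zero vectors, so
    constant profiles sit at the origin instead of propagating NaNs.
    """
    if mode == "raw":
        return matrix.copy()
    if mode != "log_zscore":
        raise ValueError(f"unknown transform mode {mode!r}")
    logged = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    z = np.nan_to_num(z, nan=0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, d2[np.arange(len(X)), labels]


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
           ) -> Tuple[np.ndarray, np.ndarray, float, int, List[float]]:
    k = centers.shape[0]
    history: List[float] = []
    labels, d2 = _assign(X, centers)
    wcss = float(d2.sum())
    history.append(wcss)
    for it in range(1, max_iter + 1):
        new_centers = centers.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:
                # reseed an empty cluster from the point farthest from its centroid
                far = int(np.argmax(d2))
                new_centers[j] = X[far]
                d2[far] = 0.0
        labels, d2 = _assign(X, new_centers)
        new_wcss = float(d2.sum())
        # Lloyd's updates can never increase the objective
        assert new_wcss <= wcss + 1e-9 * max(wcss, 1.0), "WCSS increased"
        history.append(new_wcss)
        converged = wcss - new_wcss <= tol * max(wcss, 1.0)
        centers, wcss = new_centers, new_wcss
        if converged:
            return labels, centers, wcss, it, history
    return labels, centers, wcss, max_iter, history


def kmeans_cluster(profiles: pd.DataFrame, k: int = 5, seed: int = 0,
                   restarts: int = 50, max_iter: int = 300,
                   tol: float = 1e-6) -> ClusterResult:
    """Best-of-restarts Lloyd k-means on the profile rows.

    Cluster labels are canonicalized by the peak stage of each centroid
    (earliest-peaking first), so the labelling is comparable across seeds.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers0 = _kmeanspp_init(X, k, rng)
        labels, centers, wcss, iters, history = _lloyd(X, centers0, max_iter, tol)
        if best is None or wcss < best[2] - 1e-12:
            best = (labels, centers, wcss, iters, history)
    labels, centers, wcss, iters, history = best
    order = _canonical_order(centers)
    relabel = {old: new for new, old in enumerate(order)}
    assignments = {row: relabel[int(lab)] for row, lab in zip(profiles.index, labels)}
    return ClusterResult(k, assignments, centers[order], wcss, seed, restarts,
                         iters, tuple(history))


def _canonical_order(centers: np.ndarray) -> List[int]:
    """Order clusters by centroid peak stage, then by descending peak value."""
    keys = [(int(np.argmax(c)), -float(np.max(c)), j) for j, c in enumerate(centers)]
    return [j for (_, _, j) in sorted(keys)]


def wcss_curve(profiles: pd.DataFrame, k_values: Sequence[int], seed: int = 0,
               restarts: int = 50, max_iter: int = 300,
               tol: float = 1e-6) -> List[Tuple[int, float]]:
    """WCSS at each k under the full restart protocol (elbow diagnostics)."""
    return [(int(k), kmeans_cluster(profiles, k=int(k), seed=seed,
                                    restarts=restarts, max_iter=max_iter,
                                    tol=tol).wcss)
            for k in k_values]


def order_heatmap(matrix: pd.DataFrame, result: ClusterResult) -> List[str]:
    """Deterministic heatmap row order: clusters by peak stage (earliest
    first, as canonicalized), within a cluster by descending max RPM."""
    missing = set(matrix.index) - set(result.assignments)
    if missing:
        raise ValueError(f"cluster result does not cover rows: {sorted(missing)[:3]}")
    peak = matrix.max(axis=1)
    return sorted(matrix.index,
                  key=lambda row: (result.assignments[row], -peak[row], row))


def assignments_frame(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(result.assignments.items()), columns=["locus", "cluster"])
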