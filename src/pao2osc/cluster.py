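"""Morphology clustering of FPCA score vectors.

Hartigan-Wong k-means (optimal-transfer updates with the n/(n-1) and
n/(n+1) cost factors), an AIC defined directly on the clustering output
(WCSS + 2*m*k), Monte-Carlo selection of the cluster count across random
single-start initializations, and progression ordering of the final
clusters by their mean first-component score.

Scores are clustered as-is (no standardization), preserving the variance
ranking FPCA assigns to the components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core import BREATH_SAMPLES, INSP_FRACTION

__all__ = [
    "KMeansSolution",
    "ClusterSelection",
    "OrderedClustering",
    "kmeans_hw",
    "aic_kmeans",
    "select_k_monte_carlo",
    "finalize_clustering",
]


# --------------------------------------------------------------------------
# Hartigan-Wong core (numba)
# --------------------------------------------------------------------------

@njit(cache=True)
def _hartigan_run(X, init_idx, max_passes):  # pragma: no cover - numba
    n, m = X.shape
    k = init_idx.shape[0]
    centers = np.empty((k, m))
    for c in range(k):
        for j in range(m):
            centers[c, j] = X[init_idx[c], j]

    assign = np.empty(n, dtype=np.int64)
    counts = np.zeros(k, dtype=np.int64)
    sums = np.zeros((k, m))
    for i in range(n):
        best, bd = 0, 1e300
        for c in range(k):
            d = 0.0
            for j in range(m):
                diff = X[i, j] - centers[c, j]
                d += diff * diff
            if d < bd:
                bd, best = d, c
        assign[i] = best
        counts[best] += 1
        for j in range(m):
            sums[best, j] += X[i, j]

    # empty clusters: seed each from the point farthest from its center
    for c in range(k):
        if counts[c] == 0:
            far_i, far_d = -1, -1.0
            for i in range(n):
                ci = assign[i]
                if counts[ci] <= 1:
                    continue
                d = 0.0
                for j in range(m):
                    diff = X[i, j] - sums[ci, j] / counts[ci]
                    d += diff * diff
                if d > far_d:
                    far_d, far_i = d, i
            if far_i >= 0:
                old = assign[far_i]
                counts[old] -= 1
                counts[c] += 1
                assign[far_i] = c
                for j in range(m):
                    sums[old, j] -= X[far_i, j]
                    sums[c, j] += X[far_i, j]

    for c in range(k):
        if counts[c] > 0:
            for j in range(m):
                centers[c, j] = sums[c, j] / counts[c]

    # optimal-transfer passes
    for _ in range(max_passes):
        moved = False
        for i in range(n):
            c0 = assign[i]
            n0 = counts[c0]
            if n0 <= 1:
                continue
            d0 = 0.0
            for j in range(m):
                diff = X[i, j] - centers[c0, j]
                d0 += diff * diff
            removal = d0 * n0 / (n0 - 1.0)
            best_c, best_gain = -1, -1e-12
            for c in range(k):
                if c == c0:
                    continue
                d = 0.0
                for j in range(m):
                    diff = X[i, j] - centers[c, j]
                    d += diff * diff
                insertion = d * counts[c] / (counts[c] + 1.0)
                gain = removal - insertion
                if gain > best_gain:
                    best_gain, best_c = gain, c
            if best_c >= 0 and best_gain > 1e-12:
                counts[c0] -= 1
                counts[best_c] += 1
                assign[i] = best_c
                for j in range(m):
                    sums[c0, j] -= X[i, j]
                    sums[best_c, j] += X[i, j]
                    centers[c0, j] = sums[c0, j] / counts[c0]
                    centers[best_c, j] = sums[best_c, j] / counts[best_c]
                moved = True
        if not moved:
            break

    wcss = 0.0
    for i in range(n):
        c = assign[i]
        for j in range(m):
            diff = X[i, j] - centers[c, j]
            wcss += diff * diff
    return assign, centers, wcss


@njit(cache=True)
def _mc_wcss(X, init_matrix, max_passes):  # pragma: no cover - numba
    n_iter = init_matrix.shape[0]
    out = np.empty(n_iter)
    for it in range(n_iter):
        _, _, w = _hartigan_run(X, init_matrix[it], max_passes)
        out[it] = w
    return out


_MAX_PASSES = 100


# --------------------------------------------------------------------------
# public surface
# --------------------------------------------------------------------------

@dataclass
class KMeansSolution:
    assignments: np.ndarray
    centers: np.ndarray
    wcss: float
    k: int
    m: int
    seed: int | None = None


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.ascontiguousarray(np.atleast_2d(np.asarray(points, dtype=float)))
    if pts.ndim != 2:
        raise ValueError("points must be an n x m array")
    return pts


def _random_inits(rng: np.random.Generator, n: int, k: int, n_starts: int) -> np.ndarray:
    inits = np.empty((n_starts, k), dtype=np.int64)
    for s in range(n_starts):
        inits[s] = rng.choice(n, size=k, replace=False)
    return inits


def kmeans_hw(
    points: np.ndarray, k: int, seed: int, n_starts: int = 10
) -> KMeansSolution:
    """Best of ``n_starts`` Hartigan-Wong runs from random initial centers
    (distinct data points), deterministic under the seed."""
    pts = _as_points(points)
    n, m = pts.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    inits = _random_inits(rng, n, k, n_starts)
    best = None
    for s in range(n_starts):
        assign, centers, wcss = _hartigan_run(pts, inits[s], _MAX_PASSES)
        if best is None or wcss < best[2] - 1e-12:
            best = (assign.copy(), centers.copy(), wcss)
    return KMeansSolution(
        assignments=best[0], centers=best[1], wcss=float(best[2]), k=k, m=m, seed=seed
    )


def aic_kmeans(wcss: float, m: int, k: int) -> float:
    """AIC of a k-means solution: distortion plus 2 x (parameters) with
    m coordinates per center."""
    if m < 1 or k < 1:
        raise ValueError("m and k must be >= 1")
    return float(wcss + 2.0 * m * k)


@dataclass
class ClusterSelection:
    table: pd.DataFrame  # columns k, mean_aic, sd_aic
    chosen_k: int
    n_iterations: int
    k_range: tuple[int, ...]
    tie_rule: str = "band"


def select_k_monte_carlo(
    points: np.ndarray,
    k_range: range | tuple[int, ...],
    n_iterations: int = 10_000,
    seed: int | None = None,
    m: int | None = None,
    tie_rule: str = "band",
) -> ClusterSelection:
    """Monte-Carlo AIC over candidate cluster counts.

    For each k, ``n_iterations`` independent single-start Hartigan-Wong
    runs are performed (each from a fresh random initialization) and the
    AIC of each run recorded; the across-init variability of single-start
    k-means is the quantity being measured, so no best-of restarting is
    applied here.

    Tie rule "band": every k whose mean AIC lies within one pooled SD of
    the minimum is considered equivalent and the largest such k is
    chosen; "strict" takes the arg-min.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    ks = tuple(int(k) for k in k_range)
    if not ks:
        raise ValueError("k_range is empty")
    if max(ks) > n:
        raise ValueError("largest candidate k exceeds the number of points")
    if tie_rule not in {"band", "strict"}:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    m_dim = pts.shape[1] if m is None else int(m)
    rng = np.random.default_rng(seed)

    rows = []
    for k in ks:
        inits = _random_inits(rng, n, k, n_iterations)
        wcss = _mc_wcss(pts, inits, _MAX_PASSES)
        aics = wcss + 2.0 * m_dim * k
        rows.append(
            {
                "k": k,
                "mean_aic": float(aics.mean()),
                "sd_aic": float(aics.std(ddof=1)) if len(aics) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)

    if tie_rule == "strict":
        chosen = int(table.loc[table["mean_aic"].idxmin(), "k"])
    else:
        pooled_sd = float(np.sqrt(np.mean(table["sd_aic"] ** 2)))
        lo = table["mean_aic"].min()
        in_band = table[table["mean_aic"] <= lo + pooled_sd]
        chosen = int(in_band["k"].max())
    return ClusterSelection(
        table=table,
        chosen_k=chosen,
        n_iterations=n_iterations,
        k_range=ks,
        tie_rule=tie_rule,
    )


@dataclass
class OrderedClustering:
    solution: KMeansSolution
    progression_rank: np.ndarray  # per-condition rank 1..k
    cluster_to_rank: dict[int, int]
    cluster_mean_curves: np.ndarray | None = None  # k x p, rank order


def finalize_clustering(
    points: np.ndarray,
    chosen_k: int,
    seed: int,
    n_starts: int = 100,
    curves: np.ndarray | None = None,
    insp_samples: int = int(BREATH_SAMPLES * INSP_FRACTION),
) -> OrderedClustering:
    """Best-of-``n_starts`` k-means at the chosen k, clusters ranked along
    the morphology progression.

    Ranks order clusters by their mean first-component score; when the
    member curves are supplied the direction is normalized so that rank 1
    is the cluster whose mean curve is inspiration-peaked (higher mean in
    the inspiratory third of the breath than in expiration).
    """
    pts = _as_points(points)
    sol = kmeans_hw(pts, chosen_k, seed=seed, n_starts=n_starts)

    order = []
    for c in range(chosen_k):
        members = sol.assignments == c
        order.append(pts[members, 0].mean() if members.any() else np.inf)
    by_pc1 = np.argsort(order)  # ascending mean PC1

    mean_curves = None
    if curves is not None:
        curves = np.atleast_2d(np.asarray(curves, dtype=float))
        mean_curves = np.vstack(
            [curves[sol.assignments == c].mean(axis=0) for c in by_pc1]
        )
        first = mean_curves[0]
        last = mean_curves[-1]

        def insp_score(curve: np.ndarray) -> float:
            return float(curve[:insp_samples].mean() - curve[insp_samples:].mean())

        if insp_score(last) > insp_score(first):
            by_pc1 = by_pc1[::-1]
            mean_curves = mean_curves[::-1]

    cluster_to_rank = {int(c): r + 1 for r, c in enumerate(by_pc1)}
    ranks = np.array([cluster_to_rank[int(c)] for c in sol.assignments])
    return OrderedClustering(
        solution=sol,
        progression_rank=ranks,
        cluster_to_rank=cluster_to_rank,
        cluster_mean_curves=mean_curves,
    )
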