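"""Natural-breaks discretization and Getis–Ord Gi* hot/cold-spot analysis.

Jenks natural breaks is the exact Fisher dynamic-programming solution that
minimises the total within-class sum of squared deviations of a 1-D sample.
Gi* is the local spatial-association statistic: for each cell, the weighted
sum of neighbouring values (the focal cell included) compared with its
expectation under the randomisation null, reported both as the raw ratio
``sum_j w_ij x_j / sum_j x_j`` and as the standard deviate z used for
hot/cold significance classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "jenks_breaks",
    "jenks_classify",
    "SpatialWeights",
    "build_weights",
    "gi_star",
    "CATEGORY_THRESHOLDS",
]

CATEGORY_THRESHOLDS = ((2.576, "99"), (1.960, "95"), (1.645, "90"))


# ---------------------------------------------------------------------------
# Jenks natural breaks (exact Fisher DP)
# ---------------------------------------------------------------------------


def _ssq_matrix_prefix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    return s1, s2


def _ssd(s1: np.ndarray, s2: np.ndarray, i: np.ndarray, j: int) -> np.ndarray:
    """Within-class SSD of sorted x[i:j] (vectorized over i)."""
    n = j - i
    s = s1[j] - s1[i]
    ss = s2[j] - s2[i]
    return ss - s * s / np.maximum(n, 1)


def jenks_breaks(values, k: int) -> np.ndarray:
    """Exact natural-breaks boundaries minimising within-class SSD.

    Returns the k-1 interior break points, each the upper bound of a class
    (a value equal to a break belongs to the lower class).  Deterministic;
    order of the input is irrelevant.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise ValueError(
            f"need at least k={k} distinct values, got {n_distinct}"
        )
    s1, s2 = _ssq_matrix_prefix(x)
    # D[m, j] = minimal SSD of splitting x[0:j] into m+1 classes
    INF = np.inf
    j_all = np.arange(n + 1)
    prev = (s2[j_all] - np.where(j_all > 0, s1[j_all] ** 2 / np.maximum(j_all, 1), 0.0))
    # argmin table for reconstruction: split[m][j] = i achieving the optimum
    splits = np.zeros((k, n + 1), dtype=int)
    for m in range(1, k):
        cur = np.full(n + 1, INF)
        for j in range(m + 1, n + 1):
            i = np.arange(m, j)
            cand = prev[i] + _ssd(s1, s2, i, j)
            best = int(np.argmin(cand))
            cur[j] = cand[best]
            splits[m, j] = i[best]
        prev = cur
    # reconstruct class boundaries
    bounds = [n]
    j = n
    for m in range(k - 1, 0, -1):
        j = int(splits[m, j])
        bounds.append(j)
    bounds.reverse()  # k-1 interior boundaries (indices into sorted x)
    return np.array([x[b - 1] for b in bounds[:-1]])


def jenks_objective(values, breaks) -> float:
    """Total within-class SSD of the classification induced by the breaks."""
    labels = jenks_classify(values, breaks)
    x = np.asarray(values, dtype=float)
    total = 0.0
    for lab in np.unique(labels):
        v = x[labels == lab]
        total += float(((v - v.mean()) ** 2).sum())
    return total


def jenks_classify(values, breaks) -> np.ndarray:
    """Class labels 0..k-1; a value equal to a break goes to the lower class."""
    x = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(breaks, dtype=float), x, side="left")


# ---------------------------------------------------------------------------
# Spatial weights
# ---------------------------------------------------------------------------


@dataclass
class SpatialWeights:
    """Binary neighbour lists: for each cell, neighbour indices and weights."""

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    include_self: bool
    scheme: str
    param: float

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])


def build_weights(
    cells: pd.DataFrame,
    scheme: str = "distance_band",
    d_or_k: float = 3000.0,
    include_self: bool = True,
) -> SpatialWeights:
    """Binary spatial weights from cell centroids (cx, cy).

    ``distance_band``: w_ij = 1 iff centroid distance <= d (self included when
    ``include_self``, as Gi* requires).  ``k_nearest``: the k nearest
    centroids.  Errors if the band leaves every cell isolated.
    """
    pts = cells[["cx", "cy"]].to_numpy(dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 cells to build spatial weights")
    tree = cKDTree(pts)
    neighbors: list[np.ndarray] = []
    if scheme == "distance_band":
        d = float(d_or_k)
        lists = tree.query_ball_tree(tree, r=d)
        for i, nb in enumerate(lists):
            nb = np.array(sorted(nb), dtype=int)
            if not include_self:
                nb = nb[nb != i]
            neighbors.append(nb)
        n_others = np.array([len(nb) - (1 if include_self else 0) for nb in neighbors])
        if (n_others == 0).all():
            dmin = np.min(tree.query(pts, k=2)[0][:, 1])
            raise ValueError(
                f"band distance {d} m isolates every cell; minimum centroid "
                f"spacing is {dmin:.0f} m — try d >= {dmin:.0f}"
            )
    elif scheme == "k_nearest":
        k = int(d_or_k)
        _, idx = tree.query(pts, k=k + 1)
        for i in range(n):
            nb = idx[i]
            if not include_self:
                nb = nb[nb != i][:k]
            neighbors.append(np.array(sorted(nb), dtype=int))
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    weights = [np.ones(len(nb)) for nb in neighbors]
    return SpatialWeights(neighbors, weights, include_self, scheme, float(d_or_k))


# ---------------------------------------------------------------------------
# Getis–Ord Gi*
# ---------------------------------------------------------------------------


def gi_star(cells: pd.DataFrame, weights: SpatialWeights, column: str = "esv_per_area") -> pd.DataFrame:
    """Gi* raw ratio, standard deviate z, and hot/cold category per cell.

    z_i = [sum_j w_ij x_j - Xbar W_i] / (S sqrt[(n sum_j w_ij^2 - W_i^2)/(n-1)])
    with Xbar and S the global mean and (population) standard deviation and
    W_i = sum_j w_ij.  A zero-variance field yields z = 0 / category ``ns``.
    """
    if not weights.include_self:
        raise ValueError("Gi* requires self-inclusive weights")
    x = cells[column].to_numpy(dtype=float)
    n = x.size
    if n != weights.n:
        raise ValueError("weights and cell table sizes differ")
    xbar = x.mean()
    s = np.sqrt((x * x).mean() - xbar**2)
    total = x.sum()
    lag = np.empty(n)
    wi = np.empty(n)
    wi2 = np.empty(n)
    for i, (nb, w) in enumerate(zip(weights.neighbors, weights.weights)):
        lag[i] = float((w * x[nb]).sum())
        wi[i] = float(w.sum())
        wi2[i] = float((w * w).sum())
    raw = lag / total if total != 0 else np.zeros(n)
    if s == 0:
        z = np.zeros(n)
    else:
        denom = s * np.sqrt((n * wi2 - wi**2) / (n - 1))
        z = np.where(denom > 0, (lag - xbar * wi) / np.where(denom > 0, denom, 1.0), 0.0)
    cat = np.full(n, "ns", dtype=object)
    for thr, lab in CATEGORY_THRESHOLDS:
        cat[(cat == "ns") & (z >= thr)] = f"hot{lab}"
        cat[(cat == "ns") & (z <= -thr)] = f"cold{lab}"
    out = cells[["cell_id"]].copy()
    out["gi_raw"] = raw
    out["gi_z"] = z
    out["category"] = cat
    return out
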