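"""Geo-detector factor detector: the q-statistic with significance testing.

The q-statistic measures how much of the spatial variance of a response
(here ESV per unit area) a categorical stratification explains:

    q = 1 - (1 / (N sigma^2)) * sum_h N_h sigma_h^2

with population (divide-by-N) variances both globally and within strata.
q is 0 when strata explain nothing and 1 when the response is constant
within every stratum.  Continuous drivers are discretized with natural
breaks (9 classes by default) before detection.

Significance: the noncentral-F test of the geo-detector literature
(F = ((N-L)/(L-1)) q/(1-q) against F(L-1, N-L; lambda)), with a seeded
label-permutation test as an assumption-free alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import jenks_breaks, jenks_classify

__all__ = ["QResult", "factor_q", "q_significance", "rank_factors"]


@dataclass
class QResult:
    """q-statistic with the variance decomposition behind it."""

    factor: str
    q: float
    n: int
    strata_count: int
    stratum_sizes: np.ndarray
    stratum_means: np.ndarray
    stratum_variances: np.ndarray
    global_variance: float
    p_value: float | None = None
    p_method: str | None = None


def factor_q(y, strata, factor: str = "factor") -> QResult:
    """Variance-decomposition q of a categorical stratification.

    Uses population variances throughout; singleton strata contribute zero
    within-stratum variance.  Errors when the response has no variance.
    """
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if y.shape != strata.shape:
        raise ValueError("y and strata must have the same length")
    n = y.size
    labels, inverse = np.unique(strata, return_inverse=True)
    L = labels.size
    if n < L or L < 1:
        raise ValueError(f"invalid stratification: N={n}, L={L}")
    sigma2 = float(y.var())  # population convention
    if sigma2 == 0:
        raise ValueError("response has zero variance; q undefined")
    sizes = np.bincount(inverse, minlength=L)
    sums = np.bincount(inverse, weights=y, minlength=L)
    sums2 = np.bincount(inverse, weights=y * y, minlength=L)
    means = sums / sizes
    variances = sums2 / sizes - means**2
    variances = np.maximum(variances, 0.0)
    q = 1.0 - float((sizes * variances).sum()) / (n * sigma2)
    return QResult(
        factor=factor,
        q=float(q),
        n=n,
        strata_count=int(L),
        stratum_sizes=sizes,
        stratum_means=means,
        stratum_variances=variances,
        global_variance=sigma2,
    )


def q_significance(
    res: QResult,
    method: str = "ncF",
    n_perm: int = 999,
    seed: int = 0,
    y=None,
    strata=None,
) -> float:
    """p-value of the q-statistic.

    ``ncF``: F = ((N-L)/(L-1)) q/(1-q) referred to a noncentral F with
    (L-1, N-L) degrees of freedom and noncentrality
    lambda = (1/sigma^2) [sum_h Ybar_h^2 - (sum_h sqrt(N_h) Ybar_h)^2 / N].
    ``permutation``: share of seeded label permutations with q >= observed
    (add-one smoothing); requires the raw ``y`` and ``strata``.
    """
    L, N = res.strata_count, res.n
    if L < 2:
        raise ValueError("significance of q needs at least 2 strata")
    if res.q >= 1.0:
        return 0.0
    if method == "ncF":
        f_stat = (N - L) / (L - 1) * res.q / (1.0 - res.q)
        m = res.stratum_means
        lam = (
            (m**2).sum() - (np.sqrt(res.stratum_sizes) * m).sum() ** 2 / N
        ) / res.global_variance
        lam = max(float(lam), 0.0)
        return float(stats.ncf.sf(f_stat, L - 1, N - L, lam))
    if method == "permutation":
        if y is None or strata is None:
            raise ValueError("permutation test needs the raw y and strata")
        y = np.asarray(y, dtype=float)
        strata = np.asarray(strata)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            qp = factor_q(y, rng.permutation(strata)).q
            if qp >= res.q:
                count += 1
        return (count + 1) / (n_perm + 1)
    raise ValueError(f"unknown method {method!r}")


def rank_factors(
    cells: pd.DataFrame,
    y_col: str,
    factors: list[str],
    k_classes: int = 9,
    categorical: set[str] | None = None,
    method: str = "ncF",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Factor-detector table: q and p per driver, sorted by q descending.

    Continuous drivers are discretized into ``k_classes`` natural-breaks
    strata first; drivers named in ``categorical`` are used as-is.
    """
    categorical = categorical or set()
    y = cells[y_col].to_numpy(dtype=float)
    rows = []
    for fac in factors:
        if fac not in cells.columns:
            raise ValueError(f"factor column {fac!r} missing from the cell table")
        col = cells[fac].to_numpy()
        if fac in categorical:
            strata = col
        else:
            vals = col.astype(float)
            k = min(k_classes, np.unique(vals).size)
            if k >= 2:
                strata = jenks_classify(vals, jenks_breaks(vals, k))
            else:
                strata = np.zeros(vals.size, dtype=int)
        res = factor_q(y, strata, factor=fac)
        if res.strata_count >= 2:
            res.p_value = q_significance(
                res, method=method, n_perm=n_perm, seed=seed, y=y, strata=strata
            )
        else:
            res.p_value = float("nan")
        res.p_method = method
        rows.append((fac, res.q, res.p_value, res.strata_count))
    out = pd.DataFrame(rows, columns=["factor", "q", "p", "strata"])
    return out.sort_values("q", ascending=False, kind="stable").reset_index(drop=True)
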