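"""Synthetic landscapes with known statistical structure.

Every downstream stage of the pipeline (valuation, indices, hotspots,
geo-detector, GWR) is exercised against mosaics generated here, because the
generator controls the ground truth: realised class proportions, stratum
means for the variance-decomposition q-statistic, and spatially varying
regression coefficient surfaces for GWR.

All outputs are pure functions of (parameters, seed).  Sub-streams are
derived from the one global seed by fixed offsets so a single integer
reproduces an entire scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, LandUseGrid

__all__ = [
    "LandscapeScenario",
    "gaussian_random_field",
    "synthesize_land_use",
    "driver_surfaces",
    "gwr_truth_scenario",
    "geodetector_truth_scenario",
    "simulate_landscape",
    "DEFAULT_CLASS_PROPORTIONS",
]

# A coastal-peninsula style mosaic: mostly forest and farmland, a built-up
# fringe, some grassland/wetland and aquaculture.  These are the default
# study conditions for end-to-end runs.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "forest": 0.38,
    "dry farm": 0.22,
    "paddy field": 0.06,
    "grassland": 0.08,
    "building": 0.12,
    "wetland": 0.04,
    "salt pan": 0.02,
    "mudflat": 0.02,
    "other land use": 0.02,
    "water": 0.02,
    "fish farming": 0.02,
}

# fixed seed offsets for derived sub-streams
_OFF_FIELD = 0
_OFF_LANDUSE = 1
_OFF_DRIVERS = 2
_OFF_GWR = 3
_OFF_GEODET = 4


def _sub_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1_000_003 + offset) % (2**31 - 1)


def gaussian_random_field(
    shape: tuple[int, int], range_m: float, cell_size: float, seed: int
) -> Grid:
    """Zero-mean, unit-variance random surface with Gaussian autocorrelation.

    White noise is convolved with a Gaussian kernel of sigma = range_m / 2
    (wrap-around boundary, so the field is stationary), then standardised to
    sample mean 0 and sample sd 1.  ``range_m`` at or below ``cell_size``
    degenerates to (approximately) white noise.
    """
    if not range_m > 0:
        raise ValueError(f"autocorrelation range must be > 0, got {range_m}")
    rng = np.random.default_rng(_sub_seed(seed, _OFF_FIELD))
    noise = rng.standard_normal(shape)
    sigma_px = (range_m / 2.0) / cell_size
    if sigma_px > 1e-6:
        fieldv = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    else:
        fieldv = noise
    fieldv = fieldv - fieldv.mean()
    sd = fieldv.std()
    if sd == 0:
        raise ValueError("degenerate field (zero variance); enlarge the grid")
    fieldv /= sd
    return Grid(fieldv, cell_size)


def synthesize_land_use(
    field: Grid,
    class_proportions: Mapping[str, float],
    seed: int = 0,
    legend_start: int = 1,
) -> LandUseGrid:
    """Assign classes by slicing the latent field at its empirical quantiles.

    Pixels are ranked by field value (ties broken by flat index, so the
    output is deterministic) and the first ``round(p_1 * n)`` ranks get the
    first class, the next block the second, and so on.  Realised fractions
    therefore match the targets to within one pixel.
    """
    if not class_proportions:
        raise ValueError("class_proportions is empty")
    props = {k: float(v) for k, v in class_proportions.items()}
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {total}")
    n = field.values.size
    order = np.argsort(field.values.ravel(), kind="stable")
    cum = np.cumsum(list(props.values()))
    bounds = np.rint(cum * n).astype(int)
    bounds[-1] = n
    codes_flat = np.empty(n, dtype=np.int16)
    start = 0
    legend: dict[int, str] = {}
    for i, name in enumerate(props):
        code = legend_start + i
        legend[code] = name
        codes_flat[order[start : bounds[i]]] = code
        start = bounds[i]
    codes = codes_flat.reshape(field.shape)
    return LandUseGrid(
        codes,
        legend,
        field.cell_size,
        field.origin_x,
        field.origin_y,
        field.nodata_mask.copy(),
    )


def _distance_decay(mask: np.ndarray, cell_size: float, scale_m: float) -> np.ndarray:
    """exp(-d/scale) with d the Euclidean distance to the nearest True pixel."""
    if not mask.any():
        return np.zeros(mask.shape)
    d = ndimage.distance_transform_edt(~mask) * cell_size
    return np.exp(-d / scale_m)


def driver_surfaces(
    lu: LandUseGrid, seed: int, autocorr_range: float = 2000.0
) -> dict[str, Grid]:
    """Driver rasters correlated with the land-use mosaic.

    NDVI is high on forest/grassland and low on built land; POP and GDP decay
    with distance from built-up pixels; DEM is a smooth surface with slope as
    its gradient magnitude; precipitation and temperature are smooth fields.
    Each driver gets independent noise from a sub-stream of ``seed``.
    """
    cs = lu.cell_size
    shape = lu.shape
    base_seed = _sub_seed(seed, _OFF_DRIVERS)

    def grf(off: int, rng_m: float) -> np.ndarray:
        return gaussian_random_field(shape, rng_m, cs, base_seed + off).values

    ndvi_class = {
        "forest": 0.80, "grassland": 0.65, "paddy field": 0.55, "dry farm": 0.50,
        "wetland": 0.45, "shrubbery": 0.70, "moor": 0.35, "mudflat": 0.15,
        "other land use": 0.20, "salt pan": 0.10, "building": 0.10,
        "water": 0.05, "ocean": 0.02, "fish farming": 0.08,
    }
    present = {lu.legend[int(c)] for c in np.unique(lu.codes[~lu.nodata_mask])}
    table = {c: ndvi_class.get(c, 0.3) for c in present}
    ndvi = lu.map_classes(table, "NDVI level").values + 0.05 * grf(0, autocorr_range)
    ndvi = np.clip(ndvi, -0.1, 1.0)

    dem_v = 300.0 + 180.0 * grf(1, autocorr_range * 4)
    dy, dx = np.gradient(dem_v, cs)
    slope = np.degrees(np.arctan(np.hypot(dx, dy)))

    try:
        built = lu.mask_of({"building"})
    except ValueError:
        built = np.zeros(shape, bool)
    decay = _distance_decay(built, cs, scale_m=4 * cs)
    pop = 2000.0 * decay * np.exp(0.3 * grf(2, autocorr_range))
    gdp = 5000.0 * decay * np.exp(0.3 * grf(3, autocorr_range))

    pre = 700.0 + 80.0 * grf(4, autocorr_range * 6)
    tmp = 10.0 + 1.5 * grf(5, autocorr_range * 6)

    mask = lu.nodata_mask

    def g(v: np.ndarray) -> Grid:
        return Grid(v, cs, lu.origin_x, lu.origin_y, mask.copy())

    return {
        "ndvi": g(ndvi), "dem": g(dem_v), "slope": g(slope),
        "pop": g(pop), "gdp": g(gdp), "pre": g(pre), "tmp": g(tmp),
    }


@dataclass
class LandscapeScenario:
    """A fully generated landscape: mosaic + drivers + provenance."""

    seed: int
    shape: tuple[int, int]
    cell_size: float
    class_proportions: dict[str, float]
    autocorr_range: float
    land_use: LandUseGrid
    drivers: dict[str, Grid]
    truth: dict = field(default_factory=dict)


def simulate_landscape(
    seed: int,
    shape: tuple[int, int] = (64, 64),
    cell_size: float = 500.0,
    class_proportions: Mapping[str, float] | None = None,
    autocorr_range: float = 4000.0,
) -> LandscapeScenario:
    """Generate the default mosaic scenario (land use + seven drivers)."""
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    latent = gaussian_random_field(shape, autocorr_range, cell_size, seed)
    # shuffle class-to-quantile assignment so low latent values are not always
    # the same class; keeps fractions exact while varying spatial arrangement
    rng = np.random.default_rng(_sub_seed(seed, _OFF_LANDUSE))
    names = list(props)
    rng.shuffle(names)
    lu = synthesize_land_use(latent, {n: props[n] for n in names}, seed)
    drv = driver_surfaces(lu, seed, autocorr_range)
    return LandscapeScenario(
        seed=seed,
        shape=tuple(shape),
        cell_size=cell_size,
        class_proportions=props,
        autocorr_range=autocorr_range,
        land_use=lu,
        drivers=drv,
    )


# ---------------------------------------------------------------------------
# Truth scenarios for the attribution stages
# ---------------------------------------------------------------------------


def gwr_truth_scenario(
    shape: tuple[int, int],
    coefficient_surfaces: Sequence[Callable[[np.ndarray, np.ndarray], np.ndarray]],
    noise_sd: float,
    seed: int,
    cell_size: float = 2000.0,
) -> tuple[pd.DataFrame, dict]:
    """Cell table with spatially varying regression coefficients known exactly.

    ``coefficient_surfaces[0]`` is the intercept surface beta0(u, v); each
    further entry is the coefficient surface of one covariate.  Surfaces are
    evaluated on normalised coordinates u, v in [0, 1] (west->east,
    south->north).  Covariates are i.i.d. standard normal per cell and the
    response is ``y = beta0 + sum_k betak * x_k + eps`` with Gaussian noise.

    Returns (cell table, truth) where truth carries the beta arrays evaluated
    at the cell centroids and the noise sd.
    """
    if len(coefficient_surfaces) < 2:
        raise ValueError("need an intercept surface and at least one covariate surface")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    nr, nc = shape
    rows, cols = np.indices(shape)
    cx = (cols.ravel() + 0.5) * cell_size
    cy = (nr - rows.ravel() - 0.5) * cell_size
    u = (cols.ravel() + 0.5) / nc
    v = (nr - rows.ravel() - 0.5) / nr
    n = nr * nc
    rng = np.random.default_rng(_sub_seed(seed, _OFF_GWR))
    k = len(coefficient_surfaces) - 1
    X = rng.standard_normal((n, k))
    betas = [np.asarray(f(u, v), dtype=float) * np.ones(n) for f in coefficient_surfaces]
    y = betas[0].copy()
    for j in range(k):
        y += betas[j + 1] * X[:, j]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    table = pd.DataFrame({"cell_id": np.arange(n), "cx": cx, "cy": cy})
    for j in range(k):
        table[f"x{j + 1}"] = X[:, j]
    table["y"] = y
    truth = {
        "beta": np.column_stack(betas),
        "noise_sd": noise_sd,
        "u": u,
        "v": v,
    }
    return table, truth


def geodetector_truth_scenario(
    n_cells: int,
    stratum_means: Sequence[float],
    within_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Stratified cell table with an analytically known population q.

    Cells are split equally across strata (remainder to the first strata) and
    ``y ~ N(mean_h, within_sd**2)`` within stratum h.  For equal strata the
    infinite-n q is ``B / (B + within_sd**2)`` with B the population variance
    of the stratum means.
    """
    means = np.asarray(stratum_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 strata")
    if within_sd < 0:
        raise ValueError(f"within_sd must be >= 0, got {within_sd}")
    L = means.size
    base, rem = divmod(n_cells, L)
    sizes = np.full(L, base)
    sizes[:rem] += 1
    labels = np.repeat(np.arange(L), sizes)
    rng = np.random.default_rng(_sub_seed(seed, _OFF_GEODET))
    y = means[labels] + (rng.normal(0.0, within_sd, n_cells) if within_sd > 0 else 0.0)
    # lay cells out on a square-ish grid for completeness of centroids
    nc = int(np.ceil(np.sqrt(n_cells)))
    idx = np.arange(n_cells)
    table = pd.DataFrame(
        {
            "cell_id": idx,
            "cx": (idx % nc + 0.5) * 2000.0,
            "cy": (idx // nc + 0.5) * 2000.0,
            "stratum": labels,
            "y": y,
        }
    )
    w = sizes / sizes.sum()
    mbar = float((w * means).sum())
    between = float((w * (means - mbar) ** 2).sum())
    q_pop = between / (between + within_sd**2) if (between + within_sd**2) > 0 else 0.0
    truth = {"q_population": q_pop, "stratum_means": means, "within_sd": within_sd}
    return table, truth
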