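"""Per-cell landscape and land-use structure indices.

* HAI — human activity index: area-weighted mean of per-class anthropogenic
  intensity coefficients (expert-derived, averaged over the Lohani checklist,
  Leopold matrix and Delphi methods).
* LUI — land-use intensity: 100 x sum of (grade x area share) with grades
  1 (unused) to 5 (construction); range [100, 500].
* SHDI — Shannon's diversity index over class area fractions.
* PD — patch density: 4-connected same-class patches per 100 ha.
* natural-land share — fraction of pixels in "natural" classes (see
  :func:`esvscape.grid.class_share_per_cell`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, LandUseGrid, aggregate_to_cells

__all__ = [
    "HAI_COEFFICIENTS",
    "LUI_LEVELS",
    "NATURAL_CLASSES",
    "average_intensity_coefficient",
    "hai",
    "lui",
    "shdi",
    "patch_density",
]


def average_intensity_coefficient(lohani: float, leopold: float, delphi: float) -> float:
    """Average of the three expert intensity coefficients, to 2 decimals.

    Rounding is half-away-from-zero so e.g. (0.96, 0.94, 0.91) -> 0.94.
    """
    for v in (lohani, leopold, delphi):
        if not 0 <= v <= 1:
            raise ValueError(f"intensity coefficients must be in [0,1], got {v}")
    mean = (lohani + leopold + delphi) / 3.0
    return math.floor(mean * 100 + 0.5) / 100.0


# Published expert rows (Lohani / Leopold / Delphi) averaged per class.
# Aquaculture and mudflat have no published row; nearest ecological analogues
# (water 0.12, other land use 0.08) are assigned — both configurable.
_EXPERT_ROWS: dict[str, tuple[float, float, float]] = {
    "forest": (0.12, 0.11, 0.13),
    "dry farm": (0.57, 0.58, 0.62),
    "paddy field": (0.55, 0.57, 0.65),
    "grassland": (0.09, 0.08, 0.10),
    "building": (0.96, 0.94, 0.91),
    "wetland": (0.15, 0.13, 0.14),
    "salt pan": (0.08, 0.09, 0.07),
    "other land use": (0.11, 0.06, 0.07),
    "water": (0.10, 0.14, 0.12),
}

HAI_COEFFICIENTS: dict[str, float] = {
    cls: average_intensity_coefficient(*rows) for cls, rows in _EXPERT_ROWS.items()
}
HAI_COEFFICIENTS.update(
    {
        "fish farming": HAI_COEFFICIENTS["water"],
        "mudflat": HAI_COEFFICIENTS["other land use"],
        "moor": HAI_COEFFICIENTS["wetland"],
        "ocean": HAI_COEFFICIENTS["water"],
        "shrubbery": HAI_COEFFICIENTS["forest"],
    }
)

# Land-use intensity grades, 1 = unused ... 5 = construction.
LUI_LEVELS: dict[str, int] = {
    "mudflat": 1,
    "other land use": 1,
    "moor": 1,
    "wetland": 1,  # undeveloped wet land, grouped with moor/mudflat
    "ocean": 2,
    "water": 2,
    "forest": 2,
    "grassland": 2,
    "shrubbery": 2,
    "fish farming": 3,
    "dry farm": 4,
    "paddy field": 4,
    "salt pan": 4,
    "building": 5,
}

NATURAL_CLASSES: set[str] = {
    "forest", "grassland", "wetland", "moor", "shrubbery", "mudflat", "water", "ocean",
}


def _check_table(lu: LandUseGrid, table: dict, what: str) -> None:
    present = {lu.legend[int(c)] for c in np.unique(lu.codes[~lu.nodata_mask])}
    missing = present - set(table)
    if missing:
        raise ValueError(f"missing {what} for class(es): {sorted(missing)}")


def hai(
    lu: LandUseGrid,
    cell_size_out: float,
    coefficients: dict[str, float] | None = None,
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Human activity index per analysis cell (area-weighted mean intensity)."""
    coeffs = HAI_COEFFICIENTS if coefficients is None else coefficients
    _check_table(lu, coeffs, "HAI coefficient")
    for cls_name, p in coeffs.items():
        if not 0 <= p <= 1:
            raise ValueError(f"HAI coefficient for {cls_name!r} must be in [0,1]")
    g = lu.map_classes(coeffs, "HAI coefficient")
    return aggregate_to_cells(g, cell_size_out, min_valid_fraction, "mean", column="hai")


def lui(
    lu: LandUseGrid,
    cell_size_out: float,
    levels: dict[str, int] | None = None,
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Land-use intensity index per cell: 100 x sum(grade x area share)."""
    lv = LUI_LEVELS if levels is None else levels
    _check_table(lu, lv, "LUI grade")
    for cls_name, grade in lv.items():
        if grade not in {1, 2, 3, 4, 5}:
            raise ValueError(f"LUI grade for {cls_name!r} must be 1..5, got {grade}")
    g = lu.map_classes({k: float(v) for k, v in lv.items()}, "LUI grade")
    out = aggregate_to_cells(g, cell_size_out, min_valid_fraction, "mean", column="lui")
    out["lui"] = 100.0 * out["lui"]
    return out


def shdi(
    lu: LandUseGrid, cell_size_out: float, min_valid_fraction: float = 0.5
) -> pd.DataFrame:
    """Shannon's diversity index per cell: -sum p_k ln p_k over class shares."""
    from .grid import _block_view  # blockwise view of the fine raster

    codes = Grid(
        lu.codes.astype(float), lu.cell_size, lu.origin_x, lu.origin_y, lu.nodata_mask
    )
    vals, valid, _ = _block_view(codes, cell_size_out)
    base = aggregate_to_cells(codes, cell_size_out, min_valid_fraction, "mean", column="shdi")
    out = np.empty(len(base))
    for i, (r, c) in enumerate(zip(base["row"], base["col"])):
        v = vals[r, c][valid[r, c]]
        _, counts = np.unique(v, return_counts=True)
        p = counts / counts.sum()
        out[i] = float(-(p * np.log(p)).sum())
    base["shdi"] = out
    return base


def patch_density(
    lu: LandUseGrid, cell_size_out: float, min_valid_fraction: float = 0.5
) -> pd.DataFrame:
    """4-connected same-class patches per 100 ha, patches clipped at cell edges."""
    codes = Grid(
        lu.codes.astype(float), lu.cell_size, lu.origin_x, lu.origin_y, lu.nodata_mask
    )
    base = aggregate_to_cells(codes, cell_size_out, min_valid_fraction, "mean", column="pd")
    factor = int(round(cell_size_out / lu.cell_size))
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    area_100ha = (cell_size_out**2 / 1e4) / 100.0
    out = np.empty(len(base))
    for i, (r, c) in enumerate(zip(base["row"], base["col"])):
        block = lu.codes[r * factor : (r + 1) * factor, c * factor : (c + 1) * factor]
        bmask = lu.nodata_mask[r * factor : (r + 1) * factor, c * factor : (c + 1) * factor]
        n_patches = 0
        for code in np.unique(block[~bmask]):
            _, n = ndimage.label((block == code) & ~bmask, structure=structure)
            n_patches += n
        out[i] = n_patches / area_100ha
    base["pd"] = out
    return base
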