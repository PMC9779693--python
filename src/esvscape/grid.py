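"""Raster data model, I/O and aggregation to the coarse analysis grid.

The :class:`Grid` is the universal currency of the pipeline: a single-band,
north-up, square-pixel raster with an explicit nodata mask.  Fine rasters
(land use, drivers, per-pixel service values) are aggregated onto a coarse
analysis grid (2 km by default) whose retained cells become rows of a
"cell table" — a plain :class:`pandas.DataFrame` with columns
``cell_id, cx, cy, valid_fraction`` plus one named column per variable.

Supported file formats are ESRI ASCII grid (``.asc``/``.txt``) and GeoTIFF
(``.tif``/``.tiff``, georeferencing via ModelPixelScale/ModelTiepoint tags).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "LandUseGrid",
    "read_raster",
    "write_raster",
    "aggregate_to_cells",
    "class_share_per_cell",
    "build_cell_table",
]

# GeoTIFF / GDAL private tags
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """Single-band raster: values + square cell size + top-left origin + mask.

    Row 0 is the northmost row; pixel ``(r, c)`` covers the half-open square
    ``[origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s, origin_y - r*s]``
    with ``s = cell_size`` in metres.  ``nodata_mask`` is True where the pixel
    carries no data; arithmetic between grids propagates nodata (any nodata
    operand makes the result pixel nodata).
    """

    values: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                f"nodata_mask shape {self.nodata_mask.shape} != values shape "
                f"{self.values.shape}"
            )
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of values at non-nodata pixels."""
        return self.values[~self.nodata_mask]

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """(cx, cy) coordinate arrays of pixel centres, same shape as values."""
        rows, cols = np.indices(self.shape)
        cx = self.origin_x + (cols + 0.5) * self.cell_size
        cy = self.origin_y - (rows + 0.5) * self.cell_size
        return cx, cy

    def copy(self) -> "Grid":
        return Grid(
            self.values.copy(),
            self.cell_size,
            self.origin_x,
            self.origin_y,
            self.nodata_mask.copy(),
        )

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New grid with this grid's georeferencing and the given values."""
        m = self.nodata_mask.copy() if mask is None else mask
        return Grid(np.asarray(values, float), self.cell_size, self.origin_x, self.origin_y, m)

    # -- nodata-propagating arithmetic --------------------------------------
    def _binary(self, other, op) -> "Grid":
        if isinstance(other, Grid):
            if other.shape != self.shape:
                raise ValueError("shape mismatch in grid arithmetic")
            with np.errstate(all="ignore"):
                vals = op(self.values, other.values)
            mask = self.nodata_mask | other.nodata_mask
        else:
            with np.errstate(all="ignore"):
                vals = op(self.values, other)
            mask = self.nodata_mask.copy()
        return Grid(vals, self.cell_size, self.origin_x, self.origin_y, mask)

    def __add__(self, other):
        return self._binary(other, np.add)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract)

    def __mul__(self, other):
        return self._binary(other, np.multiply)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, np.divide)

    def equals(self, other: "Grid", atol: float = 0.0) -> bool:
        """Equality on metadata, mask (exact) and values at valid pixels."""
        if self.shape != other.shape:
            return False
        if not np.array_equal(self.nodata_mask, other.nodata_mask):
            return False
        if not (
            np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        ):
            return False
        a = self.values[~self.nodata_mask]
        b = other.values[~other.nodata_mask]
        return bool(np.allclose(a, b, atol=atol, rtol=0))


@dataclass
class LandUseGrid:
    """Integer-coded land-use raster with a legend mapping codes to classes."""

    codes: np.ndarray
    legend: dict[int, str]
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("land-use codes must be integers")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        present = np.unique(self.codes[~self.nodata_mask])
        unknown = [int(c) for c in present if int(c) not in self.legend]
        if unknown:
            raise ValueError(
                f"codes {unknown} present in raster but missing from legend "
                f"{sorted(self.legend)}"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def classes(self) -> list[str]:
        return list(self.legend.values())

    def code_for(self, name: str) -> int:
        for code, cls in self.legend.items():
            if cls == name:
                return code
        raise KeyError(f"class {name!r} not in legend {list(self.legend.values())}")

    def class_areas(self) -> dict[str, float]:
        """Hectares per class over valid pixels (pixel area = cell_size² m²)."""
        px_ha = self.cell_size**2 / 1e4
        valid = self.codes[~self.nodata_mask]
        counts = {}
        for code, name in self.legend.items():
            counts[name] = float((valid == code).sum()) * px_ha
        return counts

    def mask_of(self, names: set[str] | list[str]) -> np.ndarray:
        """Boolean pixel mask of the named classes (nodata pixels False)."""
        names = set(names)
        unknown = names - set(self.legend.values())
        if unknown:
            raise ValueError(
                f"unknown class name(s) {sorted(unknown)}; legend has "
                f"{sorted(self.legend.values())}"
            )
        codes = [c for c, n in self.legend.items() if n in names]
        m = np.isin(self.codes, codes)
        m[self.nodata_mask] = False
        return m

    def as_grid(self) -> Grid:
        return Grid(
            self.codes.astype(float),
            self.cell_size,
            self.origin_x,
            self.origin_y,
            self.nodata_mask.copy(),
        )

    def map_classes(self, table: dict[str, float], what: str = "coefficient") -> Grid:
        """Grid whose pixels carry ``table[class]``; errors on a missing class."""
        present = {self.legend[int(c)] for c in np.unique(self.codes[~self.nodata_mask])}
        missing = present - set(table)
        if missing:
            raise ValueError(f"missing {what} for class(es): {sorted(missing)}")
        out = np.zeros(self.shape, dtype=float)
        for code, name in self.legend.items():
            out[self.codes == code] = table.get(name, 0.0)
        return Grid(out, self.cell_size, self.origin_x, self.origin_y, self.nodata_mask.copy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_ascii(path: str) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "xllcenter",
            "yllcenter",
            "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header or "cellsize" not in header:
        raise IOError(f"not a valid ESRI ASCII grid: {path}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    body = " ".join(lines[i:])
    values = np.array(body.split(), dtype=float)
    if values.size != nrows * ncols:
        raise IOError(
            f"{path}: expected {nrows * ncols} values, found {values.size}"
        )
    values = values.reshape(nrows, ncols)
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    else:
        x0 = header.get("xllcenter", 0.0) - cell / 2
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header.get("yllcenter", 0.0) - cell / 2
    mask = values == nodata
    return Grid(values, cell, origin_x=x0, origin_y=yll + nrows * cell, nodata_mask=mask)


def _write_ascii(grid: Grid, path: str, nodata: float = _DEFAULT_NODATA) -> None:
    nrows, ncols = grid.shape
    vals = np.asarray(grid.values, dtype=np.float32).astype(float)
    out = vals.copy()
    out[grid.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y - nrows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_tiff(path: str, band: int | None = None) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        tags = tf.pages[0].tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00").strip())
    if arr.ndim == 3:
        if band is None:
            raise ValueError(
                f"{path} has {arr.shape[0]} bands; pass band= to select one"
            )
        arr = arr[band]
    elif band not in (None, 0):
        raise ValueError(f"{path} is single-band; band={band} out of range")
    values = arr.astype(np.float64)
    if nodata is None:
        mask = ~np.isfinite(values)
    else:
        mask = (values == nodata) | ~np.isfinite(values)
    return Grid(values, float(scale[0]), origin_x=float(tie[3]), origin_y=float(tie[4]), nodata_mask=mask)


def _write_tiff(grid: Grid, path: str, nodata: float = _DEFAULT_NODATA) -> None:
    import tifffile

    out = grid.values.astype(np.float32)
    out[grid.nodata_mask] = np.float32(nodata)
    s = float(grid.cell_size)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def read_raster(path: str, band: int | None = None) -> Grid:
    """Read a GeoTIFF or ESRI ASCII grid into a :class:`Grid`.

    The file's nodata value populates the mask.  ``band`` selects a band from
    a multi-band GeoTIFF (required there, ignored for ASCII grids).
    """
    if not os.path.exists(path):
        raise IOError(f"raster file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in {".tif", ".tiff"}:
            return _read_tiff(path, band=band)
        return _read_ascii(path)
    except (IOError, ValueError):
        raise
    except Exception as exc:  # corrupt file etc.
        raise IOError(f"could not read raster {path}: {exc}") from exc


def write_raster(grid: Grid, path: str, nodata: float = _DEFAULT_NODATA) -> str:
    """Write a Grid to GeoTIFF (.tif/.tiff) or ESRI ASCII grid (anything else).

    Values are stored as float32; read_raster(write_raster(g)) reproduces the
    grid to float32 precision with an exact mask.
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    ext = os.path.splitext(path)[1].lower()
    if ext in {".tif", ".tiff"}:
        _write_tiff(grid, path, nodata)
    else:
        _write_ascii(grid, path, nodata)
    return path


# ---------------------------------------------------------------------------
# Aggregation to analysis cells
# ---------------------------------------------------------------------------


def _block_view(grid: Grid, cell_size_out: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Pad to a multiple of the block factor and return (values, valid) stacks.

    Returns arrays of shape (n_cell_rows, n_cell_cols, factor*factor) plus the
    factor.  Padded pixels count as invalid.
    """
    ratio = cell_size_out / grid.cell_size
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"analysis cell size {cell_size_out} is not an integer multiple of "
            f"the fine cell size {grid.cell_size}"
        )
    nr, nc = grid.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    vals = np.pad(grid.values, ((0, pr), (0, pc)), constant_values=np.nan)
    valid = np.pad(~grid.nodata_mask, ((0, pr), (0, pc)), constant_values=False)
    R, C = vals.shape
    vals = vals.reshape(R // factor, factor, C // factor, factor).swapaxes(1, 2)
    valid = valid.reshape(R // factor, factor, C // factor, factor).swapaxes(1, 2)
    vals = vals.reshape(vals.shape[0], vals.shape[1], -1)
    valid = valid.reshape(valid.shape[0], valid.shape[1], -1)
    return vals, valid, factor


def aggregate_to_cells(
    fine: Grid,
    cell_size_out: float,
    min_valid_fraction: float = 0.5,
    stat: str = "mean",
    column: str = "value",
) -> pd.DataFrame:
    """Aggregate a fine raster to the coarse analysis grid.

    Each analysis cell is a ``factor x factor`` block of fine pixels, where
    ``factor = cell_size_out / fine.cell_size`` (must be integer).  The
    statistic is computed over non-nodata pixels only; cells whose valid
    fraction falls below ``min_valid_fraction`` are dropped.

    Returns a DataFrame with columns
    ``cell_id, row, col, cx, cy, valid_fraction, <column>``.
    """
    if stat not in {"mean", "sum", "majority"}:
        raise ValueError(f"stat must be mean, sum or majority, got {stat!r}")
    vals, valid, factor = _block_view(fine, cell_size_out)
    n_per = valid.shape[-1]
    nvalid = valid.sum(axis=-1)
    frac = nvalid / n_per
    with np.errstate(invalid="ignore", divide="ignore"):
        if stat == "mean":
            tot = np.where(valid, vals, 0.0).sum(axis=-1)
            out = np.where(nvalid > 0, tot / np.maximum(nvalid, 1), np.nan)
        elif stat == "sum":
            out = np.where(valid, vals, 0.0).sum(axis=-1)
        else:  # majority (for categorical rasters)
            out = np.full(frac.shape, np.nan)
            for r in range(out.shape[0]):
                for c in range(out.shape[1]):
                    v = vals[r, c][valid[r, c]]
                    if v.size:
                        u, cnt = np.unique(v, return_counts=True)
                        out[r, c] = u[np.argmax(cnt)]
    keep = (frac >= min_valid_fraction) & (nvalid > 0)
    if not keep.any():
        raise ValueError(
            "aggregation dropped every analysis cell "
            f"(min_valid_fraction={min_valid_fraction})"
        )
    rows, cols = np.nonzero(keep)
    ncc = keep.shape[1]
    df = pd.DataFrame(
        {
            "cell_id": rows * ncc + cols,
            "row": rows,
            "col": cols,
            "cx": fine.origin_x + (cols + 0.5) * cell_size_out,
            "cy": fine.origin_y - (rows + 0.5) * cell_size_out,
            "valid_fraction": frac[rows, cols],
            column: out[rows, cols],
        }
    )
    return df


def class_share_per_cell(
    lu: LandUseGrid,
    cell_size_out: float,
    classes: set[str] | list[str],
    min_valid_fraction: float = 0.5,
    column: str = "share",
) -> pd.DataFrame:
    """Fraction of valid fine pixels per analysis cell in the named classes."""
    indicator = lu.mask_of(classes).astype(float)
    g = Grid(indicator, lu.cell_size, lu.origin_x, lu.origin_y, lu.nodata_mask.copy())
    return aggregate_to_cells(g, cell_size_out, min_valid_fraction, "mean", column=column)


def build_cell_table(columns: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-cell columns (each from :func:`aggregate_to_cells`) on cell_id.

    Keeps the intersection of retained cells so every row is complete.
    """
    if not columns:
        raise ValueError("no columns to join")
    out = None
    for name, df in columns.items():
        valcol = [c for c in df.columns if c not in {"cell_id", "row", "col", "cx", "cy", "valid_fraction"}]
        if len(valcol) != 1:
            raise ValueError(f"column frame {name!r} must carry exactly one value column")
        part = df[["cell_id", "row", "col", "cx", "cy", "valid_fraction", valcol[0]]].rename(
            columns={valcol[0]: name}
        )
        if out is None:
            out = part
        else:
            out = out.merge(
                part.drop(columns=["row", "col", "cx", "cy"]), on="cell_id", how="inner",
                suffixes=("", "_r"),
            )
            out["valid_fraction"] = np.minimum(out["valid_fraction"], out.pop("valid_fraction_r"))
    return out.reset_index(drop=True)
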