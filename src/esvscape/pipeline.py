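"""End-to-end orchestration: simulate -> value -> indices -> aggregate ->
hotspots -> detect -> gwr -> report, from a single validated config.

Outputs are deterministic for a fixed seed: CSVs are written with a fixed
float format so reruns are byte-identical (the manifest also records
per-stage wall time, which is excluded from that guarantee).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from . import __version__
from .defaults import default_economic_params, default_habitat_params
from .geodetector import rank_factors
from .grid import Grid, LandUseGrid, aggregate_to_cells, build_cell_table, class_share_per_cell, write_raster
from .gwr import local_fit, select_bandwidth, sign_summary
from .indices import NATURAL_CLASSES, hai, lui, patch_density, shdi
from .spatial import build_weights, gi_star
from .synthetic import LandscapeScenario, simulate_landscape
from .valuation import (
    ServiceGrids,
    compute_npp,
    food_production_value,
    habitat_degradation,
    habitat_quality,
    habitat_support_value,
    landscape_aesthetic_value,
    npp_value,
    rusle_retention,
    soil_retention_value,
    total_esv,
    water_conservation_value,
    water_retention,
    water_yield,
)

__all__ = ["RunConfig", "run_pipeline", "change_report", "value_services", "assemble_cell_table"]

_CSV_FLOAT = "%.10g"
ALL_STAGES = ("simulate", "value", "indices", "hotspots", "detect", "gwr", "report")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    rows: int = 64
    cols: int = 64
    cell_size: float = 500.0
    analysis_cell_size: float = 2000.0
    min_valid_fraction: float = 0.5
    autocorr_range: float = 4000.0
    band_distance: float | None = None  # default: 1.5 x analysis cell size
    stages: tuple[str, ...] = ALL_STAGES
    detect_factors: tuple[str, ...] = (
        "ndvi", "lui", "hai", "pop", "gdp", "natural", "dem", "slope",
        "shdi", "pd", "tmp", "pre",
    )
    gwr_factors: tuple[str, ...] = ("lui", "hai", "natural", "dem", "slope")
    gwr_separate: bool = True
    k_classes: int = 9
    n_perm: int = 999
    class_proportions: dict | None = None
    write_rasters: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}; valid: {ALL_STAGES}")
        if self.analysis_cell_size % self.cell_size != 0:
            raise ValueError("analysis_cell_size must be a multiple of cell_size")
        if self.band_distance is None:
            self.band_distance = 1.5 * self.analysis_cell_size

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s): {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        d = dict(d)
        for key in ("stages", "detect_factors", "gwr_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# valuation-stage input surfaces derived from the synthetic drivers
# ---------------------------------------------------------------------------


def _service_inputs(scn: LandscapeScenario) -> dict[str, Grid]:
    """Biophysical inputs for the valuation, derived from the driver surfaces.

    APAR scales with NDVI (more absorbed radiation under denser canopies);
    AET is a class-dependent fraction of precipitation; terrain/soil factors
    come from slope; RUSLE rainfall erosivity follows precipitation and the
    cover factor falls with NDVI.
    """
    lu, drv = scn.land_use, scn.drivers
    ndvi = drv["ndvi"].values
    pre = drv["pre"].values
    slope = drv["slope"].values

    like = drv["ndvi"].like
    apar = like(np.clip(ndvi, 0, None) * 2400.0)  # MJ/m2/a
    epsilon = like(np.full(lu.shape, 0.5))  # gC/MJ

    aet_frac = lu.map_classes(
        {c: f for c, f in {
            "forest": 0.60, "shrubbery": 0.60, "grassland": 0.55, "wetland": 0.40,
            "dry farm": 0.65, "paddy field": 0.55, "building": 0.30,
            "salt pan": 0.35, "mudflat": 0.40, "other land use": 0.50,
            "water": 0.35, "ocean": 0.35, "fish farming": 0.35, "moor": 0.45,
        }.items()},
        "AET fraction",
    ).values
    precip = like(pre)
    aet = like(aet_frac * pre)

    velocity = like(np.full(lu.shape, 300.0) - 4.0 * slope)  # gentler: slower runoff
    ti = like(8.0 - 0.15 * slope)
    ksat = like(np.full(lu.shape, 150.0) + 2.0 * slope)

    r_fac = like(0.01 * pre * 1.5)
    k_fac = like(np.full(lu.shape, 0.32))
    ls_fac = like(0.2 + 0.25 * slope)
    c_fac = like(np.clip(1.0 - np.clip(ndvi, 0, 1), 0.05, 1.0))
    p_fac = lu.map_classes(
        {c: (0.35 if c in {"dry farm", "paddy field"} else 1.0) for c in lu.classes},
        "P factor",
    )
    return {
        "apar": apar, "epsilon": epsilon, "precip": precip, "aet": aet,
        "velocity": velocity, "ti": ti, "ksat": ksat,
        "r": r_fac, "k": k_fac, "ls": ls_fac, "cfac": c_fac, "pfac": p_fac,
    }


def value_services(scn: LandscapeScenario, economic=None, habitat=None) -> ServiceGrids:
    """Run the six valuations on a synthetic scenario with default params."""
    params = economic or default_economic_params()
    hp = habitat or default_habitat_params()
    lu = scn.land_use
    inp = _service_inputs(scn)
    food = food_production_value(lu, params)
    npp = compute_npp(inp["apar"], inp["epsilon"])
    carbon = npp_value(npp, params)
    wy = water_yield(inp["precip"], inp["aet"])
    wr = water_retention(wy, inp["velocity"], inp["ti"], inp["ksat"])
    water = water_conservation_value(wr, params)
    s_amt = rusle_retention(inp["r"], inp["k"], inp["ls"], inp["cfac"], inp["pfac"])
    soil = soil_retention_value(s_amt, params)
    D = habitat_degradation(lu, hp)
    Q = habitat_quality(lu, D, hp)
    habitat_v = habitat_support_value(Q, lu, params)
    aesthetic = landscape_aesthetic_value(lu, params)
    return ServiceGrids(food, carbon, water, soil, habitat_v, aesthetic)


def assemble_cell_table(scn: LandscapeScenario, services: ServiceGrids, cfg: RunConfig) -> pd.DataFrame:
    """Aggregate ESV and all drivers/indices to the analysis grid."""
    lu = scn.land_use
    acs, mvf = cfg.analysis_cell_size, cfg.min_valid_fraction
    cols: dict[str, pd.DataFrame] = {
        "esv_per_area": aggregate_to_cells(services.total, acs, mvf, "mean"),
    }
    for name in ("ndvi", "dem", "slope", "pop", "gdp", "pre", "tmp"):
        cols[name] = aggregate_to_cells(scn.drivers[name], acs, mvf, "mean")
    cols["natural"] = class_share_per_cell(
        lu, acs, NATURAL_CLASSES & set(lu.classes), mvf
    )
    cols["hai"] = hai(lu, acs, min_valid_fraction=mvf)
    cols["lui"] = lui(lu, acs, min_valid_fraction=mvf)
    cols["shdi"] = shdi(lu, acs, min_valid_fraction=mvf)
    cols["pd"] = patch_density(lu, acs, min_valid_fraction=mvf)
    return build_cell_table(cols)


def change_report(summary1: pd.DataFrame, summary2: pd.DataFrame) -> pd.DataFrame:
    """Between-year change table: absolute loss and percent change per category.

    ``change`` is year1 minus year2 (positive = decline);
    ``pct_change = 100 (v1 - v2) / v1`` rounded to 2 decimals.  The two
    summaries must cover identical categories.
    """
    if list(summary1.index) != list(summary2.index):
        raise ValueError(
            f"category mismatch: {list(summary1.index)} vs {list(summary2.index)}"
        )
    v1 = summary1["total_cny"].astype(float)
    v2 = summary2["total_cny"].astype(float)
    out = pd.DataFrame(index=summary1.index)
    out["year1_cny"] = v1
    out["year2_cny"] = v2
    out["change"] = v1 - v2
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (v1 - v2) / v1
    out["pct_change"] = np.round(pct.replace([np.inf, -np.inf], np.nan), 2)
    return out


def _write_csv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_CSV_FLOAT)


def run_pipeline(config: RunConfig | dict, out_dir: str) -> str:
    """Run the configured stages; returns the run directory.

    Artifacts: ``cells.csv`` (cell table), ``summary_by_service.csv`` /
    ``summary_by_class.csv``, ``hotspots.csv``, ``geodetector.csv``,
    ``gwr_diagnostics.json`` + ``gwr_coefficients_<x>.csv`` +
    ``gwr_signs.csv``, and ``manifest.json``.
    """
    cfg = RunConfig.from_dict(config) if isinstance(config, dict) else config
    os.makedirs(out_dir, exist_ok=True)
    timings: dict[str, float] = {}
    stages = set(cfg.stages)

    def stage(name: str) -> bool:
        return name in stages

    t0 = time.perf_counter()
    scn = simulate_landscape(
        cfg.seed, (cfg.rows, cfg.cols), cfg.cell_size,
        cfg.class_proportions, cfg.autocorr_range,
    )
    timings["simulate"] = time.perf_counter() - t0
    if cfg.write_rasters and stage("simulate"):
        write_raster(scn.land_use.as_grid(), os.path.join(out_dir, "land_use.asc"))
        for name, g in scn.drivers.items():
            write_raster(g, os.path.join(out_dir, f"driver_{name}.asc"))

    t0 = time.perf_counter()
    services = value_services(scn)
    summaries = total_esv(services, scn.land_use)
    timings["value"] = time.perf_counter() - t0
    if stage("value"):
        _write_csv(summaries["by_service"], os.path.join(out_dir, "summary_by_service.csv"), index=True)
        _write_csv(summaries["by_class"], os.path.join(out_dir, "summary_by_class.csv"), index=True)
        if cfg.write_rasters:
            for name, g in services.items():
                write_raster(g, os.path.join(out_dir, f"service_{name}.asc"))

    t0 = time.perf_counter()
    cells = assemble_cell_table(scn, services, cfg)
    timings["indices"] = time.perf_counter() - t0
    _write_csv(cells, os.path.join(out_dir, "cells.csv"))

    if stage("hotspots"):
        t0 = time.perf_counter()
        w = build_weights(cells, "distance_band", cfg.band_distance, include_self=True)
        hot = gi_star(cells, w, "esv_per_area")
        timings["hotspots"] = time.perf_counter() - t0
        _write_csv(hot, os.path.join(out_dir, "hotspots.csv"))

    if stage("detect"):
        t0 = time.perf_counter()
        det = rank_factors(
            cells, "esv_per_area", list(cfg.detect_factors),
            k_classes=cfg.k_classes, n_perm=cfg.n_perm, seed=cfg.seed,
        )
        timings["detect"] = time.perf_counter() - t0
        _write_csv(det, os.path.join(out_dir, "geodetector.csv"))

    if stage("gwr"):
        t0 = time.perf_counter()
        diags = {}
        signs = []
        fits = {}
        groups = (
            [[f] for f in cfg.gwr_factors] if cfg.gwr_separate else [list(cfg.gwr_factors)]
        )
        for xs in groups:
            key = "+".join(xs)
            bw = select_bandwidth(cells, "esv_per_area", xs)
            fit = local_fit(cells, "esv_per_area", xs, bw)
            fits[key] = fit
            diags[key] = fit.diagnostics()
            s = sign_summary(fit)
            s.insert(0, "model", key)
            signs.append(s)
            _write_csv(fit.coefficients, os.path.join(out_dir, f"gwr_coefficients_{key}.csv"))
        timings["gwr"] = time.perf_counter() - t0
        with open(os.path.join(out_dir, "gwr_diagnostics.json"), "w") as fh:
            json.dump(diags, fh, indent=2, sort_keys=True)
        _write_csv(pd.concat(signs, ignore_index=True), os.path.join(out_dir, "gwr_signs.csv"))

    manifest = {
        "package": "esvscape",
        "version": __version__,
        "seed": cfg.seed,
        "param_hash": cfg.param_hash(),
        "stages": sorted(stages),
        "n_cells": int(len(cells)),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
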