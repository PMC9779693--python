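"""Per-hectare annual valuation of six ecosystem services on raster land use.

Services and the economic methods behind them:

* food production — market value of per-hectare yields times prices times an
  average profit margin;
* carbon sequestration & oxygen release — NPP-based: each tonne of net primary
  production fixes 1.63 t of carbon and releases 1.2 t of oxygen, priced at
  the social cost of carbon and the industrial oxygen production cost;
* water conservation — water-yield (precipitation minus actual
  evapotranspiration) retained by terrain/soil capacity, priced at the
  reservoir construction cost per cubic metre (shadow project approach);
* soil retention — RUSLE potential-minus-actual erosion, valued as avoided
  reservoir sedimentation (24% of retained sediment settles in reservoirs,
  rivers and lakes) plus avoided farmland abandonment (forestry income on the
  land area the retained soil depth represents);
* habitat support — InVEST-style habitat quality (suitability degraded by
  distance-decayed threats) scaled by a biodiversity baseline value built from
  per-class equivalent factors (1/7 of the grain output value per hectare);
* landscape aesthetics — equivalent-factor value corrected by the ratio of
  local to national tourism income per hectare.

All service grids are in CNY per hectare per year (CNY/ha/a).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, LandUseGrid

__all__ = [
    "FoodItem",
    "EconomicParams",
    "HabitatParams",
    "ServiceGrids",
    "food_production_value",
    "compute_npp",
    "npp_value",
    "water_yield",
    "water_retention",
    "water_conservation_value",
    "rusle_retention",
    "soil_retention_value",
    "habitat_degradation",
    "habitat_quality",
    "habitat_support_value",
    "biodiversity_baseline",
    "landscape_aesthetic_value",
    "total_esv",
]

# threat decay constant so that influence drops to ~5% at the maximum
# distance: exp(-2.99) ~ 0.0503 (InVEST habitat-quality convention)
THREAT_DECAY = 2.99
EQUIVALENT_DIVISOR = 7.0  # one "equivalent" = 1/7 of grain output value per ha


@dataclass
class FoodItem:
    """One food commodity: yield (t/ha/a), price (CNY/kg), profit margin."""

    yield_t_per_ha: float
    price_per_kg: float
    margin: float

    def __post_init__(self) -> None:
        if self.yield_t_per_ha < 0 or self.price_per_kg < 0:
            raise ValueError("food yield and price must be nonnegative")
        if not 0 <= self.margin <= 1:
            raise ValueError(f"profit margin must be in [0,1], got {self.margin}")

    @property
    def value(self) -> float:
        """CNY/ha/a; yield converted t -> kg."""
        return self.yield_t_per_ha * 1000.0 * self.price_per_kg * self.margin


@dataclass
class EconomicParams:
    """All prices, costs and equivalent factors of the valuation in one place.

    Units: carbon_cost CNY/t C; oxygen_cost CNY/t O2; reservoir_cost CNY/m3;
    soil bulk density g/cm3 (numerically t/m3); soil thickness m; forestry
    income CNY/ha; grain yield kg/ha; grain price CNY/kg; tourism incomes
    CNY/ha.  ``equivalent_A`` / ``equivalent_L`` are the per-class habitat
    support / landscape aesthetics equivalent factors.
    """

    food_items: dict[str, list[FoodItem]] = field(default_factory=dict)
    carbon_cost: float = 1170.0
    oxygen_cost: float = 400.0
    reservoir_cost: float = 6.11
    sediment_deposit_ratio: float = 0.24
    soil_bulk_density: float = 1.25
    soil_thickness: float = 0.5
    forestry_income: float = 3000.0
    grain_yield: float = 6000.0
    grain_price: float = 2.5
    equivalent_A: dict[str, float] = field(default_factory=dict)
    equivalent_L: dict[str, float] = field(default_factory=dict)
    tourism_local: float = 1.0
    tourism_national: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "carbon_cost", "oxygen_cost", "reservoir_cost", "soil_bulk_density",
            "soil_thickness", "forestry_income", "grain_yield", "grain_price",
            "tourism_local",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.sediment_deposit_ratio <= 1:
            raise ValueError("sediment_deposit_ratio must be in [0,1]")
        if not self.tourism_national > 0:
            raise ValueError("tourism_national must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "EconomicParams":
        d = dict(d)
        items = {
            cls_name: [FoodItem(**it) for it in lst]
            for cls_name, lst in d.pop("food_items", {}).items()
        }
        return cls(food_items=items, **d)


@dataclass
class HabitatParams:
    """InVEST-style habitat quality parameters.

    ``suitability`` maps each land-use class to H in [0,1]; threats are land
    uses exerting pressure (buildings, farmland, aquaculture by default) with
    relative weights, maximum influence distances (m), and per-class
    sensitivities S in [0,1].  ``z`` shapes the degradation response; the
    half-saturation constant is half the maximum observed degradation.
    """

    suitability: dict[str, float]
    threats: dict[str, dict] = field(default_factory=dict)
    sensitivity: dict[str, dict[str, float]] = field(default_factory=dict)
    z: float = 2.5

    def __post_init__(self) -> None:
        for cls_name, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"suitability for {cls_name!r} must be in [0,1]")
        for t, spec in self.threats.items():
            if spec.get("max_distance", 1.0) <= 0:
                raise ValueError(f"threat {t!r} max_distance must be > 0")
            if spec.get("weight", 1.0) < 0:
                raise ValueError(f"threat {t!r} weight must be >= 0")
        for cls_name, row in self.sensitivity.items():
            for t, s in row.items():
                if not 0 <= s <= 1:
                    raise ValueError(f"sensitivity[{cls_name}][{t}] must be in [0,1]")
        if not self.z > 0:
            raise ValueError("z must be > 0")


@dataclass
class ServiceGrids:
    """The six service value grids (CNY/ha/a) plus their pixelwise total."""

    food: Grid
    carbon_oxygen: Grid
    water: Grid
    soil: Grid
    habitat: Grid
    aesthetic: Grid

    NAMES = ("food", "carbon_oxygen", "water", "soil", "habitat", "aesthetic")

    @property
    def total(self) -> Grid:
        return (
            self.food + self.carbon_oxygen + self.water
            + self.soil + self.habitat + self.aesthetic
        )

    def items(self):
        for n in self.NAMES:
            yield n, getattr(self, n)


# ---------------------------------------------------------------------------
# (1) food production
# ---------------------------------------------------------------------------


def food_production_value(lu: LandUseGrid, params: EconomicParams) -> Grid:
    """Sum over food items of yield * price * margin, per land-use class.

    Classes with no food items (forest, building, ...) value to zero.
    """
    table = {name: 0.0 for name in lu.legend.values()}
    for cls_name, items in params.food_items.items():
        table[cls_name] = float(sum(it.value for it in items))
    return lu.map_classes(table, "food value")


# ---------------------------------------------------------------------------
# (2) carbon sequestration & oxygen release
# ---------------------------------------------------------------------------


def compute_npp(apar: Grid, epsilon: Grid) -> Grid:
    """NPP = APAR (MJ/m2) x light-use efficiency (gC/MJ), in t/ha/a.

    1 gC/m2 = 0.01 t/ha, hence the x0.01 conversion.
    """
    if apar.shape != epsilon.shape:
        raise ValueError(
            f"APAR shape {apar.shape} != efficiency shape {epsilon.shape}"
        )
    return (apar * epsilon) * 0.01


def npp_value(npp: Grid, params: EconomicParams) -> Grid:
    """Carbon+oxygen value: NPP * (1.63 * C_c + 1.2 * C_o), CNY/ha/a.

    Each tonne of NPP sequesters 1.63 t C and releases 1.2 t O2.
    """
    if (npp.values[~npp.nodata_mask] < 0).any():
        raise ValueError("NPP has negative valid pixels")
    return npp * (1.63 * params.carbon_cost + 1.2 * params.oxygen_cost)


# ---------------------------------------------------------------------------
# (3) water conservation
# ---------------------------------------------------------------------------


def water_yield(precip: Grid, aet: Grid) -> Grid:
    """Annual water yield Y = (1 - AET/P) * P = P - AET, in mm.

    AET outside [0, P] is clipped (with a warning); pixels with P = 0 yield 0.
    """
    if (precip.values[~precip.nodata_mask] < 0).any():
        raise ValueError("negative precipitation")
    if precip.shape != aet.shape:
        raise ValueError("precipitation / AET shape mismatch")
    a = aet.values
    p = precip.values
    valid = ~(precip.nodata_mask | aet.nodata_mask)
    if ((a[valid] < 0) | (a[valid] > p[valid])).any():
        warnings.warn("AET clipped into [0, P]", stacklevel=2)
    a = np.clip(a, 0.0, np.maximum(p, 0.0))
    return precip.like(p - a, mask=~valid)


def water_retention(yield_mm: Grid, velocity: Grid, ti: Grid, ksat: Grid) -> Grid:
    """Fraction of yield retained by flow, terrain and soil conductivity caps.

    WR = min(1, 249/velocity) * min(1, 0.9*TI/3) * min(1, Ksat/300) * Y, mm.
    """
    v = velocity.values
    valid = ~(yield_mm.nodata_mask | velocity.nodata_mask | ti.nodata_mask | ksat.nodata_mask)
    if (v[valid] <= 0).any():
        raise ValueError("velocity must be strictly positive")
    f = (
        np.minimum(1.0, 249.0 / v)
        * np.minimum(1.0, 0.9 * ti.values / 3.0)
        * np.minimum(1.0, ksat.values / 300.0)
    )
    return yield_mm.like(f * yield_mm.values, mask=~valid)


def water_conservation_value(wr: Grid, params: EconomicParams) -> Grid:
    """Value of retained water at reservoir construction cost.

    1 mm over 1 ha = 10 m3, so S_w = WR * 10 * C (CNY/ha/a).
    """
    if (wr.values[~wr.nodata_mask] < 0).any():
        raise ValueError("water retention must be nonnegative")
    return wr * (10.0 * params.reservoir_cost)


# ---------------------------------------------------------------------------
# (4) soil retention
# ---------------------------------------------------------------------------


def rusle_retention(r: Grid, k: Grid, ls: Grid, cfac: Grid, pfac: Grid) -> Grid:
    """Soil retained = potential minus actual RUSLE loss, t/ha/a.

    S = R*K*LS - R*K*LS*C*P = R*K*LS*(1 - C*P).  C and P must be in [0,1].
    """
    for g, name in ((cfac, "C"), (pfac, "P")):
        vv = g.values[~g.nodata_mask]
        if ((vv < 0) | (vv > 1)).any():
            raise ValueError(f"RUSLE {name} factor must be in [0,1]")
    potential = r * k * ls
    return potential * (1.0 - cfac.values * pfac.values)


def soil_retention_value(s_amount: Grid, params: EconomicParams) -> Grid:
    """Value of retained soil: avoided sedimentation + avoided land loss.

    Term 1: of S t/ha/a retained, a fraction (default 24%) would have settled
    in reservoirs/rivers/lakes; S/rho is its volume (m3, rho in t/m3) priced
    at the reservoir construction cost.  Term 2: S/(rho*d) is the land area
    (m2) whose topsoil of thickness d the retained mass represents, /1e4 to
    hectares, valued at the average forestry income per hectare.
    """
    rho, d = params.soil_bulk_density, params.soil_thickness
    if rho <= 0 or d <= 0:
        raise ValueError("soil bulk density and thickness must be positive")
    vv = s_amount.values[~s_amount.nodata_mask]
    if (vv < 0).any():
        raise ValueError("soil retention amount must be nonnegative")
    term1 = s_amount * (params.sediment_deposit_ratio * params.reservoir_cost / rho)
    term2 = s_amount * (params.forestry_income / (rho * d) / 1e4)
    return term1 + term2


# ---------------------------------------------------------------------------
# (5) habitat support
# ---------------------------------------------------------------------------


def habitat_degradation(lu: LandUseGrid, hp: HabitatParams) -> Grid:
    """Threat-weighted degradation D in [0,1] per pixel.

    For each threat r with weight w_r and maximum influence distance m_r, the
    influence at a pixel at Euclidean distance d is exp(-2.99 d / m_r) (1 on
    the threat itself), scaled by the pixel class's sensitivity S_{jr}; the
    weighted mean over threats is D.
    """
    if not hp.threats:
        return Grid(np.zeros(lu.shape), lu.cell_size, lu.origin_x, lu.origin_y,
                    lu.nodata_mask.copy())
    wsum = sum(spec.get("weight", 1.0) for spec in hp.threats.values())
    if wsum == 0:
        raise ValueError("threat weights sum to zero")
    D = np.zeros(lu.shape)
    present = set(lu.legend.values())
    for threat, spec in hp.threats.items():
        classes = set(spec.get("classes", [threat])) & present
        w = spec.get("weight", 1.0) / wsum
        maxdist = spec.get("max_distance", 1000.0)
        mask = lu.mask_of(classes) if classes else np.zeros(lu.shape, bool)
        if not mask.any():
            warnings.warn(f"threat {threat!r}: no source pixels, contributes 0",
                          stacklevel=2)
            continue
        dist = ndimage.distance_transform_edt(~mask) * lu.cell_size
        influence = np.exp(-THREAT_DECAY * dist / maxdist)
        sens = lu.map_classes(
            {c: hp.sensitivity.get(c, {}).get(threat, 0.0) for c in present},
            f"sensitivity to {threat}",
        ).values
        D += w * influence * sens
    return Grid(np.clip(D, 0.0, 1.0), lu.cell_size, lu.origin_x, lu.origin_y,
                lu.nodata_mask.copy())


def habitat_quality(lu: LandUseGrid, degradation: Grid, hp: HabitatParams) -> Grid:
    """Q = H_j * (1 - D^z / (D^z + k^z)), half-saturation k = max(D)/2.

    When the landscape is threat-free (max D = 0) k falls back to 0.5 so the
    expression stays defined (and Q = H everywhere).
    """
    if not hp.z > 0:
        raise ValueError("z must be > 0")
    D = degradation.values
    dmax = float(D[~degradation.nodata_mask].max()) if degradation.n_valid else 0.0
    k = dmax / 2.0 if dmax > 0 else 0.5
    H = lu.map_classes(hp.suitability, "habitat suitability").values
    with np.errstate(invalid="ignore", divide="ignore"):
        dz = np.power(np.clip(D, 0.0, 1.0), hp.z)
        q = H * (1.0 - dz / (dz + k**hp.z))
    return Grid(q, lu.cell_size, lu.origin_x, lu.origin_y, lu.nodata_mask.copy())


def biodiversity_baseline(lu: LandUseGrid, params: EconomicParams) -> float:
    """VB = sum_j (1/7) * A_j * (S_j / S) * Q * P_f, CNY/ha/a.

    A_j is the per-class habitat-support equivalent factor, S_j/S the class
    area share, Q the grain yield (kg/ha) and P_f the grain price (CNY/kg).
    """
    areas = lu.class_areas()
    total = sum(areas.values())
    if total == 0:
        raise ValueError("land-use grid has no valid pixels")
    base = params.grain_yield * params.grain_price / EQUIVALENT_DIVISOR
    vb = 0.0
    for cls_name, area in areas.items():
        if area == 0:
            continue
        a_j = params.equivalent_A.get(cls_name)
        if a_j is None:
            raise ValueError(f"missing habitat equivalent factor A for {cls_name!r}")
        vb += a_j * (area / total) * base
    return vb


def habitat_support_value(quality: Grid, lu: LandUseGrid, params: EconomicParams) -> Grid:
    """S_h(x) = (Q_x / Qbar) * VB — quality-weighted biodiversity baseline.

    By construction the spatial mean of S_h over valid pixels equals VB.
    """
    qv = quality.values[~quality.nodata_mask]
    qbar = float(qv.mean()) if qv.size else 0.0
    if qbar <= 0:
        raise ValueError("mean habitat quality is zero; habitat value undefined")
    vb = biodiversity_baseline(lu, params)
    return quality * (vb / qbar)


# ---------------------------------------------------------------------------
# (6) landscape aesthetics
# ---------------------------------------------------------------------------


def landscape_aesthetic_value(
    lu: LandUseGrid, params: EconomicParams, class_resolved: bool = False
) -> Grid:
    """Equivalent-factor aesthetic value corrected by tourism income ratio.

    Uniform mode assigns V_l * t/T to every valid pixel, where
    V_l = sum_j (1/7) * L_j * (S_j/S) * Q * P_f.  Class-resolved mode assigns
    each pixel its own class's (1/7) * L_j * Q * P_f * t/T instead (the two
    agree in spatial mean).
    """
    areas = lu.class_areas()
    total = sum(areas.values())
    if total == 0:
        raise ValueError("land-use grid has no valid pixels")
    present = {c for c, a in areas.items() if a > 0}
    missing = present - set(params.equivalent_L)
    if missing:
        raise ValueError(f"missing aesthetic equivalent factor L for {sorted(missing)}")
    base = params.grain_yield * params.grain_price / EQUIVALENT_DIVISOR
    ratio = params.tourism_local / params.tourism_national
    if class_resolved:
        table = {c: params.equivalent_L[c] * base * ratio for c in present}
        return lu.map_classes(table, "aesthetic value")
    v_l = sum(params.equivalent_L[c] * (areas[c] / total) * base for c in present)
    vals = np.full(lu.shape, v_l * ratio)
    return Grid(vals, lu.cell_size, lu.origin_x, lu.origin_y, lu.nodata_mask.copy())


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------


def total_esv(services: ServiceGrids, lu: LandUseGrid) -> dict[str, pd.DataFrame]:
    """Totals (CNY) and shares (%) by service type and by land-use class.

    Grand total = sum over valid pixels of per-ha value x pixel hectares.
    Returns ``{"by_service": ..., "by_class": ...}`` DataFrames, each with
    columns ``total_cny`` and ``share_pct``, plus a ``TOTAL`` row.
    """
    px_ha = lu.cell_size**2 / 1e4
    valid = ~lu.nodata_mask
    rows_s = {}
    for name, g in services.items():
        if g.shape != lu.shape:
            raise ValueError("service/land-use shape mismatch")
        v = g.values.copy()
        v[g.nodata_mask] = 0.0
        rows_s[name] = float(v[valid].sum()) * px_ha
    grand = sum(rows_s.values())
    tot = services.total
    tv = tot.values.copy()
    tv[tot.nodata_mask] = 0.0
    rows_c = {}
    for code, cls_name in lu.legend.items():
        m = valid & (lu.codes == code)
        rows_c[cls_name] = float(tv[m].sum()) * px_ha

    def frame(rows: dict[str, float]) -> pd.DataFrame:
        df = pd.DataFrame(
            {"total_cny": list(rows.values())}, index=list(rows.keys())
        )
        df["share_pct"] = np.round(100.0 * df["total_cny"] / grand, 2) if grand else 0.0
        df.loc["TOTAL"] = [grand, 100.0 if grand else 0.0]
        return df

    return {"by_service": frame(rows_s), "by_class": frame(rows_c)}
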