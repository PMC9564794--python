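"""Per-pixel supply and demand models for the six ecosystem services.

Services and codes:

====  =========================  ===========================  ==================
code  service                    supply model                 demand model
====  =========================  ===========================  ==================
CP    crop production            VCI-proportional allocation  per-capita consumption
WR    water retention            Budyko water yield − runoff  4-component water use
PR    PM2.5 reduction            forest dry deposition        WHO-exceedance volume
FM    flood mitigation           SCS curve-number retention   social/economic vulnerability
HM    heat mitigation            cooling capacity + parks     urban-heat-island intensity
LR    landscape recreation       zone green-area fraction     guided per-capita green area
====  =========================  ===========================  ==================

All operations take co-registered :class:`~esbundles.grid.RasterLayer` inputs
on one grid and return layers on the same grid; nodata propagates.
LULC classes: 1 cultivated, 2 forest, 3 grassland, 4 water, 5 built-up,
6 unused. Hydrologic soil groups: 1=A … 4=D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .grid import RasterLayer, GridSpec, ZoneRaster, layer_from_array

CULTIVATED, FOREST, GRASSLAND, WATER, BUILTUP, UNUSED = 1, 2, 3, 4, 5, 6
LULC_CODES = (CULTIVATED, FOREST, GRASSLAND, WATER, BUILTUP, UNUSED)
SERVICE_CODES = ("CP", "WR", "PR", "FM", "HM", "LR")


class DegenerateInputError(ValueError):
    """Raised when a normalization or allocation has no spread to work with."""


# ---------------------------------------------------------------------------
# Parameter blocks (defaults are the study's printed coefficient tables)
# ---------------------------------------------------------------------------

@dataclass
class CropParams:
    total_production: float = 2.09e6   # t, regional total allocated by VCI
    per_capita_consumption: float = 0.1221  # t/person/yr

    def __post_init__(self):
        if self.total_production <= 0 or self.per_capita_consumption <= 0:
            raise ValueError("crop parameters must be positive")


@dataclass
class WaterParams:
    """Water-retention coefficients per LULC class.

    ``kc`` evapotranspiration coefficient, ``root_depth`` mm, ``veg`` whether
    the Budyko curve applies (else AET = min(Kc·ET0, P)), ``runoff_coef``
    surface runoff coefficient C.
    """
    kc: dict[int, float] = field(default_factory=lambda: {
        1: 0.6, 2: 1.0, 3: 0.65, 4: 1.0, 5: 0.3, 6: 0.2})
    root_depth: dict[int, float] = field(default_factory=lambda: {
        1: 1000, 2: 7000, 3: 1500, 4: 1000, 5: 500, 6: 10})
    veg: dict[int, int] = field(default_factory=lambda: {
        1: 1, 2: 1, 3: 1, 4: 0, 5: 0, 6: 0})
    runoff_coef: dict[int, float] = field(default_factory=lambda: {
        1: 0.347, 2: 0.0267, 3: 0.0937, 4: 0.0, 5: 1.0, 6: 1.0})
    budyko_z: float = 5.0              # seasonality shape of w = Z·AWC/P + 1.25
    per_capita_domestic: float = 60.0  # m³/person/yr
    clamp_negative_retention: bool = False


@dataclass
class Pm25Params:
    deposition_velocity: float = 0.0009  # m/s
    resuspension: float = 0.03           # fraction re-entrained
    hours_per_day: float = 24.0
    non_rainy_days: int = 245
    permitted: float = 10.0              # WHO annual-mean guideline, μg/m³
    boundary_height: float = 200.0       # atmospheric boundary layer, m

    def __post_init__(self):
        if not (0 <= self.resuspension < 1):
            raise ValueError("resuspension must be in [0, 1)")
        if self.deposition_velocity <= 0 or self.permitted < 0:
            raise ValueError("bad PM2.5 parameters")


#: curve numbers per (LULC code, HSG 1..4); CN=0 (water) means no runoff.
_DEFAULT_CN = {
    1: (54, 70, 80, 84),
    2: (36, 60, 73, 79),
    3: (49, 69, 79, 84),
    4: (0, 0, 0, 0),
    5: (85, 90, 92, 94),
    6: (77, 86, 91, 94),
}

#: economic vulnerability scores: developed-density classes and LULC classes.
_DEFAULT_ECON = {
    "developed_high": 8,      # impervious fraction > 0.8
    "developed_moderate": 7,  # 0.5 < a ≤ 0.8
    "developed_low": 6,       # 0.2 < a ≤ 0.5
    "developed_open": 5,      # built-up with a ≤ 0.2
    UNUSED: 4, CULTIVATED: 3, GRASSLAND: 2, FOREST: 1, WATER: 1,
}


@dataclass
class FloodParams:
    design_storm: float = 100.0  # mm
    cn_table: dict[int, tuple] = field(default_factory=lambda: dict(_DEFAULT_CN))
    econ_scores: dict = field(default_factory=lambda: dict(_DEFAULT_ECON))
    weight_pvi: float = 0.5      # a (population vulnerability)
    weight_evi: float = 0.5      # b (economic vulnerability)
    weight_pop: float = 1 / 3    # α
    weight_old: float = 1 / 3    # β
    weight_child: float = 1 / 3  # γ

    def __post_init__(self):
        if abs(self.weight_pvi + self.weight_evi - 1) > 1e-12:
            raise ValueError("a + b must equal 1")
        if abs(self.weight_pop + self.weight_old + self.weight_child - 1) > 1e-12:
            raise ValueError("α + β + γ must equal 1")


@dataclass
class HeatParams:
    shade: dict[int, float] = field(default_factory=lambda: {
        1: 0, 2: 1, 3: 0, 4: 0, 5: 0, 6: 0})
    kc: dict[int, float] = field(default_factory=lambda: {
        1: 0.6, 2: 1.0, 3: 0.65, 4: 1.0, 5: 0.3, 6: 0.2})
    albedo: dict[int, float] = field(default_factory=lambda: {
        1: 0.2, 2: 0.2, 3: 0.2, 4: 0.05, 5: 0.15, 6: 0.25})
    green: dict[int, int] = field(default_factory=lambda: {
        1: 1, 2: 1, 3: 1, 4: 0, 5: 0, 6: 0})
    cooling_distance: float = 450.0        # m, distance-decay scale of parks
    large_green_area: float = 20000.0      # m², "large green area" threshold
    w_shade: float = 0.6
    w_eti: float = 0.2
    w_albedo: float = 0.2


@dataclass
class RecreationParams:
    per_capita_green: float = 13.0  # m²/person, planning guideline

    def __post_init__(self):
        if self.per_capita_green <= 0:
            raise ValueError("per-capita green area must be positive")


@dataclass
class ServiceRasters:
    service_code: str
    supply: RasterLayer
    demand: RasterLayer

    def __post_init__(self):
        if self.service_code not in SERVICE_CODES:
            raise ValueError(f"unknown service {self.service_code!r}")
        if not self.supply.spec.matches(self.demand.spec):
            raise ValueError("supply and demand grids differ")


def _lookup(table: dict[int, float], lulc: np.ndarray, what: str) -> np.ndarray:
    """Map LULC codes through a coefficient table; missing code is an error."""
    present = np.unique(lulc[lulc > 0])
    missing = [int(c) for c in present if int(c) not in table]
    if missing:
        raise KeyError(f"no {what} entry for LULC code(s) {missing}")
    out = np.zeros(lulc.shape, dtype=float)
    for code, val in table.items():
        out[lulc == code] = val
    return out


def minmax_field(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max normalize over non-nodata pixels of the full grid.

    A constant field has no spread; it normalizes to all zeros with a warning
    rather than dividing by zero.
    """
    out = np.zeros(values.shape, dtype=float)
    vals = values[mask]
    if vals.size == 0:
        return out
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi == lo:
        warnings.warn("constant field: min-max normalization degenerates to 0",
                      stacklevel=2)
        return out
    out[mask] = (values[mask] - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# Crop production (CP)
# ---------------------------------------------------------------------------

def vci(ndvi: RasterLayer, cultivated_mask: np.ndarray) -> RasterLayer:
    """Vegetation Condition Index: min-max of NDVI over cultivated pixels.

    VCI ∈ [0, 1] on cultivated pixels, nodata elsewhere; the range is taken
    over the cultivated mask only.
    """
    m = cultivated_mask & ndvi.mask
    if not m.any():
        raise DegenerateInputError("no cultivated pixels with valid NDVI")
    vals = ndvi.values[m].astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateInputError("NDVI constant over the cultivated mask")
    out = np.full(ndvi.spec.shape, ndvi.nodata, dtype=float)
    out[m] = (ndvi.values[m] - lo) / (hi - lo)
    return RasterLayer(ndvi.spec, out, nodata=ndvi.nodata, units="1")


def crop_supply(vci_layer: RasterLayer, params: CropParams) -> RasterLayer:
    """Allocate the regional crop total to cultivated pixels ∝ VCI (t/pixel)."""
    m = vci_layer.mask
    total_vci = float(vci_layer.values[m].sum())
    if total_vci <= 0:
        raise DegenerateInputError("sum of VCI is zero; cannot allocate crops")
    out = np.zeros(vci_layer.spec.shape, dtype=float)
    out[m] = params.total_production * vci_layer.values[m] / total_vci
    return RasterLayer(vci_layer.spec, out, units="t")


def crop_demand(population: RasterLayer, params: CropParams) -> RasterLayer:
    """Crop demand = persons on pixel × per-capita consumption (t/pixel)."""
    if np.any(population.values[population.mask] < 0):
        raise ValueError("negative population")
    out = population.filled(0.0) * params.per_capita_consumption
    return RasterLayer(population.spec, out, units="t")


# ---------------------------------------------------------------------------
# Water retention (WR)
# ---------------------------------------------------------------------------

def water_yield(
    precip: RasterLayer,
    pet: RasterLayer,
    awc: RasterLayer,
    lulc: RasterLayer,
    params: WaterParams,
) -> RasterLayer:
    """Annual water yield Y (mm) from the Budyko curve.

    Vegetated classes: dryness R = Kc·ET0/P, w = Z·AWC/P + 1.25,
    AET/P = (1 + wR) / (1 + wR + 1/R), Y = P·(1 − AET/P).
    Non-vegetated classes: AET = min(Kc·ET0, P), Y = P − AET.
    """
    lu = lulc.values
    kc = _lookup(params.kc, lu, "Kc")
    veg = _lookup({k: float(v) for k, v in params.veg.items()}, lu, "LULC_veg") > 0
    P = precip.masked()
    et0 = pet.masked()
    aw = awc.masked()
    if np.any(P[veg & precip.mask] <= 0):
        raise ValueError("non-positive precipitation on vegetated pixel")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = kc * et0 / P
        w = params.budyko_z * aw / P + 1.25
        aet_ratio = (1 + w * R) / (1 + w * R + 1 / R)
    y = np.where(veg, (1 - aet_ratio) * P, P - np.minimum(kc * et0, P))
    valid = precip.mask & pet.mask & awc.mask & lulc.mask
    out = np.where(valid, y, precip.nodata)
    return RasterLayer(precip.spec, out, nodata=precip.nodata, units="mm")


def water_retention_supply(
    yield_raster: RasterLayer,
    precip: RasterLayer,
    lulc: RasterLayer,
    params: WaterParams,
) -> RasterLayer:
    """Water retention WR = Y − P·C (mm); negative values propagate unless
    ``params.clamp_negative_retention`` is set."""
    c = _lookup(params.runoff_coef, lulc.values, "runoff coefficient")
    wr = yield_raster.masked() - precip.masked() * c
    if params.clamp_negative_retention:
        wr = np.maximum(wr, 0.0)
    valid = yield_raster.mask & precip.mask & lulc.mask
    out = np.where(valid, wr, yield_raster.nodata)
    return RasterLayer(yield_raster.spec, out, nodata=yield_raster.nodata,
                       units="mm")


def water_demand(
    lulc: RasterLayer,
    population: RasterLayer,
    subdistrict_use: pd.DataFrame,
    zone_raster: ZoneRaster,
    params: WaterParams,
) -> RasterLayer:
    """Total water consumption per pixel (m³/yr).

    Domestic use is per-capita × persons on every pixel; agricultural,
    industrial and ecological subdistrict totals are spread uniformly over
    that subdistrict's cultivated, built-up, and forest+grassland pixels
    respectively. A subdistrict with a nonzero total but no pixel of the
    target class cannot allocate and raises an error naming the zone.
    """
    required = {"zone_id", "agricultural", "industrial", "ecological"}
    if not required.issubset(subdistrict_use.columns):
        raise ValueError(f"water-use table needs columns {sorted(required)}")
    lu = lulc.values
    zones = zone_raster.zone_ids
    demand = population.filled(0.0) * params.per_capita_domestic

    targets = {
        "agricultural": lu == CULTIVATED,
        "industrial": lu == BUILTUP,
        "ecological": (lu == FOREST) | (lu == GRASSLAND),
    }
    for _, row in subdistrict_use.iterrows():
        zid = int(row["zone_id"])
        in_zone = zones == zid
        for comp, target in targets.items():
            total = float(row[comp])
            if total == 0:
                continue
            pix = in_zone & target
            n = int(pix.sum())
            if n == 0:
                raise ValueError(
                    f"subdistrict {zid}: {comp} consumption {total} m³ but no "
                    f"target pixels"
                )
            demand[pix] += total / n
    out = np.where(lulc.mask, demand, lulc.nodata)
    return RasterLayer(lulc.spec, out, nodata=float(lulc.nodata), units="m3")


# ---------------------------------------------------------------------------
# PM2.5 reduction (PR)
# ---------------------------------------------------------------------------

def pm25_supply(
    pm25_conc: RasterLayer,
    lai: RasterLayer,
    lulc: RasterLayer,
    params: Pm25Params,
) -> RasterLayer:
    """Annual PM2.5 dry deposition on forest pixels (g/pixel/yr).

    F = Vd·Ch·3600/10⁶ g/(m²·h); leaf area = pixel area × LAI;
    daily removal Qd = F·TCLA·T·(1 − R); annual Qy = D·Qd. Zero off-forest.
    """
    if np.any(pm25_conc.values[pm25_conc.mask] < 0):
        raise ValueError("negative PM2.5 concentration")
    forest = lulc.values == FOREST
    flux = params.deposition_velocity * pm25_conc.filled(0.0) * 3600.0 / 1e6
    tcla = lulc.spec.pixel_area * np.maximum(lai.filled(0.0), 0.0)
    qd = flux * tcla * params.hours_per_day * (1 - params.resuspension)
    qy = params.non_rainy_days * qd
    out = np.where(forest, qy, 0.0)
    valid = pm25_conc.mask & lai.mask & lulc.mask
    out = np.where(valid, out, pm25_conc.nodata)
    return RasterLayer(lulc.spec, out, nodata=pm25_conc.nodata, units="g")


def pm25_demand(pm25_annual: RasterLayer, params: Pm25Params) -> RasterLayer:
    """PM2.5 exceeding the WHO guideline over the boundary-layer column (μg/yr).

    D = (Ca − permitted)·H·A·365·24 where the annual mean Ca exceeds the
    permitted threshold; 0 otherwise.
    """
    ca = pm25_annual.masked()
    area = pm25_annual.spec.pixel_area
    excess = ca - params.permitted
    d = np.where(excess > 0,
                 excess * params.boundary_height * area * 365.0 * 24.0, 0.0)
    out = np.where(pm25_annual.mask, d, pm25_annual.nodata)
    return RasterLayer(pm25_annual.spec, out, nodata=pm25_annual.nodata,
                       units="ug")


# ---------------------------------------------------------------------------
# Flood mitigation (FM)
# ---------------------------------------------------------------------------

def flood_supply(
    lulc: RasterLayer, hsg: RasterLayer, params: FloodParams
) -> RasterLayer:
    """SCS curve-number runoff retention index FM ∈ [0, 1].

    I = 25400/CN − 254 (mm); runoff Rp = (P − 0.2I)²/(P + 0.8I) when
    P > 0.2I else 0; FM = 1 − Rp/P. CN = 0 (open water) is the infinite-
    retention limit and maps to FM = 1; CN = 100 gives FM = 0.
    """
    P = params.design_storm
    if P <= 0:
        raise ValueError("design storm depth must be positive")
    lu = lulc.values
    hg = hsg.values
    cn = np.zeros(lu.shape, dtype=float)
    present = np.unique(lu[lulc.mask])
    for code in present:
        if int(code) not in params.cn_table:
            raise KeyError(f"no CN row for LULC code {int(code)}")
    for code, row in params.cn_table.items():
        for g in (1, 2, 3, 4):
            cn[(lu == code) & (hg == g)] = row[g - 1]
    with np.errstate(divide="ignore"):
        retention = np.where(cn > 0, 25400.0 / np.maximum(cn, 1e-300) - 254.0,
                             np.inf)
    runs = P > 0.2 * retention  # CN = 0 ⇒ infinite retention ⇒ no runoff
    safe = np.where(runs, retention, 0.0)
    runoff = np.where(runs, (P - 0.2 * safe) ** 2 / (P + 0.8 * safe), 0.0)
    fm = 1.0 - runoff / P
    valid = lulc.mask & hsg.mask
    out = np.where(valid, np.clip(fm, 0.0, 1.0), lulc.nodata)
    return RasterLayer(lulc.spec, out, nodata=float(lulc.nodata), units="1")


def economic_score(
    impervious_fraction: np.ndarray, lulc: np.ndarray, params: FloodParams
) -> np.ndarray:
    """Per-pixel economic vulnerability score from impervious density / LULC."""
    s = params.econ_scores
    a = impervious_fraction
    score = np.zeros(lulc.shape, dtype=float)
    for code in (UNUSED, CULTIVATED, GRASSLAND, FOREST, WATER):
        score[lulc == code] = s[code]
    score[lulc == BUILTUP] = s["developed_open"]
    score[a > 0.2] = s["developed_low"]
    score[a > 0.5] = s["developed_moderate"]
    score[a > 0.8] = s["developed_high"]
    return score


def flood_demand(
    population: RasterLayer,
    elderly: RasterLayer,
    children: RasterLayer,
    impervious_fraction: RasterLayer,
    lulc: RasterLayer,
    params: FloodParams,
) -> RasterLayer:
    """Flood-risk social demand FRSD ∈ [0, 1].

    PVI = minmax(α·Pop + β·Old + γ·Child); EVI = minmax(economic score);
    FRSD = minmax(a·PVI + b·EVI). All normalizations are over the non-nodata
    pixels of the full grid.
    """
    a = impervious_fraction.filled(0.0)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("impervious fraction must be in [0, 1]")
    valid = (population.mask & elderly.mask & children.mask
             & impervious_fraction.mask & lulc.mask)
    raw_pvi = (params.weight_pop * population.filled(0.0)
               + params.weight_old * elderly.filled(0.0)
               + params.weight_child * children.filled(0.0))
    pvi = minmax_field(raw_pvi, valid)
    evi = minmax_field(economic_score(a, lulc.values, params), valid)
    frsd = minmax_field(params.weight_pvi * pvi + params.weight_evi * evi, valid)
    out = np.where(valid, frsd, population.nodata)
    return RasterLayer(population.spec, out, nodata=population.nodata, units="1")


# ---------------------------------------------------------------------------
# Heat mitigation (HM)
# ---------------------------------------------------------------------------

def _cooling_kernel(spec: GridSpec, dcool: float) -> np.ndarray:
    """Distance-decay kernel e^(−d/dcool) truncated at dcool."""
    r = int(np.ceil(dcool / spec.cell_size))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1].astype(float) * spec.cell_size
    d = np.hypot(dy, dx)
    k = np.exp(-d / dcool)
    k[d >= dcool] = 0.0
    return k


def heat_supply(
    lulc: RasterLayer, et0: RasterLayer, params: HeatParams
) -> RasterLayer:
    """Urban-cooling heat mitigation index HM ∈ [0, 1].

    Per-pixel cooling capacity CC = 0.6·shade + 0.2·ETI + 0.2·albedo with
    ETI = clip(Kc·ET0/ETmax, 0, 1). The park effect CCpark is the
    distance-decay-weighted mean of CC over green pixels within the cooling
    distance (weights e^(−d/dcool), normalized to sum to one, so
    CCpark ∈ [0, 1]). A pixel keeps its own CC when it is part of a green
    patch at least ``large_green_area`` m² (4-connected components of green
    pixels) or when CC ≥ CCpark; otherwise it takes CCpark. Pixels with no
    green within reach keep CC.
    """
    lu = lulc.values
    shade = _lookup(params.shade, lu, "shade")
    kc = _lookup(params.kc, lu, "Kc")
    albedo = _lookup(params.albedo, lu, "albedo")
    green = _lookup({k: float(v) for k, v in params.green.items()}, lu, "g") > 0

    et = et0.masked()
    etmax = np.nanmax(et)
    if not np.isfinite(etmax) or etmax <= 0:
        raise ValueError("maximum ET0 over the grid must be positive")
    eti = np.clip(kc * np.nan_to_num(et) / etmax, 0.0, 1.0)
    cc = params.w_shade * shade + params.w_eti * eti + params.w_albedo * albedo

    kernel = _cooling_kernel(lulc.spec, params.cooling_distance)
    g = green.astype(float)
    num = signal.fftconvolve(g * cc, kernel, mode="same")
    den = signal.fftconvolve(g, kernel, mode="same")
    with np.errstate(invalid="ignore"):
        ccpark = np.where(den > 1e-12, num / np.maximum(den, 1e-12), cc)
    ccpark = np.clip(ccpark, 0.0, 1.0)

    labels, n_patches = ndimage.label(green)
    if n_patches:
        sizes = ndimage.sum_labels(np.ones_like(g), labels,
                                   index=np.arange(1, n_patches + 1))
        big = np.zeros(n_patches + 1, dtype=bool)
        big[1:] = sizes * lulc.spec.pixel_area >= params.large_green_area
        in_big_patch = big[labels]
    else:
        in_big_patch = np.zeros(lu.shape, dtype=bool)

    hm = np.where(in_big_patch | (cc >= ccpark), cc, ccpark)
    valid = lulc.mask & et0.mask
    out = np.where(valid, hm, float(lulc.nodata))
    return RasterLayer(lulc.spec, out, nodata=float(lulc.nodata), units="1")


def heat_demand(
    lst: RasterLayer, cultivated_mask: np.ndarray, mode: str = "intended"
) -> RasterLayer:
    """Heat-mitigation demand: UHI intensity against the cropland reference.

    The reference T̄c is the mean land-surface temperature over cultivated
    pixels. ``intended`` mode (default) takes max(0, Ti − T̄c) — demand where
    a pixel is hotter than cropland; ``printed`` mode keeps the literal
    piecewise variant in which the difference is retained where Ti < T̄c.
    Either raw field is then min-max normalized to [0, 1].
    """
    if mode not in ("intended", "printed"):
        raise ValueError("mode must be 'intended' or 'printed'")
    m = cultivated_mask & lst.mask
    if not m.any():
        raise DegenerateInputError("no cultivated pixels with valid LST")
    tref = float(lst.values[m].mean())
    t = lst.masked()
    if mode == "intended":
        raw = np.maximum(0.0, t - tref)
    else:
        raw = np.where(t < tref, t - tref, 0.0)
    raw = np.nan_to_num(raw)
    hmd = minmax_field(raw, lst.mask)
    out = np.where(lst.mask, hmd, lst.nodata)
    return RasterLayer(lst.spec, out, nodata=lst.nodata, units="1")


# ---------------------------------------------------------------------------
# Landscape recreation (LR)
# ---------------------------------------------------------------------------

def recreation_supply(lulc: RasterLayer, zone_raster: ZoneRaster) -> RasterLayer:
    """Green-area share of each zone, broadcast back to its pixels (m²/m²)."""
    lu = lulc.values
    zones = zone_raster.zone_ids
    green = ((lu == FOREST) | (lu == GRASSLAND)).astype(float)
    out = np.full(lu.shape, float(lulc.nodata), dtype=float)
    for zid in np.unique(zones[zones != ZoneRaster.NODATA]):
        in_zone = (zones == zid) & lulc.mask
        n = int(in_zone.sum())
        if n == 0:
            raise ValueError(f"zone {int(zid)} has no valid pixels")
        out[in_zone] = green[in_zone].sum() / n
    return RasterLayer(lulc.spec, out, nodata=float(lulc.nodata), units="m2/m2")


def recreation_demand(
    population_density: RasterLayer, params: RecreationParams
) -> RasterLayer:
    """Demand = population density (person/m²) × guided green area (m²/person)."""
    if np.any(population_density.values[population_density.mask] < 0):
        raise ValueError("negative population density")
    out = population_density.filled(0.0) * params.per_capita_green
    out = np.where(population_density.mask, out, population_density.nodata)
    return RasterLayer(population_density.spec, out,
                       nodata=population_density.nodata, units="m2/m2")


# ---------------------------------------------------------------------------
# Driver: all six services from a landscape stack
# ---------------------------------------------------------------------------

@dataclass
class ServiceParams:
    crop: CropParams = field(default_factory=CropParams)
    water: WaterParams = field(default_factory=WaterParams)
    pm25: Pm25Params = field(default_factory=Pm25Params)
    flood: FloodParams = field(default_factory=FloodParams)
    heat: HeatParams = field(default_factory=HeatParams)
    recreation: RecreationParams = field(default_factory=RecreationParams)
    heat_demand_mode: str = "intended"


def quantify_all(
    stack, village_zones: ZoneRaster, params: ServiceParams | None = None
) -> dict[str, ServiceRasters]:
    """Compute supply and demand rasters for all six services.

    Expects the layer names produced by the synthetic generator (lulc,
    population, elderly, children, ndvi, precipitation, pet, awc, hsg, pm25,
    lai, lst, impervious) and a ``water_use`` table keyed by village zone_id.
    """
    params = params or ServiceParams()
    lulc = stack["lulc"]
    cult = lulc.values == CULTIVATED
    spec = stack.spec
    area = spec.pixel_area

    vci_l = vci(stack["ndvi"], cult)
    cp_s = crop_supply(vci_l, params.crop)
    cp_d = crop_demand(stack["population"], params.crop)

    y = water_yield(stack["precipitation"], stack["pet"], stack["awc"], lulc,
                    params.water)
    wr_mm = water_retention_supply(y, stack["precipitation"], lulc, params.water)
    # mm over the pixel → m³/pixel (mm/1000 m × 900 m²)
    wr_s = wr_mm.with_values(
        np.where(wr_mm.mask, wr_mm.values * area / 1000.0, wr_mm.nodata),
        units="m3")
    wr_d = water_demand(lulc, stack["population"], stack.tables["water_use"],
                        village_zones, params.water)

    pr_s = pm25_supply(stack["pm25"], stack["lai"], lulc, params.pm25)
    pr_d = pm25_demand(stack["pm25"], params.pm25)

    fm_s = flood_supply(lulc, stack["hsg"], params.flood)
    fm_d = flood_demand(stack["population"], stack["elderly"],
                        stack["children"], stack["impervious"], lulc,
                        params.flood)

    hm_s = heat_supply(lulc, stack["pet"], params.heat)
    hm_d = heat_demand(stack["lst"], cult, mode=params.heat_demand_mode)

    lr_s = recreation_supply(lulc, village_zones)
    pop_density = stack["population"].with_values(
        stack["population"].filled(0.0) / area, units="person/m2")
    lr_d = recreation_demand(pop_density, params.recreation)

    return {
        "CP": ServiceRasters("CP", cp_s, cp_d),
        "WR": ServiceRasters("WR", wr_s, wr_d),
        "PR": ServiceRasters("PR", pr_s, pr_d),
        "FM": ServiceRasters("FM", fm_s, fm_d),
        "HM": ServiceRasters("HM", hm_s, hm_d),
        "LR": ServiceRasters("LR", lr_s, lr_d),
    }
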