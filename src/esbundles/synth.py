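"""Synthetic landscape generator.

Emulates the input data of a rapidly urbanizing river-delta study region —
a 30 m LULC mosaic dominated by cultivated land, built-up area, and water,
population concentrated in urban cores, a monotone NW→SE air-pollution
gradient, land surface temperature coupled to impervious surface, and a
nested county ⊃ township ⊃ village administrative hierarchy — so that every
downstream stage runs without any external download. It can additionally
plant known bundle archetypes and a dominant driver, for recovery tests of
the clustering and attribution stages.

Everything is deterministic under a fixed seed (one seeded generator is
threaded through all draws).

Reference magnitudes used for the defaults (study-region statistics): mean
annual precipitation 1093 mm, regional crop total 2.09 × 10⁶ t, LULC shares
cultivated 31.32%, built-up 23.1%, water 22.56%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .grid import (
    AdminHierarchy,
    GridSpec,
    LandscapeStack,
    RasterLayer,
    ZoneRaster,
    layer_from_array,
    rasterize_hierarchy,
)
from .services import BUILTUP, CULTIVATED, FOREST, GRASSLAND, UNUSED, WATER

#: printed study-region statistics the generator emulates (year 2020).
STUDY_REGION = {
    "per_capita_gdp_cny": 158_263.0,
    "national_per_capita_gdp_cny": 72_000.0,
    "population_density_km2": 1439.0,
    "national_population_density_km2": 148.0,
    "total_population": 25.49e6,
    "mean_annual_precip_mm": 1093.0,
    "total_crop_production_t": 2.09e6,
}

#: default class weights: cultivated/forest/grassland/water/built-up/unused.
DEFAULT_CLASS_WEIGHTS = (0.3132, 0.12, 0.06, 0.2256, 0.231, 0.0502)


@dataclass
class LandscapeConfig:
    spec: GridSpec = field(default_factory=lambda: GridSpec(200, 200))
    seed: int = 0
    n_counties: int = 4
    townships_per_county: int = 4
    villages_per_township: int = 4
    lulc_class_weights: tuple = DEFAULT_CLASS_WEIGHTS
    #: fractional (row, col) positions of urban cores (three cities).
    urban_core_centers: tuple = ((0.30, 0.68), (0.46, 0.44), (0.62, 0.20))
    pop_peak: float = 60.0          # shape of the core decay (pre-rescaling)
    pop_decay_frac: float = 0.08    # e-folding distance as fraction of grid
    #: the grid is a scaled-down map of the whole study region, so regional
    #: TOTALS (population, crop production) are emulated rather than per-m²
    #: densities; this keeps the region's supply/demand balance on the grid.
    population_total: float = 25.49e6  # persons
    pm25_base: float = 28.0         # μg/m³ at the SE corner
    pm25_gradient: float = 12.0     # NW−SE contrast, μg/m³
    pm25_noise_sd: float = 0.8
    lst_impervious_coupling: float = 8.0  # °C across impervious 0→1
    precip_mean: float = 1093.0     # mm
    precip_sd: float = 60.0
    pet_mean: float = 950.0         # mm
    pet_sd: float = 50.0
    temp_mean: float = 16.2         # °C
    wind_mean: float = 3.0          # m/s
    solar_mean: float = 1500.0      # kWh/m²/yr
    awc_range: tuple = (100.0, 200.0)   # plant-available water, mm
    elderly_fraction: float = 0.18
    child_fraction: float = 0.12
    non_rainy_days: int = 245
    total_crop_production: float = 2.09e6  # t
    patchiness: float = 6.0         # LULC autocorrelation scale, pixels

    def __post_init__(self):
        w = np.asarray(self.lulc_class_weights, dtype=float)
        if w.shape != (6,) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("lulc_class_weights must be 6 proportions summing to 1")
        for name in ("n_counties", "townships_per_county", "villages_per_township"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")


@dataclass
class PlantedStructure:
    """Bundle archetypes and a driver effect to plant into a landscape.

    ``archetype_profiles`` is a k × 6 matrix (service order CP, WR, PR, FM,
    HM, LR) of relative budget targets in [−1, 1]; ``driver_effect`` names a
    driver layer and the strength of its link to archetype membership
    (0 = none); ``separation`` scales how hard the input layers are pushed
    apart between archetypes.
    """

    archetype_profiles: np.ndarray
    driver_effect: tuple = ("solar", 6.0)
    separation: float = 3.0
    seed: int = 0
    scale: str = "village"

    def __post_init__(self):
        self.archetype_profiles = np.atleast_2d(
            np.asarray(self.archetype_profiles, dtype=float))
        k, s = self.archetype_profiles.shape
        if k < 2 or s != 6:
            raise ValueError("archetype_profiles must be k×6 with k ≥ 2")
        if self.driver_effect[1] < 0:
            raise ValueError("driver effect size must be ≥ 0")


def default_archetypes(k: int = 6) -> np.ndarray:
    """k archetypes, each strongly favouring one service, mildly short on the
    rest (cycled through the six services when k > 6)."""
    arch = np.full((k, 6), -0.4)
    for g in range(k):
        arch[g, g % 6] = 1.0
    return arch


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd spatially autocorrelated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _core_field(cfg: LandscapeConfig) -> np.ndarray:
    """Sum of exponential distance decays from the urban cores, max ≈ 1."""
    nr, nc = cfg.spec.shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    decay = cfg.pop_decay_frac * max(nr, nc)
    f = np.zeros((nr, nc))
    for fr, fc in cfg.urban_core_centers:
        d = np.hypot(rr - fr * nr, cc - fc * nc)
        f += np.exp(-d / decay)
    return f / max(f.max(), 1e-12)


def _split_box(b, k: int, rng: np.random.Generator) -> list:
    """Recursively split a rectangle into k sub-rectangles with jittered cuts."""
    if k == 1:
        return [b]
    minx, miny, maxx, maxy = b.bounds
    k1 = k // 2
    frac = (k1 / k) * (1 + 0.25 * (rng.random() - 0.5))
    frac = min(max(frac, 0.2), 0.8)
    if (maxx - minx) >= (maxy - miny):  # cut the longer axis
        cut = minx + frac * (maxx - minx)
        b1, b2 = box(minx, miny, cut, maxy), box(cut, miny, maxx, maxy)
    else:
        cut = miny + frac * (maxy - miny)
        b1, b2 = box(minx, miny, maxx, cut), box(minx, cut, maxx, maxy)
    return _split_box(b1, k1, rng) + _split_box(b2, k - k1, rng)


def build_hierarchy(cfg: LandscapeConfig, rng: np.random.Generator) -> AdminHierarchy:
    """Nested rectangles: counties split the extent, townships split counties,
    villages split townships. Guarantees exact nesting."""
    spec = cfg.spec
    extent = box(
        spec.origin_x, spec.origin_y - spec.n_rows * spec.cell_size,
        spec.origin_x + spec.n_cols * spec.cell_size, spec.origin_y,
    )
    hier = AdminHierarchy()
    counties = _split_box(extent, cfg.n_counties, rng)
    hier.zones["county"] = [(i + 1, -1, g) for i, g in enumerate(counties)]
    townships, villages = [], []
    tid = vid = 0
    for cid, _, cgeom in hier.zones["county"]:
        for tgeom in _split_box(cgeom, cfg.townships_per_county, rng):
            tid += 1
            townships.append((tid, cid, tgeom))
            for vgeom in _split_box(tgeom, cfg.villages_per_township, rng):
                vid += 1
                villages.append((vid, tid, vgeom))
    hier.zones["township"] = townships
    hier.zones["village"] = villages
    hier.validate()
    return hier


def _allocate_lulc(cfg: LandscapeConfig, rng: np.random.Generator,
                   core: np.ndarray) -> np.ndarray:
    """Assign LULC classes with exact target shares and spatial patchiness.

    Each class gets a smooth propensity field (built-up biased toward urban
    cores, water toward its own large-scale field, cultivated away from
    cores); classes claim their quota of pixels in descending-weight order,
    taking the unassigned pixels where their propensity is highest.
    """
    shape = cfg.spec.shape
    n_pix = shape[0] * shape[1]
    weights = np.asarray(cfg.lulc_class_weights, dtype=float)
    prop = {c: _smooth_field(rng, shape, cfg.patchiness) for c in
            (CULTIVATED, FOREST, GRASSLAND, WATER, BUILTUP, UNUSED)}
    prop[BUILTUP] = prop[BUILTUP] + 4.0 * core
    prop[WATER] = prop[WATER] + 2.0 * _smooth_field(rng, shape, 3 * cfg.patchiness)
    prop[CULTIVATED] = prop[CULTIVATED] - 1.5 * core
    prop[FOREST] = prop[FOREST] - 1.0 * core

    counts = np.floor(weights * n_pix).astype(int)
    # distribute the rounding remainder to the largest weights
    for i in np.argsort(-weights)[: n_pix - counts.sum()]:
        counts[i] += 1
    lulc = np.zeros(shape, dtype=np.int32)
    order = np.argsort(-weights)  # largest classes claim first
    codes = np.array((CULTIVATED, FOREST, GRASSLAND, WATER, BUILTUP, UNUSED))
    for i in order:
        c, n_c = codes[i], counts[i]
        if n_c == 0:
            continue
        free = np.flatnonzero(lulc.ravel() == 0)
        pick = free[np.argsort(-prop[c].ravel()[free], kind="stable")[:n_c]]
        lulc.ravel()[pick] = c
    return lulc


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_landscape(
    cfg: LandscapeConfig,
) -> tuple[LandscapeStack, AdminHierarchy]:
    """Generate every input layer, the water-use table, and the hierarchy.

    Deterministic for a fixed ``cfg.seed``. The returned stack always
    satisfies the preconditions of the service models (positive precipitation,
    LAI ≥ 0, impervious ∈ [0, 1], at least one cultivated pixel, water-use
    totals only where target pixels exist, ...).
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.spec
    shape = spec.shape

    hier = build_hierarchy(cfg, rng)
    zone_rasters = rasterize_hierarchy(hier, spec)
    vz = zone_rasters["village"].zone_ids
    for zid, _, _ in hier.zones["village"]:
        if not (vz == zid).any():
            raise ValueError(
                f"grid {shape} too small to host the requested hierarchy "
                f"(village {zid} got no pixels)"
            )

    core = _core_field(cfg)
    lulc = _allocate_lulc(cfg, rng, core)
    stack = LandscapeStack(spec)
    stack.add("lulc", layer_from_array(spec, lulc, units="class"))

    # population and derived densities (persons per pixel; none on water)
    pop = cfg.pop_peak * core * np.exp(0.3 * _smooth_field(rng, shape, 4))
    pop = pop + 0.5 * np.exp(0.3 * _smooth_field(rng, shape, 8))
    pop[lulc == WATER] = 0.0
    pop *= cfg.population_total / pop.sum()  # emulate the regional total
    stack.add("population", layer_from_array(spec, pop, units="person"))
    eld = cfg.elderly_fraction * pop * np.clip(
        1 + 0.1 * rng.standard_normal(shape), 0.5, 1.5)
    chd = cfg.child_fraction * pop * np.clip(
        1 + 0.1 * rng.standard_normal(shape), 0.5, 1.5)
    stack.add("elderly", layer_from_array(spec, eld, units="person"))
    stack.add("children", layer_from_array(spec, chd, units="person"))

    stack.add("ndvi", layer_from_array(
        spec, np.clip(0.55 + 0.18 * _smooth_field(rng, shape, 5)
                      + 0.03 * rng.standard_normal(shape), 0.02, 0.98),
        units="1"))

    precip = np.maximum(cfg.precip_mean + cfg.precip_sd
                        * _smooth_field(rng, shape, 20), 50.0)
    pet = np.maximum(cfg.pet_mean + cfg.pet_sd
                     * _smooth_field(rng, shape, 20), 50.0)
    stack.add("precipitation", layer_from_array(spec, precip, units="mm"))
    stack.add("pet", layer_from_array(spec, pet, units="mm"))
    lo, hi = cfg.awc_range
    awc = lo + (hi - lo) * (0.5 + 0.25 * _smooth_field(rng, shape, 12)).clip(0, 1)
    stack.add("awc", layer_from_array(spec, awc, units="mm"))

    hsg_field = _smooth_field(rng, shape, 10)
    edges = np.quantile(hsg_field, [0.25, 0.5, 0.75])
    hsg = (np.searchsorted(edges, hsg_field.ravel()).reshape(shape) + 1)
    stack.add("hsg", layer_from_array(spec, hsg.astype(np.int32), units="class"))

    # PM2.5: monotone NW→SE gradient (row 0 north, col 0 west → NW highest)
    nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    diag = ((nr - 1 - rr) + (nc - 1 - cc)) / max(nr + nc - 2, 1)
    pm25 = (cfg.pm25_base + cfg.pm25_gradient * diag
            + cfg.pm25_noise_sd * _smooth_field(rng, shape, 8))
    stack.add("pm25", layer_from_array(spec, np.maximum(pm25, 0.0), units="ug/m3"))

    lai = np.full(shape, 0.2)
    lai[lulc == CULTIVATED] = 2.0
    lai[lulc == GRASSLAND] = 1.5
    lai[lulc == FOREST] = 4.5
    lai = np.maximum(lai * np.exp(0.15 * _smooth_field(rng, shape, 5)), 0.0)
    stack.add("lai", layer_from_array(spec, lai, units="m2/m2"))

    imperv = np.full(shape, 0.03)
    imperv[lulc == CULTIVATED] = 0.08
    imperv[lulc == WATER] = 0.0
    imperv[lulc == UNUSED] = 0.15
    built = lulc == BUILTUP
    imperv[built] = 0.55 + 0.4 * core[built]
    imperv = np.clip(imperv + 0.05 * _smooth_field(rng, shape, 4), 0.0, 1.0)
    imperv[lulc == WATER] = 0.0
    stack.add("impervious", layer_from_array(spec, imperv, units="fraction"))

    # newly built impervious surface (recent 5-year growth), densest where
    # development pressure (core proximity) is high but saturation is not
    nis = np.clip(0.25 * imperv * (0.4 + core)
                  * np.exp(0.3 * _smooth_field(rng, shape, 5)), 0.0, 1.0)
    stack.add("nis", layer_from_array(spec, nis, units="fraction"))

    green = (lulc == FOREST) | (lulc == GRASSLAND)
    lst = (cfg.temp_mean + cfg.lst_impervious_coupling * imperv
           - 1.5 * green + 0.5 * _smooth_field(rng, shape, 6))
    stack.add("lst", layer_from_array(spec, lst, units="degC"))

    dem = 25.0 + 20.0 * _smooth_field(rng, shape, 25)
    dem = dem - dem.min() + 1.0
    gy, gx = np.gradient(dem, spec.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gy, gx)))
    mean = ndimage.uniform_filter(dem, 5, mode="reflect")
    sq = ndimage.uniform_filter(dem**2, 5, mode="reflect")
    rough = np.sqrt(np.maximum(sq - mean**2, 0.0))
    stack.add("dem", layer_from_array(spec, dem, units="m"))
    stack.add("slope", layer_from_array(spec, slope, units="deg"))
    stack.add("roughness", layer_from_array(spec, rough, units="m"))

    gdp = (2.0 + 50.0 * pop / max(pop.max(), 1e-12) + 10.0 * imperv) \
        * np.exp(0.2 * _smooth_field(rng, shape, 6))
    stack.add("gdp", layer_from_array(spec, gdp, units="1e4CNY"))

    tex = np.stack([np.exp(0.5 * _smooth_field(rng, shape, 15)) for _ in range(3)])
    tex = 100.0 * tex / tex.sum(axis=0)
    for name, f in zip(("sand", "silt", "clay"), tex):
        stack.add(name, layer_from_array(spec, f, units="%"))

    stack.add("wind", layer_from_array(
        spec, np.maximum(cfg.wind_mean + 0.5 * _smooth_field(rng, shape, 15), 0.1),
        units="m/s"))
    stack.add("solar", layer_from_array(
        spec, np.maximum(cfg.solar_mean + 120.0 * _smooth_field(rng, shape, 15),
                         10.0), units="kWh/m2"))
    stack.add("temperature", layer_from_array(
        spec, cfg.temp_mean + 1.0 * _smooth_field(rng, shape, 20), units="degC"))

    stack.tables["water_use"] = _water_use_table(lulc, vz, hier, rng)
    return stack, hier


def _water_use_table(lulc, village_zones, hier: AdminHierarchy,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-village totals (m³/yr) proportional to the area of the using class."""
    rows = []
    for zid, _, _ in hier.zones["village"]:
        in_zone = village_zones == zid
        n_cult = int((in_zone & (lulc == CULTIVATED)).sum())
        n_ind = int((in_zone & (lulc == BUILTUP)).sum())
        n_eco = int((in_zone & ((lulc == FOREST) | (lulc == GRASSLAND))).sum())
        rows.append({
            "zone_id": zid,
            "agricultural": 400.0 * n_cult * (1 + 0.2 * rng.random()),
            "industrial": 600.0 * n_ind * (1 + 0.3 * rng.random()),
            "ecological": 100.0 * n_eco * (1 + 0.2 * rng.random()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planting bundle archetypes and a driver effect
# ---------------------------------------------------------------------------

def plant_bundles(
    stack: LandscapeStack,
    hier: AdminHierarchy,
    planted: PlantedStructure,
    zone_rasters: dict[str, ZoneRaster] | None = None,
) -> tuple[LandscapeStack, pd.DataFrame]:
    """Perturb input layers so zone-level budget vectors cluster by archetype.

    Each zone at the target scale receives a true archetype label; membership
    follows the named driver's zonal-mean rank groups with probability
    1 − exp(−effect) (so effect 0 makes labels independent of the driver).

    Planting then rebuilds the layers that control each service in two steps.
    First the zone compositions are balanced — LULC is re-drawn inside every
    zone at the global class weights (level sets of a smooth field, so patches
    stay spatially coherent) and population is redistributed — so that
    landscape composition no longer dominates the between-zone budget
    variance. Then per-service levers push the zones apart with strength
    ``separation``:

    * CP — NDVI level on cultivated pixels (supply);
    * WR — the subdistrict water-consumption totals (demand);
    * PR — LAI on forest pixels (supply);
    * FM — hydrologic soil group (supply) and elderly/child densities (demand);
    * HM — land surface temperature (demand);
    * LR — zone population total (demand; also softly couples CP/FM/WR
      demand, as urban-core structure does in real landscapes).

    Returns the perturbed stack and a table of true labels (also stored in
    ``stack.tables['planted_labels']``).
    """
    rng = np.random.default_rng(planted.seed)
    arch = planted.archetype_profiles
    k = arch.shape[0]
    sep = planted.separation
    if zone_rasters is None:
        zone_rasters = rasterize_hierarchy(hier, stack.spec)
    zr = zone_rasters[planted.scale]
    zone_ids = [z[0] for z in hier.zones[planted.scale]]
    if k > len(zone_ids):
        raise ValueError("more archetypes than zones at the target scale")

    # driver-linked label assignment: contiguous rank groups of the driver's
    # zonal mean, randomized with probability exp(-effect)
    driver_name, effect = planted.driver_effect
    driver = stack[driver_name].masked()
    zmeans = np.array([np.nanmean(driver[zr.zone_ids == z]) for z in zone_ids])
    ranks = np.argsort(np.argsort(zmeans))
    by_rank = np.minimum((ranks * k) // len(zone_ids), k - 1)
    random_labels = rng.integers(0, k, size=len(zone_ids))
    keep = rng.random(len(zone_ids)) < (1.0 - np.exp(-effect))
    labels = np.where(keep, by_rank, random_labels)

    out = LandscapeStack(stack.spec,
                         {n: l.with_values(l.values.copy()) for n, l in
                          stack.layers.items()},
                         {n: t.copy() for n, t in stack.tables.items()})
    shape = stack.spec.shape
    weights = np.array(DEFAULT_CLASS_WEIGHTS)
    codes = np.array((CULTIVATED, FOREST, GRASSLAND, WATER, BUILTUP, UNUSED))
    patch_field = _smooth_field(rng, shape, 6)
    lulc = out["lulc"].values
    pop = out["population"].values
    pop_per_pixel = float(pop.mean())
    temp_base = float(out["lst"].values.mean())
    mean_n = (zr.zone_ids != ZoneRaster.NODATA).sum() / len(zone_ids)
    # a zone's water-table demand at lever 1 — well above the domestic term so
    # the table, not population, controls the WR budget of a planted zone
    water_base = 20.0 * 60.0 * pop_per_pixel * mean_n
    water_rows = []

    for zid, g in zip(zone_ids, labels):
        p = arch[g]
        in_zone = zr.zone_ids == zid
        idx = np.flatnonzero(in_zone)
        n = idx.size

        # --- balance composition: re-draw LULC at the global class weights
        order = idx[np.argsort(patch_field.ravel()[idx], kind="stable")]
        bounds = np.round(np.cumsum(weights) * n).astype(int)
        start = 0
        for code, stop in zip(codes, bounds):
            lulc.ravel()[order[start:stop]] = code
            start = stop
        cult = in_zone & (lulc == CULTIVATED)
        forest = in_zone & (lulc == FOREST)
        green = forest | (in_zone & (lulc == GRASSLAND))
        built = in_zone & (lulc == BUILTUP)

        # impervious follows the new built-up pattern
        imp = np.full(n, 0.05)
        imp[(lulc.ravel()[idx] == BUILTUP)] = 0.8
        imp[(lulc.ravel()[idx] == WATER)] = 0.0
        out["impervious"].values.ravel()[idx] = np.clip(
            imp + 0.03 * rng.standard_normal(n), 0.0, 1.0)

        # LR lever: zone population total; spread over non-water pixels
        target_total = pop_per_pixel * n * np.exp(-0.7 * sep * p[5])
        wgt = 0.1 + out["impervious"].values.ravel()[idx]
        wgt[(lulc.ravel()[idx] == WATER)] = 0.0
        wgt = wgt / wgt.sum()
        pop.ravel()[idx] = target_total * wgt

        # FM demand lever: vulnerable densities
        frail = np.exp(-0.5 * sep * p[3])
        out["elderly"].values.ravel()[idx] = 0.18 * pop.ravel()[idx] * frail
        out["children"].values.ravel()[idx] = 0.12 * pop.ravel()[idx] * frail
        # FM supply lever: soil group
        hsg_val = int(np.clip(round(2.5 - 1.5 * np.tanh(sep * p[3] / 2.0)), 1, 4))
        out["hsg"].values[in_zone] = hsg_val

        # CP lever: NDVI level on cultivated pixels sets the zone's VCI
        # share; zone-size compensation keeps the VCI *sum* on target
        n_cult = int(cult.sum())
        comp = mean_n * weights[0] / max(n_cult, 1)
        level = (0.5 + 0.45 * np.tanh(sep * p[0] / 2.0)) * comp
        out["ndvi"].values[cult] = np.clip(
            level + 0.02 * rng.standard_normal(n_cult), 0.01, 0.99)

        # PR lever: LAI on forest pixels, compensated so the zone's leaf-area
        # sum depends on the archetype only; near-threshold PM2.5 keeps the
        # budget supply-driven
        n_forest = int(forest.sum())
        out["lai"].values[forest] = (4.5 * np.exp(sep * p[2])
                                     * mean_n * weights[1] / max(n_forest, 1))
        out["pm25"].values[in_zone] = 12.0 + 0.2 * rng.standard_normal(n)

        # HM lever: zone land surface temperature
        out["lst"].values[in_zone] = (
            temp_base + 3.0 - 4.0 * np.tanh(sep * p[4] / 2.0)
            + 0.2 * rng.standard_normal(n).reshape(-1))

        # WR lever: the zone's water-consumption totals (size-independent)
        scale_wr = np.exp(-sep * p[1])
        water_rows.append({
            "zone_id": zid,
            "agricultural": 0.5 * water_base * scale_wr,
            "industrial": 0.4 * water_base * scale_wr,
            "ecological": 0.1 * water_base * scale_wr,
        })

    if planted.scale == "village":
        out.tables["water_use"] = pd.DataFrame(water_rows)

    label_df = pd.DataFrame({"zone_id": zone_ids, "true_label": labels + 1,
                             "scale": planted.scale})
    out.tables["planted_labels"] = label_df
    return out, label_df
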