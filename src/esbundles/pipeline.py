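"""End-to-end pipeline: generate → quantify → aggregate → bundle → drivers.

A run is a pure function of (config, seed): the run-level seed is forked
deterministically into per-stage seeds (generation, planting, k-means
restarts, permutation tests), so re-running with one seed reproduces every
output byte for byte. Each stage writes its outputs into the run directory
and a manifest records the config echo, seeds, package versions, and a
checksum per CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .budgets import DEFAULT_BALANCE_BAND, ServiceBudgetTable, build_budget_tables
from .bundles import BundleResult, DEFAULT_K, DEFAULT_RESTARTS, kmeans_bundles
from .geodetector import (DEFAULT_DRIVERS, DEFAULT_PERMUTATIONS,
                          DEFAULT_STRATA, factor_detection)
from .grid import (AdminHierarchy, GridSpec, LandscapeStack, RasterLayer,
                   ZoneRaster, rasterize_hierarchy, read_hierarchy,
                   read_raster, write_hierarchy, write_raster)
from .services import ServiceParams, ServiceRasters, quantify_all
from .synth import (LandscapeConfig, PlantedStructure, default_archetypes,
                    generate_landscape, plant_bundles)

log = logging.getLogger("esbundles")

SCALES = ("county", "township", "village")


@dataclass
class BundlingConfig:
    k: int = DEFAULT_K
    n_restarts: int = DEFAULT_RESTARTS
    k_min: int = 2
    k_max: int = 10


@dataclass
class GeodetectorConfig:
    n_strata: int = DEFAULT_STRATA
    n_perm: int = DEFAULT_PERMUTATIONS
    y_mode: str = "label-code"
    drivers: tuple = DEFAULT_DRIVERS


@dataclass
class PlantingConfig:
    enabled: bool = False
    k: int = 6
    separation: float = 3.0
    driver: str = "solar"
    effect: float = 6.0


@dataclass
class RunConfig:
    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    services: ServiceParams = field(default_factory=ServiceParams)
    bundling: BundlingConfig = field(default_factory=BundlingConfig)
    geodetector: GeodetectorConfig = field(default_factory=GeodetectorConfig)
    planted: PlantingConfig = field(default_factory=PlantingConfig)
    balance_band: float = DEFAULT_BALANCE_BAND


def _build(cls, data: dict):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    if data is None:
        data = {}
    names = {f.name: f for f in dc_fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        ftype = names[key].default_factory if names[key].default_factory is not dataclasses.MISSING else None
        if isinstance(val, dict) and ftype is not None and dataclasses.is_dataclass(ftype()):
            kwargs[key] = _build(type(ftype()), val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a parsed YAML mapping; unknown keys are errors.

    The ``landscape`` block accepts the grid fields (n_rows, n_cols,
    cell_size, origin_x, origin_y, crs_label) inline.
    """
    data = dict(data or {})
    land = dict(data.pop("landscape", {}) or {})
    grid_keys = {"n_rows", "n_cols", "cell_size", "origin_x", "origin_y",
                 "crs_label"}
    grid_args = {k: land.pop(k) for k in list(land) if k in grid_keys}
    lcfg = _build(LandscapeConfig, land)
    if grid_args:
        lcfg = dataclasses.replace(lcfg, spec=GridSpec(**{
            "n_rows": lcfg.spec.n_rows, "n_cols": lcfg.spec.n_cols,
            **grid_args}))
    cfg = _build(RunConfig, data)
    return dataclasses.replace(cfg, landscape=lcfg)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Fork a run seed into independent per-stage integer seeds (< 2³¹)."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("[%s] start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            log.info("[%s] done", name)
            return out
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return deco


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@_stage("generate")
def stage_generate(config: RunConfig, seed: int, plant_seed: int):
    lcfg = dataclasses.replace(config.landscape, seed=seed)
    stack, hier = generate_landscape(lcfg)
    zone_rasters = rasterize_hierarchy(hier, stack.spec)
    labels = None
    if config.planted.enabled:
        planted = PlantedStructure(
            archetype_profiles=default_archetypes(config.planted.k),
            driver_effect=(config.planted.driver, config.planted.effect),
            separation=config.planted.separation,
            seed=plant_seed,
        )
        stack, labels = plant_bundles(stack, hier, planted, zone_rasters)
    return stack, hier, zone_rasters, labels


@_stage("quantify")
def stage_quantify(config: RunConfig, stack: LandscapeStack,
                   zone_rasters) -> dict[str, ServiceRasters]:
    params = config.services
    params.pm25.non_rainy_days = config.landscape.non_rainy_days
    params.crop.total_production = config.landscape.total_crop_production
    return quantify_all(stack, zone_rasters["village"], params)


@_stage("aggregate")
def stage_aggregate(services, zone_rasters, hier: AdminHierarchy
                    ) -> dict[str, ServiceBudgetTable]:
    parent_maps = {lv: hier.parent_map(lv) for lv in SCALES}
    return build_budget_tables(services, zone_rasters, parent_maps)


@_stage("bundle")
def stage_bundle(config: RunConfig, budgets, zone_rasters, seed: int
                 ) -> dict[str, BundleResult]:
    out = {}
    for scale in SCALES:
        table = budgets[scale]
        m = table.esdr_matrix()
        n_distinct = np.unique(m.to_numpy(), axis=0).shape[0]
        k = min(config.bundling.k, n_distinct)
        if k < config.bundling.k:
            log.warning("[bundle] %s scale has %d distinct zones; using k=%d",
                        scale, n_distinct, k)
        k_hi = min(config.bundling.k_max, max(n_distinct - 1, 2))
        zr = zone_rasters[scale].zone_ids
        areas = pd.Series(
            {zid: int((zr == zid).sum()) for zid in m.index})
        out[scale] = kmeans_bundles(
            m, k=k, seed=seed, n_restarts=config.bundling.n_restarts,
            scale=scale, zone_areas=areas,
            k_range=range(min(config.bundling.k_min, k_hi), k_hi + 1))
    return out


def driver_table(stack: LandscapeStack, zone_raster: ZoneRaster,
                 drivers=DEFAULT_DRIVERS) -> pd.DataFrame:
    """Zonal mean of every candidate driver layer at one scale."""
    from .budgets import zonal_aggregate

    cols = {}
    for name in drivers:
        cols[name] = zonal_aggregate(stack[name], zone_raster, "mean")
    return pd.DataFrame(cols)


@_stage("drivers")
def stage_drivers(config: RunConfig, stack, zone_rasters, bundle_results,
                  seed: int) -> dict[str, pd.DataFrame]:
    out = {}
    for scale in SCALES:
        dt = driver_table(stack, zone_rasters[scale],
                          config.geodetector.drivers)
        out[scale] = factor_detection(
            bundle_results[scale].labels, dt, scale=scale,
            n_strata=config.geodetector.n_strata,
            n_perm=config.geodetector.n_perm, seed=seed,
            y_mode=config.geodetector.y_mode)
    return out


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def write_stack(stack: LandscapeStack, hier: AdminHierarchy, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, layer in sorted(stack.layers.items()):
        p = out / f"{name}.tif"
        write_raster(layer, p)
        written.append(p)
    write_hierarchy(hier, out / "hierarchy.geojson")
    written.append(out / "hierarchy.geojson")
    for name, tbl in sorted(stack.tables.items()):
        p = out / f"{name}.csv"
        tbl.to_csv(p, index=False)
        written.append(p)
    return written


def read_stack(path: Path) -> tuple[LandscapeStack, AdminHierarchy]:
    path = Path(path)
    tifs = sorted(path.glob("*.tif"))
    if not tifs:
        raise FileNotFoundError(f"no rasters in {path}")
    first = read_raster(tifs[0])
    stack = LandscapeStack(first.spec)
    for p in tifs:
        stack.add(p.stem, read_raster(p, expected_spec=first.spec))
    for p in sorted(path.glob("*.csv")):
        stack.tables[p.stem] = pd.read_csv(p)
    hier = read_hierarchy(path / "hierarchy.geojson")
    return stack, hier


def write_services(services: dict[str, ServiceRasters], out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    written, units = [], []
    for code, sr in sorted(services.items()):
        for side, layer in (("supply", sr.supply), ("demand", sr.demand)):
            p = out / f"{code}_{side}.tif"
            write_raster(layer, p)
            written.append(p)
            units.append({"service": code, "side": side, "units": layer.units})
    up = out / "units_manifest.csv"
    pd.DataFrame(units).to_csv(up, index=False)
    written.append(up)
    return written


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, out_dir) -> Path:
    """Run every stage and write all outputs plus a manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_seed, plant_seed, bundle_seed, perm_seed = stage_seeds(config.seed)

    stack, hier, zone_rasters, labels = stage_generate(config, gen_seed,
                                                       plant_seed)
    written = write_stack(stack, hier, out / "stack")

    services = stage_quantify(config, stack, zone_rasters)
    written += write_services(services, out / "services")

    budgets = stage_aggregate(services, zone_rasters, hier)
    for scale, tbl in budgets.items():
        p = out / f"budget_{scale}.csv"
        tbl.table.to_csv(p)
        written.append(p)

    bundle_results = stage_bundle(config, budgets, zone_rasters, bundle_seed)
    for scale, br in bundle_results.items():
        p = out / f"bundles_{scale}.csv"
        pd.DataFrame({"bundle": br.labels,
                      "area_share": br.area_shares.reindex(br.labels).to_numpy()}
                     ).to_csv(p)
        written.append(p)
        p2 = out / f"bundle_profiles_{scale}.csv"
        br.profile_frame().to_csv(p2)
        written.append(p2)
        p3 = out / f"wss_{scale}.csv"
        br.wss_curve.to_csv(p3)
        written.append(p3)

    qtables = stage_drivers(config, stack, zone_rasters, bundle_results,
                            perm_seed)
    for scale, qt in qtables.items():
        p = out / f"drivers_q_{scale}.csv"
        qt.to_csv(p, index=False)
        written.append(p)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {"generate": gen_seed, "plant": plant_seed,
                        "bundle": bundle_seed, "permutation": perm_seed},
        "config": _config_echo(config),
        "checksums": {str(p.relative_to(out)): _checksum(p)
                      for p in written if p.suffix == ".csv"},
        "versions": _versions(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return out


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dc_fields(obj)}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj
    return enc(config)


def _versions() -> dict:
    import scipy
    import shapely
    import sklearn
    import tifffile
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "scikit-learn": sklearn.__version__,
            "shapely": shapely.__version__, "tifffile": tifffile.__version__}
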