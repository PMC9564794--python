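"""Grid/vector data model and raster/vector I/O.

Conventions used throughout the package:

* all coordinates are projected metres; grid indexing is 0-based with row 0
  at the northern edge of the extent;
* continuous layers are stored as float64, categorical layers (LULC class,
  hydrologic soil group, zone ids) as int32;
* ``nodata`` never participates in arithmetic — every operation either masks
  it out or propagates it, as documented on the operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

DEFAULT_NODATA = -9999.0

#: GeoTIFF tag codes used for the grid metadata.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class AlignmentError(ValueError):
    """Raised when two grids that must be co-registered differ."""


@dataclass(frozen=True)
class GridSpec:
    """Definition of the common analysis grid.

    ``origin_x``/``origin_y`` are the projected coordinates of the top-left
    corner of the top-left pixel; ``cell_size`` is the square pixel edge in
    metres (30 m by default, giving a 900 m² pixel area).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "local-metres"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area(self) -> float:
        """Pixel area in m² (900 m² on the default 30 m grid)."""
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel center as 2-D arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def matches(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        )


@dataclass
class RasterLayer:
    """A single-band grid; row-major values, row 0 = north."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise AlignmentError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.spec.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) pixels."""
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def masked(self) -> np.ndarray:
        """Values as float with nodata replaced by NaN."""
        out = self.values.astype(float, copy=True)
        out[~self.mask] = np.nan
        return out

    def filled(self, fill: float = 0.0) -> np.ndarray:
        out = self.values.astype(float, copy=True)
        out[~self.mask] = fill
        return out

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            self.spec, values, nodata=self.nodata,
            units=self.units if units is None else units,
        )


def layer_from_array(
    spec: GridSpec,
    values: np.ndarray,
    units: str = "",
    nodata: float = DEFAULT_NODATA,
) -> RasterLayer:
    """Convenience constructor; integer arrays are kept integral (int32)."""
    values = np.asarray(values)
    if np.issubdtype(values.dtype, np.integer) or values.dtype == bool:
        values = values.astype(np.int32)
    else:
        values = values.astype(np.float64)
    return RasterLayer(spec, values, nodata=nodata, units=units)


@dataclass
class LandscapeStack:
    """Named collection of co-registered layers plus keyed record tables."""

    spec: GridSpec
    layers: dict[str, RasterLayer] = field(default_factory=dict)
    tables: dict[str, "pd.DataFrame"] = field(default_factory=dict)  # noqa: F821

    def add(self, name: str, layer: RasterLayer) -> None:
        if not layer.spec.matches(self.spec):
            raise AlignmentError(
                f"layer {name!r} grid {layer.spec} does not match stack grid "
                f"{self.spec}"
            )
        self.layers[name] = layer

    def __getitem__(self, name: str) -> RasterLayer:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"stack has no layer {name!r}; available: {sorted(self.layers)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.layers


@dataclass
class AdminHierarchy:
    """Nested admin polygons: county ⊃ township ⊃ village.

    ``zones[level]`` is a list of ``(zone_id, parent_id, geometry)`` with
    stable integer ids unique within the level. County parents are ``-1``.
    """

    levels: tuple[str, ...] = ("county", "township", "village")
    zones: dict[str, list[tuple[int, int, BaseGeometry]]] = field(default_factory=dict)

    def validate(self) -> None:
        for level in self.levels:
            if not self.zones.get(level):
                raise ValueError(f"hierarchy level {level!r} is empty")
            ids = [z[0] for z in self.zones[level]]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate zone ids at level {level!r}")
        for child, parent in zip(self.levels[1:], self.levels[:-1]):
            parent_ids = {z[0] for z in self.zones[parent]}
            for zid, pid, _ in self.zones[child]:
                if pid not in parent_ids:
                    raise ValueError(
                        f"{child} zone {zid} has unknown parent {pid}"
                    )

    def parent_map(self, level: str) -> dict[int, int]:
        return {zid: pid for zid, pid, _ in self.zones[level]}


@dataclass
class ZoneRaster:
    """Per-pixel zone ids for one hierarchy level; nodata = -1."""

    spec: GridSpec
    zone_ids: np.ndarray
    level: str

    NODATA: int = -1

    def __post_init__(self) -> None:
        self.zone_ids = np.asarray(self.zone_ids, dtype=np.int32)
        if self.zone_ids.shape != self.spec.shape:
            raise AlignmentError("zone raster shape does not match grid")


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile, geo tags written directly)
# ---------------------------------------------------------------------------

def write_raster(layer: RasterLayer, path) -> None:
    """Write a layer as a single-band GeoTIFF.

    Grid metadata goes into the standard ModelPixelScale/ModelTiepoint tags,
    the nodata sentinel into GDAL_NODATA, and units/CRS label into the image
    description (JSON).
    """
    spec = layer.spec
    desc = json.dumps({"units": layer.units, "crs_label": spec.crs_label})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(layer.nodata)), True),
    ]
    tifffile.imwrite(
        str(path), layer.values, description=desc, extratags=extratags,
        metadata=None,
    )


def read_raster(path, expected_spec: GridSpec | None = None) -> RasterLayer:
    """Read a single-band GeoTIFF written by :func:`write_raster`.

    If ``expected_spec`` is given the file's grid must match it exactly;
    a mismatch raises :class:`AlignmentError` naming both grids.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            values = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    if values.ndim != 2:
        raise IOError(f"{path} is not a single-band raster")

    cell = float(tags.get(_TAG_PIXEL_SCALE, (30.0,))[0])
    tie = tags.get(_TAG_TIEPOINT, (0.0,) * 6)
    origin_x, origin_y = float(tie[3]), float(tie[4])
    meta = {}
    if 270 in tags:
        try:
            meta = json.loads(tags[270])
        except (json.JSONDecodeError, TypeError):
            meta = {}
    nodata = float(tags.get(_TAG_GDAL_NODATA, DEFAULT_NODATA))
    spec = GridSpec(
        n_rows=values.shape[0], n_cols=values.shape[1], cell_size=cell,
        origin_x=origin_x, origin_y=origin_y,
        crs_label=meta.get("crs_label", "local-metres"),
    )
    if expected_spec is not None and not spec.matches(expected_spec):
        raise AlignmentError(
            f"raster {path} grid {spec} does not match expected {expected_spec}"
        )
    if expected_spec is not None:
        spec = replace(spec, crs_label=expected_spec.crs_label)
    return RasterLayer(spec, values, nodata=nodata, units=meta.get("units", ""))


# ---------------------------------------------------------------------------
# Admin hierarchy I/O (GeoJSON via shapely + json)
# ---------------------------------------------------------------------------

def write_hierarchy(hier: AdminHierarchy, path) -> None:
    features = []
    for level in hier.levels:
        for zid, pid, geom in hier.zones.get(level, []):
            features.append({
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"level": level, "zone_id": int(zid),
                               "parent_id": int(pid)},
            })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_hierarchy(path) -> AdminHierarchy:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    hier = AdminHierarchy()
    zones: dict[str, list] = {lv: [] for lv in hier.levels}
    for feat in fc["features"]:
        props = feat["properties"]
        zones[props["level"]].append(
            (int(props["zone_id"]), int(props["parent_id"]),
             shape(feat["geometry"]))
        )
    hier.zones = {lv: sorted(zs, key=lambda z: z[0]) for lv, zs in zones.items()}
    hier.validate()
    return hier


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_hierarchy(
    hier: AdminHierarchy, spec: GridSpec
) -> dict[str, ZoneRaster]:
    """Rasterize every hierarchy level by pixel-center containment.

    A pixel belongs to the zone whose polygon covers its center; centers
    lying exactly on a shared edge are assigned to the first zone in
    ascending ``zone_id`` order (deterministic tie rule). Pixels covered by
    no polygon become nodata (-1).
    """
    hier.validate()
    x, y = spec.cell_centers()
    out: dict[str, ZoneRaster] = {}
    for level in hier.levels:
        ids = np.full(spec.shape, ZoneRaster.NODATA, dtype=np.int32)
        for zid, _pid, geom in sorted(hier.zones[level], key=lambda z: z[0]):
            unassigned = ids == ZoneRaster.NODATA
            if not unassigned.any():
                break
            hit = shapely.intersects_xy(geom, x[unassigned], y[unassigned])
            idx = np.flatnonzero(unassigned)
            ids.flat[idx[hit]] = zid
        out[level] = ZoneRaster(spec, ids, level)
    return out
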