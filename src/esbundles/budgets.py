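"""Zonal aggregation of supply/demand and the ecological supply–demand ratio.

The ESDR of a zone is (S − D) / ((Smax + Dmax)/2), where Smax and Dmax are
the maximum aggregated supply and demand over the zones of that scale, so
ESDR ∈ [−2, 2]: positive means surplus, negative deficit, near zero balance.
Extensive services (CP in t, WR in m³, PR in g) are aggregated by sum,
dimensionless indices (FM, HM, LR) by mean; ESDR is computed from the
zone-level aggregates, with the maxima taken within each scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterLayer, ZoneRaster
from .services import SERVICE_CODES, ServiceRasters

#: aggregation method per service (recorded in every output table).
AGGREGATION = {"CP": "sum", "WR": "sum", "PR": "sum",
               "FM": "mean", "HM": "mean", "LR": "mean"}

#: |ESDR| below this is classified "balance" on maps (configurable).
DEFAULT_BALANCE_BAND = 0.1


def zonal_aggregate(
    raster: RasterLayer, zone_raster: ZoneRaster, method: str = "sum"
) -> pd.Series:
    """Aggregate a raster over zones; nodata pixels are excluded.

    Returns a Series indexed by zone_id. A zone whose pixels are all nodata
    is an error (flagged by id).
    """
    if method not in ("sum", "mean"):
        raise ValueError("method must be 'sum' or 'mean'")
    if not raster.spec.matches(zone_raster.spec):
        raise ValueError("raster and zone raster are not co-registered")
    zones = zone_raster.zone_ids
    valid = raster.mask & (zones != ZoneRaster.NODATA)
    zids = zones[valid]
    vals = raster.values[valid].astype(float)
    all_ids = np.unique(zones[zones != ZoneRaster.NODATA])
    sums = np.bincount(zids, weights=vals, minlength=all_ids.max() + 1)
    counts = np.bincount(zids, minlength=all_ids.max() + 1)
    empty = all_ids[counts[all_ids] == 0]
    if empty.size:
        raise ValueError(f"zone(s) {empty.tolist()} contain only nodata pixels")
    out = sums[all_ids]
    if method == "mean":
        out = out / counts[all_ids]
    return pd.Series(out, index=pd.Index(all_ids, name="zone_id"), name=method)


def esdr(supply: pd.Series, demand: pd.Series) -> pd.Series:
    """Ecological supply–demand ratio per zone of one scale.

    ESDR = (S − D) / ((Smax + Dmax)/2), with maxima over the zones passed in.
    Invariant to a common positive rescaling of all S and D; its sign is the
    sign of S − D.
    """
    s = supply.astype(float)
    d = demand.reindex(s.index).astype(float)
    smax, dmax = float(s.max()), float(d.max())
    denom = (smax + dmax) / 2.0
    if denom <= 0:
        raise ValueError("Smax + Dmax must be positive")
    return (s - d) / denom


def minmax_normalize(values, target_range: str = "unit") -> np.ndarray:
    """Min-max normalization: (x − xmin)/(xmax − xmin) ∈ [0, 1].

    ``target_range='symmetric'`` additionally rescales to [−1, 1]
    (2·xnew − 1). At least two distinct values are required.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("min-max normalization needs ≥ 2 distinct values")
    out = (x - lo) / (hi - lo)
    if target_range == "symmetric":
        out = 2.0 * out - 1.0
    elif target_range != "unit":
        raise ValueError("target_range must be 'unit' or 'symmetric'")
    return out


@dataclass
class ServiceBudgetTable:
    """Per-zone supply, demand, and ESDR for the six services at one scale."""

    scale: str
    table: pd.DataFrame  # index zone_id; columns {code}_{S,D,ESDR} + parent_id
    aggregation: dict[str, str] = field(default_factory=lambda: dict(AGGREGATION))

    def esdr_matrix(self) -> pd.DataFrame:
        return self.table[[f"{c}_ESDR" for c in SERVICE_CODES]].rename(
            columns={f"{c}_ESDR": c for c in SERVICE_CODES})

    def classify(self, balance_band: float = DEFAULT_BALANCE_BAND) -> pd.DataFrame:
        """Surplus / balance / deficit per zone and service."""
        m = self.esdr_matrix()
        return m.apply(lambda col: np.where(
            np.abs(col) <= balance_band, "balance",
            np.where(col > 0, "surplus", "deficit")))


#: unit conversions applied before budgeting so supply and demand of one
#: service are commensurable (PR demand is produced in μg, supply in g).
_DEMAND_SCALE = {"PR": 1e-6}


def build_budget_tables(
    services: dict[str, ServiceRasters],
    zone_rasters: dict[str, ZoneRaster],
    parent_maps: dict[str, dict[int, int]] | None = None,
) -> dict[str, ServiceBudgetTable]:
    """One budget table per scale from the 6 services' supply/demand rasters."""
    out = {}
    for scale, zr in zone_rasters.items():
        cols = {}
        for code in SERVICE_CODES:
            sr = services[code]
            method = AGGREGATION[code]
            s = zonal_aggregate(sr.supply, zr, method)
            d = zonal_aggregate(sr.demand, zr, method) * _DEMAND_SCALE.get(code, 1.0)
            cols[f"{code}_S"] = s
            cols[f"{code}_D"] = d
            # raw sums keep hierarchy additivity; the ESDR takes a zone that
            # retains nothing as providing zero supply, not negative supply
            cols[f"{code}_ESDR"] = esdr(s.clip(lower=0.0), d.clip(lower=0.0))
        table = pd.DataFrame(cols)
        if parent_maps and scale in parent_maps:
            table.insert(0, "parent_id",
                         pd.Series(parent_maps[scale]).reindex(table.index))
        out[scale] = ServiceBudgetTable(scale, table)
    return out
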