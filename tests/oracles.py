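"""Independent scalar reference implementations of the per-pixel formulas.

Each function works on plain Python floats, written directly from the model
definitions and kept deliberately separate from the package's vectorized
code paths so the two can be compared as implementation vs oracle.
"""

from __future__ import annotations

import math
import statistics


def vci_scalar(ndvi: float, ndvi_min: float, ndvi_max: float) -> float:
    return (ndvi - ndvi_min) / (ndvi_max - ndvi_min)


def crop_supply_scalar(vci: float, vci_sum: float, total: float) -> float:
    return total * vci / vci_sum


def crop_demand_scalar(pop: float, per_capita: float) -> float:
    return pop * per_capita


def budyko_yield_scalar(p: float, et0: float, awc: float, kc: float,
                        z: float, vegetated: bool) -> float:
    if not vegetated:
        return p - min(kc * et0, p)
    r = kc * et0 / p
    w = z * awc / p + 1.25
    aet_ratio = (1 + w * r) / (1 + w * r + 1 / r)
    return (1 - aet_ratio) * p


def water_retention_scalar(y: float, p: float, c: float) -> float:
    return y - p * c


def pm25_supply_scalar(conc: float, lai: float, pixel_area: float,
                       vd: float, resusp: float, hours: float,
                       days: float, is_forest: bool) -> float:
    if not is_forest:
        return 0.0
    flux = vd * conc * 3600.0 / 1e6       # g/(m²·h)
    tcla = pixel_area * lai
    qd = flux * tcla * hours * (1 - resusp)
    return days * qd


def pm25_demand_scalar(conc: float, permitted: float, height: float,
                       pixel_area: float) -> float:
    if conc > permitted:
        return (conc - permitted) * height * pixel_area * 365.0 * 24.0
    return 0.0


def flood_supply_scalar(cn: float, storm: float) -> float:
    if cn <= 0:
        return 1.0  # infinite retention limit
    retention = 25400.0 / cn - 254.0
    if storm > 0.2 * retention:
        runoff = (storm - 0.2 * retention) ** 2 / (storm + 0.8 * retention)
    else:
        runoff = 0.0
    return 1.0 - runoff / storm


def cooling_capacity_scalar(shade: float, kc: float, et0: float,
                            etmax: float, albedo: float) -> float:
    eti = min(max(kc * et0 / etmax, 0.0), 1.0)
    return 0.6 * shade + 0.2 * eti + 0.2 * albedo


def heat_demand_raw_scalar(t: float, t_ref: float, mode: str = "intended") -> float:
    if mode == "intended":
        return max(0.0, t - t_ref)
    return t - t_ref if t < t_ref else 0.0


def recreation_demand_scalar(density: float, guided: float) -> float:
    return density * guided


def esdr_scalar(s: float, d: float, smax: float, dmax: float) -> float:
    return (s - d) / ((smax + dmax) / 2.0)


def minmax_scalar(x: float, lo: float, hi: float) -> float:
    return (x - lo) / (hi - lo)


def q_statistic_bruteforce(y, strata) -> float:
    """Group-by variance decomposition with population variances."""
    y = list(map(float, y))
    n = len(y)
    total_var = statistics.pvariance(y)
    groups: dict = {}
    for yi, si in zip(y, strata):
        groups.setdefault(si, []).append(yi)
    within = sum(len(g) * statistics.pvariance(g) if len(g) > 1 else 0.0
                 for g in groups.values())
    return 1.0 - within / (n * total_var)
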