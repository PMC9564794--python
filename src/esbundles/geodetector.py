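"""Factor-detector attribution of bundle patterns (q-statistic).

The q-statistic measures how much of the spatial variance of a response Y a
categorical stratification X explains:

    q = 1 − Σ_h N_h σ_h² / (N σ²),   h = 1..L strata,

with population (biased) variances throughout, so q ∈ [0, 1]: 0 means the
strata carry no information about Y, 1 means Y is constant within every
stratum. Continuous drivers are discretized into quantile strata first.
Significance is assessed by a permutation test (shuffling Y against the
strata), which is assumption-free and exactly reproducible under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the candidate driver set: zonal means of these layers.
DEFAULT_DRIVERS = ("gdp", "population", "impervious", "nis", "precipitation",
                   "temperature", "wind", "solar", "sand", "silt", "clay",
                   "dem", "slope", "roughness")

DEFAULT_STRATA = 5
DEFAULT_PERMUTATIONS = 999
SIGNIFICANCE_LEVEL = 0.1


@dataclass
class QResult:
    driver: str
    scale: str
    q: float
    p_value: float
    n_strata: int
    method: str = "quantile"
    y_mode: str = "label-code"

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def discretize(
    values, n_strata: int = DEFAULT_STRATA, method: str = "quantile"
) -> np.ndarray:
    """Discretize a continuous driver into strata labels 0..L−1.

    Quantile edges use the 'lower' rule (each edge is a data value), so the
    stratification is invariant under strictly monotone transforms of the
    driver; ties on an edge resolve to the lower stratum. If too few distinct
    values exist, adjacent strata merge with a warning (a constant vector is
    an error).
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot stratify a constant vector")
    if method == "quantile":
        qs = np.arange(1, n_strata) / n_strata
        edges = np.quantile(x, qs, method="lower")
    elif method == "equal_interval":
        edges = np.min(x) + np.arange(1, n_strata) * (np.ptp(x) / n_strata)
    else:
        raise ValueError("method must be 'quantile' or 'equal_interval'")
    labels = np.searchsorted(np.unique(edges), x, side="left")
    # relabel to consecutive, dropping empty strata
    uniq, labels = np.unique(labels, return_inverse=True)
    if uniq.size < n_strata:
        warnings.warn(
            f"only {uniq.size} of {n_strata} strata are distinct; merged",
            stacklevel=2)
    return labels


def q_statistic(y, strata) -> float:
    """Variance-explained q of a stratification (population variances)."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(strata)
    if y.shape != s.shape:
        raise ValueError("y and strata must align")
    y = y - y.mean()  # centering: variances unchanged, cancellation avoided
    total_var = y.var()
    if total_var <= 0:
        raise ValueError("zero total variance in y")
    _, inv, counts = np.unique(s, return_inverse=True, return_counts=True)
    sums = np.bincount(inv, weights=y)
    sqs = np.bincount(inv, weights=y * y)
    within = sqs - sums**2 / counts  # Σ_h N_h σ_h²
    q = 1.0 - within.sum() / (y.size * total_var)
    return float(min(max(q, 0.0), 1.0))


def q_significance(
    y, strata, n_perm: int = DEFAULT_PERMUTATIONS, seed: int = 0,
    statistic=q_statistic,
) -> float:
    """Permutation p-value: p = (1 + #{q_perm ≥ q_obs}) / (1 + n_perm)."""
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = np.asarray(y, dtype=float)
    s = np.asarray(strata)
    q_obs = statistic(y, s)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if statistic(rng.permutation(y), s) >= q_obs - 1e-15:
            count += 1
    return (1 + count) / (1 + n_perm)


def _indicator_mean_q(labels: np.ndarray, strata: np.ndarray) -> float:
    """Mean q over per-bundle 0/1 membership indicators (categorical Y)."""
    qs = []
    for b in np.unique(labels):
        ind = (labels == b).astype(float)
        if ind.var() > 0:
            qs.append(q_statistic(ind, strata))
    if not qs:
        raise ValueError("degenerate labels: a single bundle")
    return float(np.mean(qs))


def factor_detection(
    bundle_labels: pd.Series,
    drivers: pd.DataFrame,
    scale: str = "",
    n_strata: int = DEFAULT_STRATA,
    method: str = "quantile",
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    y_mode: str = "label-code",
) -> pd.DataFrame:
    """q and permutation p for every driver against the bundle labels.

    ``drivers`` holds one column of zonal means per driver, indexed like
    ``bundle_labels`` (zone_id). ``y_mode='label-code'`` uses the integer
    bundle label as Y (the field's common practice); ``'indicator-mean'``
    averages q over per-bundle membership indicators (the statistically
    cleaner reading of a categorical Y). Rows are sorted by descending q.
    """
    if y_mode not in ("label-code", "indicator-mean"):
        raise ValueError("y_mode must be 'label-code' or 'indicator-mean'")
    labels = bundle_labels.sort_index()
    if not labels.index.equals(drivers.sort_index().index):
        raise ValueError("bundle labels and driver rows do not align")
    drivers = drivers.sort_index()
    lab = labels.to_numpy()
    rows = []
    rng = np.random.default_rng(seed)
    for name in drivers.columns:
        strata = discretize(drivers[name].to_numpy(), n_strata, method)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if y_mode == "label-code":
            y = lab.astype(float)
            q = q_statistic(y, strata)
            p = q_significance(y, strata, n_perm=n_perm, seed=sub_seed)
        else:
            q = _indicator_mean_q(lab, strata)
            p = q_significance(
                lab.astype(float), strata, n_perm=n_perm, seed=sub_seed,
                statistic=lambda yy, ss: _indicator_mean_q(
                    yy.astype(int), ss))
        rows.append(QResult(driver=name, scale=scale, q=q, p_value=p,
                            n_strata=int(np.unique(strata).size),
                            method=method, y_mode=y_mode))
    df = pd.DataFrame([{
        "scale": r.scale, "driver": r.driver, "q": r.q, "p_value": r.p_value,
        "significant": r.significant, "n_strata": r.n_strata,
        "method": r.method, "y_mode": r.y_mode,
    } for r in rows]).sort_values("q", ascending=False, ignore_index=True)
    return df
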