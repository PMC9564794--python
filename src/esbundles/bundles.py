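"""Ecosystem-service budget bundles: k-means on normalized ESDR vectors.

Zones with similar six-service budget profiles are grouped by k-means
(Lloyd, Euclidean distance, best of ``n_restarts`` by within-cluster sum of
squares). Each ESDR column is min-max normalized before clustering so no
service dominates by scale. k defaults to 6 with elbow diagnostics always
emitted; bundles are renumbered 1..k by descending area share so numbering
is reproducible. Per-bundle Z-score profiles standardize the bundle means of
each service across bundles: Z > 0 marks a service above the bundle-mean
average, Z < 0 below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .budgets import minmax_normalize
from .services import SERVICE_CODES

DEFAULT_K = 6
DEFAULT_RESTARTS = 25


@dataclass
class BundleResult:
    scale: str
    k: int
    labels: pd.Series            # zone_id → bundle label ∈ 1..k
    centroids: np.ndarray        # k × 6 in normalized-ESDR space
    zscore_profiles: np.ndarray  # k × 6
    wss_curve: pd.Series         # candidate k → within-cluster sum of squares
    area_shares: pd.Series       # bundle label → share of total area
    seed: int
    n_restarts: int

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.zscore_profiles,
                            index=pd.RangeIndex(1, self.k + 1, name="bundle"),
                            columns=list(SERVICE_CODES))


def _as_matrix(esdr_matrix) -> tuple[np.ndarray, pd.Index]:
    if isinstance(esdr_matrix, pd.DataFrame):
        return esdr_matrix.to_numpy(dtype=float), esdr_matrix.index
    m = np.asarray(esdr_matrix, dtype=float)
    return m, pd.RangeIndex(m.shape[0])


def normalize_columns(esdr_matrix) -> np.ndarray:
    """Min-max normalize each service column to [0, 1] before clustering."""
    m, _ = _as_matrix(esdr_matrix)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        out[:, j] = minmax_normalize(m[:, j])
    return out


def _fit_kmeans(x: np.ndarray, k: int, seed: int, n_restarts: int) -> KMeans:
    if k > np.unique(x, axis=0).shape[0]:
        raise ValueError(f"k={k} exceeds the number of distinct rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    km.fit(x)
    return km


def elbow_select(
    esdr_matrix, k_range=range(2, 11), seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> tuple[int, pd.Series]:
    """Choose k by the elbow of the WSS curve.

    The WSS (best of restarts) is computed for every candidate k; the elbow
    is the k with maximum perpendicular distance to the chord joining the
    curve's endpoints. The full curve is returned for inspection.
    """
    x, _ = _as_matrix(esdr_matrix)
    ks = sorted(k_range)
    if ks[-1] > x.shape[0]:
        raise ValueError("k_range exceeds the number of zones")
    wss = [ _fit_kmeans(x, k, seed, n_restarts).inertia_ for k in ks ]
    curve = pd.Series(wss, index=pd.Index(ks, name="k"), name="wss")
    k0, k1 = ks[0], ks[-1]
    w0, w1 = wss[0], wss[-1]
    span = max(w0 - w1, 1e-300)
    # normalized coordinates so the chord distance is scale-free
    kk = (np.asarray(ks) - k0) / max(k1 - k0, 1)
    ww = (np.asarray(wss) - w1) / span
    dist = np.abs(kk + ww - 1.0) / np.sqrt(2.0)
    best = ks[int(np.argmax(dist))]
    return best, curve


def zscore_profiles(esdr_matrix, labels) -> np.ndarray:
    """Standardize per-service bundle means across bundles.

    For each service column the bundle means are reduced to Z-scores
    ((mean_b − mean of bundle means)/sd of bundle means, population sd);
    all-equal bundle means degenerate to zeros.
    """
    m, idx = _as_matrix(esdr_matrix)
    lab = np.asarray(labels)
    ks = np.unique(lab)
    if ks.size < 2:
        raise ValueError("Z-score profiles need at least two bundles")
    means = np.vstack([m[lab == b].mean(axis=0) for b in ks])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)  # population sd across bundles
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (means - mu) / sd
    z[:, sd == 0] = 0.0
    return z


def kmeans_bundles(
    esdr_matrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    scale: str = "",
    zone_areas: pd.Series | None = None,
    k_range=range(2, 11),
) -> BundleResult:
    """Cluster normalized ESDR vectors into k bundles.

    ``zone_areas`` (zone_id → pixel count or area) weights the area shares
    used for renumbering; without it every zone counts equally. The elbow
    diagnostics over ``k_range`` are always computed and attached; the
    requested k is never silently overridden.
    """
    raw, index = _as_matrix(esdr_matrix)
    x = normalize_columns(raw)
    km = _fit_kmeans(x, k, seed, n_restarts)
    raw_labels = km.labels_

    if zone_areas is None:
        areas = pd.Series(1.0, index=index)
    else:
        areas = zone_areas.reindex(index).astype(float)
    share = np.array([areas[raw_labels == b].sum() for b in range(k)])
    share = share / share.sum()
    # renumber 1..k by descending area share (stable for ties)
    order = np.argsort(-share, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = pd.Series(remap[raw_labels], index=index, name="bundle")

    centroids = km.cluster_centers_[order]
    zprof = zscore_profiles(x, labels.to_numpy())
    try:
        _, curve = elbow_select(x, k_range=k_range, seed=seed,
                                n_restarts=n_restarts)
    except ValueError:
        curve = pd.Series(dtype=float, name="wss")
    shares = pd.Series(share[order], index=pd.RangeIndex(1, k + 1, name="bundle"),
                       name="area_share")
    return BundleResult(scale=scale, k=k, labels=labels, centroids=centroids,
                        zscore_profiles=zprof, wss_curve=curve,
                        area_shares=shares, seed=seed, n_restarts=n_restarts)


def plot_profiles(result: BundleResult, path=None):
    """Optional bar-chart rendering of the Z-score profiles (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.profile_frame()
    fig, ax = plt.subplots(figsize=(8, 4))
    df.plot.bar(ax=ax)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("Z-score of bundle-mean ESDR")
    ax.set_xlabel("bundle")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
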