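"""Plot clustering and cluster-level bimodality mapping.

Plots are grouped either on a regular lon/lat grid ("fishing net", 10
arc-minute cells by default) or by K-means on the leading three
environmental principal components; each retained cluster (>= 10 plots)
gets a dip / D' / skewness / BI summary and a four-way stability label.
A bootstrap permutation-importance analysis ranks the seven key climate
and soil determinants for predicting BI (or relEV) with an ensemble
regressor.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .dip import BimodalityResult, bimodality_result
from .inventory import DETERMINANT_NAMES, PlotRecord


class ClusterMethod(str, enum.Enum):
    FISHING_NET = "fishing_net"
    KMEANS_ENV = "kmeans_env"


@dataclasses.dataclass
class ClusterSet:
    method: ClusterMethod
    assignments: dict[str, list[int]]   # cluster id -> plot indices
    min_plots: int
    n_dropped_plots: int


def fishing_net_clusters(
    plots: list[PlotRecord],
    cell_arcmin: float = 10.0,
    min_plots: int = 10,
) -> ClusterSet:
    """Group plots by half-open lon/lat grid cells of ``cell_arcmin``.

    Cell id is ``(floor(lon / d), floor(lat / d))`` with ``d`` the cell
    size in degrees; clusters with fewer than ``min_plots`` members are
    dropped.
    """
    d = cell_arcmin / 60.0
    cells: dict[str, list[int]] = {}
    for i, p in enumerate(plots):
        if not -90.0 <= p.lat <= 90.0:
            raise ValueError(f"plot {p.plot_id}: latitude outside [-90, 90]")
        key = f"{int(np.floor(p.lon / d))}_{int(np.floor(p.lat / d))}"
        cells.setdefault(key, []).append(i)
    kept = {k: v for k, v in cells.items() if len(v) >= min_plots}
    dropped = sum(len(v) for v in cells.values()) - sum(len(v) for v in kept.values())
    return ClusterSet(ClusterMethod.FISHING_NET, kept, min_plots, dropped)


def kmeans_env_clusters(
    plots: list[PlotRecord],
    k: int,
    n_pcs: int = 3,
    seed: int = 0,
    min_plots: int = 10,
) -> ClusterSet:
    """K-means on the leading environmental PCs; seeded, small clusters
    dropped (their plots leave the downstream BI analysis)."""
    from sklearn.cluster import KMeans

    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(plots):
        raise ValueError("k cannot exceed the number of plots")
    X = np.array([p.env_pcs[:n_pcs] for p in plots])
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    cells: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        cells.setdefault(f"k{lab}", []).append(i)
    kept = {key: v for key, v in cells.items() if len(v) >= min_plots}
    dropped = len(plots) - sum(len(v) for v in kept.values())
    return ClusterSet(ClusterMethod.KMEANS_ENV, kept, min_plots, dropped)


def cluster_bimodality(
    clusters: ClusterSet,
    relev: np.ndarray,
    a: float = 6.0,
    b: float = 2.0,
    compute_pvalues: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dip, D', skewness, BI and label for every retained cluster.

    ``relev`` holds one (area-based) relEV value per plot, indexed like
    the plot list the clusters were built from; plots with undefined
    relEV (NaN) are ignored.
    """
    relev = np.asarray(relev, float)
    rows = []
    for cid, idx in clusters.assignments.items():
        vals = relev[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size < clusters.min_plots:
            continue
        if np.ptp(vals) == 0:
            # degenerate single-composition cluster: minimum dip, and the
            # dominance sign follows which side of 0.5 the composition sits
            # on (sample skewness is undefined at zero variance)
            from .dip import adapted_dip, bimodality_index, classify_bi
            d = 1.0 / (2 * vals.size)
            dp = adapted_dip(d, vals.size)
            s = -1.0 if vals[0] > 0.5 else (1.0 if vals[0] < 0.5 else 0.0)
            bi = bimodality_index(dp, s, a=a, b=b)
            r = BimodalityResult(n=vals.size, dip=d, dip_adapted=dp,
                                 skewness=s, bi=bi, label=classify_bi(bi),
                                 dip_pvalue=None)
        else:
            r = bimodality_result(vals, a=a, b=b,
                                  compute_pvalue=compute_pvalues, rng=rng)
        rows.append(dict(cluster_id=cid, n=r.n, dip=r.dip, dip_adapted=r.dip_adapted,
                         skewness=r.skewness, bi=r.bi, label=r.label.value,
                         dip_pvalue=r.dip_pvalue))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# determinant importance

def permutation_importance(
    features: pd.DataFrame,
    response: np.ndarray,
    n_boot: int = 100,
    frac: float = 0.33,
    seed: int = 0,
    feature_names: tuple[str, ...] = DETERMINANT_NAMES,
    n_estimators: int = 100,
) -> pd.DataFrame:
    """Bootstrap permutation importance of the key determinants.

    Fits an ensemble regressor (random forest) on ``n_boot`` bootstrap
    subsamples of ``frac`` of the data; importance of a feature is the
    mean increase in out-of-sample squared error when that feature's
    values are permuted.  Returns mean and sd per feature over the
    bootstrap fits.
    """
    from sklearn.ensemble import RandomForestRegressor

    X = features[list(feature_names)].to_numpy(float)
    y = np.asarray(response, float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; importance undefined")
    rng = np.random.default_rng(seed)
    n = len(y)
    m = max(int(round(frac * n)), 2)
    imps = np.empty((n_boot, X.shape[1]))
    for ib in range(n_boot):
        idx = rng.integers(0, n, size=m)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size < 2:
            oob = np.arange(n)
        rf = RandomForestRegressor(n_estimators=n_estimators,
                                   random_state=int(rng.integers(2**31)))
        rf.fit(X[idx], y[idx])
        base = np.mean((rf.predict(X[oob]) - y[oob]) ** 2)
        for j in range(X.shape[1]):
            Xp = X[oob].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            imps[ib, j] = np.mean((rf.predict(Xp) - y[oob]) ** 2) - base
    return pd.DataFrame({
        "feature": list(feature_names),
        "importance_mean": imps.mean(axis=0),
        "importance_sd": imps.std(axis=0, ddof=1),
    }).sort_values("importance_mean", ascending=False, ignore_index=True)
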