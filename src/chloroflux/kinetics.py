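"""Enrichment-kinetics analytics.

Linear enrichment slopes over the short pulse window, regression of each
intermediate's enrichment on a reference metabolite (DHAP in the study design
— the extent of isotopic equilibrium with the triose-phosphate pool), paired
comparison of slope sets between species, k-means clustering of enrichment
time courses with the Tibshirani gap statistic for choosing k, and classical
(Torgerson) multidimensional scaling of the pooled curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "LabelSeries",
    "ClusterResult",
    "enrichment_slope",
    "regress_on_reference",
    "paired_slope_test",
    "gap_statistic",
    "gap_select_k",
    "cluster_and_order",
    "mds_embed",
    "DegenerateTestError",
]


class DegenerateTestError(ValueError):
    """Raised when a statistical test has no sampling variability to work with."""


@dataclass
class LabelSeries:
    """Per-metabolite enrichment trajectory.

    ``values`` may be 1-D (one trace) or 2-D ``(n_replicates, n_times)``;
    replicate traces are averaged per time point before any fitting
    (reduces the leverage of outlier replicates).
    Enrichments are fractions in [0, 1]; times in seconds.
    """

    metabolite_id: str
    times: np.ndarray
    values: np.ndarray
    pool_size: float | None = None
    n_carbons: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.metabolite_id}: times must be strictly ascending")
        if self.values.shape[-1] != self.times.size:
            raise ValueError(f"{self.metabolite_id}: values/times length mismatch")
        if np.nanmin(self.values) < -1e-9 or np.nanmax(self.values) > 1 + 1e-9:
            raise ValueError(f"{self.metabolite_id}: enrichment outside [0, 1]")

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


@dataclass
class ClusterResult:
    """k-means outcome with clusters renumbered by labelling speed.

    Cluster 1 is the fastest-labelling group (highest mean enrichment at the
    earliest time point, descending thereafter).
    """

    k: int
    labels: pd.Series            # metabolite -> cluster number in 1..k
    gap_curve: pd.DataFrame | None = None
    inertia: float = float("nan")
    centers: np.ndarray = field(default=None, repr=False)


def _window_points(series: LabelSeries, window, include_origin: bool) -> tuple:
    t = series.times
    y = series.mean
    if include_origin and (t.size == 0 or t[0] > 0):
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    return t[mask], y[mask]


def enrichment_slope(series: LabelSeries, window=(0.0, 40.0),
                     include_origin: bool = True):
    """OLS slope of mean enrichment vs time over ``window`` (fraction s⁻¹).

    The t = 0, E = 0 point is included by default (label introduction is
    essentially lag-free in the pulse design).  Returns (slope, intercept, r).
    """
    t, y = _window_points(series, window, include_origin)
    if t.size < 3:
        raise ValueError(
            f"{series.metabolite_id}: need >= 3 points in window, got {t.size}")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def regress_on_reference(series: LabelSeries, reference: LabelSeries,
                         window=(5.0, 40.0)):
    """OLS (with intercept) of metabolite enrichment on reference enrichment.

    Points are inner-joined on shared time points within ``window``.  Returns
    (slope, r) with r the Pearson correlation on the same points.
    """
    shared, ia, ib = np.intersect1d(series.times, reference.times,
                                    return_indices=True)
    mask = (shared >= window[0]) & (shared <= window[1])
    if mask.sum() < 3:
        raise ValueError("fewer than 3 shared time points in window")
    y = series.mean[ia][mask]
    x = reference.mean[ib][mask]
    if np.ptp(x) == 0:
        raise ValueError("reference enrichment has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue)


def paired_slope_test(slopes_a, slopes_b):
    """Two-sided paired t-test on metabolite-matched slope sets.

    Returns (t, p).  Raises :class:`DegenerateTestError` when the pairwise
    differences have no variance (identical sets, or a constant offset).
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need metabolite-matched sets of length >= 3")
    diff = a - b
    if np.ptp(diff) == 0:
        raise DegenerateTestError(
            "pairwise slope differences are constant; t statistic undefined"
            if diff[0] != 0 else "slope sets are identical")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _kmeans(matrix: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(matrix)
    return km


def _pooled_within_dispersion(matrix: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = matrix[labels == lab]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def gap_statistic(matrix, kmin: int = 2, kmax: int = 20, B: int = 100,
                  seed: int = 0, n_init: int = 100) -> pd.DataFrame:
    """Tibshirani gap curve for k in [kmin, kmax].

    The reference distribution draws each feature uniformly over its observed
    range; ``B`` bootstrap reference datasets per k.  Returns a frame with
    columns k, log_w, gap, se.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("input matrix contains missing values; impute first")
    if X.shape[0] < kmax + 1:
        raise ValueError(f"need at least kmax+1={kmax + 1} rows, got {X.shape[0]}")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(B)]
    rows = []
    for k in range(kmin, kmax + 1):
        km = _kmeans(X, k, seed, n_init)
        log_w = np.log(_pooled_within_dispersion(X, km.labels_))
        log_w_ref = np.empty(B)
        for b, ref in enumerate(refs):
            kmb = _kmeans(ref, k, seed + b + 1, max(1, n_init // 10))
            log_w_ref[b] = np.log(_pooled_within_dispersion(ref, kmb.labels_))
        gap = log_w_ref.mean() - log_w
        se = log_w_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)
        rows.append((k, log_w, gap, se))
    return pd.DataFrame(rows, columns=["k", "log_w", "gap", "se"])


def gap_select_k(matrix, kmin: int = 2, kmax: int = 20, B: int = 100,
                 seed: int = 0, n_init: int = 100) -> ClusterResult:
    """Choose k by the gap criterion and cluster at the chosen k.

    Selection rule: the smallest k with gap(k) >= gap(k+1) − se(k+1); if no k
    satisfies it, the k with the largest gap is used.
    """
    if hasattr(matrix, "values"):
        index = matrix.index
        X = matrix.values.astype(float)
    else:
        X = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    curve = gap_statistic(X, kmin, kmax, B, seed, n_init)
    gaps = curve["gap"].to_numpy()
    ses = curve["se"].to_numpy()
    chosen = None
    for i in range(len(gaps) - 1):
        if gaps[i] >= gaps[i + 1] - ses[i + 1]:
            chosen = int(curve["k"].iloc[i])
            break
    if chosen is None:
        chosen = int(curve["k"].iloc[int(np.argmax(gaps))])
    result = cluster_and_order(pd.DataFrame(X, index=index), chosen, seed,
                               n_init=n_init)
    result.gap_curve = curve
    return result


def cluster_and_order(matrix, k: int, seed: int, n_init: int = 100) -> ClusterResult:
    """k-means (Euclidean, ``n_init`` restarts, best inertia) with speed ordering.

    Clusters are renumbered so that cluster 1 has the highest mean value in
    the earliest column (fastest labelling), descending thereafter.
    """
    if hasattr(matrix, "values"):
        index = matrix.index
        X = matrix.values.astype(float)
    else:
        X = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    km = _kmeans(X, k, seed, n_init)
    order = np.argsort(-km.cluster_centers_[:, 0], kind="stable")
    renumber = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([renumber[int(l)] for l in km.labels_], index=index,
                       name="cluster")
    centers = km.cluster_centers_[order]
    return ClusterResult(k=k, labels=labels, inertia=float(km.inertia_),
                         centers=centers)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def mds_embed(matrix, n_components: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the rows under Euclidean distance.

    Double-centres the squared distance matrix, eigendecomposes it and keeps
    the top components (negative eigenvalues clipped to zero).  Orientation is
    fixed by making the largest-magnitude loading of each axis positive.
    """
    if hasattr(matrix, "values"):
        index = matrix.index
        X = matrix.values.astype(float)
    else:
        X = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if np.isnan(X).any():
        raise ValueError("input matrix contains missing values")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    if np.allclose(sq, 0.0):
        raise ValueError("all rows identical: rank-0 distance matrix")
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ sq @ J
    vals, vecs = np.linalg.eigh(Bmat)
    idx = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[idx], 0.0, None)
    coords = vecs[:, idx] * np.sqrt(lam)
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return pd.DataFrame(coords, index=index,
                        columns=[f"dim{j + 1}" for j in range(coords.shape[1])])
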