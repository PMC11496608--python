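"""Stem horizontal location from the lower-crown point cloud.

Returns below half the tree's top height (and above the 1 m understory cut)
are clustered with a full-covariance Gaussian mixture; the component count is
chosen by BIC, with optional greedy entropy-based merging of components.
Each candidate cluster is scored by four size metrics — distance of its
centre to the crown centre, height range, horizontal convex-hull area, and
the proportion of occupied 1 m vertical bins between 1 m and half of top
height — min-max rescaled across clusters (the first and third inverted so
small, central clusters score high) and combined into the weight

    W = p1 + 2*p2 + p3 + 2*p4,        0 <= W <= 6.

The cluster with the largest W is taken as the stem; its mean (x, y) is the
stem location.  When no cluster survives (fewer than 5 returns each, or an
empty lower half) the fall-back is the mean horizontal coordinate of the
canopy returns above half of top height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.mixture import GaussianMixture

from .segment import TreeCrown, UNDERSTORY_CUTOFF

__all__ = [
    "StemClusterMetrics",
    "StemEstimate",
    "lower_half_subset",
    "cluster_gmm",
    "compute_cluster_metrics",
    "rescale_and_weight",
    "locate_stem",
    "merge_stem_locations",
]

MIN_CLUSTER_SIZE = 5


@dataclass
class StemClusterMetrics:
    """Raw and rescaled size metrics for one candidate stem cluster."""

    cluster_id: int
    n_points: int
    center_xy: np.ndarray
    m1: float  # centre-to-crown-centre horizontal distance, m
    m2: float  # height range, m
    m3: float  # horizontal convex hull area, m^2
    m4: float  # proportion of occupied 1 m vertical bins in [1, top/2]
    p1: float = np.nan
    p2: float = np.nan
    p3: float = np.nan
    p4: float = np.nan
    weight: float = np.nan


@dataclass
class StemEstimate:
    stem_xy: np.ndarray
    method: str                 # "cluster" or "fallback"
    weight: float = np.nan
    n_points: int = 0


def lower_half_subset(crown: TreeCrown) -> np.ndarray:
    """Points with 1 m <= height < half of the crown's top height."""
    if len(crown.points) == 0:
        raise ValueError("empty crown")
    h = crown.points[:, 2]
    mask = (h >= UNDERSTORY_CUTOFF) & (h < 0.5 * crown.top_height)
    return crown.points[mask]


def cluster_gmm(
    subset: np.ndarray,
    max_components: int = 8,
    seed: int = 0,
    entropy_merge: bool = False,
) -> list[np.ndarray]:
    """Cluster 3D points with a BIC-selected full-covariance Gaussian mixture.

    Fits k = 1..max_components mixtures, keeps the lowest-BIC model, and hard
    assigns points by maximum responsibility.  With ``entropy_merge`` the
    most-overlapping component pairs are greedily merged while doing so
    removes more soft-assignment entropy than an average split contributes
    (an approximation to mixture-component combination criteria).  Clusters
    with fewer than 5 points are discarded.
    """
    subset = np.asarray(subset, dtype=float)
    if len(subset) < MIN_CLUSTER_SIZE:
        raise ValueError("fallback: fewer than 5 points")
    best = None
    kmax = min(max_components, max(1, len(subset) // MIN_CLUSTER_SIZE))
    for k in range(1, kmax + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=seed,
            n_init=1,
            reg_covar=1e-6,
        ).fit(subset)
        bic = gm.bic(subset)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    resp = gm.predict_proba(subset)

    if entropy_merge and resp.shape[1] > 1:
        resp = _entropy_merge(resp)
    labels = resp.argmax(axis=1)
    clusters = []
    for lab in np.unique(labels):
        pts = subset[labels == lab]
        if len(pts) >= MIN_CLUSTER_SIZE:
            clusters.append(pts)
    if not clusters:
        raise ValueError("fallback: all clusters below minimum size")
    return clusters


def _entropy_merge(resp: np.ndarray) -> np.ndarray:
    """Greedily merge the component pair yielding the largest entropy drop."""

    def entropy(r: np.ndarray) -> float:
        rr = np.clip(r, 1e-300, None)
        return float(-(rr * np.log(rr)).sum())

    resp = resp.copy()
    while resp.shape[1] > 1:
        base = entropy(resp)
        best_drop, best_pair = 0.0, None
        k = resp.shape[1]
        for i in range(k):
            for j in range(i + 1, k):
                merged = np.delete(resp, j, axis=1)
                merged[:, i] = resp[:, i] + resp[:, j]
                drop = base - entropy(merged)
                if drop > best_drop:
                    best_drop, best_pair = drop, (i, j)
        if best_pair is None or best_drop <= base / (2.0 * k):
            break
        i, j = best_pair
        merged = np.delete(resp, j, axis=1)
        merged[:, i] = resp[:, i] + resp[:, j]
        resp = merged
    return resp


def _hull_area(xy: np.ndarray) -> float:
    uniq = np.unique(xy, axis=0)
    if len(uniq) < 3:
        return 0.0
    try:
        return float(ConvexHull(uniq).volume)  # 2D hull "volume" is the area
    except QhullError:
        return 0.0  # collinear points span zero area


def compute_cluster_metrics(
    clusters: list[np.ndarray], crown: TreeCrown
) -> list[StemClusterMetrics]:
    """Raw metrics m1..m4 for each candidate stem cluster.

    m4 bins span [1 m, top_height/2) in 1 m steps (the last bin may be a
    partial metre); a bin counts as occupied when it holds >= 1 return.
    """
    if not clusters:
        raise ValueError("no clusters")
    upper = 0.5 * crown.top_height
    edges = np.arange(UNDERSTORY_CUTOFF, upper, 1.0)
    n_bins = max(1, len(edges))
    out = []
    for cid, pts in enumerate(clusters):
        center = pts[:, :2].mean(axis=0)
        m1 = float(np.hypot(*(center - crown.crown_center_xy)))
        m2 = float(pts[:, 2].max() - pts[:, 2].min())
        m3 = _hull_area(pts[:, :2])
        bin_idx = np.floor(pts[:, 2] - UNDERSTORY_CUTOFF).astype(int)
        bin_idx = bin_idx[(bin_idx >= 0) & (bin_idx < n_bins)]
        m4 = len(np.unique(bin_idx)) / n_bins
        out.append(StemClusterMetrics(cid, len(pts), center, m1, m2, m3, m4))
    return out


def rescale_and_weight(metrics: list[StemClusterMetrics]) -> list[StemClusterMetrics]:
    """Min-max rescale each metric across clusters and combine into W.

    p = (x - x_min) / (x_max - x_min); metrics 1 and 3 are then inverted
    (p = 1 - p) so central, compact clusters score high.  When all clusters
    share the same raw value the rescaled value is set to 1 for everyone
    (constant across clusters, so the ranking is unaffected).
    """
    if not metrics:
        raise ValueError("no clusters")
    raw = np.array([[m.m1, m.m2, m.m3, m.m4] for m in metrics], dtype=float)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    span = hi - lo
    p = np.empty_like(raw)
    for j in range(4):
        if span[j] <= 0:
            p[:, j] = 1.0
        else:
            p[:, j] = (raw[:, j] - lo[j]) / span[j]
            if j in (0, 2):  # invert distance-to-centre and hull area
                p[:, j] = 1.0 - p[:, j]
    w = p[:, 0] + 2.0 * p[:, 1] + p[:, 2] + 2.0 * p[:, 3]
    for m, pi, wi in zip(metrics, p, w):
        m.p1, m.p2, m.p3, m.p4 = (float(v) for v in pi)
        m.weight = float(wi)
    return metrics


def _fallback(crown: TreeCrown) -> StemEstimate:
    h = crown.points[:, 2]
    canopy = crown.points[h > 0.5 * crown.top_height]
    return StemEstimate(canopy[:, :2].mean(axis=0), "fallback")


def locate_stem(
    crown: TreeCrown,
    seed: int = 0,
    max_components: int = 8,
    entropy_merge: bool = False,
) -> StemEstimate:
    """Full stem-location chain for one crown.

    Ties on W are broken by larger cluster size, then larger vertical
    occupancy m4.  Falls back to the canopy-mean centre when the lower half
    is empty or no cluster reaches the 5-return minimum.
    """
    subset = lower_half_subset(crown)
    try:
        clusters = cluster_gmm(subset, max_components, seed, entropy_merge)
    except ValueError:
        return _fallback(crown)
    metrics = rescale_and_weight(compute_cluster_metrics(clusters, crown))
    best = max(metrics, key=lambda m: (m.weight, m.n_points, m.m4))
    pts = clusters[best.cluster_id]
    est = StemEstimate(pts[:, :2].mean(axis=0), "cluster", best.weight, best.n_points)
    return est


def merge_stem_locations(est_e1: StemEstimate, est_e2: StemEstimate) -> np.ndarray:
    """Combine the two epochs' stem estimates for a paired tree.

    The epoch whose winning cluster has more returns takes priority; equal
    counts (or two fall-backs) are averaged; a cluster estimate always beats
    a fall-back.
    """
    c1 = est_e1.method == "cluster"
    c2 = est_e2.method == "cluster"
    if c1 and not c2:
        return est_e1.stem_xy
    if c2 and not c1:
        return est_e2.stem_xy
    if c1 and c2:
        if est_e1.n_points > est_e2.n_points:
            return est_e1.stem_xy
        if est_e2.n_points > est_e1.n_points:
            return est_e2.stem_xy
    return (est_e1.stem_xy + est_e2.stem_xy) / 2.0
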