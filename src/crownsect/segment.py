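"""Individual tree crown (ITC) delineation, pairing, and reference matching.

Markers are found as local maxima of a 2D vertical-occupancy index built from
0.2 m voxels; crown extents come from a marker-controlled assignment on a
0.1 m canopy height model with a height-proportional maximum crown radius.
Returns below 1 m height above ground are treated as understory and never
labelled.  Crowns from two acquisitions are paired greedily by centre
distance (closest first, no duplicate ids, hard 2 m cut-off), and pair
centres can then be matched to planted-stem reference coordinates the same
way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.morphology import disk

from .cloud import PointCloud

__all__ = [
    "Raster2D",
    "CrownLabeling",
    "TreeCrown",
    "CrownPair",
    "vertical_occupancy_raster",
    "detect_markers",
    "segment_crowns",
    "extract_crowns",
    "pair_crowns",
    "match_to_reference",
]

UNDERSTORY_CUTOFF = 1.0  # m; returns below this height are never labelled


@dataclass
class Raster2D:
    """A georeferenced single-band raster (row = x index, col = y index)."""

    values: np.ndarray
    x0: float
    y0: float
    cell: float

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell
        return xs, ys

    def index_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor((xy[:, 0] - self.x0) / self.cell).astype(int)
        iy = np.floor((xy[:, 1] - self.y0) / self.cell).astype(int)
        nx, ny = self.values.shape
        return np.clip(ix, 0, nx - 1), np.clip(iy, 0, ny - 1)


@dataclass
class CrownLabeling:
    """Per-point crown ids (0 = unassigned/understory) plus marker metadata."""

    itc_id: np.ndarray                 # int per point, 0 = unassigned
    markers: np.ndarray                # (n_markers, 2) marker xy
    marker_heights: np.ndarray         # CHM height at each marker

    @property
    def n_crowns(self) -> int:
        return len(self.markers)


@dataclass
class TreeCrown:
    """One delineated crown: its returns (z = height above ground) and
    derived locations.

    ``crown_center_xy`` is the mean horizontal coordinate of returns in the
    top 50% of the crown's height; ``stem_xy`` is filled by the stem locator.
    """

    itc_id: int
    points: np.ndarray                 # (n, 3): x, y, height above ground
    epoch: str = "e1"
    stem_xy: np.ndarray | None = None
    top_height: float = field(init=False)
    crown_center_xy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("crown has no points")
        self.points = np.asarray(self.points, dtype=float)
        self.top_height = float(self.points[:, 2].max())
        top = self.points[:, 2] > 0.5 * self.top_height
        self.crown_center_xy = self.points[top, :2].mean(axis=0)


@dataclass
class CrownPair:
    itc_id_e1: int
    itc_id_e2: int
    center_distance: float
    matched_ref_id: int | None = None
    ref_offset: np.ndarray | None = None


def _heights(cloud: PointCloud) -> np.ndarray:
    if cloud.height is None:
        raise ValueError("cloud must be height-normalized first")
    return cloud.height


def vertical_occupancy_raster(cloud: PointCloud, voxel: float = 0.2) -> Raster2D:
    """Count occupied ``voxel``-sized height bins per vertical column.

    Duplicates within a voxel count once (occupancy, not density); returns
    below the 1 m understory cut-off are excluded.
    """
    h = _heights(cloud)
    keep = cloud.clean & (h >= UNDERSTORY_CUTOFF)
    xyz = cloud.xyz[keep]
    hh = h[keep]
    x0 = float(cloud.xyz[:, 0].min())
    y0 = float(cloud.xyz[:, 1].min())
    nx = int(np.floor((cloud.xyz[:, 0].max() - x0) / voxel)) + 1
    ny = int(np.floor((cloud.xyz[:, 1].max() - y0) / voxel)) + 1
    raster = Raster2D(np.zeros((nx, ny)), x0, y0, voxel)
    if len(xyz) == 0:
        return raster
    ix = np.clip(np.floor((xyz[:, 0] - x0) / voxel).astype(int), 0, nx - 1)
    iy = np.clip(np.floor((xyz[:, 1] - y0) / voxel).astype(int), 0, ny - 1)
    iz = np.floor(hh / voxel).astype(int)
    vox = np.unique(np.column_stack([ix, iy, iz]), axis=0)
    np.add.at(raster.values, (vox[:, 0], vox[:, 1]), 1.0)
    return raster


def detect_markers(
    raster: Raster2D,
    min_distance: float = 1.5,
    min_value: float = 3.0,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Locate crown-centre markers as local maxima of the occupancy raster.

    The raster is lightly Gaussian-smoothed (``smooth_sigma`` in cells, 0 to
    disable) to suppress single-cell speckle, then maxima are taken under a
    circular window of radius ``min_distance`` metres; cells below
    ``min_value`` are ignored.  Returns marker (x, y) cell-centre
    coordinates, strongest first.
    """
    if raster.values.size == 0:
        raise ValueError("empty raster")
    values = raster.values
    if smooth_sigma > 0:
        values = ndimage.gaussian_filter(values, smooth_sigma)
    rad_cells = max(1, int(round(min_distance / raster.cell)))
    peaks = peak_local_max(
        values,
        footprint=disk(rad_cells),
        threshold_abs=min_value,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    vals = values[peaks[:, 0], peaks[:, 1]]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -vals))
    peaks = peaks[order]
    xs = raster.x0 + (peaks[:, 0] + 0.5) * raster.cell
    ys = raster.y0 + (peaks[:, 1] + 0.5) * raster.cell
    return np.column_stack([xs, ys])


def _build_chm(cloud: PointCloud, cell: float) -> Raster2D:
    h = _heights(cloud)
    keep = cloud.clean
    xyz = cloud.xyz[keep]
    hh = h[keep]
    x0 = float(cloud.xyz[:, 0].min())
    y0 = float(cloud.xyz[:, 1].min())
    nx = int(np.floor((cloud.xyz[:, 0].max() - x0) / cell)) + 1
    ny = int(np.floor((cloud.xyz[:, 1].max() - y0) / cell)) + 1
    chm = np.zeros((nx, ny))
    ix = np.clip(np.floor((xyz[:, 0] - x0) / cell).astype(int), 0, nx - 1)
    iy = np.clip(np.floor((xyz[:, 1] - y0) / cell).astype(int), 0, ny - 1)
    np.maximum.at(chm, (ix, iy), hh)
    # 3x3 median pit-filling: raise pits, never lower true maxima
    med = ndimage.median_filter(chm, size=3)
    chm = np.maximum(chm, med)
    return Raster2D(chm, x0, y0, cell)


def segment_crowns(
    cloud: PointCloud,
    markers: np.ndarray,
    chm_cell: float = 0.1,
    max_radius_frac: float = 0.6,
) -> CrownLabeling:
    """Assign returns to crowns via a marker-controlled CHM segmentation.

    Each canopy CHM cell (height >= 1 m) is assigned to the nearest marker
    whose distance does not exceed ``max_radius_frac`` times that marker's
    height (a marker-height-proportional maximum crown radius); cells with no
    admissible marker stay unassigned.  Returns >= 1 m height inherit their
    cell's crown id; all other returns get id 0.
    """
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    if len(markers) == 0:
        raise ValueError("no markers")
    chm = _build_chm(cloud, chm_cell)
    mix, miy = chm.index_of(markers)
    marker_h = np.array(
        [
            chm.values[
                max(0, i - 1) : i + 2, max(0, j - 1) : j + 2
            ].max()
            for i, j in zip(mix, miy)
        ]
    )
    max_rad = max_radius_frac * marker_h

    nx, ny = chm.values.shape
    canopy = chm.values >= UNDERSTORY_CUTOFF
    cix, ciy = np.nonzero(canopy)
    cx = chm.x0 + (cix + 0.5) * chm.cell
    cy = chm.y0 + (ciy + 0.5) * chm.cell
    cell_label = np.zeros((nx, ny), dtype=int)

    tree = cKDTree(markers)
    k = min(len(markers), 6)
    dist, idx = tree.query(np.column_stack([cx, cy]), k=k)
    dist = np.atleast_2d(dist.T).T if dist.ndim == 1 else dist
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    assigned = np.zeros(len(cx), dtype=int)
    for col in range(dist.shape[1]):
        ok = (assigned == 0) & (dist[:, col] <= max_rad[idx[:, col]])
        assigned[ok] = idx[ok, col] + 1
    cell_label[cix, ciy] = assigned

    h = _heights(cloud)
    pix, piy = chm.index_of(cloud.xyz[:, :2])
    labels = cell_label[pix, piy]
    labels[~(cloud.clean & (h >= UNDERSTORY_CUTOFF))] = 0
    return CrownLabeling(labels, markers, marker_h)


def extract_crowns(
    cloud: PointCloud, labeling: CrownLabeling, epoch: str = "e1"
) -> list[TreeCrown]:
    """Materialize one :class:`TreeCrown` per non-empty crown id.

    Crown points carry height above ground as their z coordinate, which is
    the frame all downstream geometry works in.
    """
    h = _heights(cloud)
    crowns = []
    for cid in np.unique(labeling.itc_id):
        if cid == 0:
            continue
        m = labeling.itc_id == cid
        pts = np.column_stack([cloud.xyz[m, 0], cloud.xyz[m, 1], h[m]])
        crowns.append(TreeCrown(int(cid), pts, epoch=epoch))
    return crowns


def _greedy_match(
    a_xy: np.ndarray, b_xy: np.ndarray, max_dist: float
) -> list[tuple[int, int, float]]:
    """Greedy mutual matching in ascending distance order, no duplicates."""
    if len(a_xy) == 0 or len(b_xy) == 0:
        return []
    tree = cKDTree(b_xy)
    pairs = tree.query_ball_point(a_xy, max_dist)
    cand = [
        (float(np.hypot(*(a_xy[i] - b_xy[j]))), i, j)
        for i, nbrs in enumerate(pairs)
        for j in nbrs
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, d))
    return out


def pair_crowns(
    crowns_e1: list[TreeCrown],
    crowns_e2: list[TreeCrown],
    max_dist: float = 2.0,
) -> list[CrownPair]:
    """Pair crowns across epochs by closest centre, hard ``max_dist`` cut.

    Greedy in ascending distance, each crown used at most once; crowns whose
    nearest counterpart is farther than ``max_dist`` stay unpaired.  The pair
    set is symmetric in the order of the epochs.
    """
    if not crowns_e1 or not crowns_e2:
        raise ValueError("both epochs must contain crowns")
    a = np.array([c.crown_center_xy for c in crowns_e1])
    b = np.array([c.crown_center_xy for c in crowns_e2])
    return [
        CrownPair(crowns_e1[i].itc_id, crowns_e2[j].itc_id, d)
        for i, j, d in _greedy_match(a, b, max_dist)
    ]


def match_to_reference(
    pairs: list[CrownPair],
    crowns_e1: list[TreeCrown],
    crowns_e2: list[TreeCrown],
    reference_xy: np.ndarray,
    max_dist: float = 2.0,
) -> list[CrownPair]:
    """Link paired-crown centres to planted-stem reference coordinates.

    The pair centre is the mean of the two epochs' crown centres; matching is
    the same greedy closest-neighbour scheme.  Fills ``matched_ref_id`` and
    the (reference - pair centre) offset vector, useful for diagnosing a
    systematic positioning bias.
    """
    reference_xy = np.atleast_2d(np.asarray(reference_xy, dtype=float))
    by_id1 = {c.itc_id: c for c in crowns_e1}
    by_id2 = {c.itc_id: c for c in crowns_e2}
    centers = np.array(
        [
            (by_id1[p.itc_id_e1].crown_center_xy + by_id2[p.itc_id_e2].crown_center_xy)
            / 2.0
            for p in pairs
        ]
    )
    for p in pairs:
        p.matched_ref_id = None
        p.ref_offset = None
    for i, j, _d in _greedy_match(centers, reference_xy, max_dist):
        pairs[i].matched_ref_id = int(j)
        pairs[i].ref_offset = reference_xy[j] - centers[i]
    return pairs
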