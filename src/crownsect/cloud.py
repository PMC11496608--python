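"""Point-cloud container, noise filtering, ground classification, and height
normalization.

The container is a thin wrapper over numpy arrays: one ``(n, 3)`` coordinate
block plus boolean per-point flags.  Heights above ground are stored as a
separate optional column so the raw elevations are never destroyed.

Azimuth/height conventions used throughout the package:

* coordinates are metric (metres), x = easting, y = northing, z = elevation;
* azimuth 0 deg = geographic north (+y), increasing clockwise (east = 90 deg).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError, cKDTree


__all__ = [
    "PointCloud",
    "filter_isolated_noise",
    "classify_ground",
    "normalize_heights",
    "read_xyz",
    "write_xyz",
]


@dataclass
class PointCloud:
    """3D laser returns with per-point classification flags.

    Parameters
    ----------
    xyz : ndarray of shape (n, 3)
        Point coordinates in metres.
    is_ground, is_noise : bool ndarrays of shape (n,)
        Classification flags; a point is never both ground and noise.
    height : ndarray of shape (n,) or None
        Height above the interpolated ground surface, filled by
        :func:`normalize_heights`.
    """

    xyz: np.ndarray
    is_ground: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_noise: np.ndarray = field(default=None)  # type: ignore[assignment]
    height: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        n = len(self.xyz)
        if self.is_ground is None:
            self.is_ground = np.zeros(n, dtype=bool)
        else:
            self.is_ground = np.asarray(self.is_ground, dtype=bool).copy()
        if self.is_noise is None:
            self.is_noise = np.zeros(n, dtype=bool)
        else:
            self.is_noise = np.asarray(self.is_noise, dtype=bool).copy()
        if self.height is not None:
            self.height = np.asarray(self.height, dtype=float).copy()
        if np.any(self.is_ground & self.is_noise):
            raise ValueError("a point cannot be both ground and noise")

    def __len__(self) -> int:
        return len(self.xyz)

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.xyz.copy(),
            self.is_ground.copy(),
            self.is_noise.copy(),
            None if self.height is None else self.height.copy(),
        )

    @property
    def clean(self) -> np.ndarray:
        """Mask of points that are neither noise nor ground."""
        return ~(self.is_noise | self.is_ground)


def _require_nonempty(cloud: PointCloud) -> None:
    if len(cloud) == 0:
        raise ValueError("empty input")


def filter_isolated_noise(
    cloud: PointCloud, voxel_edge: float = 1.0, kernel: int = 3
) -> PointCloud:
    """Flag isolated returns as noise using a voxel-occupancy kernel.

    The cloud is binned into cubic voxels of side ``voxel_edge`` anchored at
    the cloud's minimum corner.  A point is noise when the total number of
    returns inside the ``kernel x kernel x kernel`` block of voxels centred
    on its own voxel is exactly 1 (i.e. only itself).  With the defaults this
    is the classic isolated-voxel filter: 1 m voxels, 3 x 3 x 3 m kernel.
    """
    _require_nonempty(cloud)
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 1")

    out = cloud.copy()
    idx = np.floor((cloud.xyz - cloud.xyz.min(axis=0)) / voxel_edge).astype(np.int64)
    # encode (ix, iy, iz) into a single int64 key for fast vectorized lookup
    span = idx.max(axis=0) + kernel + 1
    mult = np.array([span[1] * span[2], span[2], 1], dtype=np.int64)
    half = kernel // 2
    keys = (idx + half) @ mult  # shift so neighbor offsets stay non-negative
    uniq, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)

    neigh_total = np.zeros(len(uniq), dtype=np.int64)
    offsets = np.arange(-half, half + 1, dtype=np.int64)
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                probe = uniq + dx * mult[0] + dy * mult[1] + dz * mult[2]
                pos = np.searchsorted(uniq, probe)
                pos_clip = np.clip(pos, 0, len(uniq) - 1)
                hit = uniq[pos_clip] == probe
                neigh_total[hit] += counts[pos_clip[hit]]
    isolated = neigh_total[inverse] == 1
    out.is_noise = isolated
    out.is_ground = cloud.is_ground & ~isolated  # keep the flags disjoint
    return out


def _cell_minima(xyz: np.ndarray, usable: np.ndarray, cell: float) -> np.ndarray:
    """Indices of the lowest usable return in each horizontal grid cell."""
    cix = np.floor((xyz[:, 0] - xyz[:, 0].min()) / cell).astype(np.int64)
    ciy = np.floor((xyz[:, 1] - xyz[:, 1].min()) / cell).astype(np.int64)
    key = cix * (ciy.max() + 1) + ciy
    key[~usable] = -1
    order = np.lexsort((xyz[:, 2], key))
    ordered_key = key[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = ordered_key[1:] != ordered_key[:-1]
    seeds = order[first]
    return seeds[key[seeds] >= 0]


def classify_ground(
    cloud: PointCloud,
    cell: float = 1.0,
    seed_cell: float = 5.0,
    z_tol: float = 0.15,
    n_iter: int = 3,
) -> PointCloud:
    """Classify ground returns by coarse grid-minimum seeding plus TIN
    densification.

    The lowest non-noise return in each coarse ``seed_cell`` cell seeds the
    ground set — the coarse cell makes it very likely every seed cell holds a
    genuine terrain return even under dense crowns (a fine-cell minimum can
    be a crown-base return where the canopy blocks ground hits).  A
    triangulated surface is then fit through the current ground points and
    any point within ``z_tol`` metres of the interpolated surface is added;
    this is repeated ``n_iter`` times, which densifies the set down to the
    ``cell`` scale wherever ground returns exist.  Designed for stands with
    sparse understory where the lowest returns are reliably terrain.
    """
    _require_nonempty(cloud)
    del cell  # densification is point-wise; kept for interface stability
    out = cloud.copy()
    usable = ~out.is_noise
    xyz = out.xyz

    ground = np.zeros(len(xyz), dtype=bool)
    ground[_cell_minima(xyz, usable, seed_cell)] = True

    max_slope = 0.25  # m/m: admissible terrain gradient for hull extension
    for _ in range(n_iter):
        g_xyz = xyz[ground]
        if len(g_xyz) < 3 or _collinear(g_xyz[:, :2]):
            break
        try:
            interp = LinearNDInterpolator(g_xyz[:, :2], g_xyz[:, 2])
        except QhullError:
            break
        zg = interp(xyz[:, 0], xyz[:, 1])
        inhull = np.isfinite(zg)
        close = inhull & (np.abs(xyz[:, 2] - zg) <= z_tol)
        # outside the current hull: accept points consistent with the
        # nearest ground return under a bounded terrain slope
        outside = ~inhull & usable & ~ground
        if outside.any():
            tree = cKDTree(g_xyz[:, :2])
            d, j = tree.query(xyz[outside, :2])
            ok = np.abs(xyz[outside, 2] - g_xyz[j, 2]) <= z_tol + max_slope * d
            close[np.flatnonzero(outside)[ok]] = True
        close &= usable
        new = close & ~ground
        if not new.any():
            break
        ground |= new

    out.is_ground = ground
    out.is_noise &= ~ground
    return out


def _collinear(xy: np.ndarray, tol: float = 1e-9) -> bool:
    if len(xy) < 3:
        return True
    c = xy - xy.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def normalize_heights(cloud: PointCloud, clamp_negative: bool = True) -> PointCloud:
    """Compute height above ground via linear interpolation on the ground TIN.

    Ground points get height 0.  Non-ground points inside the convex hull of
    the ground set use barycentric interpolation on the Delaunay
    triangulation; points outside the hull fall back to the elevation of the
    nearest ground point.  Small negative heights (interpolation noise) are
    clamped to 0 by default.
    """
    _require_nonempty(cloud)
    g = cloud.is_ground & ~cloud.is_noise
    g_xyz = cloud.xyz[g]
    if len(g_xyz) < 3 or _collinear(g_xyz[:, :2]):
        raise ValueError("insufficient ground")
    out = cloud.copy()
    try:
        interp = LinearNDInterpolator(g_xyz[:, :2], g_xyz[:, 2])
    except QhullError as exc:  # pragma: no cover - guarded by _collinear
        raise ValueError("insufficient ground") from exc
    ze = interp(cloud.xyz[:, 0], cloud.xyz[:, 1])
    outside = ~np.isfinite(ze)
    if outside.any():
        tree = cKDTree(g_xyz[:, :2])
        _, nearest = tree.query(cloud.xyz[outside, :2])
        ze[outside] = g_xyz[nearest, 2]
    h = cloud.xyz[:, 2] - ze
    h[g] = 0.0
    if clamp_negative:
        h = np.maximum(h, 0.0)
    out.height = h
    return out


def read_xyz(path_or_buf: Union[str, Path, io.IOBase]) -> PointCloud:
    """Read a whitespace- or comma-delimited XYZ[H] text file.

    The first three columns are x, y, z in metres; an optional fourth column
    is interpreted as height above ground.
    """
    data = np.loadtxt(path_or_buf, delimiter=None, comments="#", ndmin=2)
    if data.size == 0:
        raise ValueError("empty input")
    if data.shape[1] < 3:
        # retry comma-delimited
        data = np.loadtxt(path_or_buf, delimiter=",", comments="#", ndmin=2)
    cloud = PointCloud(data[:, :3])
    if data.shape[1] >= 4:
        cloud.height = data[:, 3].astype(float)
    return cloud


def write_xyz(cloud: PointCloud, path: Union[str, Path]) -> None:
    """Write x y z [height] columns as plain text."""
    if cloud.height is not None:
        arr = np.column_stack([cloud.xyz, cloud.height])
    else:
        arr = cloud.xyz
    np.savetxt(path, arr, fmt="%.6f")
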