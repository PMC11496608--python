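"""3D crown geometry: alphashape meshes, cross-sections, azimuth profiles,
wedge volumes and OPCR surface complexity.

The alphashape is the boundary of the alpha complex: the crown's Delaunay
tetrahedralization keeps only tetrahedra whose circumsphere radius is at most
``alpha`` (1 m by default, matching the alphashape3d convention at alpha = 1),
and the faces that belong to exactly one kept tetrahedron form a closed
triangular surface.  All downstream quantities — volume, surface area,
horizontal cross-section polygons every 0.5 m, stem-to-edge distances every
10 deg of azimuth, 45-deg wedge volumes on a 0.1 x 0.1 x 0.5 m voxel grid,
and the orientation patch count rotated (OPCR) — are derived from this mesh.

Azimuths are compass bearings: 0 deg = north (+y), clockwise, east = 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import LineString, MultiLineString, Point, Polygon
from shapely.ops import polygonize, unary_union

__all__ = [
    "AlphaMesh",
    "CrossSection",
    "AzimuthProfile",
    "WedgeVolumes",
    "build_alphashape",
    "mesh_measures",
    "cross_section",
    "azimuth_distances",
    "azimuth_profile",
    "voxelize_and_wedge",
    "opcr",
    "azimuth_of",
]

AZIMUTH_STEP_DEG = 10.0
N_AZIMUTHS = 36
HEIGHT_STEP = 0.5
PROFILE_BASE_HEIGHT = 1.0


def azimuth_of(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Compass azimuth (degrees in [0, 360)) of the vector (dx, dy)."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


@dataclass
class AlphaMesh:
    """Closed triangular alphashape surface of one crown."""

    vertices: np.ndarray
    faces: np.ndarray
    alpha: float
    volume: float = field(init=False)
    surface_area: float = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.volume, self.surface_area = mesh_measures(self)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def export(self, path) -> None:
        """Write the mesh as OFF or PLY (format from the file extension)."""
        self.as_trimesh().export(str(path))

    @property
    def z_range(self) -> tuple[float, float]:
        z = self.vertices[self.faces.reshape(-1), 2]
        return float(z.min()), float(z.max())


@dataclass
class CrossSection:
    """Horizontal slice of a crown mesh at one height."""

    height: float
    polygons: list[Polygon]

    @property
    def is_empty(self) -> bool:
        return len(self.polygons) == 0

    def polygon_containing(self, xy) -> Polygon | None:
        p = Point(float(xy[0]), float(xy[1]))
        hits = [poly for poly in self.polygons if poly.covers(p)]
        if not hits:
            return None
        return max(hits, key=lambda g: g.area)


@dataclass
class AzimuthProfile:
    """Stem-to-crown-edge distances on a (height x 36 azimuth) grid.

    ``distances`` holds NaN where no stem-containing cross-section polygon
    exists at that height; ``cumulative`` sums over heights ignoring NaNs.
    """

    heights: np.ndarray
    distances: np.ndarray  # (n_heights, 36), NaN = missing

    @property
    def azimuths(self) -> np.ndarray:
        return np.arange(N_AZIMUTHS) * AZIMUTH_STEP_DEG

    @property
    def cumulative(self) -> np.ndarray:
        with np.errstate(all="ignore"):
            return np.nansum(self.distances, axis=0)

    @property
    def valid_heights(self) -> np.ndarray:
        return ~np.all(np.isnan(self.distances), axis=1)


@dataclass
class WedgeVolumes:
    """Crown volume split into eight 45-deg azimuth wedges around the stem."""

    volumes: np.ndarray  # (8,), wedge k spans [45k, 45k+45) degrees

    @property
    def total(self) -> float:
        return float(self.volumes.sum())

    @property
    def north(self) -> float:
        """Wedges (315-360) + (0-45)."""
        return float(self.volumes[7] + self.volumes[0])

    @property
    def south(self) -> float:
        """Wedges (135-180) + (180-225)."""
        return float(self.volumes[3] + self.volumes[4])


# ---------------------------------------------------------------------------
# alphashape construction
# ---------------------------------------------------------------------------

def _circumradii(p: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra ``p`` of shape (n, 4, 3)."""
    a, b, c, d = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    A = np.stack([b - a, c - a, d - a], axis=1) * 2.0
    rhs = np.stack(
        [
            (b * b).sum(1) - (a * a).sum(1),
            (c * c).sum(1) - (a * a).sum(1),
            (d * d).sum(1) - (a * a).sum(1),
        ],
        axis=1,
    )
    det = np.linalg.det(A)
    radii = np.full(len(p), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centre = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centre - a[ok], axis=1)
    return radii


_TET_FACES = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


def build_alphashape(points: np.ndarray, alpha: float = 1.0) -> AlphaMesh:
    """Alphashape boundary mesh of a point set.

    Keeps Delaunay tetrahedra with circumsphere radius <= ``alpha``; boundary
    faces (on exactly one kept tetrahedron) are oriented outward using the
    opposite vertex of their owning tetrahedron.  If the boundary splits into
    several connected components only the largest-volume one is kept.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("cannot tetrahedralize: fewer than 4 points")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError("cannot tetrahedralize: degenerate geometry") from exc
    tets = tri.simplices
    keep = tets[_circumradii(points[tets]) <= alpha]
    if len(keep) == 0:
        raise ValueError("alpha too small: no tetrahedra retained")

    # boundary faces: appear in exactly one kept tetrahedron
    faces = keep[:, _TET_FACES].reshape(-1, 3)          # (4n, 3), oriented per tet
    opposite = keep[:, [3, 2, 1, 0]].reshape(-1)        # vertex opposite each face
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    bf = faces[boundary]
    bopp = opposite[boundary]

    # orient each boundary face so its normal points away from the opposite vertex
    v0, v1, v2 = points[bf[:, 0]], points[bf[:, 1]], points[bf[:, 2]]
    normal = np.cross(v1 - v0, v2 - v0)
    inward = ((points[bopp] - v0) * normal).sum(1) > 0
    bf[inward] = bf[inward][:, [0, 2, 1]]

    bf = _largest_component(points, bf)
    return AlphaMesh(points, bf, alpha)


def _largest_component(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Keep the connected face component enclosing the largest volume."""
    if len(faces) == 0:
        return faces
    edges = np.sort(
        faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1
    )
    eid = np.unique(edges, axis=0, return_inverse=True)[1].reshape(-1, 3)
    fidx = np.repeat(np.arange(len(faces)), 3)
    # faces sharing an edge are connected
    order = np.argsort(eid.reshape(-1), kind="stable")
    se, sf = eid.reshape(-1)[order], fidx[order]
    starts = np.flatnonzero(np.r_[True, se[1:] != se[:-1]])
    rows, cols = [], []
    bounds = np.r_[starts, len(se)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        grp = sf[s:e]
        if len(grp) > 1:
            rows.append(np.repeat(grp[0], len(grp) - 1))
            cols.append(grp[1:])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        graph = coo_matrix(
            (np.ones(len(r)), (r, c)), shape=(len(faces), len(faces))
        )
        n_comp, labels = connected_components(graph, directed=False)
    else:
        n_comp, labels = len(faces), np.arange(len(faces))
    if n_comp == 1:
        return faces
    best, best_vol = 0, -1.0
    for comp in range(n_comp):
        sub = faces[labels == comp]
        vol = abs(_signed_volume(vertices, sub))
        if vol > best_vol:
            best, best_vol = comp, vol
    return faces[labels == best]


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def mesh_measures(mesh: AlphaMesh) -> tuple[float, float]:
    """(volume, surface area) by signed-tetrahedron and triangle-area sums."""
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    volume = abs(_signed_volume(mesh.vertices, mesh.faces))
    area = float(np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum() / 2.0)
    return volume, area


# ---------------------------------------------------------------------------
# cross-sections and azimuth distances
# ---------------------------------------------------------------------------

def _assemble_polygons(segments: np.ndarray) -> list[Polygon]:
    """Join plane-intersection segments into clean polygons (holes resolved)."""
    if len(segments) == 0:
        return []
    seg2d = np.round(segments[:, :, :2], 6)
    keep = np.linalg.norm(seg2d[:, 0] - seg2d[:, 1], axis=1) > 1e-9
    seg2d = seg2d[keep]
    if len(seg2d) == 0:
        return []
    lines = MultiLineString([LineString(s) for s in seg2d])
    rings = list(polygonize(unary_union(lines)))
    if not rings:
        return []
    # even-odd nesting: a ring inside an odd number of others is a hole
    rings.sort(key=lambda g: g.area, reverse=True)
    depth = []
    for i, g in enumerate(rings):
        pt = g.representative_point()
        depth.append(sum(1 for other in rings[:i] if other.contains(pt)))
    out = []
    for i, g in enumerate(rings):
        if depth[i] % 2 == 1:
            continue  # hole region
        holes = [
            list(rings[j].exterior.coords)
            for j in range(len(rings))
            if depth[j] == depth[i] + 1 and g.contains(rings[j].representative_point())
        ]
        poly = Polygon(g.exterior.coords, holes)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if not poly.is_empty:
            if poly.geom_type == "MultiPolygon":
                out.extend(list(poly.geoms))
            else:
                out.append(poly)
    return out


def cross_section(mesh: AlphaMesh, height: float) -> CrossSection:
    """Horizontal slice of the mesh at ``height`` (z = const plane)."""
    tm = mesh.as_trimesh()
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, float(height)]
    )
    return CrossSection(float(height), _assemble_polygons(np.asarray(segments)))


def azimuth_distances(
    section: CrossSection, stem_xy, mode: str = "farthest"
) -> np.ndarray:
    """Stem-to-crown-edge distance every 10 deg of azimuth.

    Uses the cross-section polygon containing the stem; for concave outlines
    the distance is to the farthest boundary crossing along the ray
    (drip-line semantics) or, with ``mode='nearest'``, the first exit.
    Returns 36 values, all NaN when no polygon contains the stem.
    """
    out = np.full(N_AZIMUTHS, np.nan)
    poly = None if section.is_empty else section.polygon_containing(stem_xy)
    if poly is None:
        return out
    sx, sy = float(stem_xy[0]), float(stem_xy[1])
    reach = 2.0 * poly.length + 1.0  # longer than any chord
    boundary = poly.boundary
    for k in range(N_AZIMUTHS):
        theta = np.radians(k * AZIMUTH_STEP_DEG)
        ray = LineString(
            [(sx, sy), (sx + reach * np.sin(theta), sy + reach * np.cos(theta))]
        )
        inter = boundary.intersection(ray)
        if inter.is_empty:
            out[k] = 0.0
            continue
        coords = _collect_coords(inter)
        d = np.hypot(coords[:, 0] - sx, coords[:, 1] - sy)
        out[k] = d.max() if mode == "farthest" else d[d > 1e-12].min(initial=0.0)
    return out


def _collect_coords(geom) -> np.ndarray:
    if geom.geom_type == "Point":
        return np.array([[geom.x, geom.y]])
    if geom.geom_type in ("MultiPoint", "GeometryCollection", "MultiLineString"):
        return np.vstack([_collect_coords(g) for g in geom.geoms])
    return np.asarray(geom.coords, dtype=float)


def azimuth_profile(
    mesh: AlphaMesh,
    stem_xy,
    top_height: float | None = None,
    mode: str = "farthest",
) -> AzimuthProfile:
    """Azimuth distances at every 0.5 m from 1 m up to the crown top."""
    if top_height is None:
        top_height = mesh.z_range[1]
    heights = np.arange(
        PROFILE_BASE_HEIGHT, top_height + 1e-9, HEIGHT_STEP
    )
    dist = np.full((len(heights), N_AZIMUTHS), np.nan)
    for i, h in enumerate(heights):
        section = cross_section(mesh, float(h))
        dist[i] = azimuth_distances(section, stem_xy, mode=mode)
    return AzimuthProfile(heights, dist)


# ---------------------------------------------------------------------------
# wedge volumes
# ---------------------------------------------------------------------------

def voxelize_and_wedge(
    mesh: AlphaMesh,
    stem_xy,
    cell: tuple[float, float, float] = (0.1, 0.1, 0.5),
) -> WedgeVolumes:
    """Crown volume per 45-deg azimuth wedge on a voxel grid.

    The grid spans the mesh bounding box (0.1 x 0.1 x 0.5 m cells by
    default); voxels whose centroid lies inside the mesh are assigned to the
    wedge containing the azimuth from the stem to the centroid, and each
    contributes its cell volume.  Centroid-in-mesh testing slices the mesh at
    every voxel mid-height and applies a vectorized point-in-polygon test.
    """
    dx, dy, dz = cell
    sx, sy = float(stem_xy[0]), float(stem_xy[1])
    tm = mesh.as_trimesh()
    (x0, y0, z0), (x1, y1, z1) = tm.bounds
    # anchor the horizontal grid on the stem (stem at a voxel corner) so the
    # cardinal wedge boundaries coincide with cell edges instead of slicing
    # through voxel columns
    xs = sx + (np.arange(np.floor((x0 - sx) / dx), np.ceil((x1 - sx) / dx)) + 0.5) * dx
    ys = sy + (np.arange(np.floor((y0 - sy) / dy), np.ceil((y1 - sy) / dy)) + 0.5) * dy
    zs = np.arange(z0 + dz / 2, z1, dz)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx = gx.ravel()
    gy = gy.ravel()
    az = azimuth_of(gx - sx, gy - sy)
    wedge_idx = (az // 45.0).astype(int) % 8
    # a centroid exactly on a wedge boundary is geometrically split between
    # the two wedges: count half a voxel to each
    on_boundary = np.isclose(az % 45.0, 0.0, atol=1e-9) | np.isclose(
        az % 45.0, 45.0, atol=1e-9
    )
    share = np.where(on_boundary, 0.5, 1.0)
    prev_idx = (wedge_idx - 1) % 8
    cell_vol = dx * dy * dz
    volumes = np.zeros(8)
    for z in zs:
        section = cross_section(mesh, float(z))
        if section.is_empty:
            continue
        geom = unary_union(section.polygons)
        inside = shapely.contains_xy(geom, gx, gy)
        if inside.any():
            np.add.at(volumes, wedge_idx[inside], cell_vol * share[inside])
            b = inside & on_boundary
            if b.any():
                np.add.at(volumes, prev_idx[b], cell_vol * 0.5)
    return WedgeVolumes(volumes)


# ---------------------------------------------------------------------------
# OPCR
# ---------------------------------------------------------------------------

def opcr(
    mesh: AlphaMesh,
    n_bins: int = 8,
    n_rotations: int = 8,
    min_patch_faces: int = 3,
    eps_horizontal: float = 1e-8,
) -> float:
    """Orientation patch count rotated: a surface-complexity index.

    Each face is binned by the compass azimuth of its outward normal's
    horizontal projection into ``n_bins`` sectors; patches are connected
    components (edge adjacency) of same-bin faces with at least
    ``min_patch_faces`` faces, and the patch count is averaged over
    ``n_rotations`` rotations of the bin boundaries (offset
    360/(n_bins*n_rotations) deg apart).  Faces with a near-vertical-axis
    normal (no horizontal direction) are left unbinned.
    """
    tm = mesh.as_trimesh()
    normals = tm.face_normals
    horiz = np.linalg.norm(normals[:, :2], axis=1)
    az = azimuth_of(normals[:, 0], normals[:, 1])
    assignable = horiz > eps_horizontal
    adjacency = tm.face_adjacency  # pairs of faces sharing an edge

    bin_width = 360.0 / n_bins
    step = bin_width / n_rotations
    counts = []
    for r in range(n_rotations):
        offset = r * step
        bins = np.full(len(normals), -1)
        bins[assignable] = (
            ((az[assignable] - offset) % 360.0) // bin_width
        ).astype(int)
        same = (
            (bins[adjacency[:, 0]] == bins[adjacency[:, 1]])
            & (bins[adjacency[:, 0]] >= 0)
        )
        pairs = adjacency[same]
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(len(normals), len(normals)),
        )
        n_comp, labels = connected_components(graph, directed=False)
        labels = labels.copy()
        labels[bins < 0] = -1
        valid = labels >= 0
        if not valid.any():
            counts.append(0)
            continue
        _, sizes = np.unique(labels[valid], return_counts=True)
        counts.append(int((sizes >= min_patch_faces).sum()))
    return float(np.mean(counts))
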