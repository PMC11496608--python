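"""Synthetic plantation point clouds with analytic ground truth.

Emulates a gridded conifer plantation as scanned by a drone LiDAR: crowns are
sampled from a parametric solid (a half-ellipsoid cap over a cone frustum)
whose horizontal radius can be inflated toward a chosen azimuth to mimic
asymmetric growth, plus stem returns, ground returns on a sloped plane and
isolated noise points.  Because the generating solid is analytic, total and
per-wedge crown volumes and the direction of largest radius are known exactly
(by numerical integration of the solid), giving every pipeline stage a ground
truth to be scored against.

Default layout follows an operational loblolly-pine trial: 4.42 m spacing
within rows, 3.66 m between rows (618 stems/ha), row azimuth 135 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cloud import PointCloud

__all__ = [
    "CrownParams",
    "PlotConfig",
    "generate_crown",
    "generate_plot",
    "generate_two_epoch_plot",
    "crown_truth_volumes",
]

_WEDGE_EDGES = np.arange(0.0, 361.0, 45.0)


@dataclass(frozen=True)
class CrownParams:
    """Parametric description of one tree's generating solid.

    The solid is a cone frustum from ``crown_base_height`` up to the height
    of maximum radius, capped by a half ellipsoid reaching ``total_height``.
    ``asymmetry_ratio`` >= 1 inflates the radius smoothly toward
    ``asymmetry_azimuth_deg`` (ratio 1 = radially symmetric crown).
    """

    total_height: float = 10.0          # m
    crown_base_height: float = 4.8      # m, live-crown base (~48% of height)
    max_radius: float = 1.5             # m; pre-canopy-closure crown on the default grid
    frustum_fraction: float = 0.35      # fraction of crown depth below max radius
    base_radius_fraction: float = 0.6   # radius at crown base / max_radius
    asymmetry_azimuth_deg: float = 180.0
    asymmetry_ratio: float = 1.0
    asymmetry_sharpness: float = 3.0    # lobe exponent; higher = narrower lobe
    stem_point_rate: float = 80.0       # returns per metre of stem
    foliage_density: float = 120.0      # returns per m^3 of crown volume
    surface_fraction: float = 0.35      # share of returns biased to the surface
    n_branch_clusters: int = 2          # dead-branch tufts below the live crown
    branch_cluster_points: int = 40
    branch_radius: float = 0.7          # m, horizontal extent of a tuft

    def __post_init__(self) -> None:
        if self.crown_base_height >= self.total_height:
            raise ValueError("crown_base_height must be below total_height")
        if self.asymmetry_ratio < 1:
            raise ValueError("asymmetry_ratio must be >= 1")

    # -- analytic radius field -------------------------------------------
    def radius_profile(self, h: np.ndarray) -> np.ndarray:
        """Base (symmetric) crown radius at height ``h`` above ground."""
        h = np.asarray(h, dtype=float)
        cb, top, rmax = self.crown_base_height, self.total_height, self.max_radius
        hm = cb + self.frustum_fraction * (top - cb)
        r = np.zeros_like(h)
        lower = (h >= cb) & (h <= hm)
        if hm > cb:
            r0 = self.base_radius_fraction * rmax
            r[lower] = r0 + (rmax - r0) * (h[lower] - cb) / (hm - cb)
        else:
            r[lower] = rmax
        upper = (h > hm) & (h <= top)
        with np.errstate(invalid="ignore"):
            r[upper] = rmax * np.sqrt(
                np.clip(1.0 - ((h[upper] - hm) / (top - hm)) ** 2, 0.0, 1.0)
            )
        return r

    def azimuth_factor(self, azimuth_deg: np.ndarray) -> np.ndarray:
        """Radial inflation factor: 1 opposite, ``asymmetry_ratio`` toward
        ``asymmetry_azimuth_deg``.

        The lobe is a raised cosine taken to ``asymmetry_sharpness``; the
        exponent keeps the lobe directionally concentrated so the generating
        azimuth is identifiable from sampled crowns, while the factor still
        interpolates smoothly from 1 (opposite side) to the full ratio."""
        a = np.radians(np.asarray(azimuth_deg, dtype=float) - self.asymmetry_azimuth_deg)
        lobe = ((1.0 + np.cos(a)) / 2.0) ** self.asymmetry_sharpness
        return 1.0 + (self.asymmetry_ratio - 1.0) * lobe


@dataclass(frozen=True)
class PlotConfig:
    """Layout and content of a synthetic plantation plot."""

    n_rows: int = 9
    n_cols: int = 9
    within_row_spacing: float = 4.42    # m, along a row
    between_row_spacing: float = 3.66   # m, row to row
    row_azimuth_deg: float = 135.0      # 45 or 135 in the emulated trial
    crown: CrownParams = field(default_factory=CrownParams)
    height_jitter: float = 0.05         # relative sd of per-tree total height
    ground_slope: tuple[float, float] = (0.02, 0.0)   # dz/dx, dz/dy
    ground_point_density: float = 1.5   # returns per m^2
    noise_count: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_row_spacing <= 0 or self.between_row_spacing <= 0:
            raise ValueError("spacings must be positive")

    def stem_positions(self) -> np.ndarray:
        """Stem (x, y) on the rotated grid; rows run along ``row_azimuth_deg``."""
        az = np.radians(self.row_azimuth_deg)
        u = np.array([np.sin(az), np.cos(az)])      # along-row unit vector
        v = np.array([np.cos(az), -np.sin(az)])     # across rows
        pos = []
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                pos.append(j * self.within_row_spacing * u + i * self.between_row_spacing * v)
        return np.asarray(pos)


def _tree_rng(seed: int, tree_id: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tree_id), int(salt)])


def generate_crown(
    params: CrownParams,
    stem_xy: Sequence[float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
) -> PointCloud:
    """Sample one tree's returns: crown surface + interior, plus stem returns.

    Heights are emitted directly as z (flat ground at 0); the plot generator
    adds terrain elevation afterwards.  Identical seed and parameters give a
    bit-identical cloud.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sx, sy = float(stem_xy[0]), float(stem_xy[1])

    volume = crown_truth_volumes(params)["volume"]
    n_crown = max(30, int(round(params.foliage_density * volume)))

    # height density proportional to mean squared radius -> ~uniform in volume
    hs = np.linspace(params.crown_base_height, params.total_height, 512)
    w = params.radius_profile(hs) ** 2 + 1e-9
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    h = np.interp(rng.random(n_crown), cdf, hs)
    az = rng.uniform(0.0, 360.0, n_crown)
    r_edge = params.radius_profile(h) * params.azimuth_factor(az)
    n_surf = int(round(params.surface_fraction * n_crown))
    u = np.empty(n_crown)
    u[:n_surf] = rng.random(n_surf) ** 0.25              # biased toward the surface
    u[n_surf:] = np.sqrt(rng.random(n_crown - n_surf))   # uniform over the disc
    rad = r_edge * u
    theta = np.radians(az)
    x = sx + rad * np.sin(theta)
    y = sy + rad * np.cos(theta)
    crown_pts = np.column_stack([x, y, h])

    parts = [crown_pts]
    n_stem = int(round(params.stem_point_rate * params.crown_base_height))
    if n_stem > 0:
        zs = rng.uniform(0.0, params.crown_base_height, n_stem)
        jitter = rng.normal(0.0, 0.02, (n_stem, 2))
        parts.append(np.column_stack([sx + jitter[:, 0], sy + jitter[:, 1], zs]))

    # thin dead-branch tufts below the live crown: horizontally spread,
    # vertically flat, offset from the stem (what a stem locator must reject)
    for _ in range(params.n_branch_clusters):
        if params.branch_cluster_points <= 0 or params.crown_base_height <= 1.5:
            break
        bz = rng.uniform(1.2, params.crown_base_height - 0.2)
        baz = rng.uniform(0.0, 2 * np.pi)
        boff = rng.uniform(0.3, 0.9)
        bc = np.array([sx + boff * np.sin(baz), sy + boff * np.cos(baz)])
        n_b = params.branch_cluster_points
        br = params.branch_radius * np.sqrt(rng.random(n_b))
        bth = rng.uniform(0.0, 2 * np.pi, n_b)
        bzs = bz + rng.normal(0.0, 0.05, n_b)
        parts.append(
            np.column_stack(
                [bc[0] + br * np.sin(bth), bc[1] + br * np.cos(bth), bzs]
            )
        )
    return PointCloud(np.vstack(parts))


def crown_truth_volumes(params: CrownParams, n_az: int = 1440, n_h: int = 2000) -> dict:
    """Analytic (numerically integrated) volumes of the generating solid.

    The solid is described in polar form around the stem, so its volume
    separates: V = (integral of r(h)^2 dh) * (1/2 integral of f(az)^2 daz).
    Returns the total volume, the eight 45-deg wedge volumes (azimuth
    measured from the stem, clockwise from north) and the azimuth of largest
    radius.
    """
    hs = np.linspace(params.crown_base_height, params.total_height, n_h)
    radial = np.trapezoid(params.radius_profile(hs) ** 2, hs)
    az = np.linspace(0.0, 360.0, n_az + 1)
    f2 = params.azimuth_factor(az) ** 2
    az_rad = np.radians(az)
    wedges = np.empty(8)
    for k in range(8):
        m = (az >= _WEDGE_EDGES[k]) & (az <= _WEDGE_EDGES[k + 1])
        wedges[k] = 0.5 * np.trapezoid(f2[m], az_rad[m]) * radial
    total = 0.5 * np.trapezoid(f2, az_rad) * radial
    return {
        "volume": float(total),
        "wedges": wedges,
        "largest_radius_azimuth": params.asymmetry_azimuth_deg % 360.0,
    }


def _ground_elevation(xy: np.ndarray, slope: tuple[float, float]) -> np.ndarray:
    return slope[0] * xy[..., 0] + slope[1] * xy[..., 1]


def generate_plot(config: PlotConfig) -> tuple[PointCloud, pd.DataFrame]:
    """Generate a full plot: crowns on the grid, ground returns, noise.

    Returns the merged cloud (raw elevations, unclassified) and a truth table
    with one row per tree: stem coordinates, generating parameters, analytic
    total and per-wedge crown volumes, and the largest-radius azimuth.
    """
    stems = config.stem_positions()
    clouds: list[np.ndarray] = []
    rows = []
    for tid, (sx, sy) in enumerate(stems):
        rng = _tree_rng(config.seed, tid)
        jit = 1.0 + config.height_jitter * rng.standard_normal()
        jit = float(np.clip(jit, 0.8, 1.2))
        p = replace(
            config.crown,
            total_height=config.crown.total_height * jit,
            crown_base_height=config.crown.crown_base_height * jit,
        )
        tree = generate_crown(p, (sx, sy), rng)
        elev = float(_ground_elevation(np.array([sx, sy]), config.ground_slope))
        pts = tree.xyz.copy()
        pts[:, 2] += elev
        clouds.append(pts)
        truth = crown_truth_volumes(p)
        rows.append(
            {
                "tree_id": tid,
                "stem_x": sx,
                "stem_y": sy,
                "total_height": p.total_height,
                "crown_base_height": p.crown_base_height,
                "max_radius": p.max_radius,
                "asymmetry_ratio": p.asymmetry_ratio,
                "largest_radius_azimuth": truth["largest_radius_azimuth"],
                "volume": truth["volume"],
                **{f"wedge_{k}": truth["wedges"][k] for k in range(8)},
            }
        )

    rng = np.random.default_rng([config.seed, 982_451_653])
    lo = stems.min(axis=0) - 3.0
    hi = stems.max(axis=0) + 3.0
    area = (hi[0] - lo[0]) * (hi[1] - lo[1])
    n_ground = max(16, int(round(config.ground_point_density * area)))
    gxy = rng.uniform(lo, hi, (n_ground, 2))
    gz = _ground_elevation(gxy, config.ground_slope) + rng.normal(0.0, 0.01, n_ground)
    clouds.append(np.column_stack([gxy, gz]))

    # isolated noise in a ring well clear of every crown (>= 5 m exclusion)
    if config.noise_count > 0:
        margin = 5.0 + config.crown.max_radius * config.crown.asymmetry_ratio
        ang = rng.uniform(0.0, 2 * np.pi, config.noise_count)
        ext = rng.uniform(margin, margin + 10.0, config.noise_count)
        centre = stems.mean(axis=0)
        half = (hi - lo) / 2.0
        nx = centre[0] + np.sign(np.cos(ang)) * half[0] + ext * np.cos(ang)
        ny = centre[1] + np.sign(np.sin(ang)) * half[1] + ext * np.sin(ang)
        nz = rng.uniform(config.crown.total_height + 5.0, config.crown.total_height + 30.0, config.noise_count)
        clouds.append(np.column_stack([nx, ny, nz]))

    cloud = PointCloud(np.vstack(clouds))
    return cloud, pd.DataFrame(rows)


def generate_two_epoch_plot(
    config: PlotConfig,
    height_growth: float = 0.15,
    radius_growth: float = 0.20,
    epoch2_asymmetry_ratio: float | None = 1.3,
    epoch2_asymmetry_azimuth: float | None = 180.0,
) -> tuple[PointCloud, PointCloud, pd.DataFrame, pd.DataFrame]:
    """Same plot scanned twice: epoch 2 crowns are taller, 20% wider, and
    elongated toward a preferred azimuth (south by default).

    Stems do not move between epochs; epoch-2 point sampling uses independent
    random substreams so the two scans are not point-matched.  The default
    asymmetry ratio (1.3) keeps the southern lobe inside the free southern
    growing space of the default grid, as in an interlocking but not yet
    closed canopy; pass ``None`` to inherit the epoch-1 asymmetry.
    """
    cloud1, truth1 = generate_plot(config)
    # crown base rises with height growth: self-pruning in an unthinned,
    # closing stand keeps the live-crown ratio roughly constant
    c2 = replace(
        config.crown,
        total_height=config.crown.total_height * (1 + height_growth),
        crown_base_height=config.crown.crown_base_height * (1 + height_growth),
        max_radius=config.crown.max_radius * (1 + radius_growth),
        asymmetry_ratio=(
            config.crown.asymmetry_ratio
            if epoch2_asymmetry_ratio is None
            else epoch2_asymmetry_ratio
        ),
        asymmetry_azimuth_deg=(
            config.crown.asymmetry_azimuth_deg
            if epoch2_asymmetry_azimuth is None
            else epoch2_asymmetry_azimuth
        ),
    )
    config2 = replace(config, crown=c2, seed=config.seed + 1_000_003)
    cloud2, truth2 = generate_plot(config2)
    return cloud1, cloud2, truth1, truth2
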