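"""Two-epoch pipeline orchestration.

Runs ingest -> segmentation -> pairing -> stem location -> crown geometry ->
change metrics -> circular statistics for two acquisitions of the same plot,
and writes the tabular outputs (per-tree metrics, wedge long table,
directionality table, stratified circular report) plus a run manifest.  Every
stage parameter is surfaced on :class:`PipelineConfig`; the defaults are the
operational values used throughout the package (1 m noise voxel, 0.2 m
occupancy voxels, 0.1 m CHM, alpha = 1 m, 10-deg azimuth step, 0.5 m height
step, 0.1 x 0.1 x 0.5 m wedge voxels, 2 m pairing distance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .change import (
    emulated_row_diameters,
    largest_projection_azimuth,
    overlap_change_metrics,
    wedge_percent_change,
)
from .circstats import stratified_circular_report, watson_two_sample
from .cloud import PointCloud, classify_ground, filter_isolated_noise, normalize_heights
from .geometry import azimuth_profile, build_alphashape, opcr, voxelize_and_wedge
from .segment import (
    TreeCrown,
    detect_markers,
    extract_crowns,
    pair_crowns,
    segment_crowns,
    vertical_occupancy_raster,
)
from .stems import locate_stem, merge_stem_locations

log = logging.getLogger("crownsect")

__all__ = ["PipelineConfig", "run_pipeline", "process_epoch"]


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place."""

    noise_voxel: float = 1.0
    noise_kernel: int = 3
    ground_cell: float = 1.0
    occupancy_voxel: float = 0.2
    marker_min_distance: float = 1.5
    marker_min_value: float = 3.0
    chm_cell: float = 0.1
    max_radius_frac: float = 0.6
    pairing_max_dist: float = 2.0
    alpha: float = 1.0
    azimuth_step_deg: float = 10.0
    height_step: float = 0.5
    wedge_cell: tuple[float, float, float] = (0.1, 0.1, 0.5)
    opcr_bins: int = 8
    opcr_rotations: int = 8
    opcr_min_patch_faces: int = 3
    row_azimuth_deg: float = 135.0
    seed: int = 0


def _write_footprints(path: Path, crowns: list[TreeCrown]) -> None:
    """Crown footprints (2D convex hulls of ITC returns) as GeoJSON."""
    from scipy.spatial import ConvexHull, QhullError

    features = []
    for c in crowns:
        xy = c.points[:, :2]
        try:
            hull = ConvexHull(xy)
        except QhullError:
            continue
        ring = xy[hull.vertices].tolist()
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"itc_id": int(c.itc_id), "epoch": c.epoch},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


@dataclass
class EpochResult:
    crowns: list[TreeCrown]
    cloud: PointCloud
    counts: dict = field(default_factory=dict)


def process_epoch(cloud: PointCloud, cfg: PipelineConfig, epoch: str) -> EpochResult:
    """Ingest and segment one acquisition into crowns."""
    cloud = filter_isolated_noise(cloud, cfg.noise_voxel, cfg.noise_kernel)
    n_noise = int(cloud.is_noise.sum())
    cloud = classify_ground(cloud, cfg.ground_cell)
    cloud = normalize_heights(cloud)
    raster = vertical_occupancy_raster(cloud, cfg.occupancy_voxel)
    markers = detect_markers(raster, cfg.marker_min_distance, cfg.marker_min_value)
    labeling = segment_crowns(cloud, markers, cfg.chm_cell, cfg.max_radius_frac)
    crowns = extract_crowns(cloud, labeling, epoch=epoch)
    counts = {
        "points": len(cloud),
        "noise": n_noise,
        "ground": int(cloud.is_ground.sum()),
        "markers": len(markers),
        "crowns": len(crowns),
    }
    log.info("epoch %s: %s", epoch, counts)
    return EpochResult(crowns, cloud, counts)


def run_pipeline(
    cloud_e1: PointCloud,
    cloud_e2: PointCloud,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    reference_xy: np.ndarray | None = None,
) -> dict:
    """Full two-epoch crown-morphometrics workflow.

    Returns a dict of DataFrames (``trees``, ``wedges``, ``directionality``,
    ``circular``) and summary info; when ``out_dir`` is given the tables and
    a JSON run manifest are also written there.  Per-tree geometry failures
    are logged and skipped, never fatal.
    """
    cfg = cfg or PipelineConfig()
    e1 = process_epoch(cloud_e1, cfg, "e1")
    e2 = process_epoch(cloud_e2, cfg, "e2")
    pairs = pair_crowns(e1.crowns, e2.crowns, cfg.pairing_max_dist)
    by1 = {c.itc_id: c for c in e1.crowns}
    by2 = {c.itc_id: c for c in e2.crowns}

    # stem locations per pair from the first-pass crowns
    stems, est_pairs = [], []
    n_fallback = 0
    for pair in pairs:
        est1 = locate_stem(by1[pair.itc_id_e1], seed=cfg.seed)
        est2 = locate_stem(by2[pair.itc_id_e2], seed=cfg.seed)
        n_fallback += (est1.method == "fallback") + (est2.method == "fallback")
        stems.append(merge_stem_locations(est1, est2))
        est_pairs.append((est1, est2))
    stems_arr = np.asarray(stems)

    # second segmentation pass: the located stems are far more accurate
    # markers than the occupancy-raster maxima, so crown boundaries between
    # interlocking neighbours land on the true midlines
    by1b = by2b = {}
    if len(stems_arr):
        lab1 = segment_crowns(e1.cloud, stems_arr, cfg.chm_cell, cfg.max_radius_frac)
        lab2 = segment_crowns(e2.cloud, stems_arr, cfg.chm_cell, cfg.max_radius_frac)
        by1b = {c.itc_id: c for c in extract_crowns(e1.cloud, lab1, epoch="e1")}
        by2b = {c.itc_id: c for c in extract_crowns(e2.cloud, lab2, epoch="e2")}

    tree_rows, wedge_rows, dir_rows = [], [], []
    for k, pair in enumerate(pairs):
        c1 = by1b.get(k + 1, by1[pair.itc_id_e1])
        c2 = by2b.get(k + 1, by2[pair.itc_id_e2])
        est1, est2 = est_pairs[k]
        stem = stems_arr[k]
        c1.stem_xy = c2.stem_xy = stem
        try:
            mesh1 = build_alphashape(c1.points, cfg.alpha)
            mesh2 = build_alphashape(c2.points, cfg.alpha)
        except ValueError as exc:
            log.warning("pair %d: geometry failed (%s); skipped", k, exc)
            continue
        prof1 = azimuth_profile(mesh1, stem, c1.top_height)
        prof2 = azimuth_profile(mesh2, stem, c2.top_height)
        w1 = voxelize_and_wedge(mesh1, stem, cfg.wedge_cell)
        w2 = voxelize_and_wedge(mesh2, stem, cfg.wedge_cell)
        o1 = opcr(mesh1, cfg.opcr_bins, cfg.opcr_rotations, cfg.opcr_min_patch_faces)
        o2 = opcr(mesh2, cfg.opcr_bins, cfg.opcr_rotations, cfg.opcr_min_patch_faces)
        dirm = overlap_change_metrics(prof1, prof2)
        within1, between1 = emulated_row_diameters(prof1, cfg.row_azimuth_deg)
        within2, between2 = emulated_row_diameters(prof2, cfg.row_azimuth_deg)

        tree_rows.append(
            {
                "pair_id": k,
                "itc_id_e1": pair.itc_id_e1,
                "itc_id_e2": pair.itc_id_e2,
                "stem_x": stem[0],
                "stem_y": stem[1],
                "stem_method_e1": est1.method,
                "stem_method_e2": est2.method,
                "top_height_e1": c1.top_height,
                "top_height_e2": c2.top_height,
                "volume_e1": mesh1.volume,
                "volume_e2": mesh2.volume,
                "surface_area_e1": mesh1.surface_area,
                "surface_area_e2": mesh2.surface_area,
                "opcr_e1": o1,
                "opcr_e2": o2,
                "vi_e1": mesh1.volume / o1 if o1 > 0 else np.nan,
                "vi_e2": mesh2.volume / o2 if o2 > 0 else np.nan,
                "cvol_change": mesh2.volume - mesh1.volume,
                "north_e1": w1.north,
                "south_e1": w1.south,
                "north_e2": w2.north,
                "south_e2": w2.south,
                "within_row_diam_e1": within1,
                "between_row_diam_e1": between1,
                "within_row_diam_e2": within2,
                "between_row_diam_e2": between2,
            }
        )
        for wk in range(8):
            v1, v2 = w1.volumes[wk], w2.volumes[wk]
            wedge_rows.append(
                {
                    "pair_id": k,
                    "wedge": wk,
                    "azimuth_span": f"{45*wk}-{45*wk+45}",
                    "volume_e1": v1,
                    "volume_e2": v2,
                    "cv_wedge_pct": (
                        wedge_percent_change(v1, v2) if v1 > 0 else np.nan
                    ),
                }
            )
        dir_rows.append(
            {
                "pair_id": k,
                "largest_azimuth_e1": dirm.largest_azimuth_e1,
                "largest_azimuth_e2": dirm.largest_azimuth_e2,
                "lg_azimuth": dirm.lg_azimuth,
                "ll_azimuth": dirm.ll_azimuth,
                "ac_azimuth": dirm.ac_azimuth,
            }
        )

    trees = pd.DataFrame(tree_rows)
    wedges = pd.DataFrame(wedge_rows)
    directionality = pd.DataFrame(dir_rows)

    circ = pd.DataFrame()
    watson = None
    if len(directionality):
        melted = directionality.melt(
            id_vars="pair_id",
            value_vars=[
                "largest_azimuth_e1",
                "largest_azimuth_e2",
                "lg_azimuth",
                "ll_azimuth",
                "ac_azimuth",
            ],
            var_name="metric",
            value_name="azimuth",
        ).dropna(subset=["azimuth"])
        if len(melted):
            circ = stratified_circular_report(melted, "azimuth", ["metric"])
        a = directionality["largest_azimuth_e1"].dropna().to_numpy()
        b = directionality["largest_azimuth_e2"].dropna().to_numpy()
        if len(a) >= 8 and len(b) >= 8:
            w = watson_two_sample(a, b)
            watson = {"u2": w.u2, "p_range": w.p_range}

    result = {
        "trees": trees,
        "wedges": wedges,
        "directionality": directionality,
        "circular": circ,
        "watson": watson,
        "counts": {
            "e1": e1.counts,
            "e2": e2.counts,
            "pairs": len(pairs),
            "stem_fallbacks": n_fallback,
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_footprints(out / "footprints.geojson", e1.crowns + e2.crowns)
        trees.to_csv(out / "trees.csv", index=False)
        wedges.to_csv(out / "wedges.csv", index=False)
        directionality.to_csv(out / "directionality.csv", index=False)
        circ.to_csv(out / "circular.csv", index=False)
        manifest = {
            "version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()
            },
            "counts": result["counts"],
            "watson": watson,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
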