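"""Shared fixtures: synthetic scenes are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from crownsect.cloud import classify_ground, filter_isolated_noise, normalize_heights
from crownsect.geometry import build_alphashape
from crownsect.segment import (
    detect_markers,
    extract_crowns,
    segment_crowns,
    vertical_occupancy_raster,
)
from crownsect.synthetic import PlotConfig, generate_plot


@pytest.fixture(scope="session")
def plot9():
    """Default 9 x 9 synthetic plantation with truth table."""
    return generate_plot(PlotConfig(seed=7))


@pytest.fixture(scope="session")
def processed_plot9(plot9):
    """The 9 x 9 plot taken through ingest and segmentation."""
    cloud, truth = plot9
    c = filter_isolated_noise(cloud)
    c = classify_ground(c)
    c = normalize_heights(c)
    raster = vertical_occupancy_raster(c)
    markers = detect_markers(raster)
    labeling = segment_crowns(c, markers)
    crowns = extract_crowns(c, labeling)
    return {
        "cloud": c,
        "truth": truth,
        "raster": raster,
        "markers": markers,
        "labeling": labeling,
        "crowns": crowns,
    }


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Alphashape of a dense unit-radius cylinder spanning heights 0.8-11.2 m."""
    rng = np.random.default_rng(42)
    n = 30000
    theta = rng.uniform(0, 2 * np.pi, n)
    r = np.sqrt(rng.random(n))
    z = rng.uniform(0.8, 11.2, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return build_alphashape(pts, 1.0)


@pytest.fixture(scope="session")
def sphere_points():
    """50k points filling a radius-2 sphere."""
    rng = np.random.default_rng(1)
    n = 50000
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return v * (2.0 * rng.random(n) ** (1 / 3))[:, None]
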