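"""Alphashape meshes, cross-sections, azimuth distances, wedges, OPCR."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from crownsect.geometry import (
    AlphaMesh,
    CrossSection,
    azimuth_distances,
    azimuth_profile,
    build_alphashape,
    cross_section,
    mesh_measures,
    opcr,
    voxelize_and_wedge,
)


def _unit_cube_mesh():
    corners = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    return build_alphashape(corners, alpha=2.0)


def _square_pyramid_mesh():
    verts = np.array(
        [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0, 0, 1], [0, 0, 0]],
        dtype=float,
    )
    faces = np.array(
        [[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4],
         [1, 0, 5], [2, 1, 5], [3, 2, 5], [0, 3, 5]]
    )
    return AlphaMesh(verts, faces, alpha=np.inf)


class TestAlphashape:
    def test_regular_tetrahedron_exact_volume(self):
        e = 0.5
        pts = np.array(
            [
                [0, 0, 0],
                [e, 0, 0],
                [e / 2, e * np.sqrt(3) / 2, 0],
                [e / 2, e * np.sqrt(3) / 6, e * np.sqrt(2 / 3)],
            ]
        )
        mesh = build_alphashape(pts, alpha=1.0)
        assert mesh.volume == pytest.approx(e**3 / (6 * np.sqrt(2)), rel=1e-9)

    def test_sphere_sample_volume_and_area(self, sphere_points):
        mesh = build_alphashape(sphere_points, alpha=1.0)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 8, rel=0.10)
        assert mesh.surface_area == pytest.approx(4 * np.pi * 4, rel=0.15)

    def test_cube_sample_volume(self):
        rng = np.random.default_rng(2)
        pts = rng.random((20000, 3)) * 2.0
        mesh = build_alphashape(pts, alpha=1.0)
        assert mesh.volume == pytest.approx(8.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="tetrahedralize"):
            build_alphashape(np.zeros((3, 3)))

    def test_coplanar_points_rejected(self):
        pts = np.column_stack([np.random.default_rng(0).random((50, 2)), np.zeros(50)])
        with pytest.raises(ValueError, match="tetrahedralize"):
            build_alphashape(pts)

    def test_large_alpha_matches_convex_hull(self):
        rng = np.random.default_rng(3)
        pts = rng.random((500, 3)) * 4.0
        mesh = build_alphashape(pts, alpha=1e6)
        assert mesh.volume == pytest.approx(ConvexHull(pts).volume, rel=1e-9)

    def test_volume_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        pts = rng.random((3000, 3)) * 3.0
        vols = [build_alphashape(pts, a).volume for a in (0.5, 1.0, 2.0, 10.0)]
        assert all(b >= a - 1e-9 for a, b in zip(vols, vols[1:]))


class TestMeshMeasures:
    def test_unit_cube_exact(self):
        mesh = _unit_cube_mesh()
        vol, area = mesh_measures(mesh)
        assert vol == pytest.approx(1.0, rel=1e-12)
        assert area == pytest.approx(6.0, rel=1e-12)

    def test_scaling_homogeneity(self):
        mesh = _unit_cube_mesh()
        s = 2.5
        scaled = AlphaMesh(mesh.vertices * s, mesh.faces, mesh.alpha)
        assert scaled.volume == pytest.approx(mesh.volume * s**3, rel=1e-12)
        assert scaled.surface_area == pytest.approx(mesh.surface_area * s**2, rel=1e-12)


class TestCrossSection:
    def test_cube_midplane_square(self):
        section = cross_section(_unit_cube_mesh(), 0.5)
        assert len(section.polygons) == 1
        assert section.polygons[0].area == pytest.approx(1.0, rel=1e-6)

    def test_plane_above_mesh_empty(self):
        section = cross_section(_unit_cube_mesh(), 5.0)
        assert section.is_empty

    def test_cylinder_section_area(self, cylinder_mesh):
        section = cross_section(cylinder_mesh, 6.0)
        total = sum(p.area for p in section.polygons)
        assert total == pytest.approx(np.pi, rel=0.10)


class TestAzimuthDistances:
    @staticmethod
    def _circle_section(r=1.0, center=(0.0, 0.0), h=1.0):
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ring = Polygon(np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)]))
        return CrossSection(h, [ring])

    def test_centered_circle_all_radii_equal(self):
        d = azimuth_distances(self._circle_section(), (0.0, 0.0))
        np.testing.assert_allclose(d, 1.0, atol=1e-4)

    def test_square_closed_form_distances(self):
        sq = Polygon([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        d = azimuth_distances(CrossSection(1.0, [sq]), (0.0, 0.0))
        for k in (0, 9, 18, 27):  # 0, 90, 180, 270 deg hit edge midpoints
            assert d[k] == pytest.approx(1.0, abs=1e-9)
        # closed form for a centred unit-half-side square: 1/cos(angle to
        # nearest cardinal axis); at 40 deg the ray exits near a corner
        for k in (4, 13, 22, 31):
            assert d[k] == pytest.approx(1.0 / np.cos(np.radians(40.0)), abs=1e-6)
        # exact corner distance bounds every ray
        assert d.max() <= np.sqrt(2) + 1e-9

    def test_offset_stem_inside_circle(self):
        # stem 0.5 m west of centre: east ray exits at 1.5, west at 0.5
        d = azimuth_distances(self._circle_section(center=(0.5, 0.0)), (0.0, 0.0))
        assert d[9] == pytest.approx(1.5, abs=1e-3)   # 90 deg = east
        assert d[27] == pytest.approx(0.5, abs=1e-3)  # 270 deg = west

    def test_stem_outside_all_polygons_missing(self):
        d = azimuth_distances(self._circle_section(), (5.0, 5.0))
        assert np.isnan(d).all()

    def test_matches_brute_force_oracle_on_convex_polygon(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 2 * np.pi, 12))
        poly = Polygon(np.column_stack([np.cos(t) * 2.0, np.sin(t) * 2.0]))
        stem = (0.2, -0.1)
        d = azimuth_distances(CrossSection(1.0, [poly]), stem)
        # oracle: dense boundary sampling, max distance within a narrow
        # angular window around each ray
        coords = np.asarray(poly.exterior.coords)
        pts = np.vstack(
            [
                a + (b - a) * np.linspace(0, 1, 4000)[:, None]
                for a, b in zip(coords[:-1], coords[1:])
            ]
        )
        vec = pts - np.array(stem)
        az = np.degrees(np.arctan2(vec[:, 0], vec[:, 1])) % 360
        dist = np.hypot(vec[:, 0], vec[:, 1])
        for k in range(36):
            gap = np.minimum(np.abs(az - 10 * k), 360 - np.abs(az - 10 * k))
            oracle = dist[gap <= 0.05].max()
            assert d[k] == pytest.approx(oracle, abs=0.01)


class TestAzimuthProfile:
    def test_cylinder_cumulative_equals_nheights_times_radius(self, cylinder_mesh):
        prof = azimuth_profile(cylinder_mesh, (0.0, 0.0), top_height=11.0)
        assert len(prof.heights) == 21
        np.testing.assert_allclose(prof.cumulative, 21.0, rtol=0.05)

    def test_symmetric_profile_uniform_across_azimuths(self, cylinder_mesh):
        prof = azimuth_profile(cylinder_mesh, (0.0, 0.0), top_height=11.0)
        cum = prof.cumulative
        assert (cum.max() - cum.min()) / cum.mean() < 0.05


class TestWedgeVolumes:
    def test_symmetric_cylinder_wedges_equal(self, cylinder_mesh):
        w = voxelize_and_wedge(cylinder_mesh, (0.0, 0.0))
        assert (w.volumes.max() - w.volumes.min()) / w.volumes.mean() < 0.02

    def test_wedge_sum_matches_mesh_volume(self, cylinder_mesh):
        w = voxelize_and_wedge(cylinder_mesh, (0.0, 0.0))
        assert w.total == pytest.approx(cylinder_mesh.volume, rel=0.05)

    def test_half_cylinder_empty_wedges(self):
        rng = np.random.default_rng(5)
        n = 20000
        theta = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(rng.random(n))
        # eastern half-disc: x >= 0 <-> compass azimuths 0..180
        pts = np.column_stack(
            [np.abs(r * np.cos(theta)), r * np.sin(theta), rng.uniform(0, 4, n)]
        )
        mesh = build_alphashape(pts, 1.0)
        w = voxelize_and_wedge(mesh, (0.0, 0.0))
        # wedges fully inside the unoccupied western half stay ~empty
        west = w.volumes[5] + w.volumes[6]  # 225-315 deg
        assert west < 0.02 * w.total

    def test_refined_grid_converges_to_mesh_volume(self, cylinder_mesh):
        coarse = voxelize_and_wedge(cylinder_mesh, (0, 0), cell=(0.2, 0.2, 0.5))
        fine = voxelize_and_wedge(cylinder_mesh, (0, 0), cell=(0.1, 0.1, 0.5))
        err_c = abs(coarse.total - cylinder_mesh.volume)
        err_f = abs(fine.total - cylinder_mesh.volume)
        assert err_f <= err_c + 1e-9

    def test_north_south_aggregates(self, cylinder_mesh):
        w = voxelize_and_wedge(cylinder_mesh, (0.0, 0.0))
        assert w.north == pytest.approx(w.volumes[7] + w.volumes[0])
        assert w.south == pytest.approx(w.volumes[3] + w.volumes[4])


class TestOPCR:
    def test_square_pyramid_four_patches(self):
        mesh = _square_pyramid_mesh()
        assert opcr(mesh, min_patch_faces=1) == pytest.approx(4.0)

    def test_octagonal_pyramid_eight_patches(self):
        # base offset keeps the eight face normals away from every rotated
        # bin boundary (a normal exactly on a boundary is assignment-ambiguous)
        t = np.radians(np.arange(0, 360, 45) + 32.5)
        base = np.column_stack([np.cos(t), np.sin(t), np.zeros(8)])
        verts = np.vstack([base, [0, 0, 1], [0, 0, 0]])
        faces = []
        for i in range(8):
            j = (i + 1) % 8
            faces.append([i, j, 8])   # side
            faces.append([j, i, 9])   # base
        mesh = AlphaMesh(verts, np.array(faces), np.inf)
        assert opcr(mesh, min_patch_faces=1) == pytest.approx(8.0)

    def test_invariant_under_bin_width_rotation(self):
        mesh = _square_pyramid_mesh()
        a = np.radians(45.0)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        rotated = AlphaMesh(mesh.vertices @ rot.T, mesh.faces, mesh.alpha)
        assert opcr(rotated, min_patch_faces=1) == pytest.approx(
            opcr(mesh, min_patch_faces=1)
        )

    def test_invariant_under_uniform_scaling(self):
        mesh = _square_pyramid_mesh()
        scaled = AlphaMesh(mesh.vertices * 7.3, mesh.faces, mesh.alpha)
        assert opcr(scaled) == pytest.approx(opcr(mesh))

    def test_min_patch_size_filters_small_patches(self):
        mesh = _square_pyramid_mesh()
        # each cardinal side is a single face: patches of size 1 vanish at 3
        assert opcr(mesh, min_patch_faces=3) == 0.0
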