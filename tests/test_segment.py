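"""Crown delineation, pairing, and reference matching."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from crownsect.cloud import PointCloud
from crownsect.segment import (
    TreeCrown,
    detect_markers,
    match_to_reference,
    pair_crowns,
    segment_crowns,
    vertical_occupancy_raster,
)
from crownsect.synthetic import CrownParams, generate_crown


def _normalized(xyz):
    """Cloud whose z already is height above ground."""
    c = PointCloud(xyz)
    c.height = np.asarray(xyz)[:, 2].astype(float)
    return c


class TestOccupancyRaster:
    def test_vertical_stack_counts_occupied_voxels(self):
        # points every 0.1 m from 1.0 to 5.0 in one column
        z = np.arange(1.0, 5.0, 0.1)
        xyz = np.column_stack([np.full_like(z, 0.05), np.full_like(z, 0.05), z])
        r = vertical_occupancy_raster(_normalized(xyz), voxel=0.2)
        # brute force: count occupied 0.2 m bins
        expected = len(np.unique(np.floor(z / 0.2).astype(int)))
        assert r.values.max() == expected == 20

    def test_understory_excluded_and_empty_zero(self):
        xyz = np.array([[0.1, 0.1, 0.5], [3.0, 3.0, 2.0]])
        r = vertical_occupancy_raster(_normalized(xyz), voxel=0.2)
        assert r.values.sum() == 1  # only the 2 m return counts

    def test_duplicates_in_voxel_count_once(self):
        xyz = np.array([[0.1, 0.1, 2.01], [0.11, 0.12, 2.05], [0.1, 0.1, 3.0]])
        r = vertical_occupancy_raster(_normalized(xyz), voxel=0.2)
        assert r.values.max() == 2


class TestMarkerDetection:
    @staticmethod
    def _bump_cloud(centers, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        parts = []
        for cx, cy in centers:
            xy = rng.normal([cx, cy], 0.5, (n, 2))
            z = rng.uniform(1.5, 8.0, n)
            parts.append(np.column_stack([xy, z]))
        return _normalized(np.vstack(parts))

    def test_single_bump_one_marker(self):
        r = vertical_occupancy_raster(self._bump_cloud([(5.0, 5.0)]))
        markers = detect_markers(r, min_distance=2.0)
        assert len(markers) == 1
        assert np.hypot(*(markers[0] - [5.0, 5.0])) < 0.5

    def test_two_bumps_two_markers(self):
        r = vertical_occupancy_raster(self._bump_cloud([(0.0, 0.0), (5.0, 0.0)]))
        markers = detect_markers(r, min_distance=2.0)
        assert len(markers) == 2

    def test_plot_markers_near_true_stems(self, processed_plot9):
        markers = processed_plot9["markers"]
        truth = processed_plot9["truth"]
        tree = cKDTree(truth[["stem_x", "stem_y"]].to_numpy())
        d, i = tree.query(markers)
        detected = len(set(i[d < 1.0]))
        assert detected >= 0.95 * len(truth)


class TestSegmentation:
    def test_single_crown_all_points_one_itc(self):
        tree = generate_crown(CrownParams(), (0, 0), seed=0)
        c = _normalized(tree.xyz)
        lab = segment_crowns(c, np.array([[0.0, 0.0]]))
        above = c.height >= 1.0
        assert (lab.itc_id[above] == 1).all()
        assert (lab.itc_id[~above] == 0).all()

    def test_well_separated_crowns_not_cross_assigned(self):
        a = generate_crown(CrownParams(), (0, 0), seed=1)
        b = generate_crown(CrownParams(), (12, 0), seed=2)
        xyz = np.vstack([a.xyz, b.xyz])
        c = _normalized(xyz)
        lab = segment_crowns(c, np.array([[0.0, 0.0], [12.0, 0.0]]))
        above = c.height >= 1.0
        ids_a = lab.itc_id[: len(a.xyz)][above[: len(a.xyz)]]
        ids_b = lab.itc_id[len(a.xyz):][above[len(a.xyz):]]
        assert set(np.unique(ids_a)) <= {1} and set(np.unique(ids_b)) <= {2}

    def test_no_markers_rejected(self):
        tree = generate_crown(CrownParams(), (0, 0), seed=0)
        with pytest.raises(ValueError, match="marker"):
            segment_crowns(_normalized(tree.xyz), np.empty((0, 2)))

    def test_partition_property(self, processed_plot9):
        """Every return is understory/unassigned or in exactly one crown."""
        lab = processed_plot9["labeling"]
        cloud = processed_plot9["cloud"]
        assert len(lab.itc_id) == len(cloud)
        assert (lab.itc_id >= 0).all()
        below = cloud.height < 1.0
        assert (lab.itc_id[below] == 0).all()

    def test_plot_detection_rate(self, processed_plot9):
        crowns = processed_plot9["crowns"]
        truth = processed_plot9["truth"]
        tree = cKDTree(truth[["stem_x", "stem_y"]].to_numpy())
        cent = np.array([c.crown_center_xy for c in crowns])
        d, i = tree.query(cent)
        hit = set(i[d < 1.0])
        assert len(hit) >= 0.95 * len(truth)


def _jittered_copies(crowns, dx, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for c in crowns:
        shift = np.array([*rng.uniform(-dx, dx, 2), 0.0]) if dx else np.zeros(3)
        out.append(TreeCrown(c.itc_id, c.points + shift, epoch="e2"))
    return out


class TestPairing:
    def test_identical_lists_pair_at_zero(self, processed_plot9):
        crowns = processed_plot9["crowns"]
        pairs = pair_crowns(crowns, _jittered_copies(crowns, 0.0))
        assert len(pairs) == len(crowns)
        assert all(p.center_distance < 1e-9 for p in pairs)
        assert all(p.itc_id_e1 == p.itc_id_e2 for p in pairs)

    def test_small_jitter_pairs_correctly(self, processed_plot9):
        crowns = processed_plot9["crowns"]
        moved = _jittered_copies(crowns, 0.5 / np.sqrt(2), seed=3)
        pairs = pair_crowns(crowns, moved)
        assert len(pairs) == len(crowns)
        assert all(p.itc_id_e1 == p.itc_id_e2 for p in pairs)

    def test_offset_beyond_two_metres_rejects_all(self, processed_plot9):
        crowns = processed_plot9["crowns"][:10]
        moved = [
            TreeCrown(c.itc_id, c.points + np.array([3.0, 0.0, 0.0]), epoch="e2")
            for c in crowns
        ]
        # 3 m exceeds the 2 m rule in every direction of this layout
        pairs = [
            p
            for p in pair_crowns(crowns, moved)
            if p.itc_id_e1 == p.itc_id_e2
        ]
        all_pairs = pair_crowns(crowns, moved)
        assert all(p.center_distance <= 2.0 for p in all_pairs)
        assert len(pairs) == 0

    def test_pairing_symmetric_under_epoch_swap(self, processed_plot9):
        crowns = processed_plot9["crowns"]
        moved = _jittered_copies(crowns, 0.3, seed=5)
        fwd = {(p.itc_id_e1, p.itc_id_e2) for p in pair_crowns(crowns, moved)}
        rev = {(p.itc_id_e2, p.itc_id_e1) for p in pair_crowns(moved, crowns)}
        assert fwd == rev

    def test_empty_epoch_rejected(self, processed_plot9):
        with pytest.raises(ValueError):
            pair_crowns(processed_plot9["crowns"], [])


class TestReferenceMatching:
    def _pairs(self, crowns):
        moved = _jittered_copies(crowns, 0.0)
        return pair_crowns(crowns, moved), crowns, moved

    def test_exact_reference_all_matched(self, processed_plot9):
        crowns = processed_plot9["crowns"]
        pairs, e1, e2 = self._pairs(crowns)
        ref = np.array([c.crown_center_xy for c in crowns])
        out = match_to_reference(pairs, e1, e2, ref)
        assert all(p.matched_ref_id is not None for p in out)

    def test_systematic_shift_reported(self, processed_plot9):
        crowns = processed_plot9["crowns"]
        pairs, e1, e2 = self._pairs(crowns)
        shift = np.array([-0.49, 0.49]) / np.sqrt(2)  # 0.49 m to the north-west
        ref = np.array([c.crown_center_xy for c in crowns]) + shift
        out = match_to_reference(pairs, e1, e2, ref)
        offsets = np.array([p.ref_offset for p in out if p.ref_offset is not None])
        assert len(offsets) == len(crowns)
        mean_off = np.linalg.norm(offsets.mean(axis=0))
        assert mean_off == pytest.approx(0.49, abs=0.01)

    def test_missing_reference_leaves_one_unmatched(self, processed_plot9):
        crowns = processed_plot9["crowns"]
        pairs, e1, e2 = self._pairs(crowns)
        ref = np.array([c.crown_center_xy for c in crowns])[:-1]
        out = match_to_reference(pairs, e1, e2, ref)
        unmatched = [p for p in out if p.matched_ref_id is None]
        assert len(unmatched) == 1
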