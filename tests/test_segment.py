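"""Normalization, minima detection, ROI measurement and classification."""

import numpy as np
import pytest

import fdmap as f
from fdmap.segment import JunctionROI
from fdmap.simulate import Disk, Scene, er_sheet, render_frame

from conftest import classification_scene, junction_scene, segment_frames


def _roi_from_coords(coords, label=1, area=1.0):
    coords = np.asarray(coords)
    return JunctionROI(label=label, coords=coords, area_um2=area,
                       centroid=(float(coords[:, 1].mean()), float(coords[:, 0].mean())),
                       mean_rel_intensity=0.5, mean_distance_nm=37.0,
                       circularity=1.0)


class TestNormalize:
    def test_uniform_noiseless_image_is_unity(self):
        img = np.full((64, 64), 900.0)
        rel = f.normalize_to_reference(img, offset=100.0)
        assert np.allclose(rel.values, 1.0)
        assert rel.reference_level == 900.0

    def test_all_offset_image_rejected(self):
        with pytest.raises(ValueError, match="reference not above offset"):
            f.normalize_to_reference(np.zeros((16, 16)), offset=0.0)

    def test_gain_invariance(self, dp50):
        sc = Scene(width=96, height=96, seed=2,
                   primitives=[er_sheet(Disk(48, 48, 10), z_bottom_nm=30)])
        img = render_frame(sc, dp50).astype(float)
        rel1 = f.normalize_to_reference(img, offset=100.0)
        rel2 = f.normalize_to_reference(3.0 * (img - 100.0) + 100.0, offset=100.0)
        assert np.allclose(rel1.values, rel2.values, atol=1e-9)

    def test_region_reference(self):
        img = np.full((32, 32), 1100.0)
        img[10:20, 10:20] = 600.0
        region = np.zeros((32, 32), bool)
        region[:5, :5] = True
        rel = f.normalize_to_reference(img, offset=100.0, reference=region)
        assert rel.values[0, 0] == pytest.approx(1.0)
        assert rel.values[15, 15] == pytest.approx(0.5)

    def test_simulated_junction_at_52_percent(self, dp50):
        sc = Scene(width=128, height=128, seed=6,
                   primitives=[er_sheet(Disk(64, 64, 12), z_bottom_nm=37,
                                        thickness_nm=4000.0)])
        img = render_frame(sc, dp50)
        rel = f.normalize_to_reference(img, offset=100.0)
        interior = rel.values[60:68, 60:68].mean()
        assert interior == pytest.approx(0.52, abs=0.02)


class TestDetectMinima:
    def test_uniform_image_has_no_minima(self):
        rel = f.normalize_to_reference(np.full((64, 64), 800.0), offset=0.0)
        assert not f.detect_minima(rel).any()

    def test_disk_recall(self, dp50):
        sc = Scene(width=128, height=128, seed=1,
                   primitives=[er_sheet(Disk(64, 64, 5), z_bottom_nm=37,
                                        thickness_nm=4000.0)])
        img = render_frame(sc, dp50)
        rel = f.normalize_to_reference(img, offset=100.0)
        mask = f.detect_minima(rel)
        footprint = Disk(64, 64, 5).mask((128, 128))
        recall = (mask & footprint).sum() / footprint.sum()
        assert recall >= 0.9

    def test_oversized_window_falls_back_to_global_mean(self):
        img = np.full((16, 16), 1000.0)
        img[8, 8] = 500.0
        rel = f.normalize_to_reference(img, offset=0.0, reference=1000.0)
        mask = f.detect_minima(rel, radius_px=50)
        assert mask[8, 8] and mask.sum() == 1


class TestLabelRois:
    def test_empty_mask_gives_no_rois(self):
        rel = f.normalize_to_reference(np.full((32, 32), 700.0), offset=0.0)
        assert f.label_rois(np.zeros((32, 32), bool), rel) == []

    def test_disjoint_disks_counted_and_sized(self, dp50):
        scene, truth = junction_scene(5, seed=42)
        rois = segment_frames(render_frame(scene, dp50)[None], scene)[0]
        assert len(rois) == 5
        for roi in rois:
            d = [np.hypot(roi.centroid[0] - t[0], roi.centroid[1] - t[1])
                 for t in truth]
            t = truth[int(np.argmin(d))]
            truth_area = np.pi * (t[2] * scene.pixel_size_nm / 1000.0) ** 2
            assert roi.area_um2 == pytest.approx(truth_area, rel=0.15)

    def test_blur_merged_disks_become_one_roi(self, dp50):
        prims = [er_sheet(Disk(60, 64, 6), z_bottom_nm=25, thickness_nm=4000.0),
                 er_sheet(Disk(74, 64, 6), z_bottom_nm=25, thickness_nm=4000.0)]
        sc = Scene(width=128, height=128, primitives=prims, seed=8,
                   psf_sigma_nm=200.0)
        rois = segment_frames(render_frame(sc, dp50)[None], sc,
                              occluder_thickness_nm=4000.0)[0]
        assert len(rois) == 1

    def test_min_area_filters_specks(self):
        rel = f.normalize_to_reference(np.full((64, 64), 1000.0), offset=0.0,
                                       reference=1000.0)
        mask = np.zeros((64, 64), bool)
        mask[10, 10] = True  # 0.01 um^2 at 100 nm/px, below the 0.07 floor
        assert f.label_rois(mask, rel, refine=False) == []


class TestClassification:
    def test_vesicles_and_sheets_separated(self, dp50):
        scene, kinds, positions = classification_scene(seed=3)
        stack = f.render_timeseries(scene, dp50, 8)
        roi_lists = segment_frames(stack, scene)
        f.classify_structures(roi_lists, max_link_distance_px=8.0)
        for rois in roi_lists:
            for roi in rois:
                d = [np.hypot(roi.centroid[0] - p[0], roi.centroid[1] - p[1])
                     for p in positions]
                assert roi.kind == kinds[int(np.argmin(d))]

    def test_single_frame_circular_object_unclassified(self, dp50):
        sc = Scene(width=96, height=96, seed=5,
                   primitives=[er_sheet(Disk(48, 48, 8), z_bottom_nm=25)])
        roi_lists = segment_frames(render_frame(sc, dp50)[None], sc)
        f.classify_structures(roi_lists)
        assert roi_lists[0][0].kind == "unclassified"


class TestAreaFraction:
    def test_trivial_bounds(self):
        mask = np.ones((50, 50), bool)
        assert f.junction_area_fraction([], mask) == 0.0
        full = _roi_from_coords(np.argwhere(mask))
        assert f.junction_area_fraction([full], mask) == 100.0

    def test_monotone_in_added_junctions(self, dp50):
        fractions = []
        for k in (2, 4, 6):
            scene, _ = junction_scene(k, seed=77)
            rois = segment_frames(render_frame(scene, dp50)[None], scene)[0]
            fractions.append(f.junction_area_fraction(rois, scene.mask()))
        assert fractions[0] < fractions[1] < fractions[2]

    def test_recovers_known_coverage(self, dp50):
        scene, truth = junction_scene(10, seed=5)
        rois = segment_frames(render_frame(scene, dp50)[None], scene)[0]
        true_frac = 100.0 * sum(np.pi * t[2] ** 2 for t in truth) / 256 ** 2
        assert f.junction_area_fraction(rois, scene.mask()) == \
            pytest.approx(true_frac, abs=2.0)


class TestOverlap:
    def test_identical_and_disjoint(self):
        roi = _roi_from_coords([(5, 5), (5, 6), (6, 5)])
        marker = roi.pixel_mask((20, 20))
        assert f.overlap_fraction([roi], marker) == 100.0
        assert f.overlap_fraction([roi], np.zeros((20, 20), bool)) == 0.0

    def test_three_of_four(self):
        rois = [_roi_from_coords([(r, c) for c in range(3)]) for r in (0, 4, 8, 12)]
        marker = np.zeros((16, 16), bool)
        marker[[0, 4, 8], :] = True
        assert f.overlap_fraction(rois, marker) == 75.0

    def test_majority_overlap_mode(self):
        roi = _roi_from_coords([(0, c) for c in range(10)])
        marker = np.zeros((4, 16), bool)
        marker[0, :3] = True  # 30 % of the ROI
        assert f.overlap_fraction([roi], marker) == 100.0
        assert f.overlap_fraction([roi], marker, min_overlap_fraction=0.5) == 0.0

    def test_empty_roi_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            f.overlap_fraction([], np.ones((4, 4), bool))
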