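"""Tracking, time courses, oscillation metrics, topology reconstruction."""

import math

import numpy as np
import pytest

import fdmap as f
from fdmap.segment import JunctionROI, RelativeIntensityImage
from fdmap.simulate import Disk, Scene, er_sheet, height_map, ideal_relative_image

from conftest import ramp_scene, segment_frames


def _roi(x, y, frame, area=1.0, label=1, mean_i=0.5):
    return JunctionROI(label=label, coords=np.array([[int(y), int(x)]]),
                       area_um2=area, centroid=(float(x), float(y)),
                       mean_rel_intensity=mean_i,
                       mean_distance_nm=34.7, circularity=0.7, frame=frame)


def _rel_image(values):
    values = np.asarray(values, dtype=float)
    return RelativeIntensityImage(values=values, reference_level=1000.0,
                                  cell_mask=np.ones(values.shape, bool),
                                  pixel_size_nm=100.0)


class TestTracking:
    def test_static_roi_forms_single_track(self):
        lists = [[_roi(10, 10, fr)] for fr in range(10)]
        tracks = f.track_junctions(lists)
        assert len(tracks) == 1 and tracks[0].n_frames == 10

    def test_links_beyond_max_distance_terminate(self):
        lists = [[_roi(0, 0, 0), _roi(40, 0, 0)],
                 [_roi(20, 0, 1), _roi(60, 0, 1)]]
        tracks = f.track_junctions(lists, max_link_distance_px=5.0)
        assert len(tracks) == 4
        assert all(t.n_frames == 1 for t in tracks)

    def test_every_roi_in_exactly_one_track(self):
        rng = np.random.default_rng(17)
        lists = []
        for fr in range(6):
            n = rng.integers(1, 6)
            lists.append([_roi(rng.uniform(0, 100), rng.uniform(0, 100), fr,
                               label=i + 1) for i in range(n)])
        tracks = f.track_junctions(lists, max_link_distance_px=10.0)
        seen = [id(r) for t in tracks for r in t.rois]
        expected = [id(r) for rois in lists for r in rois]
        assert sorted(seen) == sorted(expected)

    def test_growing_junction_tracked_with_increasing_area(self, dp50):
        prim = er_sheet(Disk(64, 64, 8), z_bottom_nm=30, growth_px_per_frame=0.5)
        sc = Scene(width=128, height=128, primitives=[prim], seed=2)
        stack = f.render_timeseries(sc, dp50, 6)
        tracks = f.track_junctions(segment_frames(stack, sc))
        assert len(tracks) == 1
        area = tracks[0].area_course()
        assert area[-1] > area[0] * 1.3


class TestTimecourse:
    def test_constant_depth_gives_inverted_e_minus_1(self, dp50):
        sc = Scene(width=96, height=96, shot_noise=False, read_noise_sd=0.0,
                   psf_sigma_nm=0.0, brightness_scale=20000.0,
                   primitives=[er_sheet(Disk(48, 48, 10), z_bottom_nm=50.0,
                                        thickness_nm=1e5)])
        stack = f.render_timeseries(sc, dp50, 3)
        roi_lists = segment_frames(stack, sc, occluder_thickness_nm=1e5)
        track = f.track_junctions(roi_lists)[0]
        rel_seq = [f.normalize_to_reference(stack[i], offset=100.0)
                   for i in range(3)]
        from fdmap.dynamics import junction_timecourse
        tc = junction_timecourse(rel_seq, track)
        assert np.allclose(tc, math.exp(-1), atol=0.01)

    def test_control_region_in_empty_scene_is_near_zero(self):
        rel_seq = [_rel_image(np.ones((32, 32))) for _ in range(3)]
        track = f.JunctionTrack(track_id=0)
        for fr in range(3):
            track.append(fr, _roi(10, 10, fr))
        from fdmap.dynamics import junction_timecourse
        assert np.allclose(junction_timecourse(rel_seq, track), 0.0, atol=1e-12)

    def test_course_consistency_with_inversion(self, dp50):
        """distance_course equals the background-corrected inversion of the
        inverted-intensity timecourse."""
        sc = Scene(width=96, height=96, seed=9,
                   primitives=[er_sheet(Disk(48, 48, 10), z_bottom_nm=35,
                                        thickness_nm=4000.0)])
        stack = f.render_timeseries(sc, dp50, 4)
        roi_lists = segment_frames(stack, sc, occluder_thickness_nm=None)
        track = f.track_junctions(roi_lists)[0]
        expected = [f.background_corrected_distance(1.0 - v, 0.0, 50.0)
                    for v in track.timecourse()]
        assert np.allclose(track.distance_course(), expected, atol=1e-9)


class TestOscillation:
    def test_constant_trace_has_no_oscillation(self):
        assert f.oscillation_metrics(np.full(32, 0.4)) is None

    def test_noise_only_trace_has_no_oscillation(self):
        rng = np.random.default_rng(0)
        assert f.oscillation_metrics(rng.normal(0, 1, 64)) is None

    def test_pure_sinusoid_recovered(self):
        t = np.arange(64)
        trace = 0.5 + 0.1 * np.sin(2 * np.pi * t / 10.0)
        m = f.oscillation_metrics(trace, frame_interval_s=2.0)
        assert m is not None
        assert m.period_s == pytest.approx(20.0, abs=2.0)
        assert m.amplitude == pytest.approx(0.2, abs=0.02)
        assert m.n_cycles >= 5

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="8 frames"):
            f.oscillation_metrics(np.ones(5))

    def test_simulated_junction_oscillation_period(self, dp50):
        prim = er_sheet(Disk(64, 64, 10), z_bottom_nm=40.0,
                        z_oscillation=(15.0, 10.0, 0.0))
        sc = Scene(width=128, height=128, primitives=[prim], seed=5)
        stack = f.render_timeseries(sc, dp50, 64)
        track = f.track_junctions(segment_frames(stack, sc))[0]
        m = f.oscillation_metrics(track.timecourse(), frame_interval_s=1.0)
        assert m is not None
        assert m.period_s == pytest.approx(10.0, abs=1.0)


class TestTopology:
    def test_uniform_unity_image_fully_censored(self):
        rel = _rel_image(np.ones((32, 32)))
        topo = f.reconstruct_topology(rel, dp_nm=50.0)
        assert topo.censored.all()
        assert np.allclose(topo.z_nm, topo.ceiling_nm)

    def test_plateau_at_52_percent_maps_to_37_nm(self):
        vals = np.ones((32, 32))
        vals[8:24, 8:24] = 0.52
        topo = f.reconstruct_topology(_rel_image(vals), dp_nm=50.0)
        assert topo.z_nm[16, 16] == pytest.approx(36.7, abs=0.1)
        assert not topo.censored[16, 16]

    def test_noiseless_ramp_recovered(self, dp50):
        sc = ramp_scene()
        img = f.render_frame(sc, dp50)
        rel = f.normalize_to_reference(img, offset=sc.camera_offset)
        topo = f.reconstruct_topology(rel, dp_nm=50.0)
        hm = height_map(sc)
        on = np.isfinite(hm.z_bottom_nm) & ~topo.censored
        assert np.abs(topo.z_nm[on] - hm.z_bottom_nm[on]).max() < 0.5

    def test_reconstruction_forward_roundtrip(self, dp50):
        """Re-rendering the reconstructed height map reproduces the noiseless
        input image on non-censored pixels."""
        sc = ramp_scene(thickness=75.0)
        rel_in = ideal_relative_image(sc, dp50)
        rel_img = _rel_image(rel_in)
        topo = f.reconstruct_topology(rel_img, dp_nm=50.0,
                                      occluder_thickness_nm=75.0)
        ok = ~topo.censored
        forward = np.empty_like(rel_in)
        from fdmap.optics import relative_intensity_with_occluder
        forward[ok] = relative_intensity_with_occluder(topo.z_nm[ok], 75.0, 50.0)
        assert np.abs(forward[ok] / rel_in[ok] - 1.0).max() < 1e-6

    def test_overcorrected_pixels_clamp_to_membrane(self):
        vals = np.full((8, 8), 0.10)
        topo = f.reconstruct_topology(_rel_image(vals), dp_nm=50.0, background=0.15)
        assert np.allclose(topo.z_nm, 0.0)
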