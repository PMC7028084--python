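import numpy as np
import pytest

from blebkit.morphometry import (
    BlebRegion,
    BlebTrack,
    EmptySegmentationError,
    aspect_ratio,
    bleb_kinetics,
    bleb_summary,
    detect_blebs,
    max_intensity_projection,
    segment_cell,
    track_blebs,
)
from blebkit.simulate import MovieSimConfig, render_bleb_movie


def disk_image(shape, center_rc, radius_px, value=1000.0):
    Y, X = np.indices(shape)
    img = np.zeros(shape)
    img[np.hypot(Y - center_rc[0], X - center_rc[1]) <= radius_px] = value
    return img


class TestMaxIntensityProjection:
    def test_single_plane_is_identity(self):
        plane = np.random.default_rng(0).random((1, 2, 16, 16))
        np.testing.assert_array_equal(max_intensity_projection(plane), plane[0])

    def test_disjoint_bright_spots_union(self):
        a = np.zeros((8, 8)); a[1, 1] = 5
        b = np.zeros((8, 8)); b[6, 6] = 7
        out = max_intensity_projection(np.stack([a, b]))
        assert out[1, 1] == 5 and out[6, 6] == 7

    def test_random_stack_equals_elementwise_max(self):
        stack = np.random.default_rng(1).random((3, 2, 10, 12))
        np.testing.assert_array_equal(
            max_intensity_projection(stack), np.max(stack, axis=0)
        )

    def test_mismatched_plane_shapes_rejected(self):
        with pytest.raises(ValueError):
            max_intensity_projection([np.zeros((4, 4)), np.zeros((5, 5))])


class TestSegmentCell:
    def test_synthetic_disk_area_within_two_percent(self):
        img = disk_image((100, 100), (50, 50), 30)
        mask = segment_cell(img, pixel_size_um=1.0)
        assert mask.area_um2 == pytest.approx(np.pi * 30**2, rel=0.02)

    def test_blank_frame_raises(self):
        with pytest.raises(EmptySegmentationError):
            segment_cell(np.zeros((50, 50)), 1.0)

    def test_largest_of_two_disks_returned(self):
        img = disk_image((120, 120), (30, 30), 20)
        img += disk_image((120, 120), (90, 90), 5)
        mask = segment_cell(img, 1.0)
        assert mask.area_um2 == pytest.approx(np.pi * 20**2, rel=0.05)
        # centroid at the large disk
        assert mask.centroid_um[0] == pytest.approx(30.5, abs=1)


class TestAspectRatio:
    def test_disk_has_unit_ratio(self):
        mask = disk_image((80, 80), (40, 40), 25) > 0
        assert aspect_ratio(mask).ratio == pytest.approx(1.0, rel=0.02)

    def test_axis_aligned_rectangle_ratio_equals_side_ratio(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[20:40, 10:50] = True  # 20 x 40
        ar = aspect_ratio(mask)
        assert ar.ratio == pytest.approx(2.0, rel=0.01)

    def test_rotation_invariance_within_rasterization_tolerance(self):
        from skimage.transform import rotate

        mask = np.zeros((120, 120))
        mask[50:70, 20:100] = 1.0
        rot = rotate(mask, 30, resize=False, order=0) > 0.5
        assert aspect_ratio(rot).ratio == pytest.approx(4.0, rel=0.03)

    def test_scale_invariance_is_exact(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:20, 10:40] = True
        assert aspect_ratio(mask, 1.0).ratio == aspect_ratio(mask, 0.25).ratio

    def test_degenerate_line_mask_rejected(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 5:25] = True
        with pytest.raises(ValueError):
            aspect_ratio(mask)


class TestDetectBlebs:
    def test_null_fixture_yields_zero_regions(self):
        cfg = MovieSimConfig(n_blebs=0)
        movie, _ = render_bleb_movie(cfg)
        mem, act = movie.channel("membrane"), movie.channel("actin")
        cm = segment_cell(mem[0], cfg.pixel_size_um)
        assert detect_blebs(mem[0], act[0], cm) == []

    def test_default_fixture_counts_and_centroids_match_truth(
        self, default_fixture, default_detections
    ):
        cfg, movie, gt = default_fixture
        for k, regions in enumerate(default_detections):
            truth_centroids = [
                b.centroid_um[k] for b in gt.blebs if b.masks[k].sum() > 6
            ]
            if len(truth_centroids) == cfg.n_blebs:
                assert len(regions) == cfg.n_blebs
                for tc in truth_centroids:
                    err = min(
                        np.hypot(r.centroid_um[0] - tc[0], r.centroid_um[1] - tc[1])
                        for r in regions
                    )
                    assert err <= cfg.pixel_size_um  # within one pixel

    def test_fixture_bleb_diameter_recovered_within_ten_percent(
        self, default_fixture, default_detections
    ):
        cfg, movie, gt = default_fixture
        diams = [
            r.major_axis_diameter_um
            for k in gt.steady_frames
            for r in default_detections[k]
        ]
        assert np.mean(diams) == pytest.approx(3.0, rel=0.10)

    def test_all_fixture_blebs_flagged_leading_edge(self, default_detections):
        for regions in default_detections:
            assert all(r.leading_edge for r in regions)

    def test_detection_robust_to_five_percent_noise(self):
        """Precision/recall against ground truth stays high under noise."""
        cfg = MovieSimConfig(noise_sd=0.05, seed=2)
        movie, gt = render_bleb_movie(cfg)
        mem, act = movie.channel("membrane"), movie.channel("actin")
        tp = fp = fn = 0
        for k in gt.steady_frames:
            cm = segment_cell(mem[k], cfg.pixel_size_um, frame_index=k)
            regions = detect_blebs(mem[k], act[k], cm)
            truth = [b.centroid_um[k] for b in gt.blebs if b.masks[k].any()]
            matched = set()
            for r in regions:
                dists = [
                    np.hypot(r.centroid_um[0] - t[0], r.centroid_um[1] - t[1])
                    for t in truth
                ]
                j = int(np.argmin(dists))
                if dists[j] < 1.5 and j not in matched:
                    matched.add(j)
                    tp += 1
                else:
                    fp += 1
            fn += len(truth) - len(matched)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.9

    def test_region_invariants_hold(self, default_fixture, default_detections):
        cfg, movie, gt = default_fixture
        for k, regions in enumerate(default_detections):
            cell_area = gt.cell_masks[k].sum() * cfg.pixel_size_um**2
            total = sum(r.area_um2 for r in regions)
            assert total < cell_area
            for r in regions:
                assert r.area_um2 < cell_area


class TestTrackBlebs:
    @staticmethod
    def region(frame, x, y, area=1.0):
        return BlebRegion(
            frame_index=frame, mask=np.zeros((2, 2), bool),
            centroid_um=(x, y), area_um2=area, area_fraction_pct=1.0,
            major_axis_diameter_um=1.0, leading_edge=True, mean_actin=0.0,
        )

    def test_stationary_bleb_forms_single_track(self):
        frames = [[self.region(k, 5.0, 5.0)] for k in range(4)]
        tracks = track_blebs(frames)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 2, 3]

    def test_two_separated_blebs_never_swap(self):
        frames = [
            [self.region(k, 0.0, 0.0), self.region(k, 20.0, 0.0)]
            for k in range(5)
        ]
        tracks = track_blebs(frames)
        assert len(tracks) == 2
        for trk in tracks:
            xs = {r.centroid_um[0] for r in trk.regions}
            assert len(xs) == 1  # each track stays on one bleb

    def test_track_ends_beyond_max_link_distance(self):
        frames = [[self.region(0, 0.0, 0.0)], [self.region(1, 10.0, 0.0)]]
        tracks = track_blebs(frames, max_link_dist_um=2.0)
        assert len(tracks) == 2

    def test_default_fixture_yields_one_track_per_ground_truth_bleb(
        self, default_fixture, default_bleb_tracks
    ):
        cfg, _, gt = default_fixture
        assert len(default_bleb_tracks) == len(gt.blebs) == cfg.n_blebs


class TestKinetics:
    def test_hand_area_series_with_plateau(self):
        """Areas [1,2,3,3,2,1] at 10 s/frame: 20 s expansion, 20 s retraction."""
        regions = [
            TestTrackBlebs.region(k, 0.0, 0.0, area=a)
            for k, a in enumerate([1, 2, 3, 3, 2, 1])
        ]
        trk = BlebTrack(0, regions)
        e, r = bleb_kinetics(trk, np.arange(6) * 10.0)
        assert (e, r) == (20.0, 20.0)

    def test_monotone_growth_truncated_by_movie_end_has_zero_retraction(self):
        regions = [
            TestTrackBlebs.region(k, 0.0, 0.0, area=a)
            for k, a in enumerate([1, 2, 3, 4])
        ]
        e, r = bleb_kinetics(BlebTrack(0, regions), np.arange(4) * 5.0)
        assert r == 0.0 and e == 15.0

    def test_single_frame_track_has_zero_durations(self):
        trk = BlebTrack(0, [TestTrackBlebs.region(0, 0.0, 0.0)])
        assert bleb_kinetics(trk, np.array([0.0])) == (0.0, 0.0)

    def test_expansion_plus_plateau_plus_retraction_spans_lifetime(
        self, default_fixture, default_bleb_tracks
    ):
        cfg, movie, _ = default_fixture
        ts = movie.timestamps_s
        for trk in default_bleb_tracks:
            e, r = bleb_kinetics(trk, ts)
            lifetime = ts[trk.frames[-1]] - ts[trk.frames[0]]
            areas = trk.areas_um2
            plateau = (np.isclose(areas, areas.max()).sum() - 1) * cfg.frame_interval_s
            assert e + plateau + r == pytest.approx(lifetime)

    def test_programmed_kinetics_recovered_within_one_frame_interval(
        self, single_bleb_fixture
    ):
        cfg, movie, gt = single_bleb_fixture
        mem, act = movie.channel("membrane"), movie.channel("actin")
        frames = []
        for k in range(movie.n_frames):
            cm = segment_cell(mem[k], cfg.pixel_size_um, frame_index=k)
            frames.append(detect_blebs(mem[k], act[k], cm))
        tracks = track_blebs(frames)
        assert len(tracks) == 1
        e, r = bleb_kinetics(tracks[0], movie.timestamps_s)
        assert abs(e - cfg.expansion_duration_s) <= cfg.frame_interval_s
        assert abs(r - cfg.retraction_duration_s) <= cfg.frame_interval_s


class TestSummary:
    def test_fixture_mean_blebs_per_steady_frame_matches_truth(
        self, default_fixture, default_detections
    ):
        cfg, _, gt = default_fixture
        counts = [len(default_detections[k]) for k in gt.steady_frames]
        assert np.mean(counts) == cfg.n_blebs

    def test_area_fraction_is_plain_percentage(self):
        reg = TestTrackBlebs.region(0, 0.0, 0.0, area=2.0)
        reg.area_fraction_pct = 100.0 * 2.0 / 100.0
        df = bleb_summary([BlebTrack(0, [reg])], np.array([0.0]))
        assert df.loc[0, "area_fraction_pct"] == pytest.approx(2.0)

    def test_empty_track_list_gives_empty_table(self):
        df = bleb_summary([], np.array([0.0]))
        assert len(df) == 0
        assert "area_fraction_pct" in df.columns
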