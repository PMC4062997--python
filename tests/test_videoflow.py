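"""Flow, silhouette, edge-band and direction-histogram behaviour."""

import numpy as np
import pytest
from scipy import stats

from behavtrace import synthdata as sd
from behavtrace import videoflow as vf


def brute_force_band(mask: np.ndarray, radius: int) -> np.ndarray:
    """Direct neighborhood-scan oracle for the contour dilation."""
    h, w = mask.shape
    eroded = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < h and 0 <= jj < w) or not mask[ii, jj]:
                        ok = False
            eroded[i, j] = ok
    contour = mask & ~eroded
    band = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di * di + dj * dj > radius * radius:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and contour[ii, jj]:
                        band[i, j] = True
    return band


class TestSelectFramePairs:
    @pytest.mark.parametrize("n,expected", [
        (12, [(3, 6), (6, 9), (9, 12)]),
        (3, []),
        (6, [(3, 6)]),
    ])
    def test_small_movies(self, n, expected):
        assert vf.select_frame_pairs(n) == expected

    def test_160_frame_movie_gives_52_steps(self):
        pairs = vf.select_frame_pairs(160)
        assert len(pairs) == 52
        assert pairs[-1] == (156, 159)

    def test_interval_is_120_ms_at_25_fps(self):
        (i, j) = vf.select_frame_pairs(12)[0]
        assert (j - i) / 25.0 == pytest.approx(0.120)


class TestHornSchunck:
    def test_identical_frames_give_zero_flow(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(size=(24, 24))
        flow = vf.compute_optical_flow(frame, frame)
        assert np.allclose(flow.u, 0) and np.allclose(flow.v, 0)

    def test_constant_frames_give_zero_flow(self):
        a = np.full((16, 16), 0.5)
        b = np.full((16, 16), 0.5)
        flow = vf.compute_optical_flow(a, b)
        assert np.allclose(flow.u, 0) and np.allclose(flow.v, 0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vf.compute_optical_flow(np.zeros((8, 8)), np.zeros((9, 8)))

    def test_rightward_shift_recovers_direction(self, walk_scene, walk_right_script):
        r = sd.render_silhouette_sequence(walk_right_script, walk_scene, seed=1)
        flow = vf.compute_optical_flow(r.seq.frames[2], r.seq.frames[5])
        inside = r.masks[3] & (flow.modulus > 0.05)
        ang = np.degrees(np.arctan2(-flow.v[inside], flow.u[inside]))
        mean = stats.circmean(ang, high=180, low=-180)
        assert abs(mean) < 10.0

    def test_energy_decreases_monotonically(self, walk_scene, walk_right_script):
        r = sd.render_silhouette_sequence(walk_right_script, walk_scene, seed=1)
        _, energies = vf.compute_optical_flow(
            r.seq.frames[2], r.seq.frames[5], n_iter=60, return_energy=True)
        e = np.asarray(energies)
        assert np.all(np.diff(e) <= 1e-9 * e[0])


class TestBinarizeAndSilhouette:
    def test_zero_flow_empty_mask(self):
        flow = vf.FlowField(np.zeros((8, 8)), np.zeros((8, 8)))
        assert not vf.binarize_flow(flow, 0.3).any()

    def test_uniform_flow_full_mask(self):
        flow = vf.FlowField(np.full((8, 8), 0.6), np.zeros((8, 8)))
        assert vf.binarize_flow(flow, 0.3).all()

    def test_mover_mask_overlaps_ground_truth(self, walk_scene, walk_right_script):
        r = sd.render_silhouette_sequence(walk_right_script, walk_scene, seed=1)
        flow = vf.compute_optical_flow(r.seq.frames[2], r.seq.frames[5])
        mask = vf.binarize_flow(flow, 0.3)
        gt = r.masks[3]
        iou = (mask & gt).sum() / (mask | gt).sum()
        assert iou >= 0.5

    def test_intersection_idempotent_and_disjoint(self):
        a = np.zeros((10, 10), bool); a[2:6, 2:6] = True
        b = np.zeros((10, 10), bool); b[7:9, 7:9] = True
        assert np.array_equal(vf.silhouette_from_masks(a, a).mask, a)
        assert not vf.silhouette_from_masks(a, b).mask.any()

    def test_offset_rectangles_shrink_by_offset(self):
        w = 8
        a = np.zeros((12, 20), bool); a[3:9, 4:4 + w] = True
        b = np.roll(a, 2, axis=1)
        inter = vf.silhouette_from_masks(a, b).mask
        widths = inter.sum(axis=1)
        assert widths.max() == w - 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vf.silhouette_from_masks(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


class TestEdgeBand:
    def test_empty_mask_empty_band(self):
        assert not vf.edge_band(np.zeros((10, 10), bool)).any()

    def test_square_matches_brute_force_oracle(self):
        sil = np.zeros((20, 20), bool)
        sil[5:15, 5:15] = True
        band = vf.edge_band(sil, band_px=4)
        assert np.array_equal(band, brute_force_band(sil, 2))

    def test_random_masks_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            h, w = rng.integers(6, 33, size=2)
            sil = rng.random((h, w)) < 0.35
            band = vf.edge_band(sil, band_px=4)
            assert np.array_equal(band, brute_force_band(sil, 2))

    def test_band_contains_contour_and_respects_bbox(self):
        sil = np.zeros((30, 30), bool)
        sil[10:20, 8:22] = True
        band = vf.edge_band(sil, band_px=4)
        from scipy import ndimage
        contour = sil & ~ndimage.binary_erosion(sil, np.ones((3, 3), bool),
                                                border_value=0)
        assert np.all(band[contour])
        grown = np.zeros_like(sil)
        grown[10 - 4:20 + 4, 8 - 4:22 + 4] = True
        assert not np.any(band & ~grown)


class TestDirectionHistogram:
    def _flow_at_angle(self, deg, shape=(6, 6)):
        rad = np.radians(deg)
        u = np.full(shape, np.cos(rad))
        v = np.full(shape, -np.sin(rad))  # image y axis points down
        return vf.FlowField(u, v)

    @pytest.mark.parametrize("deg,bin1", [(0, 1), (45, 2), (90, 3), (135, 4),
                                          (180, 5), (225, 6), (270, 7), (315, 8)])
    def test_canonical_angles_map_to_single_bin(self, deg, bin1):
        flow = self._flow_at_angle(deg)
        band = np.ones(flow.shape, bool)
        h = vf.direction_histogram(flow, band)
        assert h.argmax_bin == bin1
        assert h.bins[bin1 - 1] == pytest.approx(1.0)

    def test_equal_counts_give_uniform_histogram(self):
        u = np.empty(8); v = np.empty(8)
        for k, deg in enumerate(range(0, 360, 45)):
            u[k] = np.cos(np.radians(deg))
            v[k] = -np.sin(np.radians(deg))
        flow = vf.FlowField(u[None, :], v[None, :])
        h = vf.direction_histogram(flow, np.ones((1, 8), bool))
        assert np.allclose(h.bins, 0.125)

    def test_empty_band_flags_undetermined(self):
        flow = self._flow_at_angle(0)
        h = vf.direction_histogram(flow, np.zeros(flow.shape, bool))
        assert h.undetermined and np.allclose(h.bins, 0.0)

    def test_nonzero_histogram_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            flow = vf.FlowField(rng.normal(size=(9, 9)), rng.normal(size=(9, 9)))
            band = rng.random((9, 9)) < 0.5
            h = vf.direction_histogram(flow, band)
            if not h.undetermined:
                assert h.bins.sum() == pytest.approx(1.0, abs=1e-9)

    def test_quarter_turn_permutes_bins_cyclically(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(12, 12))
        v = rng.normal(size=(12, 12))
        band = rng.random((12, 12)) < 0.6
        h = vf.direction_histogram(vf.FlowField(u, v), band)
        # rotating every vector by +90 deg: (u', v') = (v, -u)
        h_rot = vf.direction_histogram(vf.FlowField(v, -u), band)
        assert np.allclose(np.roll(h.bins, 2), h_rot.bins)


class TestTimeAngleRepresentation:
    def test_static_scene_all_zero(self, small_scene):
        script = sd.ActivityScript("V1", (sd.Segment("static", 0.0, 1.2),))
        r = sd.render_silhouette_sequence(script, small_scene, seed=0)
        tam = vf.time_angle_representation(r.seq, n_iter=40)
        assert np.allclose(tam.matrix, 0.0)
        assert all(tam.undetermined)

    def test_column_count_matches_pair_count(self, walk_scene, walk_right_script):
        r = sd.render_silhouette_sequence(walk_right_script, walk_scene, seed=1)
        tam = vf.time_angle_representation(r.seq, n_iter=40)
        assert tam.n_steps == len(vf.select_frame_pairs(len(r.seq)))

    def test_right_static_left_pattern(self, small_scene):
        segs = (sd.Segment("3a", 0.0, 1.6, direction_deg=0.0, speed=15.0),
                sd.Segment("static", 1.6, 1.2),
                sd.Segment("3b", 2.8, 1.6, direction_deg=180.0, speed=15.0))
        script = sd.ActivityScript("V1", segs)
        scene = sd.SceneSpec(frame_size=(96, 64), fps=25.0, actor_size=(18, 28),
                             actor_start=(36.0, 36.0))
        r = sd.render_silhouette_sequence(script, scene, seed=0)
        tam = vf.time_angle_representation(r.seq, n_iter=60)
        dominant = np.argmax(tam.matrix, axis=0) + 1
        col_t = np.array([(i + j) / 2 / 25.0 for i, j in tam.pairs])
        right = dominant[(col_t > 0.2) & (col_t < 1.3)]
        static = tam.matrix[:, (col_t > 1.9) & (col_t < 2.6)]
        left = dominant[(col_t > 3.1) & (col_t < 4.2)]
        assert np.all(right == 1)          # motion to the right -> B1
        assert np.allclose(static, 0.0)    # static scene -> zero columns
        assert np.all(left == 5)           # motion to the left -> B5

    def test_frame_dir_round_trip(self, tmp_path, small_scene):
        script = sd.ActivityScript("V1", (sd.Segment("static", 0.0, 0.4),))
        r = sd.render_silhouette_sequence(script, small_scene, seed=0)
        vf.write_frame_dir(r.seq, tmp_path / "frames")
        back = vf.read_frame_dir(tmp_path / "frames")
        assert len(back) == len(r.seq)
        assert back.fps == r.seq.fps
        assert np.max(np.abs(back.frames - r.seq.frames)) < 1.0 / 255.0
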