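import numpy as np
import pytest

from circafish import synthetic
from circafish.errors import DimensionError
from circafish.tracker import (
    Detection,
    Trajectory,
    calibrate,
    estimate_background,
    link_tracks,
    read_trajectories_csv,
    segment_frame,
    track_video,
    write_trajectories_csv,
)
from circafish.video_io import FrameSequence, TankLayout, TankROI


def disk_frame(shape, cx, cy, r=4.0, bg=200, fg=40):
    """Render one dark anti-aliased disk on a bright floor."""
    yy, xx = np.indices(shape)
    cover = np.clip(r + 0.5 - np.hypot(xx - cx, yy - cy), 0, 1)
    return np.clip(np.round(bg + cover * (fg - bg)), 0, 255).astype(np.uint8)


@pytest.fixture
def one_tank():
    return TankLayout(
        tanks=[TankROI(0, 0, 0, 60, 60, expected_fish=1)], px_per_cm=2.0
    )


class TestBackground:
    def test_static_scene_recovered_exactly(self, static_seq):
        bg = estimate_background(static_seq, 5)
        np.testing.assert_array_equal(bg, static_seq.frames[0])

    def test_median_ignores_transient_occupancy(self):
        # disk covers a pixel in fewer than half the sampled frames
        frames = np.full((10, 20, 20), 200, np.uint8)
        frames[:4, 5, 5] = 10
        bg = estimate_background(FrameSequence(frames, 30.0), 10)
        assert bg[5, 5] == 200

    def test_close_to_true_background_under_noise(self, one_tank, schedule):
        params = synthetic.BehaviorParams(duration_s=3.0, tank_w_cm=30, tank_h_cm=30)
        trajs, _ = synthetic.simulate_trajectory(params, schedule, 1)
        rp = synthetic.RenderParams(noise_sigma=5.0, background_intensity=150.0, seed=4)
        seq = synthetic.render_video(trajs, one_tank, rp, 60, 60)
        bg = estimate_background(seq, 25)
        err = np.abs(bg.astype(float) - 150.0)
        # median of 25 noisy samples: nearly everywhere within a few sigma
        assert np.quantile(err, 0.99) <= 3 * rp.noise_sigma

    def test_n_samples_validation(self, static_seq):
        with pytest.raises(ValueError):
            estimate_background(static_seq, 11)
        with pytest.raises(ValueError):
            estimate_background(static_seq, 0)


class TestSegmentation:
    def test_frame_equal_to_background_gives_nothing(self, one_tank):
        bg = np.full((60, 60), 180, np.uint8)
        assert segment_frame(bg, bg, one_tank) == []

    def test_single_disk_centroid_subpixel(self, one_tank):
        bg = np.full((60, 60), 200, np.uint8)
        frame = disk_frame((60, 60), cx=20.0, cy=30.0)
        dets = segment_frame(frame, bg, one_tank)
        assert len(dets) == 1
        assert abs(dets[0].x - 20.0) < 0.5
        assert abs(dets[0].y - 30.0) < 0.5

    def test_two_disks_two_detections(self):
        layout = TankLayout(
            tanks=[TankROI(0, 0, 0, 60, 60, expected_fish=2)], px_per_cm=2.0
        )
        bg = np.full((60, 60), 200, np.uint8)
        frame = np.minimum(
            disk_frame((60, 60), 15, 15), disk_frame((60, 60), 45, 45)
        )
        dets = segment_frame(frame, bg, layout)
        assert len(dets) == 2

    def test_extra_blobs_keep_largest(self, one_tank):
        bg = np.full((60, 60), 200, np.uint8)
        frame = np.minimum(
            disk_frame((60, 60), 15, 15, r=5.5), disk_frame((60, 60), 45, 45, r=3.5)
        )
        dets = segment_frame(frame, bg, one_tank)  # expected_fish = 1
        assert len(dets) == 1
        assert abs(dets[0].x - 15) < 1.0

    def test_area_filter(self, one_tank):
        bg = np.full((60, 60), 200, np.uint8)
        frame = bg.copy()
        frame[10, 10] = 0  # single-pixel speck < min_area
        assert segment_frame(frame, bg, one_tank, min_area=10) == []

    def test_shape_mismatch(self, one_tank):
        with pytest.raises(DimensionError):
            segment_frame(np.zeros((4, 4)), np.zeros((5, 5)), one_tank)

    def test_brightness_offset_invariance(self, one_tank):
        bg = np.full((60, 60), 150, np.uint8)
        frame = disk_frame((60, 60), 25, 25, bg=150, fg=30)
        d1 = segment_frame(frame, bg, one_tank)
        d2 = segment_frame(frame + 40, bg + 40, one_tank)
        assert len(d1) == len(d2) == 1
        assert d1[0].x == pytest.approx(d2[0].x, abs=0.2)
        assert d1[0].y == pytest.approx(d2[0].y, abs=0.2)


class TestLinking:
    def test_full_detection_reproduces_centroids(self, one_tank):
        xs = np.linspace(5, 50, 20)
        dets = [
            [Detection(frame_index=i, tank_id=0, x=x, y=10.0, area=20)]
            for i, x in enumerate(xs)
        ]
        trajs = link_tracks(dets, one_tank, fps=30.0)
        assert len(trajs) == 1
        np.testing.assert_allclose(trajs[0].positions[:, 0], xs)
        assert trajs[0].n_interpolated == 0

    def test_midpoint_interpolation(self, one_tank):
        # one missing detection between (10,10) and (12,10) cm = (20,20), (24,20) px
        dets = [
            [Detection(0, 0, 20.0, 20.0, 20)],
            [],
            [Detection(2, 0, 24.0, 20.0, 20)],
        ]
        trajs = link_tracks(dets, one_tank, fps=30.0)
        traj_cm = calibrate(trajs[0], one_tank.px_per_cm)
        np.testing.assert_allclose(traj_cm.positions[1], [11.0, 10.0])
        assert traj_cm.n_interpolated == 1

    def test_long_gap_holds_last_position(self, one_tank):
        dets = [[Detection(0, 0, 20.0, 20.0, 20)]] + [[]] * 10 + [
            [Detection(11, 0, 22.0, 20.0, 20)]
        ]
        trajs = link_tracks(dets, one_tank, max_gap=5, fps=30.0)
        np.testing.assert_allclose(trajs[0].positions[5], [20.0, 20.0])
        assert trajs[0].n_interpolated == 0

    def test_all_missing_tank_warns(self, one_tank):
        dets = [[] for _ in range(5)]
        with pytest.warns(UserWarning, match="no detections"):
            trajs = link_tracks(dets, one_tank, fps=30.0)
        assert len(trajs) == 1
        assert trajs[0].missing.all()

    def test_trajectory_length_always_frame_count(self, one_tank):
        dets = [[], [Detection(1, 0, 30.0, 30.0, 20)], []]
        trajs = link_tracks(dets, one_tank, fps=30.0)
        assert len(trajs[0]) == 3

    def test_two_separated_fish_keep_identity(self, schedule):
        layout = TankLayout(
            tanks=[TankROI(0, 0, 0, 120, 40, expected_fish=2)], px_per_cm=2.0
        )
        # two always-moving fish in disjoint halves of the tank, never
        # within max_jump of each other (resting fish would be absorbed
        # into the median background, which is not what this test probes)
        active = synthetic.PhaseBehavior(
            mean_dwell_active_s=1e6, mean_dwell_quiescent_s=0.2,
            active_speed_mean_cms=5.0,
        )
        band = synthetic.BehaviorParams(
            light=active, dark=active,
            duration_s=8.0, tank_w_cm=25, tank_h_cm=20, seed=11,
        )
        t0, _ = synthetic.simulate_trajectory(band, schedule, 1, seed_path=(11, 0))
        t1, _ = synthetic.simulate_trajectory(band, schedule, 1, seed_path=(11, 1))
        a, b = t0[0], t1[0]
        b.positions[:, 0] += 35.0  # second fish lives in x in [35, 60) cm
        b.fish_id = 1
        frames = []
        for i in range(len(a)):
            f = np.minimum(
                disk_frame((40, 120), a.positions[i, 0] * 2, a.positions[i, 1] * 2, r=3),
                disk_frame((40, 120), b.positions[i, 0] * 2, b.positions[i, 1] * 2, r=3),
            )
            frames.append(f)
        seq = FrameSequence(np.stack(frames), fps=30.0)
        trajs = track_video(seq, layout)
        # match each output trajectory to the truth fish by mean distance
        for t in trajs:
            d_a = np.linalg.norm(t.positions - a.positions, axis=1)
            d_b = np.linalg.norm(t.positions - b.positions, axis=1)
            truth = a if np.nanmean(d_a) < np.nanmean(d_b) else b
            d = np.linalg.norm(t.positions - truth.positions, axis=1)
            # identity holds in every frame with a detection (a fish that
            # rests from frame 0 is part of the median background until it
            # first moves; those leading frames are marked missing)
            assert (d[~t.missing] < 1.0).all()


class TestCalibrate:
    def test_identity_factor(self, one_tank):
        t = Trajectory(0, 0, np.array([[3.0, 4.0]]), fps=30.0)
        np.testing.assert_array_equal(calibrate(t, 1.0).positions, t.positions)

    def test_arithmetic(self):
        t = Trajectory(0, 0, np.array([[30.0, 60.0]]), fps=30.0)
        np.testing.assert_allclose(calibrate(t, 15.0).positions, [[2.0, 4.0]])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 10, (20, 2))
        t = Trajectory(0, 0, pos, fps=30.0)
        back = calibrate(calibrate(t, 0.125), 8.0)
        np.testing.assert_allclose(back.positions, pos, rtol=1e-12)

    def test_rejects_nonpositive(self):
        t = Trajectory(0, 0, np.zeros((2, 2)), fps=30.0)
        with pytest.raises(ValueError):
            calibrate(t, 0.0)

    def test_preserves_fps(self):
        t = Trajectory(0, 0, np.zeros((2, 2)), fps=25.0)
        assert calibrate(t, 2.0).fps == 25.0


class TestPipeline:
    def test_clean_video_recovery(self, schedule):
        layout, w, h = synthetic.grid_layout(2, 1, px_per_cm=3.0)
        params = synthetic.BehaviorParams(duration_s=5.0, seed=2)
        all_trajs = []
        truths = {}
        for tank in layout.tanks:
            trajs, truth = synthetic.simulate_trajectory(
                params, schedule, 1, tank_id=tank.tank_id,
                seed_path=(2, tank.tank_id),
            )
            all_trajs += trajs
            truths[tank.tank_id] = truth
        seq = synthetic.render_video(
            all_trajs, layout, synthetic.RenderParams(noise_sigma=0.0), w, h
        )
        out = track_video(seq, layout)
        for t in out:
            true_pos = truths[t.tank_id].positions_cm[0]
            err_px = np.linalg.norm(t.positions - true_pos, axis=1) * layout.px_per_cm
            assert err_px.mean() < 0.5
            assert np.sqrt((err_px**2).mean()) < 1.0

    def test_brightness_offset_invariance(self, schedule):
        layout, w, h = synthetic.grid_layout(1, 1, px_per_cm=3.0)
        params = synthetic.BehaviorParams(duration_s=2.0, seed=5)
        trajs, _ = synthetic.simulate_trajectory(params, schedule, 1)
        seq = synthetic.render_video(
            trajs, layout, synthetic.RenderParams(noise_sigma=0.0), w, h
        )
        shifted = FrameSequence(
            np.clip(seq.frames.astype(np.int16) + 30, 0, 255).astype(np.uint8),
            seq.fps,
        )
        t1 = track_video(seq, layout)[0]
        t2 = track_video(shifted, layout)[0]
        np.testing.assert_allclose(t1.positions, t2.positions, atol=0.05)


class TestCsv:
    def test_round_trip(self, one_tank):
        rng = np.random.default_rng(1)
        trajs = [
            Trajectory(f, 0, rng.uniform(0, 10, (15, 2)), fps=30.0, units="cm")
            for f in range(2)
        ]
        import pathlib, tempfile

        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "traj.csv"
            write_trajectories_csv(trajs, p)
            back = read_trajectories_csv(p, fps=30.0)
        assert len(back) == 2
        for a, b in zip(trajs, back):
            np.testing.assert_allclose(a.positions, b.positions, rtol=1e-9)
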