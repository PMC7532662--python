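"""EB1 comet detection, linking and growth-rate statistics."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from chemoscreen.comets import (
    CometDetection,
    CometTrack,
    detect_comets,
    growth_rate,
    link_tracks,
    net_rate,
    per_cell_summary,
    track_movie,
)
from chemoscreen.simulate import simulate_comet_movie


def render_spot(shape, x, y, amplitude, background, sigma):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )


class TestDetect:
    def test_single_spot_localized_within_half_pixel(self):
        rng = np.random.default_rng(0)
        img = render_spot((64, 64), 30.3, 41.7, 100.0, 10.0, 1.5)
        img = img + rng.normal(0, 2.0, img.shape)
        dets = detect_comets(img, sigma_spot=1.5, min_snr=5)
        assert len(dets) == 1
        assert abs(dets[0].x - 30.3) < 0.5 and abs(dets[0].y - 41.7) < 0.5

    def test_pure_noise_rarely_detects(self):
        """Null simulation: >= 95% of noise-only frames yield 0 detections."""
        clean = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = rng.normal(10, 2.0, size=(64, 64))
            if len(detect_comets(frame, sigma_spot=1.5, min_snr=5)) == 0:
                clean += 1
        assert clean >= 95

    def test_two_separated_spots(self):
        img = render_spot((64, 64), 20, 32, 100, 10, 1.5)
        img += render_spot((64, 64), 20 + 9, 32, 100, 0, 1.5)  # 6*sigma apart
        dets = detect_comets(img, sigma_spot=1.5, min_snr=5)
        assert len(dets) == 2


class TestLink:
    @staticmethod
    def dets(points):
        return [
            [CometDetection(frame=f, x=x, y=y, intensity=1.0) for x, y in frame_pts]
            for f, frame_pts in enumerate(points)
        ]

    def test_single_moving_comet_one_track(self):
        pts = [[(5.0 + 3 * f, 10.0)] for f in range(8)]
        tracks = link_tracks(self.dets(pts), max_disp=6, min_track_length=4)
        assert len(tracks) == 1 and len(tracks[0]) == 8

    def test_two_distant_comets_no_switches(self):
        pts = [[(5.0 + 2 * f, 5.0), (5.0 + 2 * f, 50.0)] for f in range(6)]
        tracks = link_tracks(self.dets(pts), max_disp=6, min_track_length=4)
        assert len(tracks) == 2
        for t in tracks:
            ys = {d.y for d in t.detections}
            assert len(ys) == 1  # each track stays on its own line

    def test_no_step_exceeds_max_disp(self):
        frames, _ = simulate_comet_movie(n_comets=20, seed=5)
        tracks, _ = track_movie(frames, 0.065, 2.0, max_disp=7.0)
        for t in tracks:
            steps = np.hypot(*np.diff(t.xy, axis=0).T)
            assert np.all(steps <= 7.0 + 1e-9)

    def test_gap_closing_flag(self):
        """A missed middle detection terminates a track by default but is
        bridged with gap_closing=True."""
        pts = [[(5.0 + 2 * f, 10.0)] for f in range(9)]
        pts[4] = []  # detection missed in frame 4
        no_gap = link_tracks(self.dets(pts), max_disp=5, min_track_length=4)
        assert [len(t) for t in no_gap] == [4, 4]
        bridged = link_tracks(self.dets(pts), max_disp=5, min_track_length=4,
                              gap_closing=True)
        assert len(bridged) == 1 and len(bridged[0]) == 8
        assert np.diff(bridged[0].frames).max() == 2  # the closed gap

    def test_short_tracks_discarded(self):
        pts = [[(5.0, 5.0)], [(6.0, 5.0)], [(7.0, 5.0)]]
        assert link_tracks(self.dets(pts), max_disp=3, min_track_length=4) == []

    def test_agreement_with_optimal_assignment_oracle(self):
        """Greedy frame-pair linking agrees with exhaustive optimal
        assignment (Hungarian) on >= 95% of links at screen-like density."""
        rng = np.random.default_rng(11)
        n, n_frames, max_disp = 50, 10, 6.0
        pos = rng.uniform(5, 120, size=(n, 2))
        vel = rng.normal(0, 2.0, size=(n, 2))
        per_frame = []
        for f in range(n_frames):
            pts = pos + f * vel + rng.normal(0, 0.3, size=(n, 2))
            per_frame.append(
                [CometDetection(f, float(x), float(y), 1.0) for x, y in pts]
            )
        tracks = link_tracks(per_frame, max_disp=max_disp, min_track_length=2)
        greedy_links = set()
        for t in tracks:
            d = t.detections
            for a, b in zip(d, d[1:]):
                greedy_links.add((a.frame, round(a.x, 6), round(b.x, 6)))
        optimal_links = set()
        big = 1e9
        for f in range(n_frames - 1):
            A = per_frame[f]
            B = per_frame[f + 1]
            cost = np.full((len(A), len(B)), big)
            for i, a in enumerate(A):
                for j, b in enumerate(B):
                    d2 = np.hypot(a.x - b.x, a.y - b.y)
                    if d2 <= max_disp:
                        cost[i, j] = d2
            ri, cj = linear_sum_assignment(cost)
            for i, j in zip(ri, cj):
                if cost[i, j] < big:
                    optimal_links.add((f, round(A[i].x, 6), round(B[j].x, 6)))
        agreement = len(greedy_links & optimal_links) / len(optimal_links)
        assert agreement >= 0.95


class TestRates:
    @staticmethod
    def straight_track(step_px, n, dt_frames=1):
        dets = [
            CometDetection(frame=i * dt_frames, x=i * step_px, y=0.0, intensity=1.0)
            for i in range(n)
        ]
        return CometTrack(dets)

    def test_constant_displacement_rate(self):
        """0.3 µm per 2-s frame is 9 µm/min."""
        t = self.straight_track(step_px=0.3 / 0.1, n=10)  # 0.1 µm/px
        assert growth_rate(t, pixel_size_um=0.1, frame_interval_s=2.0) == pytest.approx(9.0)

    def test_stationary_comet_zero_rate(self):
        t = CometTrack([CometDetection(i, 5.0, 5.0, 1.0) for i in range(5)])
        assert growth_rate(t, 0.1, 2.0) == 0.0

    def test_rate_scales_with_pixel_size(self):
        t = self.straight_track(2.0, 8)
        assert growth_rate(t, 0.2, 2.0) == pytest.approx(2 * growth_rate(t, 0.1, 2.0))

    def test_path_rate_at_least_net_rate(self):
        zigzag = CometTrack(
            [CometDetection(i, float(i), float(i % 2), 1.0) for i in range(6)]
        )
        assert growth_rate(zigzag, 0.1, 2.0) > net_rate(zigzag, 0.1, 2.0)

    def test_invalid_inputs(self):
        t = self.straight_track(1.0, 5)
        with pytest.raises(ValueError):
            growth_rate(t, 0.1, 0.0)
        with pytest.raises(ValueError):
            growth_rate(CometTrack([CometDetection(0, 0, 0, 1.0)]), 0.1, 2.0)

    def test_rotation_translation_invariance(self):
        t = self.straight_track(2.0, 8)
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = t.xy @ R.T + [50, 20]
        t2 = CometTrack(
            [CometDetection(i, float(x), float(y), 1.0) for i, (x, y) in enumerate(xy)]
        )
        assert growth_rate(t2, 0.1, 2.0) == pytest.approx(growth_rate(t, 0.1, 2.0))


class TestSummary:
    def test_cell_means_and_grand_mean(self):
        s = per_cell_summary({"c1": [8.0, 10.0], "c2": [11.0], "c3": [9.0]})
        assert s["cell_means"]["c1"] == pytest.approx(9.0)
        assert s["grand_mean_of_cell_means"] == pytest.approx((9 + 11 + 9) / 3)

    def test_identical_tracks_zero_sd(self):
        s = per_cell_summary({"c": [10.0, 10.0, 10.0]})
        assert s["pooled"]["sd"] == 0.0

    def test_empty_cell_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no tracks"):
            s = per_cell_summary({"a": [5.0], "b": []})
        assert list(s["cell_means"]) == ["a"]

    def test_percentile_conventions(self):
        rates = list(np.linspace(1, 100, 100))
        s = per_cell_summary({"c": rates})
        assert s["pooled"]["p5"] < s["pooled"]["median"] < s["pooled"]["p95"]


def test_end_to_end_speed_recovery_10um():
    """Programmed 10 µm/min recovered within 5% from rendered movies."""
    rates = []
    for seed in range(3):
        frames, _ = simulate_comet_movie(n_comets=25, speed_mean=10.0, seed=seed)
        _, r = track_movie(frames, 0.065, 2.0)
        rates.extend(r)
    assert len(rates) >= 50
    assert abs(np.mean(rates) - 10.0) / 10.0 < 0.05
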