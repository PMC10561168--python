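"""Spot detection, linking and 3×3 intensity measurement."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import erf

from myddoquant.core import FrameStack, Spot, Track
from myddoquant.detect_track import (detect_spots, link_tracks,
                                     measure_intensity, round_half_away)
from myddoquant.simulate import _add_gaussian


def render_spot(shape, x, y, amplitude, sigma):
    img = np.zeros(shape)
    _add_gaussian(img, x, y, amplitude, sigma)
    return img


class TestDetectSpots:
    def test_blank_frame_gives_no_spots(self):
        assert detect_spots(np.zeros((32, 32)), 1.0, 1.0) == []

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((8, 8)), 0.0, 1.0)

    def test_subpixel_localization_within_quarter_pixel(self):
        img = render_spot((64, 64), 20.3, 41.7, 500.0, 1.0)
        spots = detect_spots(img, 1.0, 1.0)
        assert len(spots) == 1
        assert abs(spots[0].x - 20.3) <= 0.25
        assert abs(spots[0].y - 41.7) <= 0.25

    def test_resolved_pair_gives_two_detections(self):
        img = render_spot((64, 64), 20.0, 20.0, 500.0, 1.0)
        _add_gaussian(img, 30.0, 20.0, 500.0, 1.0)
        assert len(detect_spots(img, 1.0, 1.0)) == 2

    def test_duplicates_within_one_pixel_suppressed(self):
        img = render_spot((64, 64), 20.0, 20.0, 500.0, 1.0)
        _add_gaussian(img, 20.5, 20.0, 500.0, 1.0)
        assert len(detect_spots(img, 1.0, 1.0)) == 1


def brute_force_assignment(heads, spots, max_disp):
    """Enumerate all injective head→spot assignments and minimize total
    squared displacement; None marks an unassigned head."""
    ns = len(spots)
    best_key, best_assign = None, ()
    # each head picks a spot index or ns (= unassigned); injective on spots
    for assign in itertools.product(range(ns + 1), repeat=len(heads)):
        used = [a for a in assign if a < ns]
        if len(used) != len(set(used)):
            continue
        cost = 0.0
        ok = True
        for h, a in zip(heads, assign):
            if a < ns:
                d2 = (h[0] - spots[a][0]) ** 2 + (h[1] - spots[a][1]) ** 2
                if d2 > max_disp ** 2:
                    ok = False
                    break
                cost += d2
        if not ok:
            continue
        # as many links as possible, then lowest total squared displacement
        key = (-len(used), cost)
        if best_key is None or key < best_key:
            best_key, best_assign = key, assign
    return best_assign


class TestLinkTracks:
    @staticmethod
    def spot(f, x, y):
        return Spot(frame=f, x=x, y=y, quality=1.0)

    def test_two_stationary_spots_two_full_tracks(self):
        frames = [[self.spot(f, 10, 10), self.spot(f, 30, 30)]
                  for f in range(10)]
        tracks = link_tracks(frames, max_disp_px=2.0)
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_displacement_cutoff_contract(self):
        frames = [[self.spot(f, 10 + f, 10)] for f in range(10)]
        assert len(link_tracks(frames, max_disp_px=3.0, max_gap=0)) == 1
        assert len(link_tracks(frames, max_disp_px=0.5, max_gap=0)) == 10

    def test_single_spot_yields_length_one_track(self):
        tracks = link_tracks([[self.spot(0, 5, 5)]], max_disp_px=2.0)
        assert len(tracks) == 1 and len(tracks[0]) == 1

    def test_gap_closing_bridges_one_missing_frame(self):
        frames = [[self.spot(0, 10, 10)], [], [self.spot(2, 10.5, 10)]]
        tracks = link_tracks(frames, max_disp_px=2.0, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].frames.tolist() == [0, 2]
        tracks = link_tracks(frames, max_disp_px=2.0, max_gap=0)
        assert len(tracks) == 2

    def test_matches_brute_force_on_small_frames(self, rng):
        # optimal-assignment equivalence on random two-frame instances with
        # ≤6 spots per frame
        for trial in range(30):
            n0 = int(rng.integers(1, 7))
            n1 = int(rng.integers(1, 7))
            f0 = [self.spot(0, *rng.uniform(0, 20, 2)) for _ in range(n0)]
            f1 = [self.spot(1, *rng.uniform(0, 20, 2)) for _ in range(n1)]
            max_disp = 6.0
            tracks = link_tracks([f0, f1], max_disp_px=max_disp, max_gap=0)
            linked_cost = 0.0
            n_links = 0
            for t in tracks:
                if len(t) == 2:
                    linked_cost += (t.x[1] - t.x[0]) ** 2 + (t.y[1] - t.y[0]) ** 2
                    n_links += 1
            heads = [(s.x, s.y) for s in f0]
            spots = [(s.x, s.y) for s in f1]
            assign = brute_force_assignment(heads, spots, max_disp)
            bf_links = sum(1 for a in assign if a < len(spots))
            bf_cost = sum((heads[i][0] - spots[a][0]) ** 2
                          + (heads[i][1] - spots[a][1]) ** 2
                          for i, a in enumerate(assign) if a < len(spots))
            assert n_links == bf_links
            assert linked_cost == pytest.approx(bf_cost, abs=1e-9)

    def test_tracking_recovers_simulated_trajectories(self):
        # well-separated simulated spots: track/ground-truth identity
        # agreement ≥ 0.95 (nearest-position correspondence per frame)
        from myddoquant.pipeline import TrackingParams, track_stack
        from myddoquant.preprocess import subtract_background
        from myddoquant.simulate import SimConfig, render_movie, simulate_dynamics
        cfg = SimConfig(field_size_px=(256, 256), n_frames=40,
                        nucleation_rate=1.5e-4, diffusion_coeff=0.002,
                        seed=19)
        truth = simulate_dynamics(cfg)
        stack = render_movie(truth, cfg)["gfp"]
        bg = subtract_background(stack)
        tracks = track_stack(bg, TrackingParams(max_disp_px=5.0, max_gap=1))
        cf = truth.cluster_frames
        by_frame = dict(tuple(cf.groupby("frame")))
        agree = total = 0
        for t in tracks:
            ids = []
            for i, f in enumerate(t.frames):
                g = by_frame.get(int(f))
                if g is None:
                    continue
                d = np.hypot(g["x_um"] / cfg.pixel_size_um - t.x[i],
                             g["y_um"] / cfg.pixel_size_um - t.y[i])
                if d.min() < 2.0:
                    ids.append(int(g.loc[d.idxmin(), "cluster_id"]))
            if not ids:
                continue
            majority = max(set(ids), key=ids.count)
            agree += ids.count(majority)
            total += len(ids)
        assert total > 0
        assert agree / total >= 0.95


class TestMeasureIntensity:
    def test_round_half_away_convention(self):
        assert round_half_away(1.5) == 2
        assert round_half_away(2.5) == 3
        assert round_half_away(0.49) == 0
        assert round_half_away(-1.5) == -2

    def test_zero_stack_gives_zero_series(self):
        track = Track(track_id=0, channel="", frames=np.arange(5),
                      x=np.full(5, 8.0), y=np.full(5, 8.0),
                      quality=np.ones(5))
        out = measure_intensity(FrameStack(np.zeros((5, 16, 16))), track)
        assert np.all(out.intensity == 0.0)

    def test_3x3_sum_matches_error_function_closed_form(self):
        # integral I, psf sigma 1 px: 3×3 sum = I·erf(1.5/σ√2)² within 0.5%
        sigma, integral = 1.0, 1000.0
        img = render_spot((32, 32), 16.0, 16.0, integral, sigma)
        track = Track(track_id=0, channel="", frames=np.array([0]),
                      x=np.array([16.0]), y=np.array([16.0]),
                      quality=np.ones(1))
        out = measure_intensity(FrameStack(img[None]), track)
        expected = integral * erf(1.5 / (sigma * math.sqrt(2))) ** 2
        assert out.intensity[0] == pytest.approx(expected, rel=0.005)

    def test_aperture_correction_recovers_full_integral(self):
        # with the subpixel window-mass correction the measured value is the
        # spot's total integral, independent of subpixel position
        sigma, integral = 0.8, 1000.0
        for x in (16.0, 16.4, 15.7):
            img = render_spot((32, 32), x, 16.2, integral, sigma)
            track = Track(track_id=0, channel="", frames=np.array([0]),
                          x=np.array([x]), y=np.array([16.2]),
                          quality=np.ones(1))
            out = measure_intensity(FrameStack(img[None]), track,
                                    aperture_sigma_px=sigma)
            assert out.intensity[0] == pytest.approx(integral, rel=0.01)

    def test_closed_gap_interpolated_and_flagged(self):
        img = render_spot((32, 32), 16.0, 16.0, 900.0, 1.0)
        stack = FrameStack(np.stack([img, img, img]))
        track = Track(track_id=0, channel="", frames=np.array([0, 2]),
                      x=np.array([16.0, 16.0]), y=np.array([16.0, 16.0]),
                      quality=np.ones(2))
        out = measure_intensity(stack, track)
        assert len(out) == 3
        assert out.flags[1] & Track.FLAG_GAP
        assert not (out.flags[0] & Track.FLAG_GAP)
        assert out.intensity[1] == pytest.approx(out.intensity[0])

    def test_border_window_clipped_and_flagged(self):
        stack = FrameStack(np.ones((1, 16, 16)))
        track = Track(track_id=0, channel="", frames=np.array([0]),
                      x=np.array([0.2]), y=np.array([8.0]),
                      quality=np.ones(1))
        out = measure_intensity(stack, track)
        assert out.flags[0] & Track.FLAG_BORDER
        assert out.intensity[0] == 6.0  # 2×3 window remains

    def test_intensity_linear_in_fluorophore_count(self):
        # noiseless puncta of 1–20 fluorophores: 3×3 sums regress on the
        # true count with R² ≥ 0.999
        from scipy.stats import linregress
        from myddoquant.simulate import SimConfig, simulate_fixed_cell
        cfg = SimConfig(field_size_px=(256, 256), nucleation_rate=0.0,
                        shot_noise=False, read_noise_sd=0.0,
                        fluor_intensity_cv=0.0, bg_level=0.0, dark_offset=0.0,
                        seed=23)
        counts = np.arange(1, 21)
        channels, truth = simulate_fixed_cell(cfg, 20, copy_numbers=counts)
        sums = []
        for row in truth.itertuples():
            track = Track(track_id=0, channel="", frames=np.array([0]),
                          x=np.array([row.x_px]), y=np.array([row.y_px]),
                          quality=np.ones(1))
            out = measure_intensity(channels["gfp"], track,
                                    aperture_sigma_px=cfg.psf_sigma_px)
            sums.append(out.intensity[0])
        fit = linregress(truth["copy_number"], sums)
        assert fit.rvalue ** 2 >= 0.999
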