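"""Simulator contracts: dynamics, rendering, calibration and fixed-cell fields."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import erf

from myddoquant.simulate import (GroundTruth, SimConfig, gaussian_mass_in_window,
                                 render_movie, simulate_calibration_field,
                                 simulate_dynamics, simulate_fixed_cell,
                                 simulate_rela_field)


def make_config(**kw):
    base = dict(field_size_px=(64, 64), n_frames=10, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_rejects_nonfinite_and_negative_parameters(self):
        with pytest.raises(ValueError):
            make_config(diffusion_coeff=-0.1)
        with pytest.raises(ValueError):
            make_config(nucleation_rate=float("nan"))
        with pytest.raises(ValueError):
            make_config(pixel_size_um=0.0)

    def test_rejects_field_smaller_than_one_corral(self):
        # 32 px × 0.15 μm = 4.8 μm < 5 μm pitch
        with pytest.raises(ValueError):
            make_config(field_size_px=(32, 32), grid_pitch_um=5.0)

    def test_rejects_too_few_frames(self):
        with pytest.raises(ValueError):
            simulate_dynamics(make_config(n_frames=1))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = make_config(grid_pitch_um=1.0, nucleation_rate=2e-4)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestDynamics:
    def test_zero_nucleation_rate_gives_empty_process(self):
        truth = simulate_dynamics(make_config(nucleation_rate=0.0))
        assert truth.n_complexes == 0
        assert len(truth.merge_events) == 0
        assert len(truth.recruitment_events) == 0

    def test_immobile_distant_complexes_never_merge(self):
        # two complexes far apart with zero diffusion cannot meet
        cfg = make_config(field_size_px=(128, 128), n_frames=200,
                          nucleation_rate=2e-5, diffusion_coeff=0.0,
                          merge_radius_um=0.3, seed=3)
        truth = simulate_dynamics(cfg)
        assert truth.n_complexes >= 2
        assert len(truth.merge_events) == 0
        # and positions are constant over time per cluster
        for _, grp in truth.cluster_frames.groupby("cluster_id"):
            assert grp["x_um"].nunique() == 1
            assert grp["y_um"].nunique() == 1

    def test_corral_confinement_exhaustive(self):
        # every emitted position of a corral-assigned complex stays inside
        # its 1 μm corral over a long movie
        cfg = make_config(field_size_px=(64, 64), n_frames=500,
                          nucleation_rate=5e-4, diffusion_coeff=0.05,
                          grid_pitch_um=1.0, seed=11)
        truth = simulate_dynamics(cfg)
        assert truth.n_complexes > 0
        assert truth.boundary_crossings() == 0
        # per-axis excursion of every trajectory bounded by the pitch
        for cid, grp in truth.complex_frames.groupby("complex_id"):
            assert grp["x_um"].max() - grp["x_um"].min() <= 1.0 + 1e-9
            assert grp["y_um"].max() - grp["y_um"].min() <= 1.0 + 1e-9

    def test_fluorophore_conservation(self):
        cfg = make_config(field_size_px=(96, 96), n_frames=60,
                          nucleation_rate=2e-3, diffusion_coeff=0.02,
                          split_rate_per_s=5e-3, seed=21)
        truth = simulate_dynamics(cfg)
        assert len(truth.merge_events) > 0  # exercise the merge path
        assert truth.fluor_conserved()
        # total fluorophores at the last frame equal 6 × live complexes
        last = truth.complex_frames[truth.complex_frames["frame"]
                                    == truth.complex_frames["frame"].max()]
        assert last["n_fluor"].sum() == 6 * len(last)

    def test_nucleation_time_precedes_first_appearance(self):
        truth = simulate_dynamics(make_config(nucleation_rate=2e-3, seed=9))
        first = truth.complex_frames.groupby("complex_id")["t_s"].min()
        for row in truth.complexes.itertuples():
            assert row.nucleation_time_s <= first[row.complex_id] + 1e-9

    def test_split_detaches_one_complex(self):
        cfg = make_config(field_size_px=(96, 96), n_frames=80,
                          nucleation_rate=1e-3, split_rate_per_s=2e-2,
                          initial_complexes_choices=(4,),
                          initial_complexes_probs=(1.0,), seed=2)
        truth = simulate_dynamics(cfg)
        assert len(truth.split_events) > 0
        for ev in truth.split_events.itertuples():
            child = truth.complex_frames[
                (truth.complex_frames["cluster_id"] == ev.child_id)]
            assert child.groupby("frame")["complex_id"].count().iloc[0] == 1

    def test_seed_determinism_of_ground_truth(self):
        cfg = make_config(nucleation_rate=2e-3, diffusion_coeff=0.02, seed=77)
        a = simulate_dynamics(cfg)
        b = simulate_dynamics(cfg)
        assert a.complex_frames.equals(b.complex_frames)
        assert a.recruitment_events.equals(b.recruitment_events)

    def test_recruitment_fraction_monotone_in_cluster_size(self):
        # ≥500 clusters of fixed sizes: the empirical fraction recruiting a
        # partner within the movie is non-decreasing in size bin
        fracs = []
        for size in (1, 3, 6):
            cfg = SimConfig(field_size_px=(512, 512), n_frames=100,
                            nucleation_rate=2.4e-4, diffusion_coeff=0.0,
                            merge_radius_um=0.0,
                            initial_complexes_choices=(size,),
                            initial_complexes_probs=(1.0,), seed=40 + size)
            truth = simulate_dynamics(cfg)
            assert len(truth.clusters) >= 500
            pos = truth.clusters["cluster_id"].isin(
                truth.recruitment_events["cluster_id"]).mean()
            fracs.append(pos)
        assert fracs[0] < fracs[1] < fracs[2]


class TestRenderMovie:
    def test_empty_truth_renders_flat_background(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, bg_level=20.0,
                                  dark_offset=100.0)
        truth = simulate_dynamics(cfg)
        channels = render_movie(truth, cfg)
        for ch in channels.values():
            assert np.all(ch.pixels == 120)

    def test_noiseless_spot_integral_matches_amplitude(self):
        # one stationary 6-fluorophore complex: integral above background
        # equals 6 × fluor_intensity_mean to 0.1% (Gaussian mass in field)
        cfg = SimConfig(field_size_px=(64, 64), n_frames=3,
                        nucleation_rate=4e-4, diffusion_coeff=0.0,
                        shot_noise=False, read_noise_sd=0.0,
                        fluor_intensity_cv=0.0, bg_level=0.0, dark_offset=0.0,
                        seed=13)
        truth = simulate_dynamics(cfg)
        assert truth.n_complexes >= 1
        channels = render_movie(truth, cfg)
        frame = channels["gfp"].pixels[-1].astype(float)
        n_spots = truth.cluster_frames[
            truth.cluster_frames["frame"] == cfg.n_frames - 1]
        expected = 6 * cfg.fluor_intensity_mean * len(n_spots)
        # quantization to integers adds at most 0.5/px of rounding error
        assert frame.sum() == pytest.approx(expected, rel=2e-3)

    def test_same_seed_gives_bit_identical_stacks(self, small_config):
        truth = simulate_dynamics(small_config)
        a = render_movie(truth, small_config)
        b = render_movie(simulate_dynamics(small_config), small_config)
        assert np.array_equal(a["gfp"].pixels, b["gfp"].pixels)
        assert np.array_equal(a["partner"].pixels, b["partner"].pixels)

    def test_noise_streams_do_not_perturb_trajectories(self, small_config):
        loud = dataclasses.replace(small_config, read_noise_sd=10.0)
        a = simulate_dynamics(small_config)
        b = simulate_dynamics(loud)
        assert a.complex_frames.equals(b.complex_frames)


class TestCalibrationField:
    def test_single_molecule_noiseless_has_one_maximum(self, noiseless_config):
        stack, truth = simulate_calibration_field(noiseless_config, 1,
                                                  n_frames=1)
        frame = stack.pixels[0].astype(float)
        assert len(truth) == 1
        peak = np.unravel_index(np.argmax(frame), frame.shape)
        assert abs(peak[1] - truth["x_px"][0]) <= 1
        assert abs(peak[0] - truth["y_px"][0]) <= 1

    def test_zero_molecules_gives_flat_background(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, bg_level=20.0,
                                  dark_offset=100.0)
        stack, truth = simulate_calibration_field(cfg, 0, n_frames=2)
        assert np.all(stack.pixels == 120)
        assert len(truth) == 0

    def test_large_sample_mean_matches_generator(self):
        # law of large numbers on the generated intensities: 10,000 draws at
        # cv=0.3 land within 2% of the configured mean
        cfg = SimConfig(field_size_px=(1200, 1200), nucleation_rate=0.0,
                        seed=31)
        stack, truth = simulate_calibration_field(cfg, 10_000, n_frames=1)
        assert len(truth) == 10_000
        assert truth["amplitude"].mean() == pytest.approx(
            cfg.fluor_intensity_mean, rel=0.02)

    def test_minimum_separation_enforced(self):
        cfg = SimConfig(field_size_px=(128, 128), nucleation_rate=0.0, seed=2)
        _stack, truth = simulate_calibration_field(cfg, 150, n_frames=1)
        xy = truth[["x_px", "y_px"]].to_numpy()
        d = np.sqrt(((xy[None] - xy[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4 * cfg.psf_sigma_px - 1e-9

    def test_unsatisfiable_density_raises(self):
        cfg = SimConfig(field_size_px=(32, 32), nucleation_rate=0.0, seed=2)
        with pytest.raises(ValueError):
            simulate_calibration_field(cfg, 5000, n_frames=1)


class TestFixedCell:
    def test_zero_noise_stain_is_exactly_linear(self):
        cfg = SimConfig(field_size_px=(256, 256), nucleation_rate=0.0,
                        stain_noise_sd=0.0, seed=6)
        copy = np.arange(1, 21)
        _channels, truth = simulate_fixed_cell(cfg, 20, copy_numbers=copy)
        resid = truth["stain_true"] - cfg.stain_slope * truth["copy_number"]
        assert np.allclose(resid, 0.0)
        assert np.corrcoef(truth["copy_number"], truth["stain_true"])[0, 1] \
            == pytest.approx(1.0)

    def test_zero_puncta_gives_background_and_empty_table(self,
                                                          noiseless_config):
        cfg = dataclasses.replace(noiseless_config, bg_level=5.0)
        channels, truth = simulate_fixed_cell(cfg, 0)
        assert len(truth) == 0
        assert np.all(channels["gfp"].pixels == 5)
        assert np.all(channels["stain"].pixels == 5)


class TestRelaField:
    def test_true_ratio_recorded_and_channels_consistent(self):
        cfg = SimConfig(field_size_px=(300, 300), nucleation_rate=0.0, seed=8)
        channels, truth = simulate_rela_field(cfg, 4, enrichment=2.0,
                                              cell_diameter_px=60,
                                              nucleus_diameter_px=30)
        assert len(truth) == 4
        assert np.all(truth["true_ratio"] == 2.0)
        offset = cfg.dark_offset + cfg.bg_level
        rela = channels["rela"].pixels[0].astype(float) - offset
        dapi = channels["dapi"].pixels[0].astype(float) - offset
        nuc = dapi > 100
        assert rela[nuc].mean() == pytest.approx(400.0, rel=0.01)


def test_gaussian_mass_closed_form():
    # independent erf evaluation of the 3×3 window mass
    sigma = 0.8
    expected = erf(1.5 / (sigma * math.sqrt(2))) ** 2
    assert gaussian_mass_in_window(sigma, 1.5) == pytest.approx(expected)
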