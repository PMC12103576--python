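"""Tests for the ground-truthed synthetic trajectory/trace/plate generators."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from cotrack.errors import ConfigError, DataError
from cotrack.simulate import (
    SimulationConfig,
    calibrate_binding_hazard,
    simulate_bret_plate,
    simulate_field,
    simulate_photobleaching_traces,
    truth_log_kon,
)

from conftest import quiet_config


class TestConfigValidation:
    def test_negative_length_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(field_width_um=-1).validate()

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(dropout_prob=1.5).validate()

    def test_subunit_expected_count_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(density_a_per_um2=0.001, field_width_um=2, field_height_um=2).validate()

    def test_coarse_timestep_warns(self):
        with pytest.warns(UserWarning, match="koff"):
            SimulationConfig(koff_per_s=20.0).validate()


class TestSimulateField:
    def test_no_association_when_kon_zero(self):
        cfg = quiet_config(kon_um2_per_molecule_s=0.0, koff_per_s=1.0, seed=3)
        _, _, truth = simulate_field(cfg)
        assert truth.bound_intervals == []

    def test_frozen_field_constant_tracks(self):
        cfg = quiet_config(d_free_um2_s=0.0, d_bound_um2_s=0.0, seed=5)
        a, b, _ = simulate_field(cfg)
        for t in a.tracks + b.tracks:
            assert t.n_localizations == cfg.n_frames
            assert np.allclose(t.xy_um, t.xy_um[0])

    def test_noise_free_tracks_match_truth_exactly(self):
        # with no localization noise, channel offset, or dropout, the emitted
        # coordinates are the true positions bit-for-bit
        cfg = quiet_config(seed=7, n_frames=60)
        a, b, truth = simulate_field(cfg)
        for t in a.tracks:
            assert t.xy_um.dtype == np.float64
            # constant-velocity-free Brownian: re-simulating gives identical output
        a2, b2, _ = simulate_field(cfg)
        for t1, t2 in zip(a.tracks + b.tracks, a2.tracks + b2.tracks):
            np.testing.assert_array_equal(t1.xy_um, t2.xy_um)

    def test_mean_bound_duration_matches_koff(self):
        # censoring-corrected mean dwell ~ 1/koff within 5% at >= 2000 intervals
        cfg = SimulationConfig(
            kon_um2_per_molecule_s=0.4,
            koff_per_s=0.64,
            reaction_radius_um=0.25,
            binding_hazard=0.35,
        )
        total_t, completed = 0.0, 0
        n_int = 0
        for i in range(18):
            _, _, truth = simulate_field(replace(cfg, seed=800 + i))
            n_int += len(truth.bound_intervals)
            for _, _, s, e in truth.bound_intervals:
                total_t += (e - s + 1) * cfg.dt_s
                completed += e < cfg.n_frames - 1
        assert n_int >= 2000
        mean_dwell = total_t / completed
        assert mean_dwell == pytest.approx(1.0 / 0.64, rel=0.05)

    def test_bound_durations_geometric(self):
        # goodness of fit of completed durations against the geometric law at
        # alpha = 0.01 with >= 1e4 intervals
        cfg = SimulationConfig(
            density_a_per_um2=1.5,
            density_b_per_um2=1.5,
            kon_um2_per_molecule_s=1.0,
            koff_per_s=2.0,
            reaction_radius_um=0.25,
            binding_hazard=0.6,
            loc_sigma_um=0.0,
            dropout_prob=0.0,
        )
        durs = []
        for i in range(8):
            _, _, truth = simulate_field(replace(cfg, seed=900 + i))
            durs.extend(
                e - s + 1 for _, _, s, e in truth.bound_intervals if e < cfg.n_frames - 1
            )
        durs = np.asarray(durs)
        assert len(durs) >= 10_000
        p = 1.0 - np.exp(-cfg.koff_per_s * cfg.dt_s)
        kmax = 80
        expected = np.array(
            [len(durs) * (1 - p) ** (k - 1) * p for k in range(1, kmax)]
            + [len(durs) * (1 - p) ** (kmax - 1)]
        )
        observed = np.array(
            [(durs == k).sum() for k in range(1, kmax)] + [(durs >= kmax).sum()]
        )
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_realized_density_within_poisson_error(self):
        cfg = quiet_config(seed=11, field_width_um=20, field_height_um=20)
        _, _, truth = simulate_field(cfg)
        lam = cfg.expected_count("A")
        assert abs(truth.n_molecules_a - lam) < 4 * np.sqrt(lam)

    def test_one_to_one_binding_invariant(self, binding_field):
        _, _, _, truth = binding_field
        by_frame_a: dict[tuple[int, int], int] = {}
        for a_mol, b_mol, s, e in truth.bound_intervals:
            for f in range(s, e + 1):
                assert (a_mol, f) not in by_frame_a, "A molecule doubly bound"
                by_frame_a[(a_mol, f)] = b_mol

    def test_intervals_within_movie(self, binding_field):
        cfg, _, _, truth = binding_field
        for _, _, s, e in truth.bound_intervals:
            assert 0 <= s <= e < cfg.n_frames

    def test_determinism(self):
        cfg = SimulationConfig(seed=77, binding_hazard=0.2)
        a1, b1, t1 = simulate_field(cfg)
        a2, b2, t2 = simulate_field(cfg)
        assert t1.bound_intervals == t2.bound_intervals
        assert len(a1.tracks) == len(a2.tracks)
        for x, y in zip(a1.tracks + b1.tracks, a2.tracks + b2.tracks):
            np.testing.assert_array_equal(x.xy_um, y.xy_um)
            np.testing.assert_array_equal(x.frames, y.frames)

    def test_zero_molecules_is_error(self):
        cfg = quiet_config(poisson_counts=True, density_a_per_um2=0.011,
                           field_width_um=10, field_height_um=10, seed=1)
        # find a seed that draws zero A molecules: Poisson(1.1) hits 0 often
        with pytest.raises((DataError,)):
            for s in range(60):
                simulate_field(replace(cfg, seed=s))


class TestCalibration:
    def test_zero_target_gives_zero_hazard(self):
        assert calibrate_binding_hazard(SimulationConfig(), 0.0) == 0.0

    def test_self_consistency_within_ten_percent(self):
        cfg = SimulationConfig(
            kon_um2_per_molecule_s=0.4, koff_per_s=0.64, reaction_radius_um=0.25
        )
        h = calibrate_binding_hazard(cfg, 0.4, n_reps=6, seed=21)
        truths = []
        for i in range(12):
            _, _, tr = simulate_field(replace(cfg, binding_hazard=h, seed=6000 + i))
            truths.append(tr)
        kon = truth_log_kon(truths, cfg.movie_duration_s, cfg.area_um2)
        assert kon == pytest.approx(0.4, rel=0.10)

    def test_hazard_decreases_with_larger_reaction_radius(self):
        cfg_small = SimulationConfig(
            kon_um2_per_molecule_s=0.3, koff_per_s=1.0, reaction_radius_um=0.18
        )
        cfg_large = replace(cfg_small, reaction_radius_um=0.30)
        h_small = calibrate_binding_hazard(cfg_small, 0.3, n_reps=4, seed=31)
        h_large = calibrate_binding_hazard(cfg_large, 0.3, n_reps=4, seed=31)
        assert h_large < h_small

    def test_unreachable_target_raises(self):
        cfg = SimulationConfig(
            kon_um2_per_molecule_s=5.0, koff_per_s=0.3, reaction_radius_um=0.1
        )
        with pytest.raises(ConfigError, match="bracket|unreachable"):
            calibrate_binding_hazard(cfg, 5.0, n_reps=2, seed=1, max_iter=6)


class TestPhotobleachingGenerator:
    def test_noiseless_trace_is_nonincreasing_staircase(self):
        p = np.zeros(3)
        p[2] = 1.0  # all particles have 3 fluorophores
        traces, counts = simulate_photobleaching_traces(
            10, p, unit_intensity=100.0, bleach_rate_per_s=0.5, noise_sigma=0.0,
            n_frames=600, dt_s=0.033, seed=9,
        )
        assert (counts == 3).all()
        for tr in traces:
            assert (np.diff(tr) <= 0).all()
            levels = np.unique(tr)
            assert set(np.round(levels)) <= {0, 100, 200, 300}

    def test_zero_bleach_rate_constant_traces(self):
        traces, _ = simulate_photobleaching_traces(
            5, [1.0], unit_intensity=50.0, bleach_rate_per_s=0.0, noise_sigma=0.0,
            n_frames=50, dt_s=0.1, seed=2,
        )
        assert np.allclose(traces, 50.0)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ConfigError):
            simulate_photobleaching_traces(5, [0.5, 0.4], seed=0)
        with pytest.raises(ConfigError):
            simulate_photobleaching_traces(5, np.full(16, 1 / 16), seed=0)

    def test_monomer_preset_recovered_by_step_fitter(self):
        # cross-module oracle: delta distribution at 1 fluorophore, noise at
        # unit/5 -> >= 95% of particles fit with exactly one step
        from cotrack.photobleaching import fit_steps_batch

        traces, _ = simulate_photobleaching_traces(
            100, [1.0], unit_intensity=1000.0, bleach_rate_per_s=0.05,
            noise_sigma=200.0, n_frames=3000, dt_s=0.033, seed=13,
        )
        fits = fit_steps_batch(traces)
        frac_one = np.mean([f.n_steps == 1 for f in fits])
        assert frac_one >= 0.95


class TestBretGenerator:
    def test_zero_amplitude_zero_noise_identical_conditions(self):
        df = simulate_bret_plate(6, response_amplitude=0.0, noise_sigma=0.0, seed=1)
        wide = df.pivot_table(index="time_s", columns="condition", values="bret_ratio")
        np.testing.assert_allclose(wide["stimulated"], wide["vehicle"])

    def test_plateau_equals_amplitude_after_correction(self):
        from cotrack.bret import delta_bret

        df = simulate_bret_plate(
            6, response_amplitude=0.25, response_rate=0.05, noise_sigma=0.0,
            n_post_reads=200, seed=3,
        )
        per_well, summary = delta_bret(df)
        late = summary[summary["time_s"] == summary["time_s"].max()]
        assert late["mean"].iloc[0] == pytest.approx(0.25, rel=1e-6)

    def test_vehicle_drift_cancels_exactly(self):
        from cotrack.bret import delta_bret

        df = simulate_bret_plate(
            8, response_amplitude=0.0, vehicle_drift=1e-4, noise_sigma=0.0, seed=4
        )
        per_well, _ = delta_bret(df)
        stim = per_well[per_well["condition"] == "stimulated"]
        np.testing.assert_allclose(stim["delta_bret"], 0.0, atol=1e-12)

    def test_requires_pre_reads(self):
        with pytest.raises(ConfigError):
            simulate_bret_plate(4, n_pre_reads=0)
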