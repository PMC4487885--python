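"""Reduced network: connectivity, geometry, dynamics, forward model, drive."""

import numpy as np
import pytest

from ripplesim import (
    ConfigError,
    CurrentRecord,
    GeometryError,
    NetworkConfig,
    ParameterError,
    SchedulingError,
    build_network,
    calibrate_noise_rate,
    compute_lfp,
    constant_drive,
    make_sharp_wave_schedule,
    place_cells,
    run_simulation,
)
from ripplesim.network import AMPA_NOISE, Geometry


class TestBuildNetwork:
    def test_default_gaba_contact_count_is_all_to_all(self):
        net = build_network(NetworkConfig())
        assert net.n_gaba_contacts == 20 * 3080

    def test_ampa_fan_in_ten_per_basket_mean_fan_out(self):
        net = build_network(NetworkConfig())
        assert net.w_ampa.sum(axis=1).tolist() == [10] * 20
        assert net.w_ampa.sum() / 80 == pytest.approx(2.5)  # per activated pyr

    def test_exact_count_inhibition_removal(self):
        cfg = NetworkConfig(inhibition_removed_fraction=0.9)
        net = build_network(cfg)
        assert net.n_gaba_contacts == 20 * 3080 - round(0.9 * 20 * 3080)
        assert net.n_gaba_contacts == 6160

    def test_infeasible_fan_in_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(n_pyr_activated=5)

    def test_gap_ring_nearest_neighbors(self):
        net = build_network(NetworkConfig())
        degree = np.zeros(20)
        for i, j in net.gap_pairs:
            degree[i] += 1
            degree[j] += 1
        assert (degree == 2).all()

    def test_connectivity_deterministic_given_seed(self):
        a = build_network(NetworkConfig(seed=3, inhibition_removed_fraction=0.5))
        b = build_network(NetworkConfig(seed=3, inhibition_removed_fraction=0.5))
        assert np.array_equal(a.w_gaba, b.w_gaba)
        assert np.array_equal(a.w_ampa, b.w_ampa)


class TestGeometry:
    def test_distance_invariants_full_population(self):
        geo = place_cells(NetworkConfig())
        d = geo.distances
        assert len(d) == 3100
        assert d.min() == pytest.approx(50.0, abs=0.5)
        assert d.max() == pytest.approx(215.0, abs=0.5)

    def test_distance_invariants_scaled_population(self):
        geo = place_cells(NetworkConfig().scaled(300))
        d = geo.distances
        assert len(d) == 400
        assert d.min() == pytest.approx(50.0, abs=0.5)
        assert d.max() == pytest.approx(215.0, abs=0.5)

    def test_two_layers_25um_apart(self):
        geo = place_cells(NetworkConfig())
        z = np.unique(geo.positions[:, 2])
        assert np.allclose(z, [50.0, 75.0])


class TestForwardModel:
    @staticmethod
    def record(currents, weights=None, fs=10_000.0):
        currents = np.atleast_2d(np.asarray(currents, dtype=float))
        w = np.ones(currents.shape[0]) if weights is None else np.asarray(weights)
        return CurrentRecord(currents, w, fs)

    @staticmethod
    def geometry(distances_um):
        pos = np.column_stack(
            [np.zeros(len(distances_um)), np.zeros(len(distances_um)), distances_um]
        )
        return Geometry(positions=pos, electrode=np.zeros(3))

    def test_single_point_source_closed_form(self):
        # 1 nA at 100 μm with rho = 351 Ω·cm: V = rho*I/(4 pi r) ~= 2.79 μV
        lfp = compute_lfp(self.record([[1.0]]), self.geometry([100.0]))
        expected = 351.0 * 1e-9 / (4 * np.pi * 100e-6) / 100.0 * 1e6  # SI, in μV
        assert lfp.samples[0] == pytest.approx(expected, rel=1e-12)
        assert lfp.samples[0] == pytest.approx(2.793, abs=0.001)

    def test_two_equal_sources_double_the_potential(self):
        one = compute_lfp(self.record([[1.0]]), self.geometry([100.0]))
        two = compute_lfp(self.record([[1.0], [1.0]]), self.geometry([100.0, 100.0]))
        assert two.samples[0] == pytest.approx(2 * one.samples[0])

    def test_inverse_distance_law(self):
        near = compute_lfp(self.record([[1.0]]), self.geometry([100.0]))
        far = compute_lfp(self.record([[1.0]]), self.geometry([200.0]))
        assert near.samples[0] == pytest.approx(2 * far.samples[0])

    def test_linearity_in_the_current_record(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(3, 50)), rng.normal(size=(3, 50))
        geo = self.geometry([60.0, 110.0, 190.0])
        va = compute_lfp(self.record(a), geo).samples
        vb = compute_lfp(self.record(b), geo).samples
        vab = compute_lfp(self.record(a + 2 * b), geo).samples
        assert np.allclose(vab, va + 2 * vb, atol=1e-12)

    def test_zero_distance_rejected(self):
        with pytest.raises(GeometryError):
            compute_lfp(self.record([[1.0]]), self.geometry([0.0]))

    def test_electrode_at_infinity_silences_lfp(self):
        far = compute_lfp(self.record([[1.0]]), self.geometry([1e9]))
        assert abs(far.samples[0]) < 1e-6  # 1/r decay: seven decades below 100 μm


class TestNoiseCalibration:
    def test_campbell_variance_matches_target(self):
        """Shot-noise simulation at the calibrated rate recovers the variance."""
        target = 0.05  # nA²
        lam = calibrate_noise_rate(target, AMPA_NOISE)  # events per ms
        from scipy.signal import lfilter

        rng = np.random.default_rng(0)
        dt, n = 0.01, 2_000_000
        events = rng.poisson(lam * dt, size=n).astype(float)
        # unit-peak biexponential filter as two first-order exponential stages
        tr, td = AMPA_NOISE.tau_rise, AMPA_NOISE.tau_decay
        a = lfilter([1.0], [1.0, -np.exp(-dt / tr)], events)
        b = lfilter([1.0], [1.0, -np.exp(-dt / td)], events)
        i_unit = AMPA_NOISE.g_max_nS * 65.0 * 1e-3  # nA at the -65 mV holding potential
        current = i_unit * AMPA_NOISE.norm * (b - a)
        assert np.var(current[100_000:]) == pytest.approx(target, rel=0.05)

    def test_zero_intensity_means_zero_rate(self):
        assert calibrate_noise_rate(0.0, AMPA_NOISE) == 0.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ParameterError):
            calibrate_noise_rate(-1.0, AMPA_NOISE)


class TestSharpWaveSchedule:
    def test_nominal_plateau_duration_35ms(self):
        drive = make_sharp_wave_schedule(1, 0.01, 0.35, window=500.0, seed=0)
        (start, end), = drive.events
        assert end - start == pytest.approx(35.0)

    def test_zero_onset_sigma_switches_all_cells_together(self):
        drive = make_sharp_wave_schedule(3, 0.0, 0.3, window=600.0, sigma_onset=0.0)
        switches = drive.realize_switches(50)
        assert np.allclose(switches, switches[0])

    def test_fifty_events_in_ten_seconds_are_disjoint(self):
        drive = make_sharp_wave_schedule(50, 0.01, 0.35, window=10_000.0, seed=1)
        events = np.array(drive.events)
        assert len(events) == 50
        assert (events[1:, 0] >= events[:-1, 1]).all()

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(SchedulingError):
            make_sharp_wave_schedule(50, 0.0, 1.0, window=1000.0)

    def test_onset_jitter_sd_recovered(self):
        drive = make_sharp_wave_schedule(2, 0.0, 1.0, window=2000.0, sigma_onset=7.0, seed=2)
        switches = drive.realize_switches(2000)
        onsets = switches[:, 0]
        assert np.std(onsets) == pytest.approx(7.0, rel=0.1)


class TestSimulation:
    def test_zero_noise_gives_no_spikes_and_flat_lfp(self):
        cfg = NetworkConfig(n_pyr_activated=10, n_pyr_silent=10, n_basket=4,
                            basket_ampa_fan_in=4, seed=0)
        net = build_network(cfg)
        raster, rec = run_simulation(net, constant_drive(), 300.0)
        assert sum(len(t) for t in raster.spike_times) == 0
        lfp = compute_lfp(rec, net.geometry)
        assert np.max(np.abs(lfp.samples[2000:])) < 0.05  # after settling

    def test_silent_cells_never_spike_under_drive(self):
        cfg = NetworkConfig(n_pyr_activated=20, n_pyr_silent=30, n_basket=4,
                            basket_ampa_fan_in=4, seed=1)
        net = build_network(cfg)
        raster, _ = run_simulation(net, constant_drive(pyr_intensity=0.3), 400.0)
        assert all(len(t) == 0 for t in raster.by_role("silent_pyr"))
        assert sum(len(t) for t in raster.by_role("activated_pyr")) > 0

    def test_one_pyramidal_volley_discharges_a_basket(self):
        """The feedback AMPA strength lets a single synchronous volley of the
        10 afferent pyramidal cells fire a resting basket cell."""
        from dataclasses import replace

        cfg = NetworkConfig(n_pyr_activated=10, n_pyr_silent=0, n_basket=1,
                            basket_ampa_fan_in=10, gap_neighbors=0, seed=2,
                            ampa_noise=replace(AMPA_NOISE, g_max_nS=20.0))
        net = build_network(cfg)
        # brief strong pulse to make the 10 cells fire a near-synchronous volley
        drive = make_sharp_wave_schedule(1, 0.0, 3.0, window=120.0,
                                         duration_each=10.0, sigma_onset=0.0, seed=2)
        raster, _ = run_simulation(net, drive, 120.0)
        assert sum(len(t) for t in raster.by_role("activated_pyr")) >= 8
        assert len(raster.by_role("basket")[0]) >= 1

    def test_depolarization_block_at_extreme_drive(self):
        cfg = NetworkConfig(n_pyr_activated=10, n_pyr_silent=0, n_basket=0, seed=3)
        net = build_network(cfg)
        raster, _ = run_simulation(net, constant_drive(pyr_intensity=2.0), 400.0)
        late = [t[t > 200.0] for t in raster.by_role("activated_pyr")]
        assert sum(len(t) for t in late) == 0

    def test_simulation_deterministic_given_seed(self):
        cfg = NetworkConfig(n_pyr_activated=10, n_pyr_silent=10, n_basket=4,
                            basket_ampa_fan_in=4, seed=5)
        net = build_network(cfg)
        r1, c1 = run_simulation(net, constant_drive(pyr_intensity=0.2), 200.0)
        r2, c2 = run_simulation(net, constant_drive(pyr_intensity=0.2), 200.0)
        assert all(np.array_equal(a, b) for a, b in zip(r1.spike_times, r2.spike_times))
        assert np.array_equal(c1.currents_nA, c2.currents_nA)

    def test_invalid_duration_rejected(self):
        net = build_network(NetworkConfig(n_pyr_activated=10, n_pyr_silent=0,
                                          n_basket=0, seed=0))
        with pytest.raises(ParameterError):
            run_simulation(net, constant_drive(), 0.0)
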