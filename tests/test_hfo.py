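"""Ripple/fast-ripple frame labeling, episodes, phase and modality."""

import numpy as np
import pytest

from ripplesim import (
    AsynchronousParams,
    EpisodeSet,
    LFPSignal,
    ParameterError,
    PhaseHistogram,
    SynchronousParams,
    bimodality_index,
    classify_frame,
    construct_lfp,
    detect_episodes,
    fast_ripple_occurrence_ratio,
    generate_asynchronous,
    generate_synchronous,
    make_ap_template,
    ripple_phase,
    sharp_wave_has_fast_ripple,
    spike_phase_histogram,
)
from ripplesim.errors import ShapeError
from ripplesim.hfo import Episode, load_episodes, save_episodes
from ripplesim.spectral import Spectrogram
from tests.conftest import make_tone


def synthetic_spectrogram(peak_freqs, peak_power=100.0, background=0.01):
    """Frames with a single controlled peak each (4 Hz grid, 1 ms hop)."""
    freqs = np.arange(0.0, 724.0, 4.0)
    power = np.full((len(peak_freqs), len(freqs)), background)
    for i, f in enumerate(peak_freqs):
        if f is not None:
            power[i, np.argmin(np.abs(freqs - f))] = peak_power
    times = np.arange(len(peak_freqs), dtype=float)
    return Spectrogram(times=times, freqs=freqs, power=power)


class TestFrameClassification:
    def test_single_300hz_peak_is_fast_ripple(self):
        spec = synthetic_spectrogram([300.0] * 20)
        assert classify_frame(spec, 10, power_floor_factor=0.0) == "fast_ripple"

    def test_single_200hz_peak_is_ripple(self):
        spec = synthetic_spectrogram([200.0] * 20)
        assert classify_frame(spec, 10, power_floor_factor=0.0) == "ripple"

    def test_boundary_strict_inequality_favors_ripple(self):
        freqs = np.arange(0.0, 724.0, 4.0)
        power = np.ones((5, len(freqs)))
        power[:, np.argmin(np.abs(freqs - 200))] = 1.0e3
        power[:, np.argmin(np.abs(freqs - 300))] = 0.99e3
        spec = Spectrogram(times=np.arange(5.0), freqs=freqs, power=power)
        assert classify_frame(spec, 2, power_floor_factor=0.0) == "ripple"

    def test_invariance_to_per_frame_rescaling(self):
        rng = np.random.default_rng(3)
        freqs = np.arange(0.0, 724.0, 4.0)
        power = rng.exponential(size=(50, len(freqs))) + 0.01
        spec = Spectrogram(times=np.arange(50.0), freqs=freqs, power=power)
        scales = rng.uniform(0.5, 2.0, size=50)[:, None]
        scaled = Spectrogram(times=spec.times, freqs=freqs, power=power * scales)
        from ripplesim.hfo import label_frames

        a = label_frames(spec, power_floor_factor=0.0)
        b = label_frames(scaled, power_floor_factor=0.0)
        assert list(a) == list(b)

    def test_below_floor_frames_unlabeled(self):
        spec = synthetic_spectrogram([200.0] * 10 + [None] * 90, peak_power=1000.0)
        labels = [classify_frame(spec, i) for i in range(10)]
        assert all(lab == "ripple" for lab in labels)
        assert classify_frame(spec, 50) == ""


class TestOccurrenceRatio:
    def test_all_fast_ripple_frames(self):
        spec = synthetic_spectrogram([300.0] * 10)
        assert fast_ripple_occurrence_ratio(spec) == 1.0

    def test_half_and_half(self):
        spec = synthetic_spectrogram([300.0] * 5 + [200.0] * 5)
        assert fast_ripple_occurrence_ratio(spec) == 0.5

    def test_synchronous_trains_with_moderate_jitter_stay_in_ripple_band(self):
        # per-event jitter of ~6% of the 5 ms period damps the 400/600 Hz
        # comb harmonics below the 200 Hz fundamental in nearly every frame
        ev = generate_synchronous(SynchronousParams(5.0, 0.3, 100, 5000.0), seed=3)
        sig = construct_lfp(ev, make_ap_template())
        from ripplesim.spectral import compute_spectrogram

        spec = compute_spectrogram(sig, f_max_hz=720.0)
        assert fast_ripple_occurrence_ratio(spec) < 0.01


class TestSharpWaveCall:
    def test_threshold_arithmetic(self):
        spec = synthetic_spectrogram([300.0] * 3 + [200.0] * 7)
        assert sharp_wave_has_fast_ripple(spec, (0.0, 10.0), power_floor_factor=0.0) is True  # 30% >= 25%
        spec2 = synthetic_spectrogram([300.0] * 2 + [200.0] * 8)
        assert sharp_wave_has_fast_ripple(spec2, (0.0, 10.0), power_floor_factor=0.0) is False  # 20%

    def test_zero_length_interval_rejected(self):
        spec = synthetic_spectrogram([200.0] * 10)
        with pytest.raises(ParameterError):
            sharp_wave_has_fast_ripple(spec, (5.0, 5.0))


class TestEpisodes:
    def test_block_of_fast_ripple_frames_yields_one_episode(self):
        spec = synthetic_spectrogram([None] * 30 + [300.0] * 40 + [None] * 30)
        eps = detect_episodes(spec)
        assert len(eps) == 1
        ep = eps.episodes[0]
        assert ep.label == "fast_ripple"
        assert ep.duration_ms == pytest.approx(40.0, abs=2.0)

    def test_alternating_single_frames_filtered_by_min_duration(self):
        pattern = ([300.0] + [None] * 7) * 20
        spec = synthetic_spectrogram(pattern)
        assert len(detect_episodes(spec)) == 0

    def test_asynchronous_network_yields_both_episode_types(self):
        ev = generate_asynchronous(
            AsynchronousParams(5.0, 0.1, 0.25, 100, 20_000.0), seed=7
        )
        sig = construct_lfp(ev, make_ap_template())
        from ripplesim.spectral import compute_spectrogram

        spec = compute_spectrogram(sig, f_max_hz=720.0)
        eps = detect_episodes(spec, power_floor_factor=0.0)
        fr = eps.with_label("fast_ripple")
        assert len(eps.with_label("ripple")) > 10
        assert len(fr) > 10
        durations = [e.duration_ms for e in fr]
        assert 15.0 <= np.median(durations) <= 80.0

    def test_detection_is_deterministic(self):
        spec = synthetic_spectrogram([300.0] * 20 + [200.0] * 30 + [None] * 20)
        a = detect_episodes(spec)
        b = detect_episodes(spec)
        assert a == b

    def test_text_round_trip(self, tmp_path):
        eps = EpisodeSet(
            (Episode(10.0, 45.0, "ripple"), Episode(60.0, 85.0, "fast_ripple")), 100.0
        )
        path = tmp_path / "episodes.tsv"
        save_episodes(eps, path)
        back = load_episodes(path)
        assert back.episodes == eps.episodes


class TestRipplePhase:
    def test_tone_phase_advances_2pi_per_cycle(self):
        sig = make_tone(200.0, duration_ms=2000.0)
        phase = ripple_phase(sig)
        mid = slice(5000, 15_000)
        unwrapped = np.unwrap(phase[mid])
        slope = np.polyfit(np.arange(len(unwrapped)) / sig.fs, unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 200.0, rel=0.01)

    def test_phase_zero_at_signal_peaks(self):
        # 20 kHz sampling keeps the sampled-peak offset below the tolerance
        sig = make_tone(200.0, duration_ms=2000.0, fs=20_000.0)
        phase = ripple_phase(sig)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(sig.samples[10_000:30_000])
        assert np.max(np.abs(phase[10_000:30_000][peaks])) < 0.05

    def test_amplitude_modulation_leaves_phase_ramp_unchanged(self):
        fs, n = 10_000.0, 20_000
        t = np.arange(n) / fs
        am = (1.0 + 0.5 * np.sin(2 * np.pi * 5 * t)) * np.sin(2 * np.pi * 200 * t)
        phase = ripple_phase(LFPSignal(am, fs))
        ref = np.angle(np.exp(1j * (2 * np.pi * 200 * t - np.pi / 2)))
        mid = slice(4000, 16_000)
        err = np.angle(np.exp(1j * (phase[mid] - ref[mid])))
        assert np.percentile(np.abs(err), 95) < 0.1


class TestPhaseHistogramAndModality:
    @staticmethod
    def histogram_from_phases(phases, n_bins=20):
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        counts, _ = np.histogram(np.angle(np.exp(1j * phases)), bins=edges)
        return PhaseHistogram(edges, counts.astype(float), label="x", n_episodes=1)

    def test_spikes_at_single_phase_fill_one_bin(self):
        sig = make_tone(200.0, duration_ms=2000.0)
        phase = ripple_phase(sig)
        # spikes exactly at signal peaks -> phase 0
        peaks = np.flatnonzero(
            (sig.samples[1:-1] > sig.samples[:-2]) & (sig.samples[1:-1] > sig.samples[2:])
        ) + 1
        spikes = peaks / sig.fs * 1000.0
        eps = EpisodeSet((Episode(100.0, 1900.0, "ripple"),), 2000.0)
        hist = spike_phase_histogram(spikes, phase, sig.fs, 0.0, eps, "ripple")
        # phase 0 sits on a bin edge; sampled peaks straddle the two bins
        top_two = np.sort(hist.counts)[-2:].sum()
        assert top_two > 0.95 * hist.counts.sum()

    def test_uniform_spikes_give_flat_histogram(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(11)
        # incommensurate tone frequency avoids phase-grid quantization
        sig = make_tone(203.7, duration_ms=5000.0)
        phase = ripple_phase(sig)
        spikes = rng.uniform(200.0, 4800.0, size=5000)
        eps = EpisodeSet((Episode(100.0, 4900.0, "ripple"),), 5000.0)
        hist = spike_phase_histogram(spikes, phase, sig.fs, 0.0, eps, "ripple")
        counts = hist.counts * 5000  # undo per-episode normalization
        _, p = chisquare(counts)
        assert p > 0.01

    def test_missing_label_yields_empty_flag(self):
        eps = EpisodeSet((Episode(0.0, 10.0, "ripple"),), 20.0)
        hist = spike_phase_histogram(
            np.array([5.0]), np.zeros(200), 10_000.0, 0.0, eps, "fast_ripple"
        )
        assert hist.n_episodes == 0
        assert hist.counts.sum() == 0

    def test_unimodal_cluster_scores_low(self):
        # von Mises kappa=2: harmonic ratio I2(k)/I1(k) ~= 0.43 < 0.5
        rng = np.random.default_rng(0)
        hist = self.histogram_from_phases(rng.vonmises(0.0, 2.0, 4000))
        assert bimodality_index(hist) < 0.5

    def test_antiphase_clusters_score_high(self):
        rng = np.random.default_rng(1)
        phases = np.concatenate(
            [rng.vonmises(0.0, 4.0, 2000), rng.vonmises(np.pi, 4.0, 2000)]
        )
        assert bimodality_index(self.histogram_from_phases(phases)) > 1.0

    def test_harmonic_ratio_matches_direct_fourier_oracle(self):
        rng = np.random.default_rng(2)
        phases = np.concatenate(
            [rng.vonmises(0.0, 3.0, 3000), rng.vonmises(np.pi, 3.0, 1500)]
        )
        hist = self.histogram_from_phases(phases)
        theta = hist.bin_centers
        w = hist.counts
        oracle = np.abs(np.sum(w * np.exp(-2j * theta))) / np.abs(
            np.sum(w * np.exp(-1j * theta))
        )
        assert bimodality_index(hist) == pytest.approx(oracle, rel=1e-12)

    def test_empty_histogram_rejected(self):
        hist = PhaseHistogram(np.linspace(-np.pi, np.pi, 21), np.zeros(20))
        with pytest.raises(ShapeError):
            bimodality_index(hist)

    def test_uniform_histogram_flagged_low_power(self):
        hist = PhaseHistogram(np.linspace(-np.pi, np.pi, 21), np.full(20, 5.0))
        assert bimodality_index(hist) == 0.0
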