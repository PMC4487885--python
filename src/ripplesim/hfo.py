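"""High-frequency-oscillation classification: ripple vs fast-ripple labeling,
episode segmentation, occurrence statistics, and spike-phase analysis.

Definitions (fixed throughout the package):

* ripple band: 100–250 Hz; fast-ripple band: 250–700 Hz; analysis band
  100–700 Hz.
* A spectrogram frame is a *fast ripple* when its peak power above 250 Hz
  strictly exceeds its peak power in the ripple band; otherwise it is a
  *ripple* if the 100–700 Hz peak lies in the ripple band.  Frames whose
  total 100–700 Hz power is below a floor (5x the run's median frame
  power, configurable) stay unlabeled — classification never labels
  silence.  Labels are invariant to any positive per-frame rescaling of
  power, so normalized and raw spectrograms classify identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .errors import ParameterError, ShapeError
from .lfp import LFPSignal
from .spectral import Spectrogram

RIPPLE_BAND = (100.0, 250.0)
FAST_RIPPLE_BAND = (250.0, 700.0)
ANALYSIS_BAND = (100.0, 700.0)
POWER_FLOOR_FACTOR = 5.0
MIN_EPISODE_MS = 10.0
GAP_MERGE_MS = 5.0
PHASE_BINS = 20


@dataclass(frozen=True)
class Episode:
    start_ms: float
    end_ms: float
    label: str  # "ripple" | "fast_ripple"

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class EpisodeSet:
    """Non-overlapping, time-ordered labeled intervals."""

    episodes: tuple
    duration_ms: float = 0.0

    def with_label(self, label: str) -> tuple:
        return tuple(e for e in self.episodes if e.label == label)

    def __len__(self) -> int:
        return len(self.episodes)


@dataclass(frozen=True)
class PhaseHistogram:
    """Circular spike histogram over [-π, π), averaged across episodes."""

    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    label: str = ""
    n_episodes: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _band_peaks(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame peak power in ripple / fast-ripple bands + analysis-band total."""
    rip = spec.band_mask(*RIPPLE_BAND)
    # fast-ripple band is strictly above 250 Hz
    fr = (spec.freqs > FAST_RIPPLE_BAND[0]) & (spec.freqs <= FAST_RIPPLE_BAND[1])
    ana = spec.band_mask(*ANALYSIS_BAND)
    return (
        spec.power[:, rip].max(axis=1),
        spec.power[:, fr].max(axis=1),
        spec.power[:, ana].sum(axis=1),
    )


def label_frames(
    spec: Spectrogram, power_floor_factor: float = POWER_FLOOR_FACTOR
) -> np.ndarray:
    """Label every frame: 'ripple', 'fast_ripple' or '' (below floor).

    The floor is ``power_floor_factor`` times the median analysis-band frame
    power of the run; pass 0 to disable it.
    """
    rip_peak, fr_peak, total = _band_peaks(spec)
    floor = power_floor_factor * np.median(total)
    labels = np.full(spec.n_frames, "", dtype=object)
    active = total > floor
    is_fr = fr_peak > rip_peak
    labels[active & is_fr] = "fast_ripple"
    labels[active & ~is_fr] = "ripple"
    return labels


def classify_frame(
    spec: Spectrogram, frame: int, power_floor_factor: float = POWER_FLOOR_FACTOR
) -> str:
    """Label of one frame (floor computed over the whole spectrogram)."""
    if not 0 <= frame < spec.n_frames:
        raise ParameterError(f"frame {frame} out of range")
    return str(label_frames(spec, power_floor_factor)[frame])


def fast_ripple_occurrence_ratio(spec: Spectrogram) -> float:
    """Fraction of frames whose 100–700 Hz peak frequency exceeds 250 Hz.

    Pure argmax criterion — no power floor — matching the definition of
    the fast-ripple proportion used for heterogeneity sweeps.
    """
    if spec.n_frames == 0:
        raise ParameterError("empty spectrogram")
    ana = spec.band_mask(*ANALYSIS_BAND)
    f = spec.freqs[ana]
    peak_f = f[np.argmax(spec.power[:, ana], axis=1)]
    return float(np.mean(peak_f > 250.0))


def sharp_wave_has_fast_ripple(
    spec: Spectrogram,
    interval: tuple[float, float],
    min_fraction: float = 0.25,
    power_floor_factor: float = POWER_FLOOR_FACTOR,
    min_labeled_frames: int = 5,
) -> bool:
    """True iff >= ``min_fraction`` of the classified frames inside
    ``interval`` (ms) are fast ripples.

    Classification is floor-aware, and the fraction is taken over the
    *labeled* (above-floor) frames: the event's observable duration.  The
    sub-floor ramp and decay-tail frames at the event edges neither count
    as fast ripples nor dilute the fraction.  An interval with fewer than
    ``min_labeled_frames`` classified frames is never called."""
    t_lo, t_hi = interval
    if t_hi <= t_lo:
        raise ParameterError("interval must have positive length")
    inside = (spec.times >= t_lo) & (spec.times < t_hi)
    if not inside.any():
        raise ParameterError("interval contains no spectrogram frames")
    labels = label_frames(spec, power_floor_factor)[inside]
    labeled = labels != ""
    if labeled.sum() < min_labeled_frames:
        return False
    frac = float(np.mean(labels[labeled] == "fast_ripple"))
    return frac >= min_fraction


def detect_episodes(
    spec: Spectrogram,
    power_floor_factor: float = POWER_FLOOR_FACTOR,
    min_duration_ms: float = MIN_EPISODE_MS,
    gap_merge_ms: float = GAP_MERGE_MS,
) -> EpisodeSet:
    """Segment the spectrogram into ripple / fast-ripple episodes.

    Contiguous same-label runs above the power floor are merged across gaps
    shorter than ``gap_merge_ms`` and kept if at least ``min_duration_ms``
    long.  Deterministic given the spectrogram.
    """
    labels = label_frames(spec, power_floor_factor)
    times = spec.times
    runs: list[tuple[float, float, str]] = []
    start = None
    current = ""
    for i, lab in enumerate(labels):
        if lab != current:
            if current and start is not None:
                runs.append((times[start], times[i - 1], current))
            start = i if lab else None
            current = lab
    if current and start is not None:
        runs.append((times[start], times[len(labels) - 1], current))

    merged: list[list] = []
    for s, e, lab in runs:
        if merged and merged[-1][2] == lab and s - merged[-1][1] <= gap_merge_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e, lab])
    episodes = tuple(
        Episode(s, e, lab) for s, e, lab in merged if e - s >= min_duration_ms
    )
    total = float(times[-1] - times[0]) if len(times) else 0.0
    return EpisodeSet(episodes, duration_ms=total)


def ripple_phase(lfp: LFPSignal, band: tuple[float, float] = RIPPLE_BAND) -> np.ndarray:
    """Instantaneous phase of the band-passed signal, radians in [-π, π).

    Zero-phase band-pass (4th-order Butterworth, forward-backward) followed
    by the analytic signal.  Phase 0 falls at maxima of the band-passed LFP.
    """
    n = len(lfp.samples)
    if n < int(0.1 * lfp.fs):
        raise ParameterError("signal too short for phase extraction")
    sos = butter(4, band, btype="bandpass", fs=lfp.fs, output="sos")
    filtered = sosfiltfilt(sos, lfp.samples - np.mean(lfp.samples))
    return np.angle(hilbert(filtered))


def spike_phase_histogram(
    spike_times_ms,
    phase: np.ndarray,
    phase_fs: float,
    phase_t_start: float,
    episodes: EpisodeSet,
    label: str,
    n_bins: int = PHASE_BINS,
) -> PhaseHistogram:
    """Histogram of spike phases inside episodes of a given label.

    ``spike_times_ms`` is an iterable of per-cell spike-time arrays (a
    raster) or a flat array.  Each episode's histogram is normalized to
    unit mass before averaging, so long episodes do not dominate.
    """
    if isinstance(spike_times_ms, np.ndarray) and spike_times_ms.ndim == 1:
        spikes = np.sort(spike_times_ms)
    else:
        arrays = [np.asarray(a, dtype=float) for a in spike_times_ms]
        spikes = np.sort(np.concatenate(arrays)) if arrays else np.empty(0)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    selected = episodes.with_label(label)
    if not selected:
        return PhaseHistogram(edges, np.zeros(n_bins), label=label, n_episodes=0)
    acc = np.zeros(n_bins)
    n_used = 0
    for ep in selected:
        inside = spikes[(spikes >= ep.start_ms) & (spikes < ep.end_ms)]
        if len(inside) == 0:
            continue
        idx = np.rint((inside - phase_t_start) * phase_fs / 1000.0).astype(int)
        idx = idx[(idx >= 0) & (idx < len(phase))]
        if len(idx) == 0:
            continue
        counts, _ = np.histogram(phase[idx], bins=edges)
        acc += counts / counts.sum()
        n_used += 1
    if n_used:
        acc /= n_used
    return PhaseHistogram(edges, acc, label=label, n_episodes=n_used)


def bimodality_index(hist: PhaseHistogram) -> float:
    """Ratio |c2|/|c1| of the second to first circular-harmonic magnitudes.

    Unimodal phase locking gives a strong first harmonic (ratio << 1);
    two antiphase clusters cancel the first harmonic and load the second
    (ratio > 1).
    """
    w = np.asarray(hist.counts, dtype=float)
    if w.sum() <= 0:
        raise ShapeError("empty histogram has no modality")
    theta = hist.bin_centers
    c1 = np.abs(np.sum(w * np.exp(-1j * theta)))
    c2 = np.abs(np.sum(w * np.exp(-2j * theta)))
    if c1 < 1e-12 * w.sum() and c2 < 1e-12 * w.sum():
        return 0.0  # uniform: both harmonics vanish; flagged by callers
    return float(c2 / max(c1, 1e-300))


def save_episodes(episodes: EpisodeSet, path: str | Path) -> None:
    """Write episodes as 3-column delimited text (start_ms, end_ms, label)."""
    with open(path, "w") as fh:
        fh.write("# start_ms\tend_ms\tlabel\n")
        for ep in episodes.episodes:
            fh.write(f"{ep.start_ms:.6g}\t{ep.end_ms:.6g}\t{ep.label}\n")


def load_episodes(path: str | Path) -> EpisodeSet:
    eps = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            s, e, lab = line.split()
            eps.append(Episode(float(s), float(e), lab))
    duration = max((e.end_ms for e in eps), default=0.0)
    return EpisodeSet(tuple(eps), duration_ms=duration)
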