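"""Spectral estimation: Gaussian-window spectrogram, multitaper PSD, peaks, band power.

Conventions
-----------
* Spectrograms use a sliding Gaussian taper with SD 10 ms, a 1 ms hop, and
  a 4 Hz frequency grid (zero-padded FFT).  Power is squared magnitude.
* PSDs default to Thomson's multitaper estimate (DPSS tapers, NW=4, K=7);
  a plain periodogram is available and satisfies Parseval's identity
  against the time-domain variance, which the multitaper path inherits
  approximately.
* All power spectral densities are one-sided, in μV²/Hz, so integrating
  over frequency recovers variance in μV².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.signal.windows import dpss

from .errors import ParameterError, ShapeError
from .lfp import LFPSignal

SPECTROGRAM_WINDOW_SD_MS = 10.0
SPECTROGRAM_DF_HZ = 4.0
SPECTROGRAM_HOP_MS = 1.0
MULTITAPER_NW = 4.0
MULTITAPER_K = 7
PEAK_MERGE_HZ = 8.0


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency power; ``power[i, j]`` is frame ``i``, frequency ``j``."""

    times: np.ndarray = field(repr=False)  # frame centers, ms
    freqs: np.ndarray = field(repr=False)  # Hz, 4 Hz spacing
    power: np.ndarray = field(repr=False)  # (n_frames, n_freqs), >= 0
    window_sd: float = SPECTROGRAM_WINDOW_SD_MS  # ms

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    def band_mask(self, f_lo: float, f_hi: float) -> np.ndarray:
        return (self.freqs >= f_lo) & (self.freqs <= f_hi)


@dataclass(frozen=True)
class PSDResult:
    """One-sided power spectral density, μV²/Hz."""

    freqs: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    method: str = "multitaper"

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def compute_spectrogram(
    lfp: LFPSignal,
    window_sd_ms: float = SPECTROGRAM_WINDOW_SD_MS,
    hop_ms: float = SPECTROGRAM_HOP_MS,
    df_hz: float = SPECTROGRAM_DF_HZ,
    f_max_hz: float | None = None,
) -> Spectrogram:
    """Short-time Fourier power with a Gaussian taper.

    The taper spans ±3 SD; the FFT is zero-padded to put frequency bins on
    a ``df_hz`` grid.  Frames step every ``hop_ms``.  ``f_max_hz`` discards
    bins above that frequency (memory saver for long signals; the retained
    grid is unchanged).
    """
    fs = lfp.fs
    sd_samp = window_sd_ms * fs / 1000.0
    half = int(np.round(3.0 * sd_samp))
    win_len = 2 * half + 1
    if len(lfp.samples) < 6 * sd_samp:
        raise ParameterError("signal shorter than 6 spectrogram window SDs")
    window = np.exp(-0.5 * ((np.arange(win_len) - half) / sd_samp) ** 2)
    nfft = int(np.round(fs / df_hz))
    if nfft < win_len:
        raise ParameterError(f"df={df_hz} Hz not achievable at fs={fs} Hz with this window")
    hop = max(1, int(np.round(hop_ms * fs / 1000.0)))

    x = lfp.samples
    starts = np.arange(0, len(x) - win_len + 1, hop)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep = len(freqs) if f_max_hz is None else int(np.searchsorted(freqs, f_max_hz, "right"))
    windows = np.lib.stride_tricks.sliding_window_view(x, win_len)
    power = np.empty((len(starts), keep))
    for lo in range(0, len(starts), 2048):  # chunk to bound FFT workspace
        sel = starts[lo : lo + 2048]
        spec = np.fft.rfft(windows[sel] * window, n=nfft, axis=1)[:, :keep]
        power[lo : lo + len(sel)] = np.abs(spec) ** 2
    times = lfp.t_start + (starts + half) * 1000.0 / fs
    return Spectrogram(
        times=times, freqs=freqs[:keep], power=power, window_sd=window_sd_ms
    )


def compute_psd(lfp: LFPSignal, method: str = "multitaper") -> PSDResult:
    """Power spectral density of the (detrended) full-length signal.

    ``method="multitaper"`` averages K=7 DPSS eigenspectra at NW=4;
    ``method="periodogram"`` is the boxcar periodogram and satisfies
    Parseval's identity exactly.
    """
    x = np.asarray(lfp.samples, dtype=float)
    if len(x) < 256:
        raise ParameterError("need at least 256 samples for a PSD")
    x = x - x.mean()
    n = len(x)
    fs = lfp.fs
    if method == "periodogram":
        spec = np.abs(np.fft.rfft(x)) ** 2 / (n * fs)
        spec[1 : n // 2 + n % 2] *= 2.0  # one-sided: double non-DC, non-Nyquist bins
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        return PSDResult(freqs=freqs, power=spec, method=method)
    if method != "multitaper":
        raise ParameterError(f"unknown PSD method: {method!r}")
    tapers = dpss(n, MULTITAPER_NW, Kmax=MULTITAPER_K)
    spec = np.abs(np.fft.rfft(tapers * x, axis=1)) ** 2
    psd = spec.mean(axis=0) / fs
    psd[1 : n // 2 + n % 2] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PSDResult(freqs=freqs, power=psd, method=method)


def peak_frequencies(
    psd: PSDResult, band: tuple[float, float], k: int = 2
) -> list[tuple[float, float]]:
    """The ``k`` highest-power local maxima in ``band``, descending by power.

    Peaks closer than 8 Hz are merged (the stronger survives).  A flat or
    monotone spectrum in the band yields an empty list.
    """
    f_lo, f_hi = band
    if f_lo >= f_hi:
        raise ParameterError("band must satisfy f_lo < f_hi")
    mask = (psd.freqs >= f_lo) & (psd.freqs <= f_hi)
    if not mask.any():
        raise ParameterError("band outside the PSD frequency range")
    p = psd.power[mask]
    f = psd.freqs[mask]
    idx, _ = find_peaks(p)
    if len(idx) == 0:
        return []
    order = idx[np.argsort(p[idx])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(f[i] - f[j]) >= PEAK_MERGE_HZ for j in kept):
            kept.append(i)
    kept = kept[:k]
    return [(float(f[i]), float(p[i])) for i in kept]


def dominant_frequency(psd: PSDResult, band: tuple[float, float]) -> float:
    """Argmax frequency of the PSD within ``band``, Hz."""
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not mask.any():
        raise ParameterError("band outside the PSD frequency range")
    return float(psd.freqs[mask][np.argmax(psd.power[mask])])


def band_power(psd: PSDResult, f_lo: float, f_hi: float) -> float:
    """Integrated power over [f_lo, f_hi], μV² (rectangle rule on the PSD grid)."""
    if f_lo >= f_hi:
        raise ParameterError("need f_lo < f_hi")
    mask = (psd.freqs >= f_lo) & (psd.freqs < f_hi)
    return float(np.sum(psd.power[mask]) * psd.df)


def narrowband_power(psd: PSDResult, f: float, halfwidth: float = 5.0) -> float:
    """Total power within ``halfwidth`` Hz of the nominal frequency ``f``."""
    if f - halfwidth < 0:
        raise ParameterError("narrowband window extends below 0 Hz")
    return band_power(psd, f - halfwidth, f + halfwidth)


def normalize_grid(values: np.ndarray) -> np.ndarray:
    """Normalize a power grid by its maximum (max cell becomes exactly 1)."""
    values = np.asarray(values, dtype=float)
    vmax = values.max()
    if vmax <= 0:
        raise ShapeError("grid has no positive power to normalize by")
    return values / vmax
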