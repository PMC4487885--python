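"""Constructed local field potentials: template convolution over event trains.

The LFP contributed by cell *i* is the convolution of its event train
(a sum of Dirac deltas) with a fixed waveform template; the recorded LFP is
the sum over cells.  The model is linear and time-invariant and ignores
cell position and electrode filtering by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .errors import ParameterError
from .event_generators import EventTrainSet
from .templates import WaveformTemplate, measure_fwhm

DEFAULT_FS_HZ = 10_000.0


@dataclass(frozen=True)
class LFPSignal:
    """Uniformly sampled extracellular voltage trace.

    Attributes
    ----------
    samples : ndarray, μV
    fs : float, Hz
    t_start : float, ms — time of the first sample.
    """

    samples: np.ndarray = field(repr=False)
    fs: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ParameterError("LFP samples must be finite")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times, ms."""
        return self.t_start + self.dt_ms * np.arange(len(self.samples))

    @property
    def duration_ms(self) -> float:
        return self.dt_ms * len(self.samples)


def _impulse_grid(events: EventTrainSet, fs: float, n_samples: int) -> np.ndarray:
    """Counts of events per output sample, events snapped to the grid."""
    grid = np.zeros(n_samples)
    dt_ms = 1000.0 / fs
    for train in events.trains:
        if len(train) == 0:
            continue
        idx = np.rint(np.asarray(train) / dt_ms).astype(int)
        np.add.at(grid, idx, 1.0)
    return grid


def _check_resolution(template: WaveformTemplate, fs: float) -> None:
    # require at least ~5 samples across the FWHM so the kernel is resolved
    fwhm_s = measure_fwhm(template) / 1000.0
    if fs * fwhm_s < 5.0:
        raise ParameterError(
            f"fs={fs} Hz cannot resolve a template of FWHM {fwhm_s * 1000.0} ms; "
            f"need fs >= {5.0 / fwhm_s:.0f} Hz"
        )


def _resampled_kernel(template: WaveformTemplate, fs: float) -> np.ndarray:
    """Template samples on the output grid (interpolated if dt differs)."""
    dt_ms = 1000.0 / fs
    if np.isclose(template.dt, dt_ms):
        return template.samples
    t_out = np.arange(0.0, template.duration + 0.5 * dt_ms, dt_ms)
    return np.interp(t_out, template.times - template.t0, template.samples)


def construct_lfp(
    events: EventTrainSet, template: WaveformTemplate, fs: float = DEFAULT_FS_HZ
) -> LFPSignal:
    """Superpose one template copy per event, via FFT convolution.

    Event times are snapped to the nearest output sample (error at most
    ``1/(2 fs)``).  The output window covers ``[t0, duration + t0 + support]``
    so no event's template is truncated.
    """
    _check_resolution(template, fs)
    n_grid = int(np.round(events.duration * fs / 1000.0)) + 1
    grid = _impulse_grid(events, fs, n_grid)
    kernel = _resampled_kernel(template, fs)
    samples = fftconvolve(grid, kernel)
    return LFPSignal(samples, fs, t_start=template.t0)


def brute_force_lfp(
    events: EventTrainSet, template: WaveformTemplate, fs: float = DEFAULT_FS_HZ
) -> LFPSignal:
    """Reference implementation: explicit per-event sample-wise addition.

    Same contract as :func:`construct_lfp`, intended as an independent check
    on small inputs (<= 1e4 events).
    """
    if events.n_events > 10_000:
        raise ParameterError("brute_force_lfp is for small inputs (<= 1e4 events)")
    _check_resolution(template, fs)
    n_grid = int(np.round(events.duration * fs / 1000.0)) + 1
    kernel = _resampled_kernel(template, fs)
    samples = np.zeros(n_grid + len(kernel) - 1)
    dt_ms = 1000.0 / fs
    for train in events.trains:
        for t in train:
            start = int(np.rint(t / dt_ms))
            for k in range(len(kernel)):
                samples[start + k] += kernel[k]
    return LFPSignal(samples, fs, t_start=template.t0)


def save_lfp(lfp: LFPSignal, path: str | Path) -> None:
    """Write an LFP as two-column delimited text (time_ms, uV)."""
    np.savetxt(
        path,
        np.column_stack([lfp.times, lfp.samples]),
        header=f"fs={lfp.fs!r} t_start={lfp.t_start!r}",
        fmt="%.9g",
        delimiter="\t",
    )


def load_lfp(path: str | Path) -> LFPSignal:
    """Read an LFP from delimited text.

    Accepts files written by :func:`save_lfp` (header carries fs) or plain
    two-column (time_ms, uV) files, in which case fs is inferred from the
    median time step.
    """
    with open(path) as fh:
        first = fh.readline()
    data = np.loadtxt(path, delimiter="\t" if "\t" in first or first.startswith("#") else None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ParameterError(f"{path}: expected two columns (time_ms, uV)")
    if first.startswith("#") and "fs=" in first:
        meta = dict(item.split("=", 1) for item in first.lstrip("# ").split())
        fs = float(meta["fs"])
        t_start = float(meta.get("t_start", data[0, 0]))
    else:
        dt_ms = float(np.median(np.diff(data[:, 0])))
        fs = 1000.0 / dt_ms
        t_start = float(data[0, 0])
    return LFPSignal(data[:, 1], fs, t_start)
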