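"""Extracellular LFP waveform templates for action potentials and postsynaptic potentials.

The constructed-LFP model represents every spike (AP) or inhibitory
postsynaptic potential (IPSP) seen at the electrode by a fixed voltage
waveform.  The templates here are parametric analytic shapes calibrated to
the amplitude and full-width-at-half-maximum (FWHM) of the waveforms an
extracellular electrode ~200 μm from a CA1 pyramidal cell would record:

* AP: biphasic spike-like transient, peak |V| = 0.383 μV, FWHM = 0.65 ms.
* PSP: monophasic biexponential (GABA-A kinetics, τ_rise = 1.5 ms,
  τ_decay = 8.0 ms), peak |V| = 0.0237 μV, FWHM = 15.3 ms.

The downstream results depend only on amplitude, duration and the
mono/biphasic character of the kernels, so the exact analytic family
(difference of Gaussians for the AP, biexponential for the PSP) is a free
modelling choice; both are rescaled in time and voltage so the *measured*
amplitude and FWHM hit the targets above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import ParameterError, ShapeError

AP_AMPLITUDE_UV = 0.383
AP_FWHM_MS = 0.65
PSP_AMPLITUDE_UV = 0.0237
PSP_FWHM_MS = 15.3
PSP_TAU_RISE_MS = 1.5
PSP_TAU_DECAY_MS = 8.0

# Template support is truncated where |V| drops below this fraction of peak.
_SUPPORT_FRACTION = 1e-3
# Minimum support, in units of FWHM (type invariant).
_MIN_SUPPORT_FWHM = 5.2


@dataclass(frozen=True)
class WaveformTemplate:
    """A finite-support voltage waveform used as a convolution kernel.

    Attributes
    ----------
    kind : {"ap", "psp"}
    dt : float
        Sampling interval, ms.
    samples : ndarray
        Voltage values, μV.
    t0 : float
        Time of the first sample relative to the event trigger, ms.
    """

    kind: str
    dt: float
    samples: np.ndarray = field(repr=False)
    t0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ParameterError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to the event trigger, ms."""
        return self.t0 + self.dt * np.arange(len(self.samples))

    @property
    def duration(self) -> float:
        """Support length, ms."""
        return self.dt * (len(self.samples) - 1)

    def scaled(self, factor: float) -> "WaveformTemplate":
        """Return a copy with voltages multiplied by ``factor``."""
        return WaveformTemplate(self.kind, self.dt, self.samples * factor, self.t0)


def measure_amplitude(template: WaveformTemplate) -> float:
    """Peak absolute voltage of a template, μV."""
    if len(template.samples) == 0:
        raise ShapeError("empty template")
    return float(np.max(np.abs(template.samples)))


def measure_fwhm(template: WaveformTemplate) -> float:
    """Full width at half maximum of |V|, ms.

    The width of the interval around the global |V| extremum where
    |V| >= peak/2, with linear interpolation at the two crossings.
    """
    v = np.abs(template.samples)
    if len(v) < 3:
        raise ShapeError("template too short to measure a width")
    peak_idx = int(np.argmax(v))
    half = v[peak_idx] / 2.0
    if v[0] >= half or v[-1] >= half:
        raise ShapeError("waveform never drops below half maximum")

    # walk outward from the peak to the first crossing on each side
    i = peak_idx
    while v[i] >= half:
        i -= 1
    left = i + (half - v[i]) / (v[i + 1] - v[i])
    j = peak_idx
    while v[j] >= half:
        j += 1
    right = j - (half - v[j]) / (v[j - 1] - v[j])
    return float((right - left) * template.dt)


def _ap_base_shape(t: np.ndarray | float) -> np.ndarray | float:
    """Unscaled biphasic spike shape: negative main lobe + delayed positive rebound.

    Time in arbitrary units (main-lobe Gaussian SD = 1).
    """
    return -np.exp(-0.5 * t**2) + 0.35 * np.exp(-0.5 * ((t - 1.8) / 1.8) ** 2)


def _shape_fwhm(f, peak_t: float, lo: float, hi: float) -> float:
    """FWHM of |f| around the extremum at peak_t, by root bracketing."""
    peak = abs(f(peak_t))
    g = lambda t: abs(f(t)) - peak / 2.0
    left = brentq(g, lo, peak_t)
    right = brentq(g, peak_t, hi)
    return right - left


def make_ap_template(dt: float = 0.025, *, sign: float = -1.0) -> WaveformTemplate:
    """Build the extracellular action-potential template.

    Parameters
    ----------
    dt : float
        Sampling interval, ms; must be <= 0.1 ms to resolve the 0.65 ms FWHM.
    sign : float
        Polarity of the main lobe.  Extracellular somatic spikes are
        typically negative-going at the electrode; whether the recorded
        0.383 μV peak was positive or negative is not constrained by the
        calibration targets, so the polarity is configurable.
    """
    if dt > 0.1:
        raise ParameterError(
            f"dt={dt} ms is too coarse to resolve a {AP_FWHM_MS} ms FWHM; need dt <= 0.1 ms"
        )
    if sign not in (-1.0, 1.0):
        raise ParameterError("sign must be +1 or -1")

    # analytic calibration of the base shape
    res = minimize_scalar(lambda t: -abs(_ap_base_shape(t)), bounds=(-3, 3), method="bounded")
    peak_t = float(res.x)
    base_fwhm = _shape_fwhm(_ap_base_shape, peak_t, peak_t - 4, peak_t + 4)
    stretch = AP_FWHM_MS / base_fwhm  # ms per base time unit
    gain = AP_AMPLITUDE_UV / abs(_ap_base_shape(peak_t))

    def shape_ms(t_ms):
        return gain * _ap_base_shape(t_ms / stretch + peak_t)

    # support: where |V| >= _SUPPORT_FRACTION * peak, extended to >= 5 FWHM
    tt = np.linspace(-12 * stretch, 14 * stretch, 20001)
    vv = np.abs(shape_ms(tt))
    above = tt[vv >= _SUPPORT_FRACTION * AP_AMPLITUDE_UV]
    lo, hi = float(above[0]), float(above[-1])
    deficit = _MIN_SUPPORT_FWHM * AP_FWHM_MS - (hi - lo)
    if deficit > 0:
        lo -= deficit / 2
        hi += deficit / 2

    # grid aligned so one sample sits exactly on the extremum (t=0 in ms coords)
    n_lo = int(np.ceil(-lo / dt))
    n_hi = int(np.ceil(hi / dt))
    times = dt * np.arange(-n_lo, n_hi + 1)
    # base main lobe is negative-going; flip for positive polarity
    samples = shape_ms(times) if sign < 0 else -shape_ms(times)
    return WaveformTemplate("ap", dt, samples, t0=float(times[0]))


def make_psp_template(
    dt: float = 0.025,
    tau_rise: float = PSP_TAU_RISE_MS,
    tau_decay: float = PSP_TAU_DECAY_MS,
    *,
    sign: float = 1.0,
) -> WaveformTemplate:
    """Build the extracellular (I)PSP template.

    The base shape is the biexponential ``exp(-t/τ_decay) - exp(-t/τ_rise)``.
    Both time constants are stretched by the single factor that maps the
    *default* biexponential (1.5/8.0 ms) onto the 15.3 ms target FWHM, so
    that non-default time constants preserve relative comparisons; the peak
    amplitude is held at the default 0.0237 μV.
    """
    if not (0 < tau_rise < tau_decay):
        raise ParameterError("need 0 < tau_rise < tau_decay")
    if dt > PSP_FWHM_MS / 10:
        raise ParameterError(f"dt={dt} ms too coarse for the PSP template")

    default = lambda t: np.where(
        t >= 0, np.exp(-t / PSP_TAU_DECAY_MS) - np.exp(-t / PSP_TAU_RISE_MS), 0.0
    )
    t_star = (
        PSP_TAU_RISE_MS
        * PSP_TAU_DECAY_MS
        / (PSP_TAU_DECAY_MS - PSP_TAU_RISE_MS)
        * np.log(PSP_TAU_DECAY_MS / PSP_TAU_RISE_MS)
    )
    default_fwhm = _shape_fwhm(default, t_star, 1e-9, 20 * PSP_TAU_DECAY_MS)
    stretch = PSP_FWHM_MS / default_fwhm

    td, tr = tau_decay * stretch, tau_rise * stretch
    peak_t = tr * td / (td - tr) * np.log(td / tr)
    peak_v = np.exp(-peak_t / td) - np.exp(-peak_t / tr)
    gain = sign * PSP_AMPLITUDE_UV / peak_v

    def shape_ms(t):
        return gain * np.where(t >= 0, np.exp(-t / td) - np.exp(-t / tr), 0.0)

    # truncate the decay tail at the support fraction
    hi = td * np.log(abs(peak_v) / (_SUPPORT_FRACTION * peak_v))
    fwhm_here = _shape_fwhm(lambda t: shape_ms(t), peak_t, 1e-9, hi)
    hi = max(hi, _MIN_SUPPORT_FWHM * fwhm_here)
    n = int(np.ceil(hi / dt))
    times = dt * np.arange(0, n + 1)
    return WaveformTemplate("psp", dt, shape_ms(times), t0=0.0)


def save_template(template: WaveformTemplate, path: str | Path) -> None:
    """Write a template as two-column delimited text (time_ms, voltage_uV)."""
    header = f"kind={template.kind} dt={template.dt!r} t0={template.t0!r}"
    np.savetxt(
        path,
        np.column_stack([template.times, template.samples]),
        header=header,
        fmt="%.9g",
        delimiter="\t",
    )


def load_template(path: str | Path) -> WaveformTemplate:
    """Read a template written by :func:`save_template`."""
    with open(path) as fh:
        first = fh.readline().lstrip("# ").split()
    meta = dict(item.split("=", 1) for item in first)
    data = np.loadtxt(path, delimiter="\t")
    return WaveformTemplate(
        kind=meta["kind"], dt=float(meta["dt"]), samples=data[:, 1], t0=float(meta["t0"])
    )
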