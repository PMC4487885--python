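# Methods

`ripplesim` studies how hippocampal networks generate high-frequency
oscillations (HFOs) — ripples (100–250 Hz) and fast ripples (>250 Hz) — in
extracellular local field potentials (LFPs). It contains two generative
models, a spectral-analysis layer, and a ripple/fast-ripple classifier.

## The constructed-LFP model

An LFP is modelled as a sum of stereotyped voltage waveforms triggered at
spike (AP) or inhibitory postsynaptic potential (IPSP) times:

    V_i(t) = (s_i * h)(t),     s_i(t) = Σ_j δ(t − t_ij),
    V(t)   = Σ_i V_i(t)

where `h` is the AP or PSP template. The model is linear and
time-invariant and deliberately ignores cell position and electrode
filtering, isolating what the *timing statistics* of the events can and
cannot produce.

### Templates

The templates are parametric analytic shapes calibrated so that their
*measured* peak amplitude and full width at half maximum (FWHM) equal the
values an electrode ~200 μm from a CA1 pyramidal cell would record:

| kind | shape | amplitude | FWHM |
|------|-------|-----------|------|
| AP   | difference of Gaussians (biphasic; main lobe negative by default) | 0.383 μV | 0.65 ms |
| PSP  | biexponential, GABA-A kinetics (τ_rise 1.5 ms, τ_decay 8 ms) | 0.0237 μV | 15.3 ms |

Calibration is exact: the base shape's FWHM and extremum are found by root
bracketing/golden-section on the continuous function, then time and
voltage are rescaled to the targets before sampling; a grid point is
placed on the analytic extremum so the sampled amplitude is exact.
Support is truncated where |V| < 0.1% of peak and extended to at least
5.2×FWHM. For non-default synaptic time constants the biexponential is
stretched by the *same* factor that maps the default pair onto 15.3 ms,
and the amplitude is held at 0.0237 μV, so τ sweeps compare shapes, not
calibrations.

The AP template's transfer magnitude |H(f)| is nearly flat over
100–600 Hz (0.74–1.15 relative to 200 Hz); the PSP's falls ~30× over the
same range. Whether the AP's 0.383 μV extremum is positive or negative at
the electrode is not constrained by the calibration; the default is
negative (the usual extracellular spike polarity) and configurable.

### Event generators

*Synchronous*: `t_ij = jT + N(0, σ_jitter²)` — a network clock with
per-cell, per-event Gaussian jitter. Burst index j runs from 0; origin is
arbitrary since spectra are translation invariant.

*Asynchronous*: each cell draws an intrinsic mean interval
μ_i ~ N(μ_pop, σ_μ²) once, starts at a uniform random phase, and produces
intervals N(μ_i, σ_jitter²). Nonpositive draws are redrawn; the parameter
guard μ_pop > 4·max(σ_μ, σ_jitter) keeps the redraw probability below
~3×10⁻⁵ so the Gaussian form is effectively unperturbed. Defaults follow
the study conditions: μ_pop = 5 ms (200 Hz), 100 cells for AP trains,
1500 for PSP trains.

### Convolution

Events are snapped to the output sample grid (10 kHz default; error ≤
1/(2fs)) and the impulse grid is FFT-convolved with the kernel; no
template is ever truncated at the signal edges. A brute-force per-event
adder (`brute_force_lfp`) serves as the independent oracle; the two agree
to <10⁻⁹ μV on small instances. The sampling-rate guard requires ≥5
samples per template FWHM — the AP template at the default 10 kHz has 6.5.

## The reduced biophysical network

A pyramidal–interneuron (PING) circuit: 80 *activated* pyramidal cells
receive Poisson AMPA "noise" synapses; 20 fast-spiking basket cells
inhibit **all** pyramidal cells (GABA-A: τ 1.5/8 ms, E −80 mV, 5.5 nS per
contact) and are gap-junction coupled in a nearest-neighbour ring; 3000
*silent* pyramidal cells receive only that inhibition and never spike —
they exist because their summed IPSP currents dominate the field. Each
basket cell receives AMPA feedback from 10 random activated cells (mean
fan-out 2.5 per activated cell). Inhibition removal deletes an exact
count, `round(fraction × 61600)`, of GABA contacts uniformly at random
(reproducible, no binomial scatter).

### Cell models

Single-compartment conductance-based models (densities in mS/cm²):

* **Basket** — Wang–Buzsáki fast-spiking interneuron (φ = 5), which
  sustains >400 Hz. Membrane area 10⁻⁶ cm²: basket somata are small, so
  their own currents contribute little to the LFP, as they should.
* **Activated pyramidal** — Traub–Miles soma with two modifications that
  stand in for the slower multicompartment morphology: the recovery gates
  (h, n) are slowed 0.3×, lengthening the refractory period so sustained
  firing saturates near 200–250 Hz, and an M-type adaptation current
  (g = 1.2 mS/cm²) shapes the f–I curve. Very strong drive produces
  depolarization block (Na inactivation), as in the full model.
  Area 2×10⁻⁵ cm².
* **Silent pyramidal** — passive leak + GABA conductance. Exact for cells
  that never reach threshold and ~10× cheaper. In scaled mode the 3000
  silent cells are represented by 300 carrying 10× LFP weight (flagged in
  run metadata); their currents are linear in the shared basket
  conductance trace, so this is a controlled approximation.

Integration is exponential-Euler at a fixed 0.025 ms step with exact
exponential relaxation of gating variables; a finiteness check aborts on
divergence. Spikes are upward 0 mV crossings. All noise streams derive
from one master seed.

### Noise intensity (nA²)

The drive parameter is defined operationally as the stationary variance
of the summed noise-synapse current into a cell at the resting potential.
Campbell's theorem converts a target variance σ² into a Poisson event
rate λ = σ² / (i_unit² ∫e(t)²dt) for the configured unitary conductance
(2 nS on pyramidal cells, 0.1 nS on baskets — baskets get smaller,
denser events so that drive is smooth at their small capacitance). The
shot-noise variance of the calibrated process matches the requested
intensity to within a few percent (verified by simulation in the test
suite). Because the reduced cells' input impedance differs from the
original multicompartment models, intensity *values* are not portable
between the two; the sweep grids in `experiments.py` are this package's
calibrated study conditions.

### Forward model

The extracellular potential is the point-source sum (resistivity
ρ = 351 Ω·cm):

    V(t) = ρ/(4π) Σ_j w_j I_j(t) / r_j

For a single-compartment cell the net transmembrane current equals the
negative capacitive current, so the simulation records `I_j = −C dV_j/dt`
(in nA) at 10 kHz. Units: ρ [Ω·cm], I [nA], r [μm] give
V_μV = 10·ρ·I/(4πr); 1 nA at 100 μm is 2.79 μV.

Geometry: all cells lie in two planar layers 50 and 75 μm from the
electrode (normal to its axis), on a uniform square grid truncated to a
disk, with the in-plane scale chosen so the farthest cell sits at exactly
215 μm and one cell on the axis at exactly 50 μm. Cell roles are
assigned to positions by a seeded permutation.

### Sharp waves

A sharp wave is a 35 ms plateau of elevated noise intensity; each cell's
onset and offset are jittered by N(0, 7² ms) so the population envelope
is physiological rather than hypersynchronous. Schedules place events
disjointly (error otherwise); per-cell switch times are clipped to stay
ordered. The baseline intensity between sharp waves is kept low
(0.001 nA²) so the network is quiet between events.

## Spectral analysis

* **Spectrogram**: Gaussian taper, SD 10 ms (±3 SD support), 1 ms hop,
  FFT zero-padded to a 4 Hz bin grid, power = squared magnitude.
* **PSD**: Thomson multitaper over the full window, NW = 4 with 7 DPSS
  tapers (configurable); a plain periodogram satisfies Parseval's
  identity against the time-domain variance to <1%, and PSDs are
  one-sided in μV²/Hz so band integrals are variances.
* **Peaks**: local maxima, merged within 8 Hz, ranked by power.
* **Narrowband power**: integral over f±5 Hz; grid results are
  normalized by the grid maximum.

## Ripple / fast-ripple classification

Bands: ripple 100–250 Hz, fast ripple (250, 700] Hz, analysis 100–700 Hz.
A frame is a *fast ripple* when its fast-ripple-band peak power strictly
exceeds its ripple-band peak; otherwise a ripple. Frames whose
analysis-band total power falls below a floor (5× the run's median frame
power by default, configurable; disable for continuously active signals)
stay unlabeled — classification never labels silence, and labels are
invariant to any positive per-frame rescaling. Episodes are contiguous
same-label runs, gap-merged within 5 ms, minimum duration 10 ms (one
window SD), deterministically derived from the spectrogram. A sharp wave
"contains a fast ripple" when ≥25% of its frames classify as fast
ripples under the floor-aware rule. The floor matters here twice over:
without it, the decaying tail of a sharp wave produces spurious
fast-ripple frames after the rhythm has died; with the default 5× factor,
the broadband onset/offset population transients of the reduced model
inflate the run median enough to unlabel most in-event frames. The
fraction is taken over the *labeled* (above-floor) frames — the event's
observable duration — so weak edge frames neither trigger nor dilute a
call, and an event with fewer than 5 classified frames is never called.
The sharp-wave experiment uses a 2× floor (the in-event rhythm stays
classified although onset/offset transients inflate the run median) and
scores frames only up to one window-SD before the plateau's nominal end:
closer to the edge, a frame's ±3 SD Gaussian window averages mostly
post-offset decay, whose collapsed ripple peak can spuriously lose to
residual harmonic content.

The *fast-ripple occurrence ratio* (fraction of frames whose 100–700 Hz
argmax exceeds 250 Hz) intentionally uses the raw argmax with no floor,
matching its definition as a proportion of total time.

Ripple phase is the angle of the analytic signal (Hilbert transform) of
the 100–250 Hz zero-phase band-passed LFP; phase 0 falls at band-passed
maxima. Spike-phase histograms use 20 bins over [−π, π), normalized per
episode before averaging.

### Per-episode modality analysis

The bimodality index is |c₂|/|c₁| of a histogram's circular harmonics:
below ~0.5 for a unimodal von Mises cluster, above 1 for two antiphase
clusters. In the uncoupled network experiment the antiphase-cluster
geometry drifts from episode to episode (the clusters are nearly
balanced, so the ripple-band residual that anchors the phase reference is
weak), and averaging histograms across episodes washes the bimodality
out. The episode-level analysis therefore computes the index per episode
(episodes with <200 spikes are skipped as unstable) and reports medians
per label. The underlying bicluster structure was verified independently:
inside fast-ripple episodes the pooled spike train's Fourier component at
twice the fundamental dominates the fundamental, and inside ripple
episodes the reverse holds.

## Experiment runners and problem sizes

Every figure-level experiment is a seeded, deterministic runner returning
per-grid-point means and SEMs. Canonical repetition counts are 10
simulations per grid point, 100 realizations per synchronous-grid cell,
50 sharp waves per condition, and a 20 s asynchronous run; `scale < 1`
shrinks durations and counts proportionally and marks the result
non-canonical. The test suite runs the biophysical experiments with 300
silent cells and 0.6–8 s simulations per condition, and the
synchronous-model grids with 3–5 realizations per cell; these reduced
sizes reproduce all the qualitative contrasts the full-scale runs show,
at the cost of larger sampling error on individual grid points.

Calibrated study conditions (defaults in `experiments.py`):

* basket-drive sweep: 1–5 ×10⁻⁵ nA² (gamma→fast-ripple approach;
  LFP peak frequency tracks basket rate within ~5%);
* pyramidal-drive sweep: 0.1–0.77 nA² (dominant rhythm stays ≤260 Hz
  with inhibition intact);
* sharp waves: peak 0.40 nA² (strong drive short of depolarization
  block), base 0.001 nA², 50 events at 120 ms spacing; removal grid
  (0, 0.45, 0.9) — the proportion of events containing fast ripples
  jumps across a steep transition near 50% removal and plateaus above
  it, so levels beyond the transition are not reliably ordered;
* uncoupled cluster: 0.1–0.3 nA² (rate-locked fundamental + harmonic);
  block probe at 1.5 nA²; long-run episode analysis at 0.2 nA².

## Numerical and design notes

* The f-narrowband power of a T-periodic event model scales as
  f²|H(f)|², because the event rate equals the drive frequency. "AP
  amplitude is constant with frequency" is therefore asserted on the
  per-burst amplitude √P/f ~ |H(f)| (flat within 2× for the AP template),
  while the PSP collapse is visible in both raw power (>10×) and
  per-burst amplitude (~30×).
* For independent same-rate cells (the asynchronous model), each cell's
  spike train is a Dirac comb whose 2f₀ line carries mass comparable to
  its f₀ line, and random phases across cells give no population-level
  coherence advantage at the fundamental. Consequently (i) the PSD argmax
  of a single realization can land on the 400 Hz harmonic (the package
  reports the median over realizations where a point estimate is needed),
  and (ii) the frame-level fast-ripple occurrence ratio of the
  asynchronous model has a floor of roughly 0.4 at *every* within-cell
  jitter up to 14% of the mean interval: harmonic suppression strong
  enough to push it below 1% would require |H(400)/H(200)| ≲ 0.1, which
  no waveform honoring the 0.383 μV / 0.65 ms calibration can provide.
  Long, variance-reduced spectral estimates *do* separate the
  diffusion-broadened harmonic from the fundamental, but 10 ms-SD
  spectrogram frames cannot. The heterogeneity sweep therefore shows a
  clear monotone decline of fast-ripple occurrence, not extinction.
* The synchronous model behaves differently: per-event jitter damps the
  coherent harmonic as exp(−(2πfσ)²/2), so at σ ≥ ~6% of the period the
  comb's argmax flips cleanly from the harmonic to the fundamental.
* Episode counts in the long uncoupled run depend strongly on the drive
  and the floor; they are order-of-magnitude quantities, not calibration
  targets.

## What the synthetic conditions do not capture

No theta or slower rhythms, no OLM or other interneuron classes, no
multicompartment morphologies or dendritic sink/source structure in the
constructed model, no electrode filtering, no distance weighting in the
constructed model, and no coupling between the constructed model's
"cells". Passing tests show that the implemented mechanisms reproduce
the intended network phenomena at reduced scale; they do not certify
clinical HFO detection on recorded data.
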