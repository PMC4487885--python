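"""Reduced conductance-based pyramidal–basket network with a point-source LFP.

The network mirrors the canonical CA1 ripple circuit: a small cluster of
*activated* pyramidal cells driven by Poisson synaptic noise, a gap-junction
coupled ring of fast-spiking basket cells that inhibit *every* pyramidal
cell, and a large population of *silent* pyramidal cells whose only input is
that inhibition — they never spike, but their IPSP currents dominate the
recorded field.

Cell models (single compartment, densities in mS/cm², time in ms):

* basket — Wang–Buzsáki fast-spiking interneuron (sustains > 400 Hz);
* activated pyramidal — Traub–Miles soma plus an M-type adaptation current,
  so firing saturates near ~200 Hz and very strong drive produces
  depolarization block;
* silent pyramidal — passive leak + GABA-A conductance (exact for a cell
  that never crosses threshold, and an order of magnitude cheaper).

The extracellular potential is the point-source sum
``V = ρ/(4π) Σ_j I_j / r_j`` over per-cell membrane currents.  For a single
compartment the net transmembrane current is the negative capacitive
current, ``I_j = −C dV_j/dt``, which is what the simulation records.

Noise-intensity semantics: the drive parameter (nA²) is the stationary
variance of the summed noise-synapse current into a cell at the resting
potential; :func:`calibrate_noise_rate` converts it into a Poisson event
rate for the configured unitary conductance via Campbell's theorem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .errors import ConfigError, GeometryError, IntegrationError, ParameterError, SchedulingError
from .lfp import LFPSignal

MIN_DISTANCE_UM = 50.0
MAX_DISTANCE_UM = 215.0
LAYER_SEPARATION_UM = 25.0
RHO_OHM_CM = 351.0


@dataclass(frozen=True)
class SynapseParams:
    tau_rise: float  # ms
    tau_decay: float  # ms
    e_rev: float  # mV
    g_max_nS: float  # per contact

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ParameterError("need 0 < tau_rise < tau_decay")

    @property
    def peak_time(self) -> float:
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def norm(self) -> float:
        """Scale so one event peaks at exactly g_max."""
        tp = self.peak_time
        return 1.0 / (np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))

    @property
    def sq_integral_ms(self) -> float:
        """∫ e(t)² dt of the unit-peak biexponential, ms (Campbell's theorem)."""
        tr, td = self.tau_rise, self.tau_decay
        return self.norm**2 * (td / 2 + tr / 2 - 2 * tr * td / (tr + td))


GABA = SynapseParams(tau_rise=1.5, tau_decay=8.0, e_rev=-80.0, g_max_nS=5.5)
AMPA_FEEDBACK = SynapseParams(tau_rise=0.2, tau_decay=1.0, e_rev=0.0, g_max_nS=0.1)
AMPA_NOISE = SynapseParams(tau_rise=0.2, tau_decay=1.0, e_rev=0.0, g_max_nS=2.0)
AMPA_NOISE_BASKET = SynapseParams(tau_rise=0.2, tau_decay=1.0, e_rev=0.0, g_max_nS=0.1)


@dataclass(frozen=True)
class NetworkConfig:
    """Cell counts, synapses, geometry and integration settings."""

    n_pyr_activated: int = 80
    n_pyr_silent: int = 3000
    n_basket: int = 20
    silent_weight: float = 1.0  # LFP weight per silent cell (scaled mode uses >1)
    gaba: SynapseParams = GABA
    ampa_feedback: SynapseParams = AMPA_FEEDBACK
    ampa_noise: SynapseParams = AMPA_NOISE
    ampa_noise_basket: SynapseParams = AMPA_NOISE_BASKET
    basket_ampa_fan_in: int = 10
    gap_junction_nS: float = 1.0
    gap_neighbors: int = 2
    inhibition_removed_fraction: float = 0.0
    area_pyr_cm2: float = 2.0e-5
    area_basket_cm2: float = 1.0e-6
    g_adapt_mS_cm2: float = 1.2  # M-current density on activated pyramidal cells
    rho_ohm_cm: float = RHO_OHM_CM
    dt_ms: float = 0.025
    lfp_fs_hz: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pyr_activated, self.n_pyr_silent, self.n_basket) < 0:
            raise ConfigError("cell counts must be nonnegative")
        if not 0.0 <= self.inhibition_removed_fraction <= 1.0:
            raise ConfigError("inhibition_removed_fraction must lie in [0, 1]")
        if self.rho_ohm_cm <= 0:
            raise ConfigError("rho must be positive")
        if self.n_basket > 0 and 0 < self.n_pyr_activated < self.basket_ampa_fan_in:
            raise ConfigError(
                f"each basket needs {self.basket_ampa_fan_in} distinct activated "
                f"pyramidal afferents; only {self.n_pyr_activated} available"
            )

    @property
    def n_pyr_total(self) -> int:
        return self.n_pyr_activated + self.n_pyr_silent

    @property
    def n_cells(self) -> int:
        return self.n_pyr_total + self.n_basket

    def scaled(self, n_silent: int = 300) -> "NetworkConfig":
        """Desk-scale variant: fewer silent cells, each weighted up in the LFP."""
        if n_silent <= 0 or self.n_pyr_silent % n_silent:
            raise ConfigError("n_silent must divide the full silent count")
        return replace(
            self,
            n_pyr_silent=n_silent,
            silent_weight=self.n_pyr_silent / n_silent * self.silent_weight,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class Geometry:
    """Cell coordinates (μm), electrode at the origin."""

    positions: np.ndarray = field(repr=False)  # (n_cells, 3)
    electrode: np.ndarray = field(repr=False)  # (3,)

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.positions - self.electrode, axis=1)


@dataclass(frozen=True)
class NetworkInstance:
    """A realized network: connectivity draws plus geometry."""

    config: NetworkConfig
    w_gaba: np.ndarray = field(repr=False)  # (n_pyr_total, n_basket) 0/1
    w_ampa: np.ndarray = field(repr=False)  # (n_basket, n_pyr_activated) 0/1
    gap_pairs: np.ndarray = field(repr=False)  # (n_edges, 2) basket indices
    geometry: Geometry = None

    @property
    def n_gaba_contacts(self) -> int:
        return int(self.w_gaba.sum())


@dataclass(frozen=True)
class SpikeRaster:
    """Per-cell spike times with role labels."""

    spike_times: tuple  # tuple of ndarrays, ms
    roles: tuple  # "activated_pyr" | "silent_pyr" | "basket"
    duration_ms: float

    def by_role(self, role: str) -> list[np.ndarray]:
        return [t for t, r in zip(self.spike_times, self.roles) if r == role]

    def mean_rate_hz(self, role: str) -> float:
        trains = self.by_role(role)
        if not trains:
            return 0.0
        return float(np.mean([len(t) for t in trains]) / (self.duration_ms / 1000.0))


@dataclass(frozen=True)
class CurrentRecord:
    """Per-cell membrane current sampled for the forward model."""

    currents_nA: np.ndarray = field(repr=False)  # (n_cells, n_samples)
    weights: np.ndarray = field(repr=False)  # per-cell LFP weight
    fs: float  # Hz
    t_start: float = 0.0  # ms


@dataclass(frozen=True)
class DriveSchedule:
    """Noise-intensity time course (nA²) for the two driven populations.

    ``events`` holds nominal (start_ms, end_ms) plateaus during which the
    target population's intensity is ``peak`` instead of ``base``; onset and
    offset are jittered per cell by N(0, sigma_onset²) when realized.
    """

    base_pyr: float = 0.0
    base_basket: float = 0.0
    peak: float = 0.0
    target: str = "pyr"  # population whose plateaus apply
    events: tuple = ()  # ((start, end), ...) nominal, ms
    sigma_onset: float = 0.0  # ms
    seed: int = 0

    def realize_switches(self, n_cells: int) -> np.ndarray:
        """Per-cell sorted switch times, shape (n_cells, 2*n_events)."""
        rng = np.random.default_rng(self.seed)
        if not self.events:
            return np.empty((n_cells, 0))
        nominal = np.array(self.events, dtype=float)  # (n_events, 2)
        jitter = (
            rng.normal(0.0, self.sigma_onset, size=(n_cells, nominal.shape[0], 2))
            if self.sigma_onset > 0
            else np.zeros((n_cells, nominal.shape[0], 2))
        )
        switches = nominal[None, :, :] + jitter
        # enforce per-cell ordering: offset after onset, events disjoint
        switches[:, :, 1] = np.maximum(switches[:, :, 1], switches[:, :, 0] + 0.5)
        flat = switches.reshape(n_cells, -1)
        flat = np.maximum.accumulate(flat, axis=1)
        return flat


def constant_drive(pyr_intensity: float = 0.0, basket_intensity: float = 0.0) -> DriveSchedule:
    """Time-invariant noise drive."""
    return DriveSchedule(base_pyr=pyr_intensity, base_basket=basket_intensity)


def make_sharp_wave_schedule(
    n_events: int,
    base_intensity: float,
    peak_intensity: float,
    window: float,
    duration_each: float = 35.0,
    sigma_onset: float = 7.0,
    seed: int = 0,
    target: str = "pyr",
) -> DriveSchedule:
    """Evenly spaced sharp-wave plateaus of elevated drive.

    Each event raises the target population's noise intensity to
    ``peak_intensity`` for a nominal ``duration_each`` (35 ms), with per-cell
    Gaussian onset/offset jitter (σ = ``sigma_onset``).
    """
    if n_events < 1:
        raise SchedulingError("need at least one event")
    period = window / n_events
    margin = 6.0 * sigma_onset
    if period < duration_each + margin:
        raise SchedulingError(
            f"{n_events} events of {duration_each} ms (+{margin:.0f} ms jitter margin) "
            f"do not fit disjointly in a {window} ms window"
        )
    starts = (np.arange(n_events) + 0.5) * period - duration_each / 2.0
    events = tuple((float(s), float(s + duration_each)) for s in starts)
    return DriveSchedule(
        base_pyr=base_intensity if target == "pyr" else 0.0,
        base_basket=base_intensity if target == "basket" else 0.0,
        peak=peak_intensity,
        target=target,
        events=events,
        sigma_onset=sigma_onset,
        seed=seed,
    )


def calibrate_noise_rate(
    intensity_nA2: float, syn: SynapseParams, v_hold_mV: float = -65.0
) -> float:
    """Poisson event rate (per ms) whose shot-noise current variance at
    ``v_hold_mV`` equals ``intensity_nA2``, by Campbell's theorem."""
    if intensity_nA2 < 0:
        raise ParameterError("noise intensity must be nonnegative")
    if intensity_nA2 == 0.0:
        return 0.0
    i_unit_nA = syn.g_max_nS * abs(v_hold_mV - syn.e_rev) * 1e-3  # nS·mV = pA
    return intensity_nA2 / (i_unit_nA**2 * syn.sq_integral_ms)


def place_cells(cfg: NetworkConfig) -> Geometry:
    """Two-layer planar disk of cells facing the electrode.

    The electrode sits at the origin; the near layer is 50 μm away along z,
    the far layer 25 μm behind it.  Within each layer, cells occupy a
    uniform square grid truncated to a disk (nearest-to-axis points first),
    and in-plane coordinates are scaled so that the farthest cell lies at
    exactly 215 μm.  A cell sits on the axis of the near layer, so the
    minimum distance is exactly 50 μm.
    """
    n = cfg.n_cells
    n_near = (n + 1) // 2
    layers = [(n_near, MIN_DISTANCE_UM), (n - n_near, MIN_DISTANCE_UM + LAYER_SEPARATION_UM)]
    pts = []
    for n_layer, z in layers:
        if n_layer == 0:
            continue
        k = int(np.ceil(np.sqrt(n_layer)))
        if k % 2 == 0:
            k += 1
        ax = np.arange(k) - k // 2
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        xy = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        order = np.lexsort((xy[:, 1], xy[:, 0], np.hypot(xy[:, 0], xy[:, 1])))
        chosen = xy[order[:n_layer]]
        pts.append(np.column_stack([chosen, np.full(n_layer, z)]))
    pos = np.concatenate(pts, axis=0)
    r_xy = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(divide="ignore"):
        scale = np.where(
            r_xy > 0, np.sqrt(MAX_DISTANCE_UM**2 - pos[:, 2] ** 2) / r_xy, np.inf
        )
    s = float(np.min(scale))
    if not np.isfinite(s):  # all cells on the axis (tiny networks)
        s = 1.0
    pos[:, :2] *= s
    # deterministic role->position shuffle so roles are spatially interleaved
    rng = np.random.default_rng(cfg.seed)
    pos = pos[rng.permutation(len(pos))]
    geo = Geometry(positions=pos, electrode=np.zeros(3))
    d = geo.distances
    if abs(d.min() - MIN_DISTANCE_UM) > 0.5 or (
        len(d) > 1 and abs(d.max() - MAX_DISTANCE_UM) > 0.5
    ):
        raise GeometryError(
            f"layout violates distance invariants: min={d.min():.2f}, max={d.max():.2f}"
        )
    return geo


def build_network(cfg: NetworkConfig) -> NetworkInstance:
    """Realize connectivity: all-to-all basket→pyr GABA (minus removals),
    10 activated-pyr AMPA afferents per basket, nearest-neighbour gap ring."""
    rng = np.random.default_rng(cfg.seed)
    n_pyr, n_bas, n_act = cfg.n_pyr_total, cfg.n_basket, cfg.n_pyr_activated

    w_gaba = np.ones((n_pyr, n_bas), dtype=np.float64)
    n_remove = int(round(cfg.inhibition_removed_fraction * n_pyr * n_bas))
    if n_remove:
        flat = rng.choice(n_pyr * n_bas, size=n_remove, replace=False)
        w_gaba.ravel()[flat] = 0.0

    w_ampa = np.zeros((n_bas, n_act), dtype=np.float64)
    for b in range(n_bas):
        w_ampa[b, rng.choice(n_act, size=cfg.basket_ampa_fan_in, replace=False)] = 1.0

    pairs = []
    if n_bas > 1 and cfg.gap_neighbors > 0:
        half = max(1, cfg.gap_neighbors // 2)
        for i in range(n_bas):
            for d in range(1, half + 1):
                pairs.append((i, (i + d) % n_bas))
    gap_pairs = np.array(sorted(set(map(tuple, map(sorted, pairs)))), dtype=int) if pairs else np.empty((0, 2), int)

    return NetworkInstance(
        config=cfg,
        w_gaba=w_gaba,
        w_ampa=w_ampa,
        gap_pairs=gap_pairs,
        geometry=place_cells(cfg),
    )


# ---------------------------------------------------------------------------
# membrane dynamics
# ---------------------------------------------------------------------------

def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the singularity at x=0 removed."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)), x / (1.0 - np.exp(-x / y)))
    return out


# slow-down factor on the pyramidal recovery gates (h, n): lengthens the
# refractory period so sustained firing saturates near ~200 Hz
_PYR_RECOVERY_SCALE = 0.3


def _rtm_rates(v):
    """Traub–Miles soma rate functions (pyramidal), recovery slowed."""
    s = _PYR_RECOVERY_SCALE
    am = 0.32 * _vtrap(v + 54.0, 4.0)
    bm = 0.28 * _vtrap(-(v + 27.0), 5.0)
    ah = s * 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = s * 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = s * 0.032 * _vtrap(v + 52.0, 5.0)
    bn = s * 0.5 * np.exp(-(v + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


def _wb_rates(v):
    """Wang–Buzsáki interneuron rate functions (φ = 5 folded in)."""
    am = 0.1 * _vtrap(v + 35.0, 10.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 5.0 * 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 5.0 * 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    an = 5.0 * 0.01 * _vtrap(v + 34.0, 10.0)
    bn = 5.0 * 0.125 * np.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _m_current_rates(v):
    winf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tw = 400.0 / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))
    return winf, tw


def _gate_update(x, alpha, beta, dt):
    tau = 1.0 / (alpha + beta)
    xinf = alpha * tau
    return xinf + (x - xinf) * np.exp(-dt / tau)


# pyramidal (RTM) constants
_PYR = dict(gna=100.0, gk=80.0, gl=0.1, ena=50.0, ek=-100.0, el=-67.0, c=1.0)
# basket (WB) constants
_BAS = dict(gna=35.0, gk=9.0, gl=0.1, ena=55.0, ek=-90.0, el=-65.0, c=1.0)


def run_simulation(
    net: NetworkInstance,
    drive: DriveSchedule,
    duration: float,
    record_currents: bool = True,
) -> tuple[SpikeRaster, CurrentRecord]:
    """Integrate the network for ``duration`` ms.

    Fixed-step exponential-Euler integration at ``config.dt_ms``; gating
    variables use exact relaxation toward their voltage-dependent targets.
    Poisson noise-synapse events are drawn per cell per step from streams
    derived from the master seed.  Membrane currents (−C dV/dt per cell, in
    nA) are recorded at ``config.lfp_fs_hz`` for the forward model.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    cfg = net.config
    dt = cfg.dt_ms
    n_steps = int(np.round(duration / dt))
    stride = max(1, int(np.round(1000.0 / (cfg.lfp_fs_hz * dt))))
    n_rec = n_steps // stride
    n_act, n_sil, n_bas = cfg.n_pyr_activated, cfg.n_pyr_silent, cfg.n_basket
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD1CE]))

    # --- state ---------------------------------------------------------
    v_act = _PYR["el"] + rng.uniform(-5, 5, n_act)
    am, bm, ah, bh, an, bn = _rtm_rates(v_act)
    m_act, h_act, n_gate_act = am / (am + bm), ah / (ah + bh), an / (an + bn)
    w_act, _ = _m_current_rates(v_act)

    v_sil = np.full(n_sil, _PYR["el"], dtype=float)

    v_bas = _BAS["el"] + rng.uniform(-5, 5, n_bas)
    amb, bmb, ahb, bhb, anb, bnb = _wb_rates(v_bas)
    h_bas, n_gate_bas = ahb / (ahb + bhb), anb / (anb + bnb)

    # synapse traces (rise A, decay B), one per presynaptic source
    dec_r_g, dec_d_g = np.exp(-dt / cfg.gaba.tau_rise), np.exp(-dt / cfg.gaba.tau_decay)
    dec_r_a, dec_d_a = np.exp(-dt / cfg.ampa_feedback.tau_rise), np.exp(-dt / cfg.ampa_feedback.tau_decay)
    dec_r_n, dec_d_n = np.exp(-dt / cfg.ampa_noise.tau_rise), np.exp(-dt / cfg.ampa_noise.tau_decay)
    A_gaba = np.zeros(n_bas); B_gaba = np.zeros(n_bas)
    A_ampa = np.zeros(n_act); B_ampa = np.zeros(n_act)
    A_na = np.zeros(n_act); B_na = np.zeros(n_act)  # noise onto activated pyr
    A_nb = np.zeros(n_bas); B_nb = np.zeros(n_bas)  # noise onto baskets

    # conductance conversions: nS -> mS/cm² on the target membrane
    gaba_density = cfg.gaba.g_max_nS * 1e-6 / cfg.area_pyr_cm2 * cfg.gaba.norm
    ampa_density = (
        cfg.ampa_feedback.g_max_nS * 1e-6 / cfg.area_basket_cm2 * cfg.ampa_feedback.norm
    )
    noise_density_pyr = cfg.ampa_noise.g_max_nS * 1e-6 / cfg.area_pyr_cm2 * cfg.ampa_noise.norm
    noise_density_bas = (
        cfg.ampa_noise_basket.g_max_nS * 1e-6 / cfg.area_basket_cm2 * cfg.ampa_noise_basket.norm
    )
    gap_density = cfg.gap_junction_nS * 1e-6 / cfg.area_basket_cm2

    # gap junction adjacency
    gap_adj = np.zeros((n_bas, n_bas))
    for i, j in net.gap_pairs:
        gap_adj[i, j] = gap_adj[j, i] = 1.0
    gap_degree = gap_adj.sum(axis=1)

    # noise rates from the drive schedule
    lam_pyr_base = calibrate_noise_rate(drive.base_pyr, cfg.ampa_noise)
    lam_bas_base = calibrate_noise_rate(drive.base_basket, cfg.ampa_noise_basket)
    lam_peak = calibrate_noise_rate(
        drive.peak, cfg.ampa_noise if drive.target == "pyr" else cfg.ampa_noise_basket
    )
    n_target = n_act if drive.target == "pyr" else n_bas
    switches = drive.realize_switches(n_target)
    n_switch = switches.shape[1]
    ptr = np.zeros(n_target, dtype=int)
    elevated = np.zeros(n_target, dtype=bool)
    lam_act = np.full(n_act, lam_pyr_base)
    lam_bas = np.full(n_bas, lam_bas_base)

    w_gaba_act = net.w_gaba[:n_act]
    w_gaba_sil = net.w_gaba[n_act:]

    spikes: list[list[float]] = [[] for _ in range(cfg.n_cells)]
    currents = (
        np.zeros((cfg.n_cells, n_rec), dtype=np.float32) if record_currents else None
    )
    area_vec = np.concatenate(
        [
            np.full(n_act + n_sil, cfg.area_pyr_cm2),
            np.full(n_bas, cfg.area_basket_cm2),
        ]
    )
    weights = np.concatenate(
        [np.ones(n_act), np.full(n_sil, cfg.silent_weight), np.ones(n_bas)]
    )

    prev_v_act = v_act.copy()
    prev_v_bas = v_bas.copy()

    for step in range(n_steps):
        t = step * dt

        # drive schedule switches
        if n_switch:
            active_ptr = ptr < n_switch
            due = active_ptr & (switches[np.arange(n_target), np.minimum(ptr, n_switch - 1)] <= t)
            if due.any():
                elevated[due] = ~elevated[due]
                ptr[due] += 1
                lam_target = np.where(
                    elevated,
                    lam_peak,
                    lam_pyr_base if drive.target == "pyr" else lam_bas_base,
                )
                if drive.target == "pyr":
                    lam_act = lam_target
                else:
                    lam_bas = lam_target

        # noise events
        if np.any(lam_act > 0):
            k = rng.poisson(lam_act * dt)
            A_na += k; B_na += k
        if np.any(lam_bas > 0):
            k = rng.poisson(lam_bas * dt)
            A_nb += k; B_nb += k

        # presynaptic conductance traces
        g_gaba_src = B_gaba - A_gaba  # per basket, unit-peak scale
        g_ampa_src = B_ampa - A_ampa  # per activated pyr

        # --- activated pyramidal cells ---------------------------------
        am, bm, ah, bh, an, bn = _rtm_rates(v_act)
        m_act = _gate_update(m_act, am, bm, dt)
        h_act = _gate_update(h_act, ah, bh, dt)
        n_gate_act = _gate_update(n_gate_act, an, bn, dt)
        winf, tw = _m_current_rates(v_act)
        w_act = winf + (w_act - winf) * np.exp(-dt / tw)

        g_gaba_act = gaba_density * (w_gaba_act @ g_gaba_src)
        g_noise_act = noise_density_pyr * (B_na - A_na)
        g_na = _PYR["gna"] * m_act**3 * h_act
        g_k = _PYR["gk"] * n_gate_act**4 + cfg.g_adapt_mS_cm2 * w_act
        g_tot = g_na + g_k + _PYR["gl"] + g_gaba_act + g_noise_act
        v_inf = (
            g_na * _PYR["ena"]
            + g_k * _PYR["ek"]
            + _PYR["gl"] * _PYR["el"]
            + g_gaba_act * cfg.gaba.e_rev
            + g_noise_act * cfg.ampa_noise.e_rev
        ) / g_tot
        v_act = v_inf + (v_act - v_inf) * np.exp(-g_tot * dt / _PYR["c"])

        # --- silent pyramidal cells (passive) ---------------------------
        if n_sil:
            g_gaba_sil = gaba_density * (w_gaba_sil @ g_gaba_src)
            g_tot_s = _PYR["gl"] + g_gaba_sil
            v_inf_s = (_PYR["gl"] * _PYR["el"] + g_gaba_sil * cfg.gaba.e_rev) / g_tot_s
            new_v_sil = v_inf_s + (v_sil - v_inf_s) * np.exp(-g_tot_s * dt / _PYR["c"])
        else:
            new_v_sil = v_sil

        # --- basket cells ------------------------------------------------
        amb, bmb, ahb, bhb, anb, bnb = _wb_rates(v_bas)
        m_inf_b = amb / (amb + bmb)
        h_bas = _gate_update(h_bas, ahb, bhb, dt)
        n_gate_bas = _gate_update(n_gate_bas, anb, bnb, dt)
        g_ampa_bas = ampa_density * (net.w_ampa @ g_ampa_src)
        g_noise_bas = noise_density_bas * (B_nb - A_nb)
        g_na_b = _BAS["gna"] * m_inf_b**3 * h_bas
        g_k_b = _BAS["gk"] * n_gate_bas**4
        g_gap = gap_density * gap_degree
        gap_drive = gap_density * (gap_adj @ v_bas)
        g_tot_b = g_na_b + g_k_b + _BAS["gl"] + g_ampa_bas + g_noise_bas + g_gap
        v_inf_b = (
            g_na_b * _BAS["ena"]
            + g_k_b * _BAS["ek"]
            + _BAS["gl"] * _BAS["el"]
            + g_ampa_bas * cfg.ampa_feedback.e_rev
            + g_noise_bas * cfg.ampa_noise.e_rev
            + gap_drive
        ) / g_tot_b
        v_bas = v_inf_b + (v_bas - v_inf_b) * np.exp(-g_tot_b * dt / _BAS["c"])

        # --- spikes (upward crossing of 0 mV) ----------------------------
        crossed_act = (prev_v_act < 0.0) & (v_act >= 0.0)
        if crossed_act.any():
            for i in np.nonzero(crossed_act)[0]:
                spikes[i].append(t)
            A_ampa[crossed_act] += 1.0
            B_ampa[crossed_act] += 1.0
        crossed_bas = (prev_v_bas < 0.0) & (v_bas >= 0.0)
        if crossed_bas.any():
            for i in np.nonzero(crossed_bas)[0]:
                spikes[n_act + n_sil + i].append(t)
            A_gaba[crossed_bas] += 1.0
            B_gaba[crossed_bas] += 1.0

        # decay synapse traces
        A_gaba *= dec_r_g; B_gaba *= dec_d_g
        A_ampa *= dec_r_a; B_ampa *= dec_d_a
        A_na *= dec_r_n; B_na *= dec_d_n
        A_nb *= dec_r_n; B_nb *= dec_d_n

        # --- record membrane current (−C dV/dt, in nA) -------------------
        if record_currents and step % stride == stride - 1:
            j = step // stride
            dv = np.concatenate([v_act - prev_v_act, new_v_sil - v_sil, v_bas - prev_v_bas])
            currents[:, j] = (-(dv / dt) * area_vec * 1e3).astype(np.float32)

        prev_v_act = v_act.copy()
        prev_v_bas = v_bas.copy()
        v_sil = new_v_sil

        if step % 4000 == 0:
            if not (np.all(np.isfinite(v_act)) and np.all(np.isfinite(v_bas))):
                raise IntegrationError(f"membrane potential diverged at t={t:.2f} ms")

    roles = (
        ("activated_pyr",) * n_act + ("silent_pyr",) * n_sil + ("basket",) * n_bas
    )
    raster = SpikeRaster(
        spike_times=tuple(np.asarray(s) for s in spikes),
        roles=roles,
        duration_ms=duration,
    )
    record = CurrentRecord(
        currents_nA=currents if record_currents else np.zeros((cfg.n_cells, 0), np.float32),
        weights=weights,
        fs=cfg.lfp_fs_hz,
    )
    return raster, record


def compute_lfp(
    rec: CurrentRecord, geo: Geometry, rho_ohm_cm: float = RHO_OHM_CM, fs: float | None = None
) -> LFPSignal:
    """Point-source forward model: ``V = ρ/(4π) Σ_j w_j I_j / r_j``.

    Currents in nA, distances in μm, ρ in Ω·cm give microvolts via
    ``V_μV = 10 · ρ · I / (4π r)``.  Linear in the current record.
    """
    r = geo.distances
    if rec.currents_nA.shape[0] != len(r):
        raise GeometryError("current record and geometry cover different cells")
    if np.any(r <= 0):
        raise GeometryError("a cell coincides with the electrode (r = 0)")
    coeff = 10.0 * rho_ohm_cm / (4.0 * np.pi) * rec.weights / r  # μV per nA
    samples = coeff @ rec.currents_nA
    out_fs = fs or rec.fs
    if out_fs != rec.fs:
        raise ParameterError("resampling the current record is not supported")
    return LFPSignal(samples.astype(float), rec.fs, rec.t_start)
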