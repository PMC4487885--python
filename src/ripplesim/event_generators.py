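"""Point-process event-train generators for the constructed-LFP model.

Two generative regimes are implemented:

* **Synchronous**: a "master clock" drives the whole population with period
  ``T``; each cell responds to burst *j* at time ``j*T + N(0, σ_jitter²)``.
  σ_jitter controls how tightly the population bursts are synchronized.

* **Asynchronous**: there is no clock.  Each cell *i* has an intrinsic mean
  interevent interval μ_i ~ N(μ_pop, σ_μ²) drawn once, starts at a uniformly
  random phase, and produces successive intervals N(μ_i, σ_jitter²).
  Distinct cells are completely independent; σ_μ measures between-cell rate
  heterogeneity and σ_jitter within-cell interval variability.

Event times are in milliseconds throughout.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class SynchronousParams:
    """Parameters of the synchronous (clock-driven) generator."""

    T: float  # network period, ms
    sigma_jitter: float  # per-event Gaussian jitter SD, ms
    n_cells: int
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ParameterError("period T must be positive")
        if self.sigma_jitter < 0:
            raise ParameterError("sigma_jitter must be nonnegative")
        if self.n_cells < 1 or self.duration <= 0:
            raise ParameterError("need n_cells >= 1 and duration > 0")


@dataclass(frozen=True)
class AsynchronousParams:
    """Parameters of the asynchronous (independent-renewal) generator."""

    mu_pop: float  # population mean interevent interval, ms
    sigma_mu: float  # between-cell spread of intrinsic intervals, ms
    sigma_jitter: float  # within-cell interval jitter, ms
    n_cells: int
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.mu_pop <= 0:
            raise ParameterError("mu_pop must be positive")
        if self.sigma_mu < 0 or self.sigma_jitter < 0:
            raise ParameterError("sigmas must be nonnegative")
        if self.mu_pop <= 4 * max(self.sigma_mu, self.sigma_jitter):
            raise ParameterError(
                "mu_pop must exceed 4*max(sigma_mu, sigma_jitter) to keep "
                "negative-interval redraws negligible"
            )
        if self.n_cells < 1 or self.duration <= 0:
            raise ParameterError("need n_cells >= 1 and duration > 0")


@dataclass(frozen=True)
class EventTrainSet:
    """Per-cell ordered event times with generator provenance."""

    trains: tuple  # tuple of float ndarrays, one per cell
    duration: float  # ms
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.trains)

    @property
    def n_events(self) -> int:
        return int(sum(len(t) for t in self.trains))

    def all_events(self) -> np.ndarray:
        """All event times pooled across cells, sorted."""
        if self.n_cells == 0:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))

    def subset(self, cells: Sequence[int]) -> "EventTrainSet":
        return EventTrainSet(
            tuple(self.trains[i] for i in cells), self.duration, dict(self.meta)
        )


def generate_synchronous(p: SynchronousParams, seed: int) -> EventTrainSet:
    """Draw clock-driven event trains: ``t_ij = j*T + N(0, σ_jitter²)``.

    Jitter is independent per cell and per event.  Events falling outside
    ``[0, duration)`` are discarded; each train is sorted (large jitter can
    reorder neighbouring bursts).
    """
    rng = np.random.default_rng(seed)
    # burst grid covers [0, duration] plus one period of margin each side so
    # jittered events can enter the window from either edge
    margin = int(np.ceil(5 * p.sigma_jitter / p.T)) + 1 if p.sigma_jitter else 0
    j = np.arange(-margin, int(np.floor(p.duration / p.T)) + margin + 1)
    nominal = j * p.T
    trains = []
    for _ in range(p.n_cells):
        t = nominal + rng.normal(0.0, p.sigma_jitter, size=nominal.shape) \
            if p.sigma_jitter > 0 else nominal.astype(float)
        t = np.sort(t[(t >= 0) & (t < p.duration)])
        trains.append(t)
    meta = {
        "generator": "synchronous",
        "T": p.T,
        "sigma_jitter": p.sigma_jitter,
        "seed": seed,
    }
    return EventTrainSet(tuple(trains), p.duration, meta)


def generate_asynchronous(p: AsynchronousParams, seed: int) -> EventTrainSet:
    """Draw independent renewal trains with Gaussian intervals.

    Each cell's intrinsic interval μ_i ~ N(μ_pop, σ_μ²) is drawn once
    (redrawn if nonpositive); the first event is uniform on [0, μ_i) so the
    population starts fully dephased; successive intervals are
    N(μ_i, σ_jitter²), redrawn while nonpositive.
    """
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(p.n_cells):
        mu_i = rng.normal(p.mu_pop, p.sigma_mu)
        while mu_i <= 0:
            mu_i = rng.normal(p.mu_pop, p.sigma_mu)
        # expected count plus slack; top up in the rare shortfall case
        t = float(rng.uniform(0.0, mu_i))
        events = []
        while t < p.duration:
            events.append(t)
            isi = rng.normal(mu_i, p.sigma_jitter) if p.sigma_jitter > 0 else mu_i
            while isi <= 0:
                isi = rng.normal(mu_i, p.sigma_jitter)
            t += isi
        trains.append(np.asarray(events))
    meta = {
        "generator": "asynchronous",
        "mu_pop": p.mu_pop,
        "sigma_mu": p.sigma_mu,
        "sigma_jitter": p.sigma_jitter,
        "seed": seed,
    }
    return EventTrainSet(tuple(trains), p.duration, meta)


def save_event_trains(events: EventTrainSet, path: str | Path) -> None:
    """Write trains as delimited text: columns (cell_id, time_ms)."""
    with open(path, "w") as fh:
        fh.write(f"# duration={events.duration!r}\n")
        for key, value in events.meta.items():
            fh.write(f"# {key}={value!r}\n")
        fh.write("# cell_id\ttime_ms\n")
        for i, train in enumerate(events.trains):
            for t in train:
                fh.write(f"{i}\t{t:.9g}\n")


def load_event_trains(path: str | Path) -> EventTrainSet:
    """Read trains written by :func:`save_event_trains`."""
    meta: dict = {}
    duration = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, value = body.split("=", 1)
                    try:
                        parsed = ast.literal_eval(value)
                    except (ValueError, SyntaxError):
                        parsed = value
                    if key == "duration":
                        duration = float(parsed)
                    else:
                        meta[key] = parsed
                continue
            cell, t = line.split()
            rows.append((int(cell), float(t)))
    if duration is None:
        raise ParameterError(f"{path}: missing '# duration=' header")
    n_cells = max((c for c, _ in rows), default=-1) + 1
    trains = [[] for _ in range(n_cells)]
    for cell, t in rows:
        trains[cell].append(t)
    return EventTrainSet(
        tuple(np.asarray(sorted(t)) for t in trains), duration, meta
    )
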