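"""End-to-end physics simulation of single-molecule recycling.

A molecule performs 1-D Brownian motion along the capillary axis (capillary
frame); the capillary is carried by the piezo stage (lab frame) past a fixed
Gaussian laser focus at the lab origin, so the emission rate is set by the
lab-frame offset ``x_stage + x_mol``.  Photon counts are drawn per 10 us bin
from an inhomogeneous Poisson law and fed to the same streaming matched
filter and feedback controller that process real data, closing the loop.

Frames: lab-frame molecule position = stage position + capillary-frame
position; the focus sits at the lab origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .burst import (
    BurstEvent,
    StreamingDetector,
    WSSKernel,
    background_threshold,
    make_kernel,
)
from .control import (
    CycleRecord,
    RecyclingConfig,
    RecyclingController,
    StageModel,
    StageTrajectory,
)

__all__ = [
    "TICK",
    "DiffusionModel",
    "BeamModel",
    "PhotonData",
    "GroundTruth",
    "SimulationRun",
    "propagator_pdf",
    "step_brownian",
    "emit_photons",
    "photons_from_rates",
    "run_experiment",
    "simulate_immobilized_bead",
]

#: Photon timestamp clock period: 10 ns.
TICK = 1.0e-8


@dataclass(frozen=True)
class DiffusionModel:
    """Drift--diffusion transport along the channel axis.

    The Green's function for a point release is Gaussian with mean
    ``mu(t) = v t`` and standard deviation ``sigma(t) = sqrt(2 D t)``.
    """

    D: float = 5.0e-11
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")

    def mu(self, t: float) -> float:
        return self.v * t

    def sigma(self, t: float) -> float:
        return math.sqrt(2.0 * self.D * t)


@dataclass(frozen=True)
class BeamModel:
    """Gaussian laser focus plus uniform Poisson background.

    The detected rate at transverse offset ``x`` from the focus centre is
    ``peak_rate * exp(-2 x**2 / omega0**2) + background`` (counts/s).
    """

    omega0: float = 1.0e-6
    peak_rate: float = 1.0e5
    background: float = 1.0e3

    def __post_init__(self) -> None:
        if self.omega0 <= 0 or self.peak_rate <= 0 or self.background < 0:
            raise ValueError("require omega0 > 0, peak_rate > 0, background >= 0")

    def rate(self, offset) -> np.ndarray:
        """Total detection rate (counts/s) at lab-frame offset(s) ``offset``."""
        x = np.asarray(offset, dtype=float)
        return self.peak_rate * np.exp(-2.0 * x**2 / self.omega0**2) + self.background

    def molecular_rate(self, offset) -> np.ndarray:
        x = np.asarray(offset, dtype=float)
        return self.peak_rate * np.exp(-2.0 * x**2 / self.omega0**2)


@dataclass
class PhotonData:
    """Photon stream: integer 10 ns timestamps plus binned counts.

    ``ticks`` are non-decreasing uint64 multiples of the 10 ns clock;
    ``bin_counts[k]`` counts the photons in ``[k, k+1) * bin_width``.
    """

    ticks: np.ndarray
    bin_counts: np.ndarray
    bin_width: float = 1.0e-5

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=np.uint64)
        self.bin_counts = np.asarray(self.bin_counts)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(self.ticks) > 1 and np.any(np.diff(self.ticks.astype(np.int64)) < 0):
            raise ValueError("ticks must be non-decreasing")
        if np.any(self.bin_counts < 0):
            raise ValueError("bin_counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.bin_counts)

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def arrival_times(self) -> np.ndarray:
        """Photon arrival times in seconds."""
        return self.ticks.astype(float) * TICK


@dataclass
class GroundTruth:
    """Reference trajectories for validating the analysis chain."""

    times: np.ndarray
    x_mol: np.ndarray
    x_stage: np.ndarray
    bleach_time: float | None = None
    intruder_tracks: list = field(default_factory=list)


@dataclass
class SimulationRun:
    """Closed-loop simulation output.

    Iterable as the ``(ground_truth, photons, records)`` triple; the burst
    events seen by the controller and the commanded stage trajectory are
    kept alongside for diagnostics.
    """

    ground_truth: GroundTruth
    photons: PhotonData
    records: list[CycleRecord]
    burst_events: list[BurstEvent]
    trajectory: StageTrajectory

    def __iter__(self):
        return iter((self.ground_truth, self.photons, self.records))


def propagator_pdf(x, t: float, model: DiffusionModel) -> np.ndarray:
    """Gaussian transition density for displacement ``x`` after time ``t``.

    Mean ``v t``, standard deviation ``sqrt(2 D t)``.  ``t`` must be
    positive (the ``t = 0`` limit is a point mass, not a density) and the
    model must diffuse (``D > 0``).
    """
    if t <= 0:
        raise ValueError("t must be positive; t = 0 is the point-mass initial state")
    if model.D <= 0:
        raise ValueError("the density is degenerate for D = 0")
    s = model.sigma(t)
    xr = (np.asarray(x, dtype=float) - model.mu(t)) / s
    return np.exp(-0.5 * xr**2) / (s * math.sqrt(2.0 * math.pi))


def step_brownian(x, dt: float, model: DiffusionModel, rng: np.random.Generator):
    """One Euler--Maruyama step: ``x + v dt + sqrt(2 D dt) * z``.

    ``x`` may be a scalar or an array (one independent draw per element).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, dtype=float)
    z = rng.standard_normal(x.shape)
    out = x + model.v * dt + math.sqrt(2.0 * model.D * dt) * z
    return out if out.shape else float(out)


def _uniform_ticks(
    bin_idx: np.ndarray, dt: float, rng: np.random.Generator, t0: float = 0.0
) -> np.ndarray:
    """Integer 10 ns timestamps placed uniformly within their bins.

    Pure integer arithmetic guarantees every tick stays inside its bin
    (a float rounding at the bin edge could otherwise leak into the next).
    """
    per_bin = max(1, int(round(dt / TICK)))
    offs = np.floor(rng.random(len(bin_idx)) * per_bin).astype(np.uint64)
    base = np.uint64(int(round(t0 / TICK)))
    return np.sort(base + bin_idx * np.uint64(per_bin) + offs)


def photons_from_rates(
    rates: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    t0: float = 0.0,
    bin_width: float | None = None,
) -> PhotonData:
    """Draw an inhomogeneous Poisson photon stream from per-step rates.

    Counts are Poisson with mean ``rate * dt`` per step; each photon gets a
    uniform position within its step, quantised to the 10 ns clock.  If
    ``bin_width`` exceeds ``dt`` (it must then be an integer multiple) the
    counts are aggregated into coarser bins while the ticks keep full
    resolution.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    counts = rng.poisson(rates * dt)
    total = int(counts.sum())
    idx = np.repeat(np.arange(len(counts), dtype=np.uint64), counts)
    ticks = _uniform_ticks(idx, dt, rng, t0)
    if bin_width is None or bin_width == dt:
        return PhotonData(ticks, counts.astype(np.int64), dt)
    factor = bin_width / dt
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("bin_width must be a positive integer multiple of dt")
    factor = int(round(factor))
    n_full = (len(counts) // factor) * factor
    coarse = counts[:n_full].reshape(-1, factor).sum(axis=1)
    keep = ticks < np.uint64(round((t0 + n_full * dt) / TICK))
    return PhotonData(ticks[keep], coarse.astype(np.int64), bin_width)


def emit_photons(
    relative_offset_series: np.ndarray,
    beam: BeamModel,
    dt: float,
    rng: np.random.Generator,
    t0: float = 0.0,
    bin_width: float | None = None,
    molecular_on: np.ndarray | None = None,
) -> PhotonData:
    """Photon stream for a molecule at given lab-frame offsets from the focus.

    ``molecular_on`` optionally masks the molecular term (e.g. zero after a
    photobleach); the background persists regardless.
    """
    rates = beam.molecular_rate(relative_offset_series)
    if molecular_on is not None:
        rates = rates * np.asarray(molecular_on, dtype=float)
    rates = rates + beam.background
    return photons_from_rates(rates, dt, rng, t0=t0, bin_width=bin_width)


def run_experiment(
    diff: DiffusionModel,
    beam: BeamModel,
    stage: StageModel | None = None,
    control: RecyclingConfig | None = None,
    kernel: WSSKernel | None = None,
    duration: float = 6.0,
    rng: np.random.Generator | None = None,
    *,
    threshold: float | None = None,
    x0: float = 0.0,
    bleach_time: float | None = None,
    bleach_mean_photons: float | None = None,
    intruder_rate: float = 0.0,
    intruder_offset: float = 2.0e-6,
) -> SimulationRun:
    """Closed-loop recycling simulation.

    The molecule diffuses in the capillary frame; the controller commands
    the stage; photons are generated from the lab-frame offset to the fixed
    focus and run through the *streaming* matched filter, whose events drive
    the controller exactly as on real data.  The molecule starts at ``x0``
    with the controller initialised on it (a burst has just been located).

    Photobleaching is off by default; ``bleach_time`` forces a bleach at a
    set time, while ``bleach_mean_photons`` draws an exponential photon
    budget weighted by the instantaneous excitation rate.  ``intruder_rate``
    (arrivals/s) admits independent second molecules entering the recycling
    region, ``intruder_offset`` metres from the tracked centre.

    Returns a :class:`SimulationRun`, unpackable as
    ``ground_truth, photons, records``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    stage = stage if stage is not None else StageModel()
    control = control if control is not None else RecyclingConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if kernel is None:
        kernel = make_kernel(beam.omega0 / (2.0 * stage.v_trans))
    if threshold is None:
        threshold = kernel.threshold
    if threshold is None:
        threshold = background_threshold(kernel, beam.background)
    dtw = kernel.dt_w
    n_cycles = int(math.floor(duration / control.delta_t + 1e-9))
    if n_cycles < 1:
        raise ValueError("duration shorter than one reversal delay")
    n_bin = int(round(control.delta_t / dtw))

    detector = StreamingDetector(kernel, threshold)
    ctrl = RecyclingController(control, stage, X0=x0 / stage.unit_scale)

    sig_step = math.sqrt(2.0 * diff.D * dtw)
    budget = (
        rng.exponential(bleach_mean_photons)
        if bleach_mean_photons is not None
        else math.inf
    )
    x = float(x0)
    cum_excitation = 0.0
    actual_bleach: float | None = None
    intruders: list[float] = []
    intruder_tracks: list[tuple[np.ndarray, np.ndarray]] = []

    events: list[BurstEvent] = []
    ev_ptr = 0
    count_chunks: list[np.ndarray] = []
    tick_chunks: list[np.ndarray] = []
    xmol_chunks: list[np.ndarray] = []
    xstage_chunks: list[np.ndarray] = []

    for _ in range(n_cycles):
        tp = ctrl.tp
        t = tp + np.arange(n_bin) * dtw
        steps = rng.standard_normal(n_bin) * sig_step + diff.v * dtw
        pos = x + np.concatenate(([0.0], np.cumsum(steps[:-1])))
        x = pos[-1] + steps[-1]
        sp = ctrl.stage_position_m(t)
        offset = sp + pos
        mol = beam.molecular_rate(offset)

        if actual_bleach is not None:
            mol[:] = 0.0
        elif bleach_time is not None and bleach_time <= t[-1]:
            k = int(np.searchsorted(t, bleach_time))
            mol[k:] = 0.0
            actual_bleach = bleach_time
        elif math.isfinite(budget):
            cum = cum_excitation + np.cumsum(mol * dtw)
            if cum[-1] >= budget:
                k = int(np.searchsorted(cum, budget))
                k = min(k, n_bin - 1)
                actual_bleach = float(t[k])
                mol[k:] = 0.0
            else:
                cum_excitation = float(cum[-1])

        rate = mol + beam.background

        if intruder_rate > 0:
            n_new = rng.poisson(intruder_rate * control.delta_t)
            center_m = ctrl.X * stage.unit_scale
            for _k in range(n_new):
                side = 1.0 if rng.random() < 0.5 else -1.0
                intruders.append(center_m + side * intruder_offset)
            survivors = []
            for p0 in intruders:
                isteps = rng.standard_normal(n_bin) * sig_step + diff.v * dtw
                ipath = p0 + np.concatenate(([0.0], np.cumsum(isteps[:-1])))
                rate = rate + beam.molecular_rate(sp + ipath)
                intruder_tracks.append((t, ipath))
                p_end = ipath[-1] + isteps[-1]
                if abs(p_end - ctrl.X * stage.unit_scale) < 10.0e-6:
                    survivors.append(p_end)
            intruders = survivors

        counts = rng.poisson(rate * dtw)
        bins_done = sum(len(c) for c in count_chunks)
        local = np.repeat(np.arange(n_bin, dtype=np.uint64), counts)
        tick_chunks.append(
            _uniform_ticks(np.uint64(bins_done) + local, dtw, rng)
        )
        count_chunks.append(counts)
        xmol_chunks.append(pos)
        xstage_chunks.append(sp)

        events.extend(detector.push(counts))
        while ev_ptr < len(events) and events[ev_ptr].t_peak < tp:
            ev_ptr += 1
        tw = None
        window_end = tp + control.delta_t
        if ev_ptr < len(events) and events[ev_ptr].t_peak < window_end:
            tw = events[ev_ptr].t_peak
            while ev_ptr < len(events) and events[ev_ptr].t_peak < window_end:
                ev_ptr += 1
        ctrl.complete_cycle(tw)

    events.extend(detector.flush())

    all_counts = np.concatenate(count_chunks)
    photons = PhotonData(
        ticks=np.concatenate(tick_chunks),
        bin_counts=all_counts.astype(np.int64),
        bin_width=dtw,
    )
    truth = GroundTruth(
        times=np.arange(len(all_counts)) * dtw,
        x_mol=np.concatenate(xmol_chunks),
        x_stage=np.concatenate(xstage_chunks),
        bleach_time=actual_bleach,
        intruder_tracks=intruder_tracks,
    )
    return SimulationRun(
        ground_truth=truth,
        photons=photons,
        records=ctrl.records,
        burst_events=events,
        trajectory=ctrl.trajectory,
    )


def simulate_immobilized_bead(
    beam: BeamModel,
    stage: StageModel | None = None,
    passes: int = 10,
    delta_t: float = 0.03,
    rng: np.random.Generator | None = None,
    x_t: float = 10_000.0,
    bead_offset: float = 0.0,
    dt: float = 1.0e-5,
) -> PhotonData:
    """Photon stream from a bead fixed in the stage frame, recycled open-loop.

    The stage sweeps back and forth between ``-x_t`` and ``+x_t`` piezo
    units at ``v_trans``, one sweep per reversal delay ``delta_t``, for
    ``passes`` sweeps; a bead at stage-frame position ``bead_offset``
    transits the focus once per sweep.  Used to exercise the ACF transit
    and recycle-period calibration without diffusion (D = 0).
    """
    if passes < 1:
        raise ValueError("passes must be at least 1")
    stage = stage if stage is not None else StageModel()
    rng = rng if rng is not None else np.random.default_rng()
    t_trans = 2.0 * x_t / stage.speed_units
    if delta_t <= t_trans:
        raise ValueError("delta_t must exceed the translation time")
    bt: list[float] = []
    bx: list[float] = []
    for i in range(passes):
        d = 1.0 if i % 2 == 0 else -1.0
        bt.extend([i * delta_t, i * delta_t + t_trans])
        bx.extend([-d * x_t, d * x_t])
    n = int(round(passes * delta_t / dt))
    times = np.arange(n) * dt
    pos_units = np.interp(times, bt, bx)
    offsets = pos_units * stage.unit_scale + bead_offset
    return photons_from_rates(beam.rate(offsets), dt, rng)
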