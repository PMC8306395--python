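"""Recycling feedback controller for the piezo stage.

Every cycle the stage launches from a point a prescheduled offset ``x_t``
before the tracked molecule-position estimate, sweeps through it at constant
speed to the far side, dwells, and reverses after a fixed delay ``delta_t``.
The estimate is corrected once per detected burst from the innovation
between the measured launch-to-burst interval ``tw - tp`` and its running
mean ``m``::

    X(i+1) = X(i) + C * ((tw(i) - tp(i)) - m)          (literal form)

with ``C`` in piezo units per millisecond.  Geometrically the innovation
measures the position error *along the scan direction*, which alternates,
so by default the controller applies the update with an extra ``-(-1)**i``
parity factor (``signed_feedback=True``); the literal constant-sign form is
available for comparison and is only marginally stable.

Positions are tracked in piezo units (0.458 nm each by default); the stage
trajectory is piecewise linear with all translation segments at ``v_trans``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "StageModel",
    "RecyclingConfig",
    "CycleRecord",
    "StageTrajectory",
    "update_center",
    "RecyclingController",
    "run_controller",
]

#: Default stage displacement per piezo unit: 4.58 um / 10,000 units.
DEFAULT_UNIT_SCALE = 4.58e-10


class ConfigurationError(ValueError):
    """Raised when a recycling configuration cannot be scheduled."""


@dataclass(frozen=True)
class StageModel:
    """Piezo translation stage.

    ``unit_scale`` converts piezo units to metres, ``v_trans`` is the
    constant translation speed, ``travel_limits`` bound the commanded
    position (piezo units) and ``actuation_delay`` is the command-to-motion
    latency.
    """

    unit_scale: float = DEFAULT_UNIT_SCALE
    v_trans: float = 2.0e-3
    # ~ +/-100 um at the default unit scale (a 200 um travel stage).
    travel_limits: tuple[float, float] = (-218_000.0, 218_000.0)
    actuation_delay: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.unit_scale <= 0 or self.v_trans <= 0:
            raise ValueError("unit_scale and v_trans must be positive")
        lo, hi = self.travel_limits
        if not lo < hi:
            raise ValueError("travel_limits must satisfy min < max")
        if self.actuation_delay < 0:
            raise ValueError("actuation_delay must be non-negative")

    @property
    def speed_units(self) -> float:
        """Translation speed in piezo units per second."""
        return self.v_trans / self.unit_scale


@dataclass(frozen=True)
class RecyclingConfig:
    """Feedback-loop parameters.

    ``delta_t`` is the reversal delay (the cycle period), ``x_t`` the
    prescheduled launch offset in piezo units, ``gain`` the feedback scale
    factor C in piezo units per millisecond (``None`` selects the deadbeat
    value matched to the stage speed), ``m_window`` the number of completed
    cycles in the running mean of ``tw - tp``, and ``miss_timeout`` the
    extra wait beyond ``delta_t`` before a cycle is declared missed
    (``None`` means ``delta_t``; scheduling itself keeps the fixed period).

    Only bursts peaking within the translation phase plus ``accept_margin``
    carry the sweep-crossing geometry of the transit-time centre update;
    bursts later in the cycle (a molecule hovering near the focus while the
    stage dwells) instead re-centre the estimate on the focus position at
    the peak time.  Both are recorded as detections; the analysis-side
    transit-time filter separates them.
    """

    delta_t: float = 0.03
    x_t: float = 10_000.0
    gain: float | None = None
    m_window: int = 20
    miss_timeout: float | None = None
    signed_feedback: bool = True
    accept_margin: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.x_t <= 0:
            raise ValueError("x_t must be positive")
        if self.m_window < 1:
            raise ValueError("m_window must be at least 1")
        if self.miss_timeout is not None and self.miss_timeout < 0:
            raise ValueError("miss_timeout must be non-negative")


@dataclass(frozen=True)
class CycleRecord:
    """One recycle: index, launch time, burst time, centre, parity, miss flag."""

    i: int
    tp: float
    tw: float | None
    X: float
    direction: int
    missed: bool

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not self.missed and self.tw is not None and self.tw < self.tp:
            raise ValueError("tw must not precede tp")


@dataclass
class StageTrajectory:
    """Commanded stage path as piecewise-linear breakpoints (piezo units)."""

    times: np.ndarray
    positions_units: np.ndarray
    unit_scale: float = DEFAULT_UNIT_SCALE
    clamp_events: list = field(default_factory=list)

    def position_units(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.positions_units)

    def position_m(self, t) -> np.ndarray:
        return self.position_units(t) * self.unit_scale


def update_center(X_i: float, tw_i: float, tp_i: float, m: float, C: float) -> float:
    """Proportional centre update from the transit-time innovation.

    Returns ``X_i + ((tw_i - tp_i) - m) * C`` with times in seconds and
    ``C`` in piezo units per millisecond.  When the measured interval equals
    its running mean the centre is unchanged.
    """
    if tw_i < tp_i:
        raise ValueError("tw_i must not precede tp_i")
    return X_i + ((tw_i - tp_i) - m) * 1.0e3 * C


class RecyclingController:
    """Stateful recycling scheduler.

    Drive it by alternating :meth:`stage_position_m` queries (to evaluate
    the commanded path during the current cycle) with one
    :meth:`complete_cycle` call per cycle, passing the bound burst time or
    ``None`` for a miss.  The launch time ``tp`` denotes the start of stage
    *motion*; the actuation delay is consumed from the preceding dwell.
    """

    def __init__(
        self,
        config: RecyclingConfig,
        stage: StageModel,
        X0: float = 0.0,
        t0: float = 0.0,
    ) -> None:
        t_trans = 2.0 * config.x_t / stage.speed_units
        if config.delta_t <= t_trans + stage.actuation_delay:
            raise ConfigurationError(
                f"delta_t={config.delta_t:g} s cannot accommodate the "
                f"{t_trans:g} s translation plus the {stage.actuation_delay:g} s "
                "actuation delay"
            )
        self.config = config
        self.stage = stage
        self.gain = (
            config.gain
            if config.gain is not None
            else stage.v_trans * 1.0e-3 / stage.unit_scale
        )
        self.X = float(X0)
        self.i = 0
        self.tp = float(t0)
        self._t_trans = t_trans
        self._m0 = config.x_t / stage.speed_units
        # Seed the running mean with the nominal transit time so that early
        # (legitimately large) diffusion innovations do not bias the centre
        # reference before the window fills.
        self._m_hist: deque[float] = deque(
            [self._m0] * config.m_window, maxlen=config.m_window
        )
        self.records: list[CycleRecord] = []
        self.clamp_events: list[tuple[int, float]] = []
        self._bt: list[float] = [self.tp]
        self._bx: list[float] = [self._clamp(-self.X - self.direction * config.x_t)]
        self._extend_translation()

    # -- state -------------------------------------------------------------

    @property
    def direction(self) -> int:
        """Scan direction parity for the current cycle: +1 on even cycles."""
        return 1 if self.i % 2 == 0 else -1

    @property
    def accept_window(self) -> float:
        """Length of the burst-acceptance window after each launch (s)."""
        return min(self._t_trans + self.config.accept_margin, self.config.delta_t)

    @property
    def m(self) -> float:
        """Running mean of ``tw - tp`` over recent non-missed cycles (s)."""
        if not self._m_hist:
            return self._m0
        return float(np.mean(self._m_hist))

    @property
    def trajectory(self) -> StageTrajectory:
        return StageTrajectory(
            times=np.asarray(self._bt),
            positions_units=np.asarray(self._bx),
            unit_scale=self.stage.unit_scale,
            clamp_events=list(self.clamp_events),
        )

    def stage_position_units(self, t) -> np.ndarray:
        return np.interp(t, self._bt, self._bx)

    def stage_position_m(self, t) -> np.ndarray:
        return self.stage_position_units(t) * self.stage.unit_scale

    # -- cycle advancement -------------------------------------------------

    def complete_cycle(self, tw: float | None) -> CycleRecord:
        """Close the current cycle with its burst time (or a miss).

        Applies the centre update for a detected burst (frozen centre on a
        miss), schedules the end-of-dwell adjustment move to the next launch
        point, and begins the next cycle's translation at ``tp + delta_t``.
        """
        d = self.direction
        missed = tw is None
        rec = CycleRecord(
            i=self.i, tp=self.tp, tw=tw, X=self.X, direction=d, missed=missed
        )
        self.records.append(rec)
        if missed:
            X_new = self.X
        elif tw - self.tp <= self.accept_window:
            c_eff = (-d * self.gain) if self.config.signed_feedback else self.gain
            # A burst from the commanded sweep can differ from the mean
            # transit time by at most the half-sweep duration x_t / speed;
            # clip the innovation there so a stray early/late peak cannot
            # throw the centre beyond the swept range.
            inn_max = self.config.x_t / self.stage.speed_units
            inn = float(np.clip((tw - self.tp) - self.m, -inn_max, inn_max))
            X_new = update_center(self.X, self.tp + self.m + inn, self.tp,
                                  self.m, c_eff)
            self._m_hist.append(tw - self.tp)
        elif self.gain != 0.0:
            # Burst after the sweep: the molecule is hovering at the focus
            # while the stage dwells, so the best position estimate is the
            # focus position itself (the transit-time geometry of the
            # centre update does not apply).  The running mean is left
            # untouched; the analysis-side transit-time filter later
            # rejects such cycles.  Skipped entirely when feedback is off
            # (C = 0), which keeps that case a true open loop.
            X_new = self._clamp(-float(self.stage_position_units(tw)))
        else:
            X_new = self.X

        tp_next = self.tp + self.config.delta_t
        next_start = self._clamp(-X_new + d * self.config.x_t)
        cur = self._bx[-1]
        t_adj = abs(next_start - cur) / self.stage.speed_units
        t_adj_start = max(tp_next - t_adj, self._bt[-1])
        self._append(t_adj_start, cur)
        self._append(t_adj_start + t_adj, next_start)

        self.i += 1
        self.X = X_new
        self.tp = tp_next
        self._extend_translation()
        return rec

    # -- internals ---------------------------------------------------------

    def _clamp(self, pos: float) -> float:
        lo, hi = self.stage.travel_limits
        if pos < lo or pos > hi:
            self.clamp_events.append((self.i, pos))
            return float(np.clip(pos, lo, hi))
        return pos

    def _append(self, t: float, x: float) -> None:
        if t > self._bt[-1] + 1e-12:
            self._bt.append(t)
            self._bx.append(x)
        else:
            self._bx[-1] = x

    def _extend_translation(self) -> None:
        start = self._bx[-1]
        end = self._clamp(-self.X + self.direction * self.config.x_t)
        self._append(self.tp, start)
        dur = abs(end - start) / self.stage.speed_units
        self._append(self.tp + dur, end)


def rebind_bursts(records: list[CycleRecord], burst_stream) -> list[CycleRecord]:
    """Re-derive each cycle's burst time from a reprocessed burst stream.

    Post-processing re-detects bursts from the stored photon record (often
    at a different threshold than the real-time loop used) and re-binds
    them to the recorded cycles: the first burst peaking in each cycle's
    window replaces ``tw``; cycles with no such burst become missed.  The
    commanded centres, launch times and parities are untouched -- they are
    history.
    """
    peaks = [getattr(b, "t_peak", b) for b in burst_stream]
    if any(b2 < b1 for b1, b2 in zip(peaks, peaks[1:])):
        raise ValueError("burst stream must be time-ordered")
    if len(records) > 1:
        last_window = records[-1].tp - records[-2].tp
    else:
        last_window = float("inf")
    ends = [r.tp for r in records[1:]] + [records[-1].tp + last_window]
    out: list[CycleRecord] = []
    j = 0
    for rec, window_end in zip(records, ends):
        while j < len(peaks) and peaks[j] < rec.tp:
            j += 1
        tw = peaks[j] if j < len(peaks) and peaks[j] < window_end else None
        out.append(
            CycleRecord(
                i=rec.i,
                tp=rec.tp,
                tw=tw,
                X=rec.X,
                direction=rec.direction,
                missed=tw is None,
            )
        )
    return out


def run_controller(
    burst_stream,
    config: RecyclingConfig,
    stage: StageModel,
    t_end: float,
    X0: float = 0.0,
    t0: float = 0.0,
) -> tuple[list[CycleRecord], StageTrajectory]:
    """Replay a time-ordered burst stream through the recycling controller.

    ``burst_stream`` is a sequence of burst peak times (floats) or objects
    with a ``t_peak`` attribute, in increasing time order.  The first burst
    falling in each cycle window ``[tp, tp + delta_t)`` is bound to that
    cycle; later bursts in the window (e.g. from an intruding molecule) are
    ignored by the update.  Cycles run until ``t_end``.
    """
    peaks = [getattr(b, "t_peak", b) for b in burst_stream]
    if any(b2 < b1 for b1, b2 in zip(peaks, peaks[1:])):
        raise ValueError("burst stream must be time-ordered")
    ctrl = RecyclingController(config, stage, X0=X0, t0=t0)
    j = 0
    while ctrl.tp + config.delta_t <= t_end + 1e-12:
        window_end = ctrl.tp + config.delta_t
        while j < len(peaks) and peaks[j] < ctrl.tp:
            j += 1
        tw = None
        if j < len(peaks) and peaks[j] < window_end:
            tw = peaks[j]
            while j < len(peaks) and peaks[j] < window_end:
                j += 1
        ctrl.complete_cycle(tw)
    return ctrl.records, ctrl.trajectory
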