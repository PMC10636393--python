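"""Theta-burst stimulation (TBS) pulse trains, sessions and course.

Both protocols are built from three-pulse 50-Hz bursts repeated every
200 ms (5 Hz burst rate) at 80% of the resting motor threshold:

* iTBS — 2-s trains (10 bursts, 30 pulses) repeated 40 times with a 6.3-s
  inter-train gap: 1200 pulses.
* cTBS — one continuous train. In the study's stated form 600 bursts are
  delivered for 1800 pulses ("published" mode); the conventional cTBS-600
  (200 bursts, 600 pulses) is available as mode="conventional".

An accelerated course is five sessions per day for five days with 1-h
gaps; each session stimulates the prescribed targets in rank order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .prescribe import TargetPrescription, ITBS, CTBS


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class TBSParams:
    """Pulse-train timing. All times seconds, intensity as a fraction of
    resting motor threshold. The 2-s iTBS train duration is not free: it
    is forced by 1200 pulses / 40 trains / 3 pulses per burst at 5 Hz."""

    pulses_per_burst: int = 3
    intra_burst_frequency_hz: float = 50.0
    burst_period_s: float = 0.2
    train_duration_s: float = 2.0
    n_trains_itbs: int = 40
    inter_train_interval_s: float = 6.3
    n_bursts_ctbs: int = 600
    intensity_rmt: float = 0.80

    def __post_init__(self):
        for name in ("pulses_per_burst", "intra_burst_frequency_hz",
                     "burst_period_s", "train_duration_s", "n_trains_itbs",
                     "inter_train_interval_s", "n_bursts_ctbs"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be positive")
        if not 0 < self.intensity_rmt <= 1:
            raise ProtocolError("intensity must be in (0, 1] of RMT")
        bursts = self.train_duration_s / self.burst_period_s
        if abs(bursts - round(bursts)) > 1e-9:
            raise ProtocolError(
                "train_duration_s must be an integer multiple of "
                "burst_period_s")

    @property
    def bursts_per_train(self) -> int:
        return int(round(self.train_duration_s / self.burst_period_s))

    @property
    def intra_burst_spacing_s(self) -> float:
        return 1.0 / self.intra_burst_frequency_hz


@dataclass
class TBSProtocol:
    """Concrete pulse timing for one target."""

    kind: str                  # "iTBS" | "cTBS"
    pulse_times_s: np.ndarray  # strictly increasing, from protocol onset
    n_pulses: int
    duration_s: float          # span including trailing train period
    intensity_rmt: float
    params: TBSParams

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_pulses": int(self.n_pulses),
                "duration_s": float(self.duration_s),
                "intensity_rmt": float(self.intensity_rmt),
                "pulse_times_ms": (self.pulse_times_s * 1000).tolist()}

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"pulse_time_ms": self.pulse_times_s * 1000}).to_csv(
            path, index=False)


def _burst_times(params: TBSParams) -> np.ndarray:
    return np.arange(params.pulses_per_burst) * params.intra_burst_spacing_s


def build_itbs(params: TBSParams = TBSParams()) -> TBSProtocol:
    """Intermittent TBS: n_trains trains of bursts at 5 Hz.

    Defaults give 40 trains x 10 bursts x 3 pulses = 1200 pulses over
    40*2 + 39*6.3 = 325.7 s (the inter-train interval is the gap between
    train end and the next train's onset).
    """
    burst = _burst_times(params)
    times = []
    train_stride = params.train_duration_s + params.inter_train_interval_s
    for k in range(params.n_trains_itbs):
        t0 = k * train_stride
        for b in range(params.bursts_per_train):
            times.append(t0 + b * params.burst_period_s + burst)
    times = np.concatenate(times)
    duration = (params.n_trains_itbs * params.train_duration_s
                + (params.n_trains_itbs - 1)
                * params.inter_train_interval_s)
    return TBSProtocol(kind=ITBS, pulse_times_s=times,
                       n_pulses=times.size, duration_s=duration,
                       intensity_rmt=params.intensity_rmt, params=params)


def build_ctbs(params: TBSParams = TBSParams(),
               mode: str = "published") -> TBSProtocol:
    """Continuous TBS: one uninterrupted train of three-pulse bursts.

    mode="published" delivers params.n_bursts_ctbs bursts (default 600, hence
    1800 pulses over 120 s); mode="conventional" delivers the standard
    cTBS-600 (200 bursts, 600 pulses).
    """
    if mode not in ("published", "conventional"):
        raise ProtocolError("mode must be 'published' or 'conventional'")
    n_bursts = params.n_bursts_ctbs if mode == "published" else 200
    burst = _burst_times(params)
    times = np.concatenate(
        [b * params.burst_period_s + burst for b in range(n_bursts)])
    duration = n_bursts * params.burst_period_s
    return TBSProtocol(kind=CTBS, pulse_times_s=times,
                       n_pulses=times.size, duration_s=duration,
                       intensity_rmt=params.intensity_rmt, params=params)


@dataclass
class SessionProtocol:
    """Per-target protocols concatenated in prescription rank order."""

    segments: list            # (target name, protocol kind, offset_s)
    protocols: list           # TBSProtocol per target
    duration_s: float
    n_pulses: int
    inter_target_pause_s: float

    def to_dict(self) -> dict:
        return {
            "duration_s": float(self.duration_s),
            "n_pulses": int(self.n_pulses),
            "inter_target_pause_s": float(self.inter_target_pause_s),
            "segments": [
                {"target": name, "kind": kind, "offset_s": float(off),
                 "n_pulses": int(p.n_pulses),
                 "duration_s": float(p.duration_s)}
                for (name, kind, off), p in zip(self.segments,
                                                self.protocols)],
        }


def build_session(rx: TargetPrescription,
                  params: TBSParams = TBSParams(),
                  inter_target_pause_s: float = 60.0,
                  ctbs_mode: str = "published") -> SessionProtocol:
    """Stimulate the prescribed targets in sequence in a single session."""
    if not rx.targets:
        raise ProtocolError("cannot build a session from an empty "
                            "prescription")
    segments, protos = [], []
    offset = 0.0
    for t in sorted(rx.targets, key=lambda t: t.rank):
        proto = (build_itbs(params) if t.protocol == ITBS
                 else build_ctbs(params, mode=ctbs_mode))
        segments.append((str(t.name), proto.kind, offset))
        protos.append(proto)
        offset += proto.duration_s + inter_target_pause_s
    duration = offset - inter_target_pause_s
    return SessionProtocol(
        segments=segments, protocols=protos, duration_s=duration,
        n_pulses=sum(p.n_pulses for p in protos),
        inter_target_pause_s=inter_target_pause_s)


@dataclass(frozen=True)
class SessionSchedule:
    """Accelerated schedule: five sessions per day for five days, 1-h
    gaps between sessions."""

    sessions_per_day: int = 5
    n_days: int = 5
    inter_session_gap_h: float = 1.0

    def __post_init__(self):
        if self.sessions_per_day < 1 or self.n_days < 1:
            raise ProtocolError("schedule counts must be positive")
        if self.inter_session_gap_h <= 0:
            raise ProtocolError("inter-session gap must be positive")


@dataclass
class CourseCalendar:
    """Start times of every session over the course."""

    session_starts_s: list     # (day, start-of-day offset seconds)
    n_sessions: int
    session_duration_s: float
    total_pulses: int

    def to_dict(self) -> dict:
        return {"n_sessions": int(self.n_sessions),
                "session_duration_s": float(self.session_duration_s),
                "total_pulses": int(self.total_pulses),
                "session_starts": [
                    {"day": int(d), "start_s": float(s)}
                    for d, s in self.session_starts_s]}


def build_course(schedule: SessionSchedule,
                 session: SessionProtocol) -> CourseCalendar:
    """Lay sessions out on the calendar; consecutive same-day starts are
    separated by session duration plus the gap."""
    gap_s = schedule.inter_session_gap_h * 3600.0
    stride = session.duration_s + gap_s
    day_span = (schedule.sessions_per_day * session.duration_s
                + (schedule.sessions_per_day - 1) * gap_s)
    if day_span > 24 * 3600:
        raise ProtocolError(
            f"infeasible day: {schedule.sessions_per_day} sessions of "
            f"{session.duration_s:.0f}s with {gap_s:.0f}s gaps exceed 24 h")
    starts = [(day, k * stride)
              for day in range(schedule.n_days)
              for k in range(schedule.sessions_per_day)]
    n_sessions = len(starts)
    return CourseCalendar(
        session_starts_s=starts, n_sessions=n_sessions,
        session_duration_s=session.duration_s,
        total_pulses=n_sessions * session.n_pulses)


def protocol_to_json(session: SessionProtocol, course: CourseCalendar,
                     path) -> None:
    with open(path, "w") as fh:
        json.dump({"session": session.to_dict(),
                   "course": course.to_dict()}, fh, indent=2)
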