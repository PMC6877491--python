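"""Signal-contingent sampling: expanding session schedules and driving runs.

An ``aa-session`` declares its sampling plan as two attributes:
``dates="01/08/2018;03/08/2018-05/08/2018"`` (semicolon-separated single
days or inclusive day ranges) and ``times="10:00;15:00;20:00"``.  The
concrete trigger list is the Cartesian product of the expanded dates and
times, in chronological order.

Times are naive study-local (no timezone or DST modelling).  The date
dialect defaults to day-first (``DD/MM/YYYY``) with a switch for
``MM/DD/YYYY``; the dialect used is recorded in run metadata.  Each
trigger carries an expiry window (default 60 minutes): a session answered
after the window, declined by the participant, or arriving while a
previous session is still open (default policy) counts as missed and
contributes no data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional

import numpy as np

from .document_model import NodePath, ProtocolDocument, SessionNode, format_path, iter_nodes
from .records_io import DataRecord
from .runtime import (
    ExecutionTrace,
    Responder,
    SessionDeclined,
    SessionExpired,
    SimulatedClock,
    VariableStore,
    run_nodes,
)
from .widgets import LocationProvider

__all__ = [
    "ScheduleError",
    "TriggerSchedule",
    "StudyConfig",
    "RunSummary",
    "StudyResult",
    "parse_dates",
    "parse_times",
    "expand_schedule",
    "expand_all_schedules",
    "run_study_clock",
    "DATE_DIALECTS",
]


class ScheduleError(ValueError):
    """Malformed dates/times specification; names the offending item."""


DATE_DIALECTS = {
    "DD/MM/YYYY": "%d/%m/%Y",
    "MM/DD/YYYY": "%m/%d/%Y",
}

DEFAULT_EXPIRY_MINUTES = 60


@dataclass(frozen=True)
class TriggerSchedule:
    """Concrete triggers for one session container."""

    triggers: tuple[datetime, ...]
    session_path: NodePath
    expiry_minutes: float = DEFAULT_EXPIRY_MINUTES


@dataclass(frozen=True)
class StudyConfig:
    date_format: str = "DD/MM/YYYY"
    expiry_minutes: float = DEFAULT_EXPIRY_MINUTES
    on_overlap: str = "miss"  # miss | queue

    def __post_init__(self):
        if self.date_format not in DATE_DIALECTS:
            raise ScheduleError(f"unknown date dialect {self.date_format!r}")
        if self.on_overlap not in ("miss", "queue"):
            raise ScheduleError(f"unknown overlap policy {self.on_overlap!r}")


@dataclass
class RunSummary:
    participants: int = 0
    triggers: int = 0
    responses: int = 0
    missed: int = 0


@dataclass
class StudyResult:
    records: list[DataRecord] = field(default_factory=list)
    traces: dict[str, ExecutionTrace] = field(default_factory=dict)
    stores: dict[str, VariableStore] = field(default_factory=dict)
    summary: RunSummary = field(default_factory=RunSummary)


# --------------------------------------------------------------------------
# schedule expansion


def parse_dates(spec: str, date_format: str = "DD/MM/YYYY") -> list[date]:
    """Expand a dates attribute into sorted, deduplicated calendar days.

    Items are separated by ``;``; each is a single day or an inclusive
    range ``start-end``.
    """
    pattern = DATE_DIALECTS.get(date_format)
    if pattern is None:
        raise ScheduleError(f"unknown date dialect {date_format!r}")

    def one(text: str) -> date:
        try:
            return datetime.strptime(text.strip(), pattern).date()
        except ValueError as exc:
            raise ScheduleError(f"bad date {text.strip()!r}: {exc}") from exc

    days: set[date] = set()
    for item in spec.split(";"):
        item = item.strip()
        if not item:
            continue
        if "-" in item:
            start_text, _, end_text = item.partition("-")
            start, end = one(start_text), one(end_text)
            if end < start:
                raise ScheduleError(
                    f"range {item!r} ends before it starts")
            current = start
            while current <= end:
                days.add(current)
                current += timedelta(days=1)
        else:
            days.add(one(item))
    if not days:
        raise ScheduleError(f"empty dates specification {spec!r}")
    return sorted(days)


def parse_times(spec: str) -> list[time]:
    """Expand a times attribute (24-hour ``HH:MM``, ``;``-separated) into
    sorted, deduplicated times of day."""
    times: set[time] = set()
    for item in spec.split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            times.add(datetime.strptime(item, "%H:%M").time())
        except ValueError as exc:
            raise ScheduleError(f"bad time {item!r}: {exc}") from exc
    if not times:
        raise ScheduleError(f"empty times specification {spec!r}")
    return sorted(times)


def expand_schedule(session: SessionNode, session_path: NodePath = (), *,
                    date_format: str = "DD/MM/YYYY",
                    expiry_minutes: float = DEFAULT_EXPIRY_MINUTES,
                    ) -> TriggerSchedule:
    """Cartesian product dates x times, chronologically ordered; the
    trigger count is exactly ``|dates| * |times|``."""
    days = parse_dates(session.dates_spec, date_format)
    clock_times = parse_times(session.times_spec)
    triggers = tuple(sorted(
        datetime.combine(d, t) for d in days for t in clock_times))
    return TriggerSchedule(triggers=triggers, session_path=session_path,
                           expiry_minutes=expiry_minutes)


def expand_all_schedules(doc: ProtocolDocument,
                         config: Optional[StudyConfig] = None,
                         ) -> list[TriggerSchedule]:
    """One TriggerSchedule per aa-session in the document."""
    config = config or StudyConfig()
    return [
        expand_schedule(node, path, date_format=config.date_format,
                        expiry_minutes=config.expiry_minutes)
        for path, node in iter_nodes(doc) if isinstance(node, SessionNode)
    ]


# --------------------------------------------------------------------------
# driving the study clock


def _default_rng(participant_id: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(participant_id.encode("utf-8")))


def run_study_clock(
    doc: ProtocolDocument,
    schedules: list[TriggerSchedule],
    responders: dict[str, Responder],
    config: Optional[StudyConfig] = None,
    *,
    rngs: Optional[dict[str, np.random.Generator]] = None,
    location_providers: Optional[dict[str, LocationProvider]] = None,
) -> StudyResult:
    """Advance a simulated clock through every trigger for every participant.

    Each participant has an independent clock, variable store (persistent
    across sessions) and trace.  ``session_index`` on records is the
    participant's chronological trigger ordinal (missed triggers included,
    so indices are stable across compliance levels).
    """
    from .document_model import node_at  # local to avoid cycle at import time

    config = config or StudyConfig()
    result = StudyResult(summary=RunSummary(participants=len(responders)))

    merged: list[tuple[datetime, TriggerSchedule]] = sorted(
        ((trigger, sched) for sched in schedules for trigger in sched.triggers),
        key=lambda pair: pair[0])

    for participant_id, responder in responders.items():
        store = VariableStore()
        trace = ExecutionTrace()
        rng = (rngs or {}).get(participant_id) or _default_rng(participant_id)
        provider = (location_providers or {}).get(participant_id)
        clock = SimulatedClock(merged[0][0] if merged else datetime(1970, 1, 1))

        for session_index, (trigger, sched) in enumerate(merged):
            result.summary.triggers += 1
            session = node_at(doc, sched.session_path)
            deadline = trigger + timedelta(minutes=sched.expiry_minutes)
            path_text = format_path(sched.session_path)

            if clock.now > trigger and config.on_overlap == "miss":
                result.summary.missed += 1
                trace.warn("trigger missed: previous session still open",
                           path_text, trigger)
                continue
            clock.at_least(trigger)
            responder.begin_trigger(session_index, trigger)
            if not responder.accepts_trigger(trigger):
                result.summary.missed += 1
                trace.warn("trigger missed: participant declined",
                           path_text, trigger)
                continue

            snapshot = store.snapshot()
            trace.add("instantiated", path_text, clock.now, tag=session.tag,
                      session_index=session_index)
            try:
                records, _ = run_nodes(
                    session.children, store, responder, clock, rng,
                    location_provider=provider, trace=trace,
                    participant_id=participant_id,
                    session_index=session_index, trigger_time=trigger,
                    deadline=deadline, path_prefix=sched.session_path)
            except (SessionDeclined, SessionExpired) as exc:
                store.restore(snapshot)
                result.summary.missed += 1
                trace.warn(f"trigger missed: {exc}", path_text, trigger)
                continue
            trace.add("completed", path_text, clock.now, tag=session.tag,
                      session_index=session_index)
            result.records.extend(records)
            result.summary.responses += 1

        result.traces[participant_id] = trace
        result.stores[participant_id] = store

    result.records.sort(key=lambda r: (r.participant_id, r.trigger_time))
    return result
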