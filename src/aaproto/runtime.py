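"""Execution semantics for protocol trees.

The engine treats a protocol document as a program for a small virtual
machine: widgets write named variables into a per-participant memory,
sequences instantiate their children strictly one at a time (each child
starts only after the previous one signals completion), and
choose/when/otherwise blocks instantiate the first branch whose test holds.
Instantiation is *lazy* — content in unselected branches is never
instantiated, so it never consumes resources and never appears in the
trace.

Execution is headless and fully deterministic: participant behaviour comes
from an injected :class:`Responder`, time from an injected
:class:`SimulatedClock`, randomness from a seeded stream.  Faults at run
time (unparseable tests, stale references) degrade to warnings rather than
halting, mirroring how such protocols misbehave silently in the field; the
linter catches them statically instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Union

import numpy as np

from .document_model import (
    ChooseNode,
    NodePath,
    OtherwiseBranch,
    ProtocolNode,
    RawHtmlNode,
    ScreenNode,
    SequenceNode,
    SessionNode,
    UnknownNode,
    WhenBranch,
    WidgetNode,
    format_path,
)
from .expression import ExpressionSyntaxError, eval_expr, parse_expr
from .records_io import MISSING_VALUE, DataRecord
from .widgets import (
    LocationProvider,
    ValueDomain,
    auto_value,
    interpolate_text,
    response_domain,
)

__all__ = [
    "VariableStore",
    "TraceEvent",
    "ExecutionTrace",
    "SimulatedClock",
    "ScreenResponse",
    "Responder",
    "DomainViolationError",
    "UnknownWidgetError",
    "SessionDeclined",
    "SessionExpired",
    "RunContext",
    "run_nodes",
    "evaluate_choose",
    "submit_screen",
]

#: value stored for a multi-select answer: selected options joined by ';'
MULTI_JOIN = ";"


class DomainViolationError(ValueError):
    """A responder returned a value outside the widget's domain."""


class UnknownWidgetError(KeyError):
    """An answer names a variable with no widget on the screen."""


class SessionDeclined(Exception):
    """The responder declined the trigger; the session is missed."""


class SessionExpired(Exception):
    """The expiry window elapsed before the session finished."""


# --------------------------------------------------------------------------
# memory, time, trace


class VariableStore:
    """Named-value memory for one participant.

    Lives for the whole study (values persist across sessions so later
    items can re-use earlier input); every write is logged.
    """

    def __init__(self) -> None:
        self.values: dict[str, object] = {}
        self.write_log: list[tuple[Optional[datetime], str, object]] = []

    def get(self, name: str, default=None):
        return self.values.get(name, default)

    def set(self, name: str, value, when: Optional[datetime] = None) -> None:
        self.values[name] = value
        self.write_log.append((when, name, value))

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def snapshot(self) -> tuple[dict, int]:
        return dict(self.values), len(self.write_log)

    def restore(self, snapshot: tuple[dict, int]) -> None:
        values, log_length = snapshot
        self.values = values
        del self.write_log[log_length:]


@dataclass(frozen=True)
class TraceEvent:
    kind: str  # instantiated | completed | branch_selected | warning
    path: str
    time: Optional[datetime]
    detail: tuple = ()  # sorted (key, value) pairs

    def to_json(self) -> str:
        obj = {"kind": self.kind, "path": self.path,
               "time": self.time.isoformat() if self.time else None}
        obj.update(dict(self.detail))
        return json.dumps(obj, sort_keys=True)


class ExecutionTrace:
    """Ordered event log of one or more runs; exports as JSON lines."""

    def __init__(self) -> None:
        self.events: list[TraceEvent] = []

    def add(self, kind: str, path: str, time: Optional[datetime] = None, **detail):
        self.events.append(
            TraceEvent(kind, path, time, tuple(sorted(detail.items()))))

    def warn(self, message: str, path: str = "", time: Optional[datetime] = None):
        self.add("warning", path, time, message=message)

    @property
    def warnings(self) -> list[TraceEvent]:
        return [e for e in self.events if e.kind == "warning"]

    def instantiated_paths(self) -> list[str]:
        return [e.path for e in self.events if e.kind == "instantiated"]

    def to_jsonl(self) -> str:
        return "\n".join(e.to_json() for e in self.events) + ("\n" if self.events else "")


class SimulatedClock:
    """Injectable study clock; response latencies advance it."""

    def __init__(self, start: datetime):
        self.now = start

    def advance(self, seconds: float) -> None:
        if seconds < 0:
            raise ValueError("cannot advance the clock backwards")
        self.now = self.now + timedelta(seconds=seconds)

    def at_least(self, when: datetime) -> None:
        if when > self.now:
            self.now = when


# --------------------------------------------------------------------------
# responder contract


@dataclass(frozen=True)
class ScreenResponse:
    """Answers for one screen: variable name -> value (list for
    multi-select), plus the seconds the participant took."""

    answers: dict
    latency: float = 0.0


class Responder:
    """Stands in for the human participant.  Subclasses override
    :meth:`respond`; declining a whole trigger goes through
    :meth:`accepts_trigger`."""

    def begin_trigger(self, session_index: int, when: datetime) -> None:
        """Called by the scheduler before each trigger is offered."""

    def accepts_trigger(self, when: datetime) -> bool:
        return True

    def respond(self, screen: ScreenNode, domains: list[ValueDomain],
                now: datetime) -> Optional[ScreenResponse]:
        raise NotImplementedError


# --------------------------------------------------------------------------
# execution


@dataclass
class RunContext:
    """Everything one session run needs; produced records accumulate here."""

    store: VariableStore
    responder: Responder
    clock: SimulatedClock
    rng: Optional[np.random.Generator] = None
    location_provider: Optional[LocationProvider] = None
    trace: ExecutionTrace = field(default_factory=ExecutionTrace)
    participant_id: str = "p0"
    session_index: int = 0
    trigger_time: Optional[datetime] = None
    deadline: Optional[datetime] = None
    records: list[DataRecord] = field(default_factory=list)


def evaluate_choose(choose: ChooseNode, store,
                    warn=None) -> Union[int, str, None]:
    """Index of the first when-branch whose test is true; ``"otherwise"``
    when none hold and an otherwise branch exists; None when nothing is
    selected (the choose then completes with no content instantiated).
    Unparseable tests count as false with a warning — never an exception.
    """
    for index, branch in enumerate(choose.whens):
        try:
            expr = parse_expr(branch.test)
        except ExpressionSyntaxError as exc:
            if warn is not None:
                warn(f"unparseable test {branch.test!r}: {exc}")
            continue
        if eval_expr(expr, store, warn=warn):
            return index
    if choose.otherwise is not None:
        return "otherwise"
    return None


def submit_screen(screen: ScreenNode, answers: dict, store: VariableStore,
                  clock: SimulatedClock, *, participant_id: str = "p0",
                  session_index: int = 0,
                  trigger_time: Optional[datetime] = None) -> list[DataRecord]:
    """Commit one screen's answers: write the store, build one record per
    answered widget (one per selected option for multi-select) and one
    missing-marker record per unanswered named widget."""
    named = {w.name: w for w in screen.input_widgets if w.name}
    for name in answers:
        if name not in named:
            raise UnknownWidgetError(
                f"answer for '{name}' but no such widget on the screen")
    records: list[DataRecord] = []
    now = clock.now
    trigger = trigger_time or now
    for widget in screen.input_widgets:
        if not widget.name:
            continue  # nothing to capture without a variable name
        domain = response_domain(widget)
        if widget.name not in answers:
            records.append(DataRecord(
                participant_id, session_index, trigger, now,
                widget.kind, widget.name, MISSING_VALUE, missing=True))
            continue
        value = answers[widget.name]
        selected = list(value) if isinstance(value, (list, tuple)) else [value]
        if isinstance(value, (list, tuple)) and not domain.multi:
            raise DomainViolationError(
                f"widget '{widget.name}' is single-select but got {value!r}")
        for item in selected:
            if not domain.contains(str(item)):
                raise DomainViolationError(
                    f"value {item!r} outside the domain of widget '{widget.name}'")
            records.append(DataRecord(
                participant_id, session_index, trigger, now,
                widget.kind, widget.name, str(item)))
        store.set(widget.name,
                  MULTI_JOIN.join(str(i) for i in selected)
                  if isinstance(value, (list, tuple)) else str(value),
                  when=now)
    return records


def _run_screen(screen: ScreenNode, path: NodePath, ctx: RunContext) -> None:
    path_text = format_path(path)
    ctx.trace.add("instantiated", path_text, ctx.clock.now, tag=screen.tag)
    # all child widgets appear simultaneously with the screen; content
    # renders and non-interactive widgets write the store in child order
    for i, child in enumerate(screen.children):
        child_path = format_path(path + (i,))
        ctx.trace.add("instantiated", child_path, ctx.clock.now, tag=child.tag)
        if isinstance(child, RawHtmlNode):
            rendered = interpolate_text(
                child.content, ctx.store,
                warn=lambda m: ctx.trace.warn(m, child_path, ctx.clock.now))
            ctx.trace.add("completed", child_path, ctx.clock.now, text=rendered)
        elif isinstance(child, WidgetNode) and child.is_auto:
            result = auto_value(child, rng=ctx.rng,
                                location_provider=ctx.location_provider,
                                now=ctx.clock.now)
            if result is not None and result[0]:
                ctx.store.set(result[0], result[1], when=ctx.clock.now)
            ctx.trace.add("completed", child_path, ctx.clock.now, tag=child.tag)
    domains = [response_domain(w) for w in screen.input_widgets]
    response = ctx.responder.respond(screen, domains, ctx.clock.now)
    if response is None:
        raise SessionDeclined(f"no response to screen {path_text}")
    ctx.clock.advance(response.latency)
    if ctx.deadline is not None and ctx.clock.now > ctx.deadline:
        raise SessionExpired(
            f"screen {path_text} answered after the expiry window")
    ctx.records.extend(submit_screen(
        screen, response.answers, ctx.store, ctx.clock,
        participant_id=ctx.participant_id, session_index=ctx.session_index,
        trigger_time=ctx.trigger_time))
    ctx.trace.add("completed", path_text, ctx.clock.now, tag=screen.tag)


def _run_node(node: ProtocolNode, path: NodePath, ctx: RunContext) -> None:
    path_text = format_path(path)
    if isinstance(node, ScreenNode):
        _run_screen(node, path, ctx)
        return
    if isinstance(node, WidgetNode) and node.is_input:
        # a bare input widget outside any screen runs as its own one-widget screen
        _run_screen(ScreenNode(children=[node], source_span=node.source_span),
                    path[:-1] + (path[-1],), ctx)
        return

    ctx.trace.add("instantiated", path_text, ctx.clock.now, tag=node.tag)
    if isinstance(node, RawHtmlNode):
        rendered = interpolate_text(
            node.content, ctx.store,
            warn=lambda m: ctx.trace.warn(m, path_text, ctx.clock.now))
        ctx.trace.add("completed", path_text, ctx.clock.now, text=rendered)
        return
    if isinstance(node, WidgetNode):  # non-interactive kinds
        result = auto_value(node, rng=ctx.rng,
                            location_provider=ctx.location_provider,
                            now=ctx.clock.now)
        if result is not None:
            name, value = result
            if name:
                ctx.store.set(name, value, when=ctx.clock.now)
            else:
                ctx.trace.warn(f"<{node.tag}> without a name writes nothing",
                               path_text, ctx.clock.now)
        ctx.trace.add("completed", path_text, ctx.clock.now, tag=node.tag)
        return
    if isinstance(node, SequenceNode):
        _run_children(node.children, path, ctx)
        ctx.trace.add("completed", path_text, ctx.clock.now, tag=node.tag)
        return
    if isinstance(node, ChooseNode):
        selection = evaluate_choose(
            node, ctx.store,
            warn=lambda m: ctx.trace.warn(m, path_text, ctx.clock.now))
        ctx.trace.add("branch_selected", path_text, ctx.clock.now,
                      branch="none" if selection is None else str(selection))
        if selection is not None:
            if selection == "otherwise":
                branch: Union[WhenBranch, OtherwiseBranch] = node.otherwise
            else:
                branch = node.whens[selection]
            branch_path = path + (node.children.index(branch),)
            ctx.trace.add("instantiated", format_path(branch_path),
                          ctx.clock.now, tag=branch.tag)
            # branch children execute as an implicit sequence
            _run_children(branch.children, branch_path, ctx)
            ctx.trace.add("completed", format_path(branch_path),
                          ctx.clock.now, tag=branch.tag)
        ctx.trace.add("completed", path_text, ctx.clock.now, tag=node.tag)
        return
    if isinstance(node, SessionNode):
        ctx.trace.warn("nested aa-session is not executed inline; sessions "
                       "run from the trigger scheduler", path_text, ctx.clock.now)
        ctx.trace.add("completed", path_text, ctx.clock.now, tag=node.tag)
        return
    if isinstance(node, (WhenBranch, OtherwiseBranch)):
        _run_children(node.children, path, ctx)
        ctx.trace.add("completed", path_text, ctx.clock.now, tag=node.tag)
        return
    # UnknownNode: skipped, non-halting
    ctx.trace.warn(f"unknown element <{node.tag}> skipped", path_text,
                   ctx.clock.now)
    ctx.trace.add("completed", path_text, ctx.clock.now, tag=node.tag)


def _run_children(children: list[ProtocolNode], prefix: NodePath,
                  ctx: RunContext) -> None:
    # strictly one at a time: each child starts only after the previous
    # one's completion signal
    for i, child in enumerate(children):
        _run_node(child, prefix + (i,), ctx)


def run_nodes(nodes: list[ProtocolNode], store: VariableStore,
              responder: Responder, clock: SimulatedClock,
              rng: Optional[np.random.Generator] = None, *,
              location_provider: Optional[LocationProvider] = None,
              trace: Optional[ExecutionTrace] = None,
              participant_id: str = "p0", session_index: int = 0,
              trigger_time: Optional[datetime] = None,
              deadline: Optional[datetime] = None,
              path_prefix: NodePath = (),
              ) -> tuple[list[DataRecord], ExecutionTrace]:
    """Execute an ordered list of protocol nodes.

    Returns the captured records and the execution trace.  Raises
    :class:`SessionDeclined` / :class:`SessionExpired` when the responder
    declines or the expiry deadline passes (the scheduler turns these into
    missed triggers), and :class:`DomainViolationError` for out-of-domain
    answers.
    """
    ctx = RunContext(
        store=store, responder=responder, clock=clock, rng=rng,
        location_provider=location_provider,
        trace=trace if trace is not None else ExecutionTrace(),
        participant_id=participant_id, session_index=session_index,
        trigger_time=trigger_time, deadline=deadline)
    _run_children(nodes, path_prefix, ctx)
    return ctx.records, ctx.trace
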