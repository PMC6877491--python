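"""Synthetic participants and random protocol fixtures.

Two jobs: (1) simulate whole studies against a protocol document with a
cohort of seeded synthetic participants, each with a per-trigger Bernoulli
compliance probability, a latency model and an answering policy; (2)
generate random *valid* protocol documents (lint-clean by construction)
for property-based testing of the parser, linter and runtime.

Compliance is modelled as independent per-trigger Bernoulli draws and
latency as either a fixed delay or an exponential with a given mean —
the simplest defensible models; time-varying compliance is an extension
hook, not a default.  Seeds derive deterministically from one master seed
so a whole simulated study is reproducible bit-for-bit.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional

import numpy as np

from .document_model import (
    ChooseNode,
    OtherwiseBranch,
    ProtocolDocument,
    ProtocolNode,
    RawHtmlNode,
    ScreenNode,
    SequenceNode,
    SessionNode,
    WhenBranch,
    WidgetNode,
    serialize_protocol,
)
from .linter import format_diagnostics, has_errors, lint
from .records_io import RecordSet, protocol_checksum
from .runtime import Responder, ScreenResponse
from .scheduler import StudyConfig, StudyResult, expand_all_schedules, run_study_clock
from .widgets import ValueDomain

__all__ = [
    "ENGINE_VERSION",
    "FREE_TEXT_VOCABULARY",
    "LatencyModel",
    "ParticipantProfile",
    "RandomResponder",
    "ScriptedResponder",
    "LintError",
    "random_responder",
    "derive_seed",
    "make_profiles",
    "simulate_study",
    "GeneratorParams",
    "generate_protocol",
]

ENGINE_VERSION = "0.1.0"

#: small fixed vocabulary for simulated free-text answers
FREE_TEXT_VOCABULARY = (
    "fine", "okay", "tired", "busy", "at home", "with friends",
    "stressed", "relaxed", "on my way", "nothing much",
)


class LintError(RuntimeError):
    """The protocol has lint errors and the run was not forced."""


@dataclass(frozen=True)
class LatencyModel:
    """Response delay per screen: ``fixed`` seconds or ``exponential``
    with the given mean."""

    kind: str = "exponential"  # fixed | exponential
    seconds: float = 30.0

    def __post_init__(self):
        if self.kind not in ("fixed", "exponential"):
            raise ValueError(f"unknown latency model {self.kind!r}")
        if self.seconds < 0:
            raise ValueError("latency must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.seconds
        return float(rng.exponential(self.seconds))


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    seed: Optional[int] = None
    compliance_p: float = 1.0
    latency_model: LatencyModel = LatencyModel()
    policy: str = "random_uniform"  # random_uniform | scripted
    scripted_answers: tuple = ()  # (session_index, variable, value) rows

    def __post_init__(self):
        if not 0.0 <= self.compliance_p <= 1.0:
            raise ValueError("compliance_p must be in [0, 1]")


# --------------------------------------------------------------------------
# responders


class RandomResponder(Responder):
    """Answers uniformly over each widget's response domain, responds to a
    trigger with probability ``compliance_p``."""

    def __init__(self, profile: ParticipantProfile, seed: int):
        self.profile = profile
        self.rng = np.random.default_rng([seed, 0])

    def accepts_trigger(self, when: datetime) -> bool:
        return bool(self.rng.random() < self.profile.compliance_p)

    def _draw(self, domain: ValueDomain):
        rng = self.rng
        if domain.kind == "free_text":
            return FREE_TEXT_VOCABULARY[int(rng.integers(len(FREE_TEXT_VOCABULARY)))]
        if domain.kind == "grid":
            row = int(rng.integers(domain.rows))
            col = int(rng.integers(domain.cols))
            return f"{row},{col}"
        values = [v for v, _ in domain.options]
        if domain.multi:
            picked = [v for v in values if rng.random() < 0.5]
            return picked or [values[int(rng.integers(len(values)))]]
        return values[int(rng.integers(len(values)))]

    def respond(self, screen: ScreenNode, domains, now):
        answers = {}
        for widget, domain in zip(screen.input_widgets, domains):
            if widget.name:
                answers[widget.name] = self._draw(domain)
        return ScreenResponse(answers=answers,
                              latency=self.profile.latency_model.draw(self.rng))


class ScriptedResponder(Responder):
    """Plays back an answer table of (session_index, variable, value) rows;
    variables without a scripted value go unanswered (missing records)."""

    def __init__(self, rows, latency: float = 0.0):
        self.table: dict[tuple[int, str], str] = {
            (int(s), str(v)): str(val) for s, v, val in rows}
        self.latency = latency
        self.session_index = 0

    def begin_trigger(self, session_index: int, when: datetime) -> None:
        self.session_index = session_index

    def respond(self, screen: ScreenNode, domains, now):
        answers = {}
        for widget in screen.input_widgets:
            key = (self.session_index, widget.name)
            if widget.name and key in self.table:
                answers[widget.name] = self.table[key]
        return ScreenResponse(answers=answers, latency=self.latency)


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-participant seed: master XOR a Weyl-sequence
    increment, reduced below 2**31."""
    return (int(master_seed) ^ (0x9E3779B9 * (index + 1))) % (2**31)


def random_responder(profile: ParticipantProfile,
                     master_seed: int = 0, index: int = 0) -> RandomResponder:
    seed = profile.seed if profile.seed is not None else derive_seed(master_seed, index)
    return RandomResponder(profile, seed)


def make_profiles(n: int, compliance_p: float = 1.0,
                  latency_model: Optional[LatencyModel] = None,
                  ) -> list[ParticipantProfile]:
    """A homogeneous cohort ``p000..`` of n participants."""
    latency = latency_model or LatencyModel()
    return [ParticipantProfile(participant_id=f"p{i:03d}",
                               compliance_p=compliance_p,
                               latency_model=latency)
            for i in range(n)]


# --------------------------------------------------------------------------
# whole-study simulation


def simulate_study(doc: ProtocolDocument,
                   profiles: list[ParticipantProfile],
                   config: Optional[StudyConfig] = None,
                   master_seed: int = 0, *,
                   force: bool = False,
                   ) -> tuple[RecordSet, StudyResult]:
    """Run the full study for a cohort; returns the sorted record set
    (with run metadata) and the raw study result (traces, stores,
    summary).  Refuses lint-erroneous protocols unless ``force``."""
    config = config or StudyConfig()
    diagnostics = lint(doc, date_format=config.date_format)
    if has_errors(diagnostics) and not force:
        raise LintError("protocol has lint errors:\n"
                        + format_diagnostics(diagnostics))

    schedules = expand_all_schedules(doc, config)
    responders: dict[str, Responder] = {}
    rngs: dict[str, np.random.Generator] = {}
    seeds: dict[str, int] = {}
    for index, profile in enumerate(profiles):
        seed = profile.seed if profile.seed is not None else derive_seed(master_seed, index)
        seeds[profile.participant_id] = seed
        if profile.policy == "scripted":
            responders[profile.participant_id] = ScriptedResponder(
                profile.scripted_answers)
        else:
            responders[profile.participant_id] = RandomResponder(profile, seed)
        # independent stream for in-protocol randomness (aa-function-random)
        rngs[profile.participant_id] = np.random.default_rng([seed, 1])

    result = run_study_clock(doc, schedules, responders, config, rngs=rngs)
    record_set = RecordSet(records=list(result.records), run_metadata={
        "engine_version": ENGINE_VERSION,
        "protocol_checksum": protocol_checksum(serialize_protocol(doc)),
        "master_seed": int(master_seed),
        "participant_seeds": seeds,
        "config": {
            "date_format": config.date_format,
            "expiry_minutes": config.expiry_minutes,
            "on_overlap": config.on_overlap,
        },
        "summary": {
            "participants": result.summary.participants,
            "triggers": result.summary.triggers,
            "responses": result.summary.responses,
            "missed": result.summary.missed,
        },
        "warnings": sum(len(t.warnings) for t in result.traces.values()),
    })
    record_set.sort()
    return record_set, result


# --------------------------------------------------------------------------
# random protocol fixtures


@dataclass(frozen=True)
class GeneratorParams:
    """Size bounds for generated protocols.  size=0 collapses to the
    minimal protocol: one session, one screen, one likert."""

    max_screens: int = 3
    max_widgets_per_screen: int = 3
    max_chooses: int = 1
    max_branch_screens: int = 1
    size: int = 1  # 0 => minimal protocol


_WORDS = ("how", "are", "you", "feeling", "right", "now", "today",
          "since", "the", "last", "prompt", "please", "rate", "describe")


def _text(rng: _random.Random, low: int = 2, high: int = 6) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(rng.randint(low, high)))


class _ProtocolGenerator:
    def __init__(self, rng: _random.Random, params: GeneratorParams):
        self.rng = rng
        self.params = params
        self.counter = 0
        self.written: list[str] = []  # definitely-written, in write order

    def fresh_name(self) -> str:
        self.counter += 1
        return f"v{self.counter - 1}"

    def make_widget(self, kind: str, named: bool = True) -> WidgetNode:
        rng = self.rng
        name = self.fresh_name() if named else ""
        if kind == "textfield":
            return WidgetNode("textfield", name,
                              {"label": _text(rng)})
        if kind == "likert":
            attrs: dict = {"label": _text(rng)}
            flag = rng.choice(["five", "seven", None])
            if flag:
                attrs[flag] = True
            return WidgetNode("likert", name, attrs)
        if kind == "multiple_choice":
            n = rng.randint(2, 5)
            items = [WidgetNode("choice_item", "", {"value": str(i + 1)},
                                children=[RawHtmlNode(f"choice {_text(rng, 1, 2)}")])
                     for i in range(n)]
            attrs = {}
            if rng.random() < 0.3:
                attrs["multi"] = True
            return WidgetNode("multiple_choice", name, attrs, children=items)
        if kind == "boxgrid":
            return WidgetNode("boxgrid", name, {
                "vboxes": rng.randint(1, 4), "hboxes": rng.randint(1, 4),
                "width": 200, "height": 200,
                "top-label": _text(rng, 1, 2), "bottom-label": _text(rng, 1, 2),
                "left-label": _text(rng, 1, 2), "right-label": _text(rng, 1, 2)})
        if kind == "variable":
            return WidgetNode("variable", name, {"value": _text(rng, 1, 2)})
        if kind == "function_random":
            low = rng.randint(0, 3)
            return WidgetNode("function_random", name,
                              {"min": low, "max": low + rng.randint(0, 5)})
        return WidgetNode("geolocation", name, {})

    def make_screen(self) -> ScreenNode:
        rng = self.rng
        children: list[ProtocolNode] = []
        if rng.random() < 0.6:
            text = _text(rng)
            if self.written and rng.random() < 0.5:
                text += " {{" + rng.choice(self.written) + "}} "
            children.append(RawHtmlNode(f"<p>{text}</p>"))
        kinds = ["textfield", "likert", "multiple_choice", "boxgrid",
                 "variable", "function_random", "geolocation"]
        n = rng.randint(1, self.params.max_widgets_per_screen)
        for _ in range(n):
            widget = self.make_widget(rng.choice(kinds))
            children.append(widget)
            if widget.name:
                self.written.append(widget.name)
        return ScreenNode(children=children)

    def make_choose(self) -> ChooseNode:
        rng = self.rng
        subject = rng.choice(self.written)
        outer_written = list(self.written)
        branches: list[ProtocolNode] = []
        for value in range(rng.randint(1, 3)):
            test = rng.choice([
                f"{subject}=='{value + 1}'",
                f"{subject}<{value + 2}",
                f"{subject}=='{value + 1}'||{subject}=='{value + 2}'",
            ])
            self.written = list(outer_written)
            children = [self.make_branch_body()]
            branches.append(WhenBranch(test=test, children=children))
        if rng.random() < 0.7:
            self.written = list(outer_written)
            branches.append(OtherwiseBranch(children=[self.make_branch_body()]))
        # branch-local writes do not escape the conditional
        self.written = outer_written
        return ChooseNode(children=branches)

    def make_branch_body(self) -> ProtocolNode:
        if self.rng.random() < 0.7:
            return self.make_screen()
        return RawHtmlNode(f"<p>{_text(self.rng)}</p>")

    def make_session_specs(self) -> tuple[str, str]:
        rng = self.rng
        items = []
        for _ in range(rng.randint(1, 2)):
            day = rng.randint(1, 20)
            month = rng.randint(1, 12)
            if rng.random() < 0.5:
                span = rng.randint(0, 4)
                items.append(f"{day:02d}/{month:02d}/2018-"
                             f"{day + span:02d}/{month:02d}/2018")
            else:
                items.append(f"{day:02d}/{month:02d}/2018")
        times = sorted({f"{rng.randint(8, 21):02d}:{rng.choice([0, 15, 30, 45]):02d}"
                        for _ in range(rng.randint(1, 3))})
        return ";".join(items), ";".join(times)

    def build(self) -> ProtocolDocument:
        if self.params.size == 0:
            likert = WidgetNode("likert", self.fresh_name(),
                                {"label": "please rate", "five": True})
            session = SessionNode("01/08/2018", "10:00",
                                  children=[ScreenNode(children=[likert])])
            return ProtocolDocument(nodes=[session])
        rng = self.rng
        body: list[ProtocolNode] = []
        # a guaranteed early writer so tests and placeholders have a target
        seed_widget = self.make_widget(rng.choice(["variable", "function_random"]))
        self.written.append(seed_widget.name)
        body.append(seed_widget)
        n_screens = rng.randint(1, self.params.max_screens)
        choose_budget = self.params.max_chooses
        for _ in range(n_screens):
            body.append(self.make_screen())
            if choose_budget and self.written and rng.random() < 0.6:
                body.append(self.make_choose())
                choose_budget -= 1
        dates, times = self.make_session_specs()
        session = SessionNode(dates, times,
                              children=[SequenceNode(children=body)])
        nodes: list[ProtocolNode] = []
        if rng.random() < 0.5:
            nodes.append(RawHtmlNode(f"<h1>{_text(rng, 2, 4)}</h1>"))
        nodes.append(session)
        return ProtocolDocument(nodes=nodes)


def generate_protocol(gen_seed: int,
                      size_params: Optional[GeneratorParams] = None,
                      ) -> ProtocolDocument:
    """A random valid protocol: screens of random widgets inside a session
    sequence, conditionals reading previously-written variables, adaptive
    text, and a random date/time schedule.  Lint-clean by construction."""
    params = size_params or GeneratorParams()
    rng = _random.Random(gen_seed)
    return _ProtocolGenerator(rng, params).build()
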