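from datetime import datetime

import pytest

import aaproto as A
from aaproto import examples as E


@pytest.fixture
def diary_doc():
    return A.parse_protocol(E.DIARY_PROTOCOL, source_name="diary")


@pytest.fixture
def clock():
    return A.SimulatedClock(datetime(2018, 8, 1, 10, 0))


class DictResponder(A.Responder):
    """Answers every screen from a fixed mapping; names absent from the
    mapping go unanswered."""

    def __init__(self, answers=None, latency=0.0):
        self.answers = answers or {}
        self.latency = latency

    def respond(self, screen, domains, now):
        picked = {w.name: self.answers[w.name]
                  for w in screen.input_widgets
                  if w.name and w.name in self.answers}
        return A.ScreenResponse(answers=picked, latency=self.latency)


class FirstOptionResponder(A.Responder):
    """Deterministically answers each widget with the first legal value."""

    def respond(self, screen, domains, now):
        answers = {}
        for widget, domain in zip(screen.input_widgets, domains):
            if not widget.name:
                continue
            if domain.kind == "free_text":
                answers[widget.name] = "text"
            elif domain.kind == "grid":
                answers[widget.name] = "0,0"
            elif domain.multi:
                answers[widget.name] = [domain.options[0][0]]
            else:
                answers[widget.name] = domain.options[0][0]
        return A.ScreenResponse(answers=answers, latency=1.0)


@pytest.fixture
def dict_responder():
    return DictResponder


@pytest.fixture
def first_option_responder():
    return FirstOptionResponder()
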