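"""Lazy instantiation, sequence control signals and screen submission."""

from datetime import datetime

import numpy as np
import pytest

import aaproto as A
from aaproto import examples as E
from aaproto.runtime import (
    DomainViolationError,
    SessionDeclined,
    UnknownWidgetError,
    evaluate_choose,
    submit_screen,
)

from conftest import DictResponder, FirstOptionResponder

START = datetime(2018, 8, 1, 10, 0)


def run_fragment(html, responder, rng=None, store=None):
    doc = A.parse_protocol(html)
    store = store or A.VariableStore()
    clock = A.SimulatedClock(START)
    records, trace = A.run_nodes(doc.nodes, store, responder, clock, rng)
    return records, trace, store


def screen_instantiations(trace):
    return [e.path for e in trace.events
            if e.kind == "instantiated" and dict(e.detail).get("tag") == "aa-screen"]


class TestSequencing:
    def test_three_screens_run_in_document_order(self):
        _, trace, _ = run_fragment(E.SEQUENCE_THREE_SCREENS, DictResponder())
        paths = screen_instantiations(trace)
        assert len(paths) == 3
        assert paths == sorted(paths)

    def test_each_screen_starts_after_the_previous_completes(self):
        _, trace, _ = run_fragment(E.SEQUENCE_THREE_SCREENS,
                                   DictResponder(latency=10.0))
        times = [e.time for e in trace.events if e.kind == "completed"]
        assert times == sorted(times)

    def test_empty_sequence_completes_immediately_with_no_records(self):
        records, trace, _ = run_fragment("<aa-sequence></aa-sequence>",
                                         DictResponder())
        assert records == []
        kinds = [e.kind for e in trace.events]
        assert kinds == ["instantiated", "completed"]

    def test_bare_input_widget_runs_as_single_widget_screen(self):
        records, _, store = run_fragment(E.LIKERT_FIVE, FirstOptionResponder())
        (record,) = records
        assert (record.variable, record.value) == ("myScale", "1")
        assert store.get("myScale") == "1"


class TestConditionals:
    def test_first_true_branch_wins(self):
        choose = A.parse_protocol(E.CHOOSE).nodes[0]
        assert evaluate_choose(choose, {"myVariable": "myValue"}) == 0
        assert evaluate_choose(choose, {"myVariable": "otherValue"}) == 1

    def test_otherwise_when_no_test_holds(self):
        choose = A.parse_protocol(E.CHOOSE).nodes[0]
        assert evaluate_choose(choose, {"myVariable": "somethingElse"}) == "otherwise"

    def test_none_when_no_test_holds_and_no_otherwise(self):
        html = ('<aa-choose><aa-when test="v==1">a</aa-when></aa-choose>')
        (choose,) = A.parse_protocol(html).nodes
        assert evaluate_choose(choose, {}) is None

    def test_ties_break_by_document_order(self):
        html = ('<aa-choose><aa-when test="1==1">a</aa-when>'
                '<aa-when test="1==1">b</aa-when></aa-choose>')
        (choose,) = A.parse_protocol(html).nodes
        assert evaluate_choose(choose, {}) == 0

    def test_unparseable_test_is_false_with_warning(self):
        html = ('<aa-choose><aa-when test="=== broken">a</aa-when>'
                "<aa-otherwise>b</aa-otherwise></aa-choose>")
        (choose,) = A.parse_protocol(html).nodes
        warnings = []
        assert evaluate_choose(choose, {}, warn=warnings.append) == "otherwise"
        assert warnings

    @pytest.mark.parametrize("outcome", [1, 2, 3])
    def test_forced_branching_instantiates_exactly_one_group(self, outcome):
        html = E.RANDOM_BRANCHING.replace('min="1" max="3"',
                                          f'min="{outcome}" max="{outcome}"')
        records, trace, store = run_fragment(html, FirstOptionResponder(),
                                             rng=np.random.default_rng(0))
        assert store.get("random_choice") == outcome
        group_events = [e for e in trace.events
                        if e.kind == "instantiated"
                        and dict(e.detail).get("tag") == "aa-multiple-choice"]
        assert len(group_events) == 1
        names = {n for n in store.values if n.startswith("behavior_")}
        assert names == {f"behavior_{'abc'[outcome - 1]}"}

    def test_three_distinct_groups_across_all_outcomes(self):
        seen = set()
        for outcome in (1, 2, 3):
            html = E.RANDOM_BRANCHING.replace(
                'min="1" max="3"', f'min="{outcome}" max="{outcome}"')
            _, _, store = run_fragment(html, FirstOptionResponder(),
                                       rng=np.random.default_rng(0))
            seen |= {n for n in store.values if n.startswith("behavior_")}
        assert seen == {"behavior_a", "behavior_b", "behavior_c"}

    def test_unselected_branch_content_never_instantiated(self):
        html = E.RANDOM_BRANCHING.replace('min="1" max="3"', 'min="2" max="2"')
        doc = A.parse_protocol(html)
        _, trace, _ = run_fragment(html, FirstOptionResponder(),
                                   rng=np.random.default_rng(0))
        instantiated = set(trace.instantiated_paths())
        # locate the unselected branches and assert no descendant appears
        from aaproto.document_model import WhenBranch, format_path, iter_nodes
        selected_prefixes = {p for p in instantiated}
        for path, node in iter_nodes(doc):
            if isinstance(node, WhenBranch) and "random_choice==2" not in node.test:
                prefix = format_path(path)
                assert all(not p.startswith(prefix) for p in instantiated)


class TestScreens:
    def test_single_textfield_answer_yields_one_record(self, clock):
        (screen,) = A.parse_protocol(
            '<aa-screen><aa-textfield name="myText"></aa-textfield></aa-screen>'
        ).nodes
        store = A.VariableStore()
        records = submit_screen(screen, {"myText": "hello"}, store, clock)
        (record,) = records
        assert (record.variable, record.value, record.missing) == (
            "myText", "hello", False)
        assert store.get("myText") == "hello"

    def test_screen_without_inputs_completes_with_zero_records(self):
        records, trace, _ = run_fragment("<aa-screen><p>info only</p></aa-screen>",
                                         DictResponder())
        assert records == []
        assert any(e.kind == "completed" for e in trace.events)

    def test_unanswered_widget_yields_missing_marker_record(self, clock):
        (screen,) = A.parse_protocol(
            '<aa-screen><aa-likert name="mood" five></aa-likert></aa-screen>').nodes
        (record,) = submit_screen(screen, {}, A.VariableStore(), clock)
        assert record.missing is True and record.value == ""

    def test_multi_select_yields_one_record_per_option(self, clock):
        html = ('<aa-screen><aa-multiple-choice name="m" multi>'
                '<aa-choice-item value="1">a</aa-choice-item>'
                '<aa-choice-item value="2">b</aa-choice-item>'
                '<aa-choice-item value="3">c</aa-choice-item>'
                "</aa-multiple-choice></aa-screen>")
        (screen,) = A.parse_protocol(html).nodes
        store = A.VariableStore()
        records = submit_screen(screen, {"m": ["1", "3"]}, store, clock)
        assert [r.value for r in records] == ["1", "3"]
        assert store.get("m") == "1;3"

    def test_out_of_domain_answer_is_rejected_naming_the_widget(self, clock):
        (screen,) = A.parse_protocol(
            '<aa-screen><aa-likert name="mood" five></aa-likert></aa-screen>').nodes
        with pytest.raises(DomainViolationError, match="mood"):
            submit_screen(screen, {"mood": "9"}, A.VariableStore(), clock)

    def test_answer_for_absent_widget_is_rejected(self, clock):
        (screen,) = A.parse_protocol("<aa-screen></aa-screen>").nodes
        with pytest.raises(UnknownWidgetError):
            submit_screen(screen, {"ghost": "1"}, A.VariableStore(), clock)

    def test_auto_widget_inside_screen_writes_the_store(self):
        html = ('<aa-screen><aa-variable name="v" value="42"></aa-variable>'
                "</aa-screen>")
        _, _, store = run_fragment(html, DictResponder())
        assert store.get("v") == "42"

    def test_no_response_raises_session_declined(self):
        class Refuses(A.Responder):
            def respond(self, screen, domains, now):
                return None

        with pytest.raises(SessionDeclined):
            run_fragment("<aa-screen>hi</aa-screen>", Refuses())


class TestStoreAndDeterminism:
    def test_adaptive_text_renders_earlier_answers(self, diary_doc):
        responder = DictResponder({"mood": "3", "company": "others",
                                   "social_pleasant": "5"})
        session = diary_doc.sessions[0]
        store = A.VariableStore()
        clock = A.SimulatedClock(START)
        _, trace = A.run_nodes(session.children, store, responder, clock)
        rendered = [dict(e.detail).get("text", "") for e in trace.events
                    if e.kind == "completed"]
        assert any("(others)" in text for text in rendered)

    def test_records_match_store_values(self, diary_doc):
        responder = DictResponder({"mood": "4", "company": "alone",
                                   "activity": "reading"})
        session = diary_doc.sessions[0]
        store = A.VariableStore()
        records, _ = A.run_nodes(session.children, store, responder,
                                 A.SimulatedClock(START))
        for record in records:
            if not record.missing:
                assert str(store.get(record.variable)) == record.value

    def test_repeated_runs_are_byte_identical(self, diary_doc):
        outputs = []
        for _ in range(2):
            responder = A.RandomResponder(
                A.ParticipantProfile("p0", compliance_p=1.0), seed=11)
            store = A.VariableStore()
            records, trace = A.run_nodes(
                diary_doc.sessions[0].children, store, responder,
                A.SimulatedClock(START), np.random.default_rng(3))
            outputs.append((records, trace.to_jsonl()))
        assert outputs[0] == outputs[1]

    def test_write_log_keeps_every_write(self):
        store = A.VariableStore()
        store.set("a", "1")
        store.set("a", "2")
        assert store.get("a") == "2"
        assert [entry[1:] for entry in store.write_log] == [("a", "1"), ("a", "2")]
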