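"""Static diagnostics: duplicates, dangling references, structural faults."""

import random

import pytest

import aaproto as A
from aaproto import examples as E
from aaproto.cohort_sim import generate_protocol
from aaproto.document_model import (
    ChooseNode,
    OtherwiseBranch,
    ProtocolDocument,
    RawHtmlNode,
    WhenBranch,
    WidgetNode,
)
from aaproto.linter import has_errors, lint

from oracles import has_dangling_read


def codes(diagnostics):
    return [d.code for d in diagnostics]


class TestIndividualChecks:
    def test_duplicate_variable_names(self):
        doc = A.parse_protocol(
            '<aa-likert name="mood" five></aa-likert>'
            '<aa-textfield name="mood"></aa-textfield>')
        found = [d for d in lint(doc) if d.code == "DUPLICATE_VARIABLE"]
        assert len(found) == 1
        assert found[0].severity == "error"
        assert "mood" in found[0].message

    def test_allow_rewrite_suppresses_duplicates(self):
        doc = A.parse_protocol(
            '<aa-variable name="mood" value="1"></aa-variable>'
            '<aa-likert name="mood" five></aa-likert>')
        assert "DUPLICATE_VARIABLE" in codes(lint(doc))
        assert "DUPLICATE_VARIABLE" not in codes(
            lint(doc, allow_rewrite=["mood"]))

    def test_clean_diary_document_has_zero_diagnostics(self, diary_doc):
        assert lint(diary_doc) == []

    def test_misspelled_test_reference_is_dangling(self):
        doc = A.parse_protocol(
            '<aa-screen><aa-likert name="mood" five></aa-likert></aa-screen>'
            '<aa-choose><aa-when test="moood==\'1\'">x</aa-when></aa-choose>')
        found = [d for d in lint(doc) if d.code == "DANGLING_REFERENCE"]
        assert len(found) == 1 and "moood" in found[0].message

    def test_placeholder_reference_before_write_is_dangling(self):
        doc = A.parse_protocol(
            "<p>hello {{mood}}</p>"
            '<aa-screen><aa-likert name="mood" five></aa-likert></aa-screen>')
        assert "DANGLING_REFERENCE" in codes(lint(doc))

    def test_screen_text_cannot_read_same_screen_answers(self):
        doc = A.parse_protocol(
            '<aa-screen><aa-likert name="mood" five></aa-likert>'
            "<p>you said {{mood}}</p></aa-screen>")
        assert "DANGLING_REFERENCE" in codes(lint(doc))

    def test_auto_widget_write_visible_later_on_same_screen(self):
        doc = A.parse_protocol(
            '<aa-screen><aa-variable name="v" value="1"></aa-variable>'
            "<p>{{v}}</p></aa-screen>")
        assert "DANGLING_REFERENCE" not in codes(lint(doc))

    def test_write_on_only_one_branch_does_not_dominate(self):
        doc = A.parse_protocol(
            '<aa-variable name="sel" value="1"></aa-variable>'
            '<aa-choose><aa-when test="sel==\'1\'">'
            '<aa-variable name="x" value="2"></aa-variable></aa-when></aa-choose>'
            "<p>{{x}}</p>")
        assert "DANGLING_REFERENCE" in codes(lint(doc))

    def test_write_on_every_branch_including_otherwise_dominates(self):
        doc = A.parse_protocol(
            '<aa-variable name="sel" value="1"></aa-variable>'
            '<aa-choose><aa-when test="sel==\'1\'">'
            '<aa-variable name="x" value="2"></aa-variable></aa-when>'
            '<aa-otherwise><aa-variable name="x2" value="3"></aa-variable>'
            "</aa-otherwise></aa-choose>")
        doc2 = A.parse_protocol(
            '<aa-variable name="sel" value="1"></aa-variable>'
            '<aa-choose><aa-when test="sel==\'1\'">'
            '<aa-variable name="x" value="2"></aa-variable></aa-when>'
            '<aa-otherwise><aa-variable name="x" value="3"></aa-variable>'
            "</aa-otherwise></aa-choose>"
            "<p>{{x}}</p>")
        assert "DANGLING_REFERENCE" not in codes(lint(doc))
        relevant = [d for d in lint(doc2) if d.code == "DANGLING_REFERENCE"]
        assert relevant == []

    def test_unknown_element_is_a_warning(self):
        doc = A.parse_protocol("<aa-slider name='s'></aa-slider>")
        (diag,) = [d for d in lint(doc) if d.code == "UNKNOWN_ELEMENT"]
        assert diag.severity == "warning"

    def test_unparseable_test_is_an_error(self):
        doc = A.parse_protocol(
            '<aa-choose><aa-when test="=== nope">x</aa-when></aa-choose>')
        assert "BAD_EXPRESSION" in codes(lint(doc))

    def test_malformed_schedule_is_an_error(self):
        doc = A.parse_protocol(
            '<aa-session dates="99/99/2018" times="10:00"></aa-session>')
        assert "BAD_SCHEDULE" in codes(lint(doc))

    def test_conflicting_likert_flags(self):
        doc = A.parse_protocol('<aa-likert name="s" five seven></aa-likert>')
        assert "CONFLICTING_FLAGS" in codes(lint(doc))

    def test_nested_screen_warns(self):
        doc = A.parse_protocol(
            "<aa-screen><aa-screen>inner</aa-screen></aa-screen>")
        (diag,) = [d for d in lint(doc) if d.code == "NESTED_SCREEN"]
        assert diag.severity == "warning"

    def test_unnamed_input_widget_warns_but_is_not_an_error(self):
        doc = A.parse_protocol(E.SCREEN_WITH_CONTENT)
        diagnostics = lint(doc)
        assert any(d.code == "MISSING_NAME" for d in diagnostics)
        assert not has_errors(diagnostics)

    def test_deterministic_output(self, diary_doc):
        doc = A.parse_protocol(
            '<aa-likert name="a" five seven></aa-likert>'
            '<aa-likert name="a" five></aa-likert>'
            "<p>{{ghost}}</p>")
        assert lint(doc) == lint(doc)
        assert [d.node_path for d in lint(doc)] == sorted(
            d.node_path for d in lint(doc))


# ---------------------------------------------------------------------------
# soundness against exhaustive path enumeration

_NAMES = ["x", "y", "z"]


def gen_steps(rng, depth=2, width=4):
    steps = []
    for _ in range(rng.randint(1, width)):
        roll = rng.random()
        if roll < 0.40:
            steps.append(("write", rng.choice(_NAMES)))
        elif roll < 0.70:
            steps.append(("read", rng.choice(_NAMES)))
        elif depth > 0:
            branches = [gen_steps(rng, depth - 1, 2)
                        for _ in range(rng.randint(1, 2))]
            steps.append(("choose", branches, rng.random() < 0.5))
    return steps


def steps_to_nodes(steps):
    nodes = []
    for step in steps:
        if step[0] == "write":
            nodes.append(WidgetNode("variable", step[1], {"value": "1"}))
        elif step[0] == "read":
            nodes.append(RawHtmlNode("<p>{{" + step[1] + "}}</p>"))
        else:
            _, branches, has_otherwise = step
            children = [WhenBranch(test="sel=='1'",
                                   children=steps_to_nodes(branch))
                        for branch in branches]
            if has_otherwise:
                last = children.pop()
                children.append(OtherwiseBranch(children=last.children))
            nodes.append(ChooseNode(children=children))
    return nodes


def steps_to_doc(steps):
    guard = WidgetNode("variable", "sel", {"value": "1"})
    return ProtocolDocument(nodes=[guard] + steps_to_nodes(steps))


class TestDanglingReferenceSoundness:
    @pytest.mark.parametrize("chunk", range(4))
    def test_matches_exhaustive_path_enumeration(self, chunk):
        rng = random.Random(100 + chunk)
        for _ in range(60):
            steps = gen_steps(rng)
            doc = steps_to_doc(steps)
            flagged = any(d.code == "DANGLING_REFERENCE" for d in lint(doc))
            assert flagged == has_dangling_read(steps), steps


class TestMutationHarness:
    """Every injected duplicate-name or dangling-reference fault is caught."""

    def test_duplicating_a_widget_name_is_always_flagged(self):
        applicable = 0
        for seed in range(60):
            doc = generate_protocol(seed)
            named = [w for w in A.collect_widgets(doc) if w.name]
            if len(named) < 2:
                continue
            applicable += 1
            assert not has_errors(lint(doc))
            named[1].name = named[0].name
            assert any(d.code == "DUPLICATE_VARIABLE" for d in lint(doc)), seed
        assert applicable >= 20

    def test_renaming_a_referenced_widget_is_always_flagged(self):
        applicable = 0
        for seed in range(60):
            doc = generate_protocol(seed)
            referenced = _first_referenced_widget(doc)
            if referenced is None:
                continue
            applicable += 1
            assert not has_errors(lint(doc))
            referenced.name = referenced.name + "_renamed"
            assert any(d.code == "DANGLING_REFERENCE" for d in lint(doc)), seed
        assert applicable >= 20


def _first_referenced_widget(doc):
    """The widget writing the first variable some test or placeholder reads."""
    import re

    from aaproto.document_model import iter_nodes
    from aaproto.expression import expr_variables, parse_expr
    from aaproto.widgets import template_variables

    read: set[str] = set()
    for _, node in iter_nodes(doc):
        if isinstance(node, WhenBranch) and node.test.strip():
            read |= expr_variables(parse_expr(node.test))
        if isinstance(node, RawHtmlNode):
            read |= set(template_variables(node.content))
        if isinstance(node, WidgetNode):
            for value in node.attributes.values():
                if isinstance(value, str):
                    read |= set(template_variables(value))
    for _, node in iter_nodes(doc):
        if isinstance(node, WidgetNode) and node.name in read:
            return node
    return None
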