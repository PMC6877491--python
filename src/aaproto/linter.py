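"""Static diagnostics for protocol documents.

A faulty protocol does not halt at run time — a duplicated variable name
silently overwrites earlier answers, and a test or placeholder referring
to a variable that is never written simply evaluates false or renders
verbatim.  Both faults corrupt the collected data while the study appears
to run normally, which is exactly why they escape attention in the field.
The linter catches them before any participant is enrolled.

Severity policy: anything that silently corrupts data (duplicate names,
dangling reads, bad expressions, bad schedules) is an ``error``;
stylistic or recoverable issues are ``warning``.  Reference analysis is
conservative: a read is flagged unless a write dominates it on every path
that can reach it, so dynamically impossible branches may over-warn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .document_model import (
    ChooseNode,
    NodePath,
    OtherwiseBranch,
    ProtocolDocument,
    ProtocolNode,
    RawHtmlNode,
    ScreenNode,
    SequenceNode,
    SessionNode,
    SourceSpan,
    UnknownNode,
    WhenBranch,
    WidgetNode,
    format_path,
    iter_nodes,
)
from .expression import ExpressionSyntaxError, expr_variables, parse_expr
from .scheduler import ScheduleError, parse_dates, parse_times
from .widgets import template_variables

__all__ = ["Diagnostic", "lint", "has_errors", "format_diagnostics"]


@dataclass(frozen=True)
class Diagnostic:
    code: str
    severity: str  # error | warning
    message: str
    node_path: NodePath
    source_span: SourceSpan = (0, 0)

    def render(self) -> str:
        line, column = self.source_span
        where = f" (line {line}, column {column})" if line else ""
        return (f"{self.severity} {self.code} {format_path(self.node_path)}: "
                f"{self.message}{where}")

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity,
            "message": self.message,
            "node_path": format_path(self.node_path),
            "line": self.source_span[0],
            "column": self.source_span[1],
        }


def has_errors(diagnostics: Iterable[Diagnostic]) -> bool:
    return any(d.severity == "error" for d in diagnostics)


def format_diagnostics(diagnostics: Iterable[Diagnostic]) -> str:
    return "\n".join(d.render() for d in diagnostics)


# --------------------------------------------------------------------------


def _widget_writes(node: ProtocolNode) -> bool:
    return (isinstance(node, WidgetNode)
            and node.kind != "choice_item" and bool(node.name))


class _Linter:
    def __init__(self, doc: ProtocolDocument, allow_rewrite: frozenset,
                 date_format: str):
        self.doc = doc
        self.allow_rewrite = allow_rewrite
        self.date_format = date_format
        self.diagnostics: list[Diagnostic] = []

    def report(self, code: str, severity: str, message: str,
               path: NodePath, span: SourceSpan = (0, 0)) -> None:
        self.diagnostics.append(Diagnostic(code, severity, message, path, span))

    # -- per-node checks --------------------------------------------------

    def node_checks(self) -> None:
        screen_paths: list[NodePath] = []
        for path, node in iter_nodes(self.doc):
            if isinstance(node, UnknownNode):
                self.report("UNKNOWN_ELEMENT", "warning",
                            f"unknown element <{node.tag_name}>",
                            path, node.source_span)
            elif isinstance(node, WidgetNode):
                self.widget_checks(path, node)
            elif isinstance(node, WhenBranch):
                if not node.test.strip():
                    self.report("BAD_EXPRESSION", "error",
                                "empty test attribute", path, node.source_span)
                else:
                    try:
                        parse_expr(node.test)
                    except ExpressionSyntaxError as exc:
                        self.report("BAD_EXPRESSION", "error",
                                    f"unparseable test {node.test!r}: {exc}",
                                    path, node.source_span)
            elif isinstance(node, SessionNode):
                for spec, parser in ((node.dates_spec, self.check_dates),
                                     (node.times_spec, parse_times)):
                    try:
                        parser(spec)
                    except ScheduleError as exc:
                        self.report("BAD_SCHEDULE", "error", str(exc),
                                    path, node.source_span)
            elif isinstance(node, ScreenNode):
                if any(path[:len(p)] == p for p in screen_paths):
                    self.report("NESTED_SCREEN", "warning",
                                "aa-screen nested inside aa-screen",
                                path, node.source_span)
                screen_paths.append(path)

    def check_dates(self, spec: str):
        return parse_dates(spec, self.date_format)

    def widget_checks(self, path: NodePath, node: WidgetNode) -> None:
        span = node.source_span
        if node.kind == "likert" and node.flag("five") and node.flag("seven"):
            self.report("CONFLICTING_FLAGS", "error",
                        "likert carries both 'five' and 'seven'", path, span)
        if node.kind == "function_random":
            low = node.attributes.get("min", 0)
            high = node.attributes.get("max", 0)
            if low > high:
                self.report("BAD_WIDGET", "error",
                            f"random range min {low} > max {high}", path, span)
        if node.kind == "boxgrid":
            if (node.attributes.get("vboxes", 1) < 1
                    or node.attributes.get("hboxes", 1) < 1):
                self.report("BAD_WIDGET", "error",
                            "boxgrid needs vboxes >= 1 and hboxes >= 1",
                            path, span)
        if node.kind == "multiple_choice" and not node.choice_items:
            self.report("BAD_WIDGET", "error",
                        "multiple-choice without choice items", path, span)
        if node.is_input and not node.name and node.kind != "choice_item":
            self.report("MISSING_NAME", "warning",
                        f"<{node.tag}> has no name; its answer is not captured",
                        path, span)

    # -- duplicates -------------------------------------------------------

    def duplicate_checks(self) -> None:
        seen: dict[str, NodePath] = {}
        for path, node in iter_nodes(self.doc):
            if not _widget_writes(node):
                continue
            if node.name in seen and node.name not in self.allow_rewrite:
                self.report(
                    "DUPLICATE_VARIABLE", "error",
                    f"variable name '{node.name}' already used at "
                    f"{format_path(seen[node.name])}", path, node.source_span)
            seen.setdefault(node.name, path)

    # -- reference analysis ----------------------------------------------

    def reference_checks(self) -> None:
        self.walk(self.doc.nodes, (), frozenset())

    def check_text_refs(self, text: str, written: frozenset,
                        path: NodePath, span: SourceSpan) -> None:
        for name in template_variables(text):
            if name not in written:
                self.report("DANGLING_REFERENCE", "error",
                            f"placeholder '{{{{{name}}}}}' reads a variable "
                            "not written on every path to it", path, span)

    def check_widget_refs(self, node: WidgetNode, written: frozenset,
                          path: NodePath) -> None:
        for key in ("label", "value", "top-label", "bottom-label",
                    "left-label", "right-label"):
            value = node.attributes.get(key)
            if isinstance(value, str):
                self.check_text_refs(value, written, path, node.source_span)

    def walk(self, nodes: list[ProtocolNode], prefix: NodePath,
             written: frozenset, offset: int = 0) -> frozenset:
        """Conservative dataflow: returns the variables definitely written
        after executing ``nodes`` given ``written`` on entry."""
        for i, node in enumerate(nodes, start=offset):
            path = prefix + (i,)
            if isinstance(node, RawHtmlNode):
                self.check_text_refs(node.content, written, path,
                                     node.source_span)
            elif isinstance(node, WidgetNode):
                self.check_widget_refs(node, written, path)
                for item in node.choice_items:
                    self.check_text_refs(item.text_content, written, path,
                                         item.source_span)
                if _widget_writes(node):
                    written = written | {node.name}
            elif isinstance(node, ScreenNode):
                written = self.walk_screen(node, path, written)
            elif isinstance(node, (SequenceNode, SessionNode,
                                   WhenBranch, OtherwiseBranch)):
                written = self.walk(node.children, path, written)
            elif isinstance(node, ChooseNode):
                for j, child in enumerate(node.children):
                    if isinstance(child, (WhenBranch, OtherwiseBranch)):
                        if isinstance(child, WhenBranch) and child.test.strip():
                            try:
                                refs = expr_variables(parse_expr(child.test))
                            except ExpressionSyntaxError:
                                refs = set()  # reported as BAD_EXPRESSION
                            for name in sorted(refs):
                                if name not in written:
                                    self.report(
                                        "DANGLING_REFERENCE", "error",
                                        f"test reads '{name}' which is not "
                                        "written on every path to it",
                                        path + (j,), child.source_span)
                branch_writes = [
                    self.walk(child.children, path + (j,), written)
                    for j, child in enumerate(node.children)
                    if isinstance(child, (WhenBranch, OtherwiseBranch))]
                if node.otherwise is None:
                    branch_writes.append(written)  # nothing-selected path
                if branch_writes:
                    result = branch_writes[0]
                    for other in branch_writes[1:]:
                        result = result & other
                    written = result
            # UnknownNode subtrees are skipped at run time, so neither
            # their writes nor their reads take part in the analysis
        return written

    def walk_screen(self, screen: ScreenNode, path: NodePath,
                    written: frozenset) -> frozenset:
        """Screen content renders at instantiation, so its text may only
        reference variables written before that moment (non-interactive
        child widgets write immediately, in child order); participant
        answers become available only after the screen is submitted."""
        pending: set[str] = set()
        for j, child in enumerate(screen.children):
            child_path = path + (j,)
            if isinstance(child, RawHtmlNode):
                self.check_text_refs(child.content, written, child_path,
                                     child.source_span)
            elif isinstance(child, WidgetNode):
                self.check_widget_refs(child, written, child_path)
                for item in child.choice_items:
                    self.check_text_refs(item.text_content, written,
                                         child_path, item.source_span)
                if _widget_writes(child):
                    if child.is_auto:
                        written = written | {child.name}
                    else:
                        pending.add(child.name)
            else:
                written = self.walk([child], path, written, offset=j)
        return written | pending


def lint(doc: ProtocolDocument, *, allow_rewrite: Iterable[str] = (),
         date_format: str = "DD/MM/YYYY") -> list[Diagnostic]:
    """All diagnostics for a parsed document, in deterministic order
    (document position, then code).

    ``allow_rewrite`` suppresses DUPLICATE_VARIABLE for names that are
    intentionally overwritten (adaptive-text workflows).
    """
    engine = _Linter(doc, frozenset(allow_rewrite), date_format)
    engine.node_checks()
    engine.duplicate_checks()
    engine.reference_checks()
    engine.diagnostics.sort(key=lambda d: (d.node_path, d.code, d.message))
    return engine.diagnostics
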