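"""Typed document model for ambulatory-assessment protocol HTML.

An AA protocol is a single HTML document in which ``aa-*`` custom elements
describe both the study *materials* (input widgets such as likert scales,
text fields, multiple-choice groups) and the study *procedures* (sequences,
conditionals, triggered sampling sessions).  This module parses such a
document into a typed tree, keeps every byte of interleaved standard HTML
verbatim, and serializes the tree back to a canonical text form so that
protocols can be diffed and shared between labs.

The parser is built on the stdlib :class:`html.parser.HTMLParser`, which is
lenient about standard HTML (unclosed ``<p>`` tags are fine) while this
module enforces strict, well-nested structure for the ``aa-*`` vocabulary
itself.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field
from html.parser import HTMLParser
from typing import Iterator, Optional, Union

__all__ = [
    "ProtocolError",
    "ProtocolParseError",
    "AttributeValueError",
    "SerializationError",
    "SourceSpan",
    "NodePath",
    "RawHtmlNode",
    "WidgetNode",
    "ScreenNode",
    "SequenceNode",
    "WhenBranch",
    "OtherwiseBranch",
    "ChooseNode",
    "SessionNode",
    "UnknownNode",
    "ProtocolNode",
    "ProtocolDocument",
    "parse_protocol",
    "serialize_protocol",
    "collect_widgets",
    "iter_nodes",
    "node_at",
    "format_path",
    "WIDGET_TAGS",
    "INPUT_KINDS",
    "AUTO_KINDS",
]

SourceSpan = tuple[int, int]  # (line, column), 1-based line as reported by HTMLParser
NodePath = tuple[int, ...]  # child indices from the document root


class ProtocolError(Exception):
    """Base class for all protocol-handling errors."""


class ProtocolParseError(ProtocolError):
    """Malformed aa-* structure (bad nesting, unclosed element)."""

    def __init__(self, message: str, span: SourceSpan = (0, 0)):
        super().__init__(f"{message} (line {span[0]}, column {span[1]})" if span != (0, 0) else message)
        self.span = span


class AttributeValueError(ProtocolParseError):
    """An attribute that must be an integer is not one."""


class SerializationError(ProtocolError):
    """A node violating its invariants cannot be serialized."""


# --------------------------------------------------------------------------
# vocabulary

WIDGET_TAGS: dict[str, str] = {
    "aa-textfield": "textfield",
    "aa-boxgrid": "boxgrid",
    "aa-likert": "likert",
    "aa-multiple-choice": "multiple_choice",
    "aa-choice-item": "choice_item",
    "aa-variable": "variable",
    "aa-geolocation": "geolocation",
    "aa-function-random": "function_random",
}
KIND_TO_TAG = {v: k for k, v in WIDGET_TAGS.items()}

STRUCTURAL_TAGS = {
    "aa-screen",
    "aa-sequence",
    "aa-choose",
    "aa-when",
    "aa-otherwise",
    "aa-session",
}
KNOWN_TAGS = set(WIDGET_TAGS) | STRUCTURAL_TAGS

#: widget kinds that collect input from a participant
INPUT_KINDS = frozenset({"textfield", "boxgrid", "likert", "multiple_choice"})
#: widget kinds that produce a value without user interaction
AUTO_KINDS = frozenset({"variable", "geolocation", "function_random"})

_INT_ATTRS = frozenset({"min", "max", "vboxes", "hboxes", "width", "height"})
_FLAG_ATTRS = frozenset({"five", "seven", "multi"})

# canonical attribute order for serialization (documented normative form)
_ATTR_ORDER = [
    "name", "label", "value", "min", "max", "vboxes", "hboxes",
    "width", "height", "top-label", "bottom-label", "left-label",
    "right-label", "multi", "five", "seven", "test", "dates", "times",
    "submit-label",
]
_ATTR_RANK = {a: i for i, a in enumerate(_ATTR_ORDER)}


# --------------------------------------------------------------------------
# node types


@dataclass
class RawHtmlNode:
    """A verbatim run of non-aa markup (text, standard tags, comments)."""

    content: str
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    tag = "#raw"

    @property
    def children(self) -> list["ProtocolNode"]:
        return []


@dataclass
class WidgetNode:
    """One declarative element: an input-collecting or value-producing widget."""

    kind: str
    name: str = ""
    attributes: dict = field(default_factory=dict)
    children: list["ProtocolNode"] = field(default_factory=list)
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    @property
    def tag(self) -> str:
        return KIND_TO_TAG[self.kind]

    @property
    def is_input(self) -> bool:
        return self.kind in INPUT_KINDS

    @property
    def is_auto(self) -> bool:
        return self.kind in AUTO_KINDS

    def flag(self, name: str) -> bool:
        return bool(self.attributes.get(name, False))

    @property
    def label(self) -> str:
        return str(self.attributes.get("label", ""))

    @property
    def likert_points(self) -> int:
        """Number of scale points: 7 with the ``seven`` flag, else 5."""
        return 7 if self.flag("seven") and not self.flag("five") else 5

    @property
    def choice_items(self) -> list["WidgetNode"]:
        return [c for c in self.children
                if isinstance(c, WidgetNode) and c.kind == "choice_item"]

    @property
    def text_content(self) -> str:
        """Concatenated raw text inside the element (choice-item labels)."""
        return "".join(c.content for c in self.children if isinstance(c, RawHtmlNode))


@dataclass
class ScreenNode:
    """Groups content and widgets; completion is one submit event."""

    children: list["ProtocolNode"] = field(default_factory=list)
    submit_label: str = "submit"
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    tag = "aa-screen"

    @property
    def input_widgets(self) -> list[WidgetNode]:
        return [c for c in self.children if isinstance(c, WidgetNode) and c.is_input]


@dataclass
class SequenceNode:
    """Instantiates its children one at a time, in document order."""

    children: list["ProtocolNode"] = field(default_factory=list)
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    tag = "aa-sequence"


@dataclass
class WhenBranch:
    test: str
    children: list["ProtocolNode"] = field(default_factory=list)
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    tag = "aa-when"


@dataclass
class OtherwiseBranch:
    children: list["ProtocolNode"] = field(default_factory=list)
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    tag = "aa-otherwise"


@dataclass
class ChooseNode:
    """First-true conditional; at most one otherwise branch, always last.

    ``children`` may also hold whitespace-only :class:`RawHtmlNode` runs that
    appeared between branches in the source, preserved for round-tripping.
    """

    children: list["ProtocolNode"] = field(default_factory=list)
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    tag = "aa-choose"

    @property
    def whens(self) -> list[WhenBranch]:
        return [c for c in self.children if isinstance(c, WhenBranch)]

    @property
    def otherwise(self) -> Optional[OtherwiseBranch]:
        for c in self.children:
            if isinstance(c, OtherwiseBranch):
                return c
        return None


@dataclass
class SessionNode:
    """Sampling-session container triggered at dates x times."""

    dates_spec: str = ""
    times_spec: str = ""
    children: list["ProtocolNode"] = field(default_factory=list)
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    tag = "aa-session"


@dataclass
class UnknownNode:
    """An aa-* element outside the known vocabulary.

    Parsed rather than rejected so a faulty protocol still loads; the linter
    reports it as UNKNOWN_ELEMENT.
    """

    tag_name: str
    attributes: dict = field(default_factory=dict)
    children: list["ProtocolNode"] = field(default_factory=list)
    source_span: SourceSpan = field(default=(0, 0), compare=False, repr=False)

    @property
    def tag(self) -> str:
        return self.tag_name


ProtocolNode = Union[
    RawHtmlNode, WidgetNode, ScreenNode, SequenceNode,
    WhenBranch, OtherwiseBranch, ChooseNode, SessionNode, UnknownNode,
]


@dataclass
class ProtocolDocument:
    """Ordered protocol tree; the single source of truth for a study."""

    nodes: list[ProtocolNode] = field(default_factory=list)
    source_name: str = field(default="<string>", compare=False)
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def sessions(self) -> list[SessionNode]:
        return [n for _, n in iter_nodes(self) if isinstance(n, SessionNode)]


# --------------------------------------------------------------------------
# parsing


class _Frame:
    __slots__ = ("tag", "attrs", "span", "children", "raw", "raw_span")

    def __init__(self, tag: str, attrs: list, span: SourceSpan):
        self.tag = tag
        self.attrs = attrs
        self.span = span
        self.children: list[ProtocolNode] = []
        self.raw: list[str] = []
        self.raw_span: SourceSpan = (0, 0)


def _is_aa(tag: str) -> bool:
    return tag.startswith("aa-")


class _ProtocolParser(HTMLParser):
    """Event-driven parser: aa-* elements become typed nodes, everything
    else accumulates verbatim into RawHtmlNode runs."""

    def __init__(self) -> None:
        # convert_charrefs=False keeps entity/char references verbatim so raw
        # HTML survives round-trips byte-identically
        super().__init__(convert_charrefs=False)
        self.root = _Frame("#document", [], (1, 0))
        self.stack: list[_Frame] = [self.root]

    # -- raw accumulation ------------------------------------------------

    def _push_raw(self, text: str) -> None:
        frame = self.stack[-1]
        if not frame.raw:
            frame.raw_span = self.getpos()
        frame.raw.append(text)

    def _flush_raw(self) -> None:
        frame = self.stack[-1]
        if frame.raw:
            frame.children.append(
                RawHtmlNode("".join(frame.raw), source_span=frame.raw_span))
            frame.raw = []

    # -- HTMLParser hooks ------------------------------------------------

    def handle_starttag(self, tag, attrs):
        if _is_aa(tag):
            self._check_nesting(tag)
            self._flush_raw()
            self.stack.append(_Frame(tag, attrs, self.getpos()))
        else:
            self._push_raw(self.get_starttag_text())

    def handle_startendtag(self, tag, attrs):
        if _is_aa(tag):
            self._check_nesting(tag)
            self._flush_raw()
            frame = _Frame(tag, attrs, self.getpos())
            self.stack[-1].children.append(_build_node(frame))
        else:
            self._push_raw(self.get_starttag_text())

    def handle_endtag(self, tag):
        if not _is_aa(tag):
            self._push_raw(f"</{tag}>")
            return
        if len(self.stack) < 2 or self.stack[-1].tag != tag:
            raise ProtocolParseError(
                f"unexpected closing tag </{tag}>", self.getpos())
        self._flush_raw()
        frame = self.stack.pop()
        self.stack[-1].children.append(_build_node(frame))

    def handle_data(self, data):
        self._push_raw(data)

    def handle_entityref(self, name):
        self._push_raw(f"&{name};")

    def handle_charref(self, name):
        self._push_raw(f"&#{name};")

    def handle_comment(self, data):
        self._push_raw(f"<!--{data}-->")

    def handle_decl(self, decl):
        self._push_raw(f"<!{decl}>")

    def handle_pi(self, data):
        self._push_raw(f"<?{data}>")

    # -- structural checks ------------------------------------------------

    def _check_nesting(self, tag: str) -> None:
        parent = self.stack[-1].tag
        if tag in ("aa-when", "aa-otherwise") and parent != "aa-choose":
            raise ProtocolParseError(
                f"<{tag}> is only allowed inside <aa-choose>", self.getpos())
        if tag == "aa-choice-item" and parent != "aa-multiple-choice":
            raise ProtocolParseError(
                "<aa-choice-item> is only allowed inside <aa-multiple-choice>",
                self.getpos())

    def finish(self) -> list[ProtocolNode]:
        self.close()
        if len(self.stack) != 1:
            frame = self.stack[-1]
            raise ProtocolParseError(f"unclosed <{frame.tag}>", frame.span)
        self._flush_raw()
        return self.root.children


def _typed_attributes(tag: str, attrs: list, span: SourceSpan) -> dict:
    out: dict = {}
    for key, value in attrs:
        if key in _FLAG_ATTRS:
            out[key] = True
        elif key in _INT_ATTRS:
            try:
                out[key] = int(str(value))
            except (TypeError, ValueError):
                raise AttributeValueError(
                    f"<{tag}> attribute {key}={value!r} must be an integer", span)
        else:
            out[key] = "" if value is None else value
    return out


def _build_node(frame: _Frame) -> ProtocolNode:
    tag, span, children = frame.tag, frame.span, frame.children
    if tag in WIDGET_TAGS:
        attrs = _typed_attributes(tag, frame.attrs, span)
        name = str(attrs.pop("name", ""))
        return WidgetNode(kind=WIDGET_TAGS[tag], name=name, attributes=attrs,
                          children=children, source_span=span)
    attrs = _typed_attributes(tag, frame.attrs, span)
    if tag == "aa-screen":
        return ScreenNode(children=children,
                          submit_label=str(attrs.get("submit-label", "submit")),
                          source_span=span)
    if tag == "aa-sequence":
        return SequenceNode(children=children, source_span=span)
    if tag == "aa-when":
        return WhenBranch(test=str(attrs.get("test", "")), children=children,
                          source_span=span)
    if tag == "aa-otherwise":
        return OtherwiseBranch(children=children, source_span=span)
    if tag == "aa-choose":
        _check_choose_children(children, span)
        return ChooseNode(children=children, source_span=span)
    if tag == "aa-session":
        return SessionNode(dates_spec=str(attrs.get("dates", "")),
                           times_spec=str(attrs.get("times", "")),
                           children=children, source_span=span)
    # unknown aa-* tag: keep raw attributes, flag for the linter
    raw_attrs = {k: ("" if v is None else v) for k, v in frame.attrs}
    return UnknownNode(tag_name=tag, attributes=raw_attrs, children=children,
                       source_span=span)


def _check_choose_children(children: list[ProtocolNode], span: SourceSpan) -> None:
    seen_otherwise = False
    for child in children:
        if isinstance(child, RawHtmlNode):
            if child.content.strip():
                raise ProtocolParseError(
                    "<aa-choose> may only contain <aa-when>/<aa-otherwise>",
                    child.source_span)
            continue
        if isinstance(child, OtherwiseBranch):
            if seen_otherwise:
                raise ProtocolParseError(
                    "<aa-choose> may contain at most one <aa-otherwise>", span)
            seen_otherwise = True
        elif isinstance(child, WhenBranch):
            if seen_otherwise:
                raise ProtocolParseError(
                    "<aa-otherwise> must be the last branch of <aa-choose>", span)
        else:
            raise ProtocolParseError(
                "<aa-choose> may only contain <aa-when>/<aa-otherwise>", span)


def parse_protocol(html_text: str, source_name: str = "<string>") -> ProtocolDocument:
    """Parse protocol HTML into a :class:`ProtocolDocument`.

    Standard HTML is tolerated leniently and preserved verbatim; aa-*
    elements must be properly closed and well nested or a
    :class:`ProtocolParseError` (with source position) is raised.
    """
    parser = _ProtocolParser()
    parser.feed(html_text)
    nodes = parser.finish()
    return ProtocolDocument(nodes=nodes, source_name=source_name)


# --------------------------------------------------------------------------
# serialization


def _escape_attr(value) -> str:
    return _html.escape(str(value), quote=True)


def _attr_sort_key(key: str):
    return (_ATTR_RANK.get(key, len(_ATTR_ORDER)), key)


def _open_tag(tag: str, attrs: dict) -> str:
    parts = [tag]
    for key in sorted(attrs, key=_attr_sort_key):
        value = attrs[key]
        if key in _FLAG_ATTRS or value is True:
            if value:
                parts.append(key)
        else:
            parts.append(f'{key}="{_escape_attr(value)}"')
    return "<" + " ".join(parts) + ">"


def _serialize_node(node: ProtocolNode, path: NodePath) -> str:
    if isinstance(node, RawHtmlNode):
        return node.content
    inner = "".join(_serialize_node(c, path + (i,))
                    for i, c in enumerate(node.children))
    if isinstance(node, WidgetNode):
        attrs = dict(node.attributes)
        if node.name:
            attrs["name"] = node.name
        return f"{_open_tag(node.tag, attrs)}{inner}</{node.tag}>"
    if isinstance(node, ScreenNode):
        attrs = {} if node.submit_label == "submit" else {"submit-label": node.submit_label}
        return f"{_open_tag('aa-screen', attrs)}{inner}</aa-screen>"
    if isinstance(node, SequenceNode):
        return f"<aa-sequence>{inner}</aa-sequence>"
    if isinstance(node, WhenBranch):
        return f'<aa-when test="{_escape_attr(node.test)}">{inner}</aa-when>'
    if isinstance(node, OtherwiseBranch):
        return f"<aa-otherwise>{inner}</aa-otherwise>"
    if isinstance(node, ChooseNode):
        try:
            _check_choose_children(node.children, node.source_span)
        except ProtocolParseError as exc:
            raise SerializationError(
                f"invalid aa-choose at {format_path(path)}: {exc}") from exc
        return f"<aa-choose>{inner}</aa-choose>"
    if isinstance(node, SessionNode):
        attrs = {}
        if node.dates_spec:
            attrs["dates"] = node.dates_spec
        if node.times_spec:
            attrs["times"] = node.times_spec
        return f"{_open_tag('aa-session', attrs)}{inner}</aa-session>"
    if isinstance(node, UnknownNode):
        return f"{_open_tag(node.tag_name, node.attributes)}{inner}</{node.tag_name}>"
    raise SerializationError(f"unserializable node at {format_path(path)}: {node!r}")


def serialize_protocol(doc: ProtocolDocument) -> str:
    """Emit the canonical text form: lowercase tags, fixed attribute order,
    boolean flags bare, raw HTML verbatim.  ``parse_protocol`` of the output
    reproduces an equal tree."""
    return "".join(_serialize_node(n, (i,)) for i, n in enumerate(doc.nodes))


# --------------------------------------------------------------------------
# traversal helpers


def iter_nodes(doc: ProtocolDocument) -> Iterator[tuple[NodePath, ProtocolNode]]:
    """Depth-first, document-order iteration over (path, node) pairs."""

    def walk(nodes: list[ProtocolNode], prefix: NodePath):
        for i, node in enumerate(nodes):
            path = prefix + (i,)
            yield path, node
            yield from walk(node.children, path)

    yield from walk(doc.nodes, ())


def node_at(doc: ProtocolDocument, path: NodePath) -> ProtocolNode:
    nodes = doc.nodes
    node: Optional[ProtocolNode] = None
    for index in path:
        node = nodes[index]
        nodes = node.children
    if node is None:
        raise KeyError("empty path")
    return node


def format_path(path: NodePath) -> str:
    return "/" + "/".join(str(i) for i in path)


def collect_widgets(doc: ProtocolDocument) -> list[WidgetNode]:
    """All widgets in document order, including those inside unselected
    branches.  Choice items are reachable via their parent's
    ``choice_items`` and are not listed separately."""
    return [n for _, n in iter_nodes(doc)
            if isinstance(n, WidgetNode) and n.kind != "choice_item"]
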