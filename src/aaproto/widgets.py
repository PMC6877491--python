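"""Per-kind widget semantics.

Each widget either offers a *response domain* to the participant
(textfield, likert, multiple-choice, boxgrid) or computes a value on
instantiation without interaction (variable, random generator,
geolocation).  This module defines both behaviours plus adaptive-text
interpolation ("pipping"): re-using a participant's earlier input inside
later item text via ``{{name}}`` placeholders.

Conventions fixed here because the element vocabulary leaves them open:

* likert option values are ``"1"``..``"k"`` left to right, with k = 5
  unless the ``seven`` flag is set;
* the random generator draws integers uniformly from the inclusive range
  [min, max];
* a boxgrid response is a 0-based ``"row,col"`` cell, row 0 at the top,
  with ``vboxes`` rows and ``hboxes`` columns;
* a geolocation fix serializes as ``"lat,lon"`` in decimal degrees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Optional, Protocol

import numpy as np

from .document_model import WidgetNode

__all__ = [
    "ValueDomain",
    "LocationFix",
    "LocationProvider",
    "FixedLocationProvider",
    "NotInputCollectingError",
    "WidgetConfigError",
    "response_domain",
    "auto_value",
    "interpolate_text",
]


class NotInputCollectingError(TypeError):
    """response_domain called on a widget that computes its own value."""


class WidgetConfigError(ValueError):
    """Widget attributes are inconsistent (e.g. random min > max)."""


@dataclass(frozen=True)
class ValueDomain:
    """The set of values a widget can legally produce."""

    kind: str  # free_text | ordinal | categorical | grid | computed
    options: tuple[tuple[str, str], ...] = ()  # (value, label) pairs
    rows: int = 0
    cols: int = 0
    multi: bool = False

    def __len__(self) -> int:
        if self.kind == "grid":
            return self.rows * self.cols
        return len(self.options)

    def contains(self, value: str) -> bool:
        """Membership test for a single serialized response value."""
        if self.kind == "free_text":
            return True
        if self.kind == "grid":
            m = re.fullmatch(r"(\d+),(\d+)", value)
            if not m:
                return False
            row, col = int(m.group(1)), int(m.group(2))
            return 0 <= row < self.rows and 0 <= col < self.cols

        return any(value == v for v, _ in self.options)


@dataclass(frozen=True)
class LocationFix:
    latitude: float
    longitude: float
    timestamp: datetime

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")

    def serialize(self) -> str:
        return f"{self.latitude:.6f},{self.longitude:.6f}"


class LocationProvider(Protocol):
    def get_fix(self, now: datetime) -> LocationFix: ...


@dataclass
class FixedLocationProvider:
    """Headless default: always reports the same configured position."""

    latitude: float = 0.0
    longitude: float = 0.0

    def get_fix(self, now: datetime) -> LocationFix:
        return LocationFix(self.latitude, self.longitude, now)


# --------------------------------------------------------------------------
# response domains


def response_domain(widget: WidgetNode) -> ValueDomain:
    """Domain of legal responses for an input-collecting widget."""
    if not widget.is_input:
        raise NotInputCollectingError(
            f"<{widget.tag}> does not collect participant input")
    if widget.kind == "textfield":
        return ValueDomain("free_text")
    if widget.kind == "likert":
        k = widget.likert_points
        options = tuple((str(i), str(i)) for i in range(1, k + 1))
        return ValueDomain("ordinal", options=options)
    if widget.kind == "multiple_choice":
        options = tuple(
            (str(item.attributes.get("value", "")), item.text_content.strip())
            for item in widget.choice_items)
        if not options:
            raise WidgetConfigError(
                f"multiple-choice '{widget.name}' has no choice items")
        return ValueDomain("categorical", options=options, multi=widget.flag("multi"))
    # boxgrid
    rows = int(widget.attributes.get("vboxes", 1))
    cols = int(widget.attributes.get("hboxes", 1))
    if rows < 1 or cols < 1:
        raise WidgetConfigError(
            f"boxgrid '{widget.name}' needs vboxes >= 1 and hboxes >= 1")
    return ValueDomain("grid", rows=rows, cols=cols)


# --------------------------------------------------------------------------
# non-interactive widgets


def auto_value(
    widget: WidgetNode,
    rng: Optional[np.random.Generator] = None,
    location_provider: Optional[LocationProvider] = None,
    now: Optional[datetime] = None,
) -> Optional[tuple[str, object]]:
    """Compute the (variable, value) a non-interactive widget writes.

    Returns None for input-collecting widgets.  Randomness is consumed only
    by the random-generator kind; ``variable`` and ``geolocation`` leave the
    stream untouched.
    """
    if widget.is_input:
        return None
    if widget.kind == "variable":
        return widget.name, str(widget.attributes.get("value", ""))
    if widget.kind == "function_random":
        low = int(widget.attributes.get("min", 0))
        high = int(widget.attributes.get("max", 0))
        if low > high:
            raise WidgetConfigError(
                f"random generator '{widget.name}': min {low} > max {high}")
        if rng is None:
            raise WidgetConfigError("random generator needs a seeded stream")
        return widget.name, int(rng.integers(low, high + 1))
    # geolocation
    provider = location_provider or FixedLocationProvider()
    fix = provider.get_fix(now or datetime(1970, 1, 1))
    return widget.name, fix.serialize()


# --------------------------------------------------------------------------
# adaptive text ("pipping")

_PLACEHOLDER_RE = re.compile(r"\{\{\s*([A-Za-z_][A-Za-z0-9_]*)\s*\}\}")


def interpolate_text(template: str, store,
                     warn: Optional[Callable[[str], None]] = None) -> str:
    """Replace ``{{name}}`` placeholders with stored values.

    Unknown names stay verbatim and emit one warning each through ``warn``;
    never raises, so a stale reference cannot halt a running study.
    """
    _missing = object()

    def replace(match: re.Match) -> str:
        name = match.group(1)
        value = store.get(name, _missing)
        if value is _missing:
            if warn is not None:
                warn(f"placeholder '{{{{{name}}}}}' has no stored value")
            return match.group(0)
        return str(value)

    return _PLACEHOLDER_RE.sub(replace, template)


def template_variables(template: str) -> list[str]:
    """Placeholder names appearing in a template, in order."""
    return [m.group(1) for m in _PLACEHOLDER_RE.finditer(template)]
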