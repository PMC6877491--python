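"""Canonical data-record model and tidy-format writers/readers.

Collected values are kept in long (tidy) form — one row per captured
value — because branching protocols do not yield a fixed column set per
session.  CSV output is RFC-4180 with a fixed header and LF newlines so
identical record sets always produce identical bytes; run metadata goes to
a ``<path>.meta.json`` sidecar.  Missing answers carry an empty value plus
an explicit ``missing`` flag, avoiding sentinel collisions with real text.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "MISSING_VALUE",
    "DataRecord",
    "RecordSet",
    "RecordFormatError",
    "write_records",
    "read_records",
    "records_to_frame",
    "pivot_wide",
    "protocol_checksum",
]

#: marker stored in ``value`` when an item went unanswered
MISSING_VALUE = ""

CSV_FIELDS = [
    "participant_id", "session_index", "trigger_time", "response_time",
    "widget_kind", "variable", "value", "missing",
]


class RecordFormatError(ValueError):
    """Schema or invariant violation in a record file; names the first bad row."""


@dataclass(frozen=True)
class DataRecord:
    """One captured value from one widget in one triggered session."""

    participant_id: str
    session_index: int
    trigger_time: datetime
    response_time: Optional[datetime]
    widget_kind: str
    variable: str
    value: str
    missing: bool = False

    def __post_init__(self):
        if self.session_index < 0:
            raise RecordFormatError("session_index must be >= 0")
        if self.response_time is not None and self.response_time < self.trigger_time:
            raise RecordFormatError(
                f"response_time {self.response_time.isoformat()} earlier than "
                f"trigger_time {self.trigger_time.isoformat()}")
        if self.missing and self.value != MISSING_VALUE:
            raise RecordFormatError("missing records must carry the empty marker")


@dataclass
class RecordSet:
    """Ordered records plus the metadata needed to reproduce the run."""

    records: list[DataRecord] = field(default_factory=list)
    run_metadata: dict = field(default_factory=dict)

    def sort(self) -> None:
        """Canonical order: participant, trigger time, capture order."""
        self.records.sort(key=lambda r: (r.participant_id, r.trigger_time))

    def __len__(self) -> int:
        return len(self.records)


def protocol_checksum(canonical_html: str) -> str:
    return hashlib.sha256(canonical_html.encode("utf-8")).hexdigest()


# --------------------------------------------------------------------------
# serialization


def _record_row(record: DataRecord) -> list[str]:
    return [
        record.participant_id,
        str(record.session_index),
        record.trigger_time.isoformat(),
        record.response_time.isoformat() if record.response_time else "",
        record.widget_kind,
        record.variable,
        record.value,
        "true" if record.missing else "false",
    ]


def _row_record(row: dict, row_number: int) -> DataRecord:
    try:
        response = row["response_time"]
        return DataRecord(
            participant_id=row["participant_id"],
            session_index=int(row["session_index"]),
            trigger_time=datetime.fromisoformat(row["trigger_time"]),
            response_time=datetime.fromisoformat(response) if response else None,
            widget_kind=row["widget_kind"],
            variable=row["variable"],
            value=row["value"],
            missing=row["missing"] == "true",
        )
    except (KeyError, TypeError, ValueError, RecordFormatError) as exc:
        raise RecordFormatError(f"row {row_number}: {exc}") from exc


def write_records(record_set: RecordSet, path, fmt: str = "csv") -> None:
    """Write records to ``path`` as ``csv`` or ``jsonl``; metadata is
    written alongside to ``<path>.meta.json``."""
    path = Path(path)
    if fmt == "csv":
        buffer = io.StringIO()
        writer = csv.writer(buffer, lineterminator="\n")
        writer.writerow(CSV_FIELDS)
        for record in record_set.records:
            writer.writerow(_record_row(record))
        path.write_text(buffer.getvalue(), encoding="utf-8")
    elif fmt == "jsonl":
        lines = []
        for record in record_set.records:
            obj = dict(zip(CSV_FIELDS, _record_row(record)))
            obj["session_index"] = record.session_index
            obj["missing"] = record.missing
            lines.append(json.dumps(obj, sort_keys=True))
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    meta_path = path.with_name(path.name + ".meta.json")
    meta_path.write_text(
        json.dumps(record_set.run_metadata, sort_keys=True, indent=2) + "\n",
        encoding="utf-8")


def read_records(path, fmt: str = "csv") -> RecordSet:
    """Read a file written by :func:`write_records`, validating the schema
    and per-record invariants; the first offending row is named."""
    path = Path(path)
    records: list[DataRecord] = []
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames != CSV_FIELDS:
                raise RecordFormatError(
                    f"bad header: expected {CSV_FIELDS}, found {reader.fieldnames}")
            for row_number, row in enumerate(reader, start=2):
                if None in row or any(v is None for v in row.values()):
                    raise RecordFormatError(f"row {row_number}: wrong field count")
                records.append(_row_record(row, row_number))
    elif fmt == "jsonl":
        for line_number, line in enumerate(
                path.read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            obj = {k: (("true" if v else "false") if k == "missing"
                       else str(v)) for k, v in obj.items()}
            records.append(_row_record(obj, line_number))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    meta_path = path.with_name(path.name + ".meta.json")
    metadata = {}
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text(encoding="utf-8"))
    return RecordSet(records=records, run_metadata=metadata)


# --------------------------------------------------------------------------
# analysis helpers


def records_to_frame(record_set: RecordSet) -> pd.DataFrame:
    """Records as a tidy pandas DataFrame (one row per captured value)."""
    return pd.DataFrame(
        [dict(zip(CSV_FIELDS, _record_row(r))) for r in record_set.records],
        columns=CSV_FIELDS)


def pivot_wide(record_set: RecordSet) -> pd.DataFrame:
    """Wide form: one row per (participant, session), one column per
    variable.  Unanswered or never-presented items become NaN; a variable
    captured more than once in a session keeps its last value."""
    frame = records_to_frame(record_set)
    if frame.empty:
        return pd.DataFrame(columns=["participant_id", "session_index"])
    frame = frame[frame["missing"] == "false"]
    frame = frame.drop_duplicates(
        subset=["participant_id", "session_index", "variable"], keep="last")
    wide = frame.pivot(index=["participant_id", "session_index"],
                       columns="variable", values="value")
    wide.columns.name = None
    return wide.reset_index()
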