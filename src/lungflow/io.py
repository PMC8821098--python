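"""Event-table I/O: CSV (canonical) and FCS 3.1, with label sidecars.

CSV files carry the sample metadata in ``#``-prefixed header comments and
round-trip values at 10 significant digits.  FCS files hold the numeric
columns; non-numeric labels travel in a ``<name>.labels.csv`` sidecar.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .events import LABEL_COLUMN, TRUTH_COLUMN, EventTable
from .fcs import read_fcs, write_fcs

__all__ = ["read_events", "write_events", "IOError_", "check_channels"]

_META_PREFIX = "# lungflow-metadata: "


class IOError_(ValueError):
    """Raised for unreadable or inconsistent event files."""


def _label_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in (TRUTH_COLUMN, LABEL_COLUMN) if c in frame.columns]


def write_events(table: EventTable, path) -> None:
    """Write an event table; format chosen by extension (.csv or .fcs)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w") as fh:
            fh.write(_META_PREFIX + json.dumps(table.metadata, sort_keys=True)
                     + "\n")
            table.data.to_csv(fh, index=False, float_format="%.10g")
    elif path.suffix.lower() == ".fcs":
        labels = _label_columns(table.data)
        numeric = table.data.drop(columns=labels)
        write_fcs(numeric, path, metadata=table.metadata)
        if labels:
            table.data[labels].to_csv(path.with_suffix(path.suffix
                                                       + ".labels.csv"),
                                      index=False)
    else:
        raise IOError_(f"unknown event file format: {path.suffix!r}")


def read_events(path, expected_channels: list[str] | None = None) -> EventTable:
    """Read an event table written by :func:`write_events`.

    With ``expected_channels``, missing channels raise an error listing
    them; extra columns are preserved and flagged with a warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        metadata: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith(_META_PREFIX):
                metadata = json.loads(first[len(_META_PREFIX):])
            else:
                fh.seek(0)
            frame = pd.read_csv(fh)
    elif path.suffix.lower() == ".fcs":
        frame, metadata = read_fcs(path)
        sidecar = path.with_suffix(path.suffix + ".labels.csv")
        if sidecar.exists():
            labels = pd.read_csv(sidecar)
            for c in labels.columns:
                frame[c] = labels[c].to_numpy()
    else:
        raise IOError_(f"unknown event file format: {path.suffix!r}")
    table = EventTable(frame, metadata)
    if expected_channels is not None:
        check_channels(table, expected_channels)
    return table


def check_channels(table: EventTable, expected: list[str]) -> dict[str, str]:
    """Validate event columns against an expected channel list.

    Returns a rename map for case-insensitive matches; raises on genuinely
    missing channels and warns about extras.
    """
    cols = list(table.data.columns)
    lower = {c.lower(): c for c in cols}
    rename: dict[str, str] = {}
    missing: list[str] = []
    for ch in expected:
        if ch in cols:
            continue
        if ch.lower() in lower:
            rename[lower[ch.lower()]] = ch
        else:
            missing.append(ch)
    if missing:
        raise IOError_(f"event file lacks channels: {missing}")
    if rename:
        table.data.rename(columns=rename, inplace=True)
        warnings.warn(f"renamed channels to canonical case: {rename}")
    extras = [c for c in table.data.columns
              if c not in expected and c not in (TRUTH_COLUMN, LABEL_COLUMN)
              and c not in ("FSC-A", "FSC-W", "SSC-A")]
    if extras:
        warnings.warn(f"extra channels preserved: {extras}")
    return rename
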