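"""Minimal FCS 3.1 writer/reader (list mode, float32, little-endian).

Covers what the pipeline needs: numeric event data with standard $PnN
channel names and a metadata keyword, written and read back losslessly
within float32 precision.  Non-numeric columns (labels) go to a sidecar
CSV handled by :mod:`lungflow.io`.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["write_fcs", "read_fcs", "FcsError"]

_DELIM = "/"
_HEADER_LEN = 58
_METADATA_KEY = "LUNGFLOWMETA"


class FcsError(ValueError):
    pass


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [""]
    for k, v in keywords.items():
        v = str(v).replace(_DELIM, "\\")
        parts.append(f"{k}{_DELIM}{v}")
    return (_DELIM.join(parts) + _DELIM).encode("utf-8")


def write_fcs(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write numeric columns of *frame* as one FCS 3.1 dataset."""
    cols = list(frame.columns)
    data = np.ascontiguousarray(frame.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par), "$TOT": str(n_events),
    }
    for i, c in enumerate(cols, start=1):
        keywords[f"$P{i}N"] = c
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        rng = float(np.nanmax(data[:, i - 1])) if n_events else 1.0
        keywords[f"$P{i}R"] = str(int(max(1.0, np.ceil(abs(rng)) + 1)))
    if metadata:
        keywords[_METADATA_KEY] = json.dumps(metadata, sort_keys=True)

    # offsets depend on the TEXT length; fixed-width keyword values make the
    # computation a simple two-pass
    for key in ("$BEGINDATA", "$ENDDATA"):
        keywords[key] = "0" * 12
    text = _text_segment(keywords)
    begin_text = _HEADER_LEN
    end_text = begin_text + len(text) - 1
    begin_data = end_text + 1
    end_data = begin_data + data.nbytes - 1
    keywords["$BEGINDATA"] = str(begin_data).zfill(12)
    keywords["$ENDDATA"] = str(end_data).zfill(12)
    text = _text_segment(keywords)
    assert len(text) == end_text - begin_text + 1

    def off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT offsets are authoritative
        return s.rjust(8).encode()

    header = b"FCS3.1    " + off(begin_text) + off(end_text)
    header += off(begin_data if end_data < 10**8 else 0)
    header += off(end_data if end_data < 10**8 else 0)
    header += off(0) + off(0)
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path) -> tuple[pd.DataFrame, dict]:
    """Read one FCS 3.x dataset; returns (frame, metadata)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw[:6].startswith(b"FCS3"):
        raise FcsError(f"{path}: not an FCS 3.x file")
    try:
        begin_text = int(raw[10:18])
        end_text = int(raw[18:26])
    except ValueError as exc:
        raise FcsError(f"{path}: malformed FCS header") from exc
    text = raw[begin_text:end_text + 1].decode("utf-8")
    delim, body = text[0], text[1:]
    items = body.split(delim)
    if items and items[-1] == "":
        items = items[:-1]
    if len(items) % 2:
        raise FcsError(f"{path}: malformed TEXT segment")
    kw = {items[i]: items[i + 1] for i in range(0, len(items), 2)}

    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise FcsError(f"{path}: only list-mode float data supported")
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    begin_data = int(kw["$BEGINDATA"])
    end_data = int(kw["$ENDDATA"])
    buf = raw[begin_data:end_data + 1]
    data = np.frombuffer(buf, dtype=f"{order}f4", count=n_par * n_tot)
    data = data.reshape(n_tot, n_par).astype(float)
    cols = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    frame = pd.DataFrame(data, columns=cols)
    meta = {}
    if _METADATA_KEY in kw:
        try:
            meta = json.loads(kw[_METADATA_KEY].replace("\\", _DELIM))
        except json.JSONDecodeError:
            meta = {}
    return frame, meta
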