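"""Event-level container: per-event detector intensities plus scatter."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .panel import FLUOR_CHANNELS, SCATTER_PARAMS

__all__ = ["EventTable", "TRUTH_COLUMN", "LABEL_COLUMN"]

TRUTH_COLUMN = "truth_label"
LABEL_COLUMN = "label"


@dataclass
class EventTable:
    """A table of cytometry events.

    ``data`` holds one row per event over the 14 fluorescence channels
    (arbitrary fluorescence units), the scatter parameters FSC-A/FSC-W/SSC-A,
    and optionally a hidden ground-truth label column.  ``metadata`` carries
    sample id, condition, seed, tissue mass, beads added and processing flags
    (e.g. ``compensated``).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        num = self.data[[c for c in self.data.columns if c != TRUTH_COLUMN
                         and c != LABEL_COLUMN]]
        if not num.empty and not num.map(lambda v: v == v).all().all():
            raise ValueError("event intensities must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fluor_channels(self) -> list[str]:
        return [c for c in FLUOR_CHANNELS if c in self.data.columns]

    @property
    def scatter_params(self) -> list[str]:
        return [c for c in SCATTER_PARAMS if c in self.data.columns]

    @property
    def truth(self) -> pd.Series | None:
        if TRUTH_COLUMN in self.data.columns:
            return self.data[TRUTH_COLUMN]
        return None

    def copy(self) -> "EventTable":
        return EventTable(self.data.copy(), dict(self.metadata))

    def with_columns(self, frame: pd.DataFrame) -> "EventTable":
        out = self.copy()
        for c in frame.columns:
            out.data[c] = frame[c].to_numpy()
        return out
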