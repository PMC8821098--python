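"""Multispectral panel data model and channel-sharing resolvability logic.

The panel deliberately assigns several antibodies to fluorochromes read in a
single detector channel (e.g. CD146-AF488, GITR-FITC and SiglecH-FITC all
land in the FITC/AF488 detector).  The design is sound only because the
gating hierarchy never interrogates two co-channel markers on the same
cells; :func:`check_sharing` verifies this against a gating tree.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .gating import GatingTree

__all__ = [
    "DETECTOR_CHANNELS",
    "VIABILITY_CHANNEL",
    "FLUOR_CHANNELS",
    "SCATTER_PARAMS",
    "AntibodyEntry",
    "Panel",
    "SharingReport",
    "PanelError",
    "load_panel",
    "default_panel",
    "detector_channels",
    "marker_readouts",
    "parameter_count",
    "check_sharing",
]

#: Canonical detector channel names of the 13-detector configuration.
DETECTOR_CHANNELS: tuple[str, ...] = (
    "FITC_AF488",
    "PE",
    "PE-CF594",
    "PerCP-Cy5.5",
    "PE-Cy7",
    "APC_AF647",
    "AF700",
    "APC-Cy7_APC-eF780",
    "VioBlue",
    "BV510",
    "BV605",
    "BV650",
    "BV711",
)

#: The live/dead dye (7-AAD) occupies its own simulated detector, kept
#: outside the 13 antibody detectors.
VIABILITY_CHANNEL = "7AAD"

#: All fluorescence channels, viability last.  Order is the canonical column
#: order of event tables and the row/column order of spillover matrices.
FLUOR_CHANNELS: tuple[str, ...] = DETECTOR_CHANNELS + (VIABILITY_CHANNEL,)

SCATTER_PARAMS: tuple[str, ...] = ("FSC-A", "FSC-W", "SSC-A")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True)
class AntibodyEntry:
    """One antibody of the stain: antigen, label and bookkeeping metadata.

    ``dilution`` is the fold factor of the working dilution (5000 means
    1:5000).  ``combined_group`` marks antigens intentionally read as one
    stain (their summed signal is a single readout).
    """

    antigen: str
    fluorochrome: str
    dilution: float
    combined_group: str | None = None
    target_note: str = ""

    def __post_init__(self) -> None:
        if not self.antigen:
            raise PanelError("antibody entry needs an antigen name")
        if self.dilution <= 0:
            raise PanelError(
                f"{self.antigen}: dilution must be positive, got {self.dilution}"
            )


@dataclass(frozen=True)
class Panel:
    """A validated antibody panel plus the fluorochrome -> detector merge map."""

    entries: tuple[AntibodyEntry, ...]
    channel_map: dict[str, str]
    viability_channel: str = VIABILITY_CHANNEL
    scatter_params: tuple[str, ...] = SCATTER_PARAMS

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.antigen, e.fluorochrome)
            if key in seen:
                raise PanelError(
                    f"duplicate antigen+fluorochrome pair {e.antigen}/{e.fluorochrome}"
                )
            seen.add(key)
            if e.fluorochrome not in self.channel_map:
                raise PanelError(
                    f"fluorochrome {e.fluorochrome!r} of {e.antigen} missing "
                    "from channel_map"
                )
        if self.viability_channel in set(self.channel_map.values()):
            raise PanelError(
                "viability channel must be distinct from antibody detectors"
            )
        # entries sharing a combined_group must be read in one detector
        groups: dict[str, set[str]] = {}
        for e in self.entries:
            if e.combined_group:
                groups.setdefault(e.combined_group, set()).add(
                    self.channel_map[e.fluorochrome]
                )
        for g, chans in groups.items():
            if len(chans) > 1:
                raise PanelError(
                    f"combined_group {g!r} spans several detectors: {sorted(chans)}"
                )

    def entry_channel(self, entry: AntibodyEntry) -> str:
        return self.channel_map[entry.fluorochrome]

    def readout_channels(self) -> dict[str, str]:
        """Map readout name -> detector channel."""
        out: dict[str, str] = {}
        for name, members in self._readout_groups():
            out[name] = self.channel_map[members[0].fluorochrome]
        return out

    def channel_readouts(self) -> dict[str, list[str]]:
        """Map detector channel -> readouts occupying it."""
        out: dict[str, list[str]] = {}
        for name, chan in self.readout_channels().items():
            out.setdefault(chan, []).append(name)
        return out

    def readout_antigens(self) -> dict[str, tuple[str, ...]]:
        """Map readout name -> the antigens summed into it."""
        return {
            name: tuple(e.antigen for e in members)
            for name, members in self._readout_groups()
        }

    def _readout_groups(self) -> list[tuple[str, list[AntibodyEntry]]]:
        grouped: dict[str, list[AntibodyEntry]] = {}
        order: list[str] = []
        for e in sorted(self.entries, key=lambda e: e.antigen):
            key = f"group:{e.combined_group}" if e.combined_group else f"antigen:{e.antigen}"
            if key not in grouped:
                grouped[key] = []
            grouped[key].append(e)
        for key in grouped:
            order.append(key)
        out = []
        for key in sorted(order):
            members = grouped[key]
            name = "/".join(e.antigen for e in members)
            out.append((name, members))
        return out


#: Fluorochrome -> detector merges of the default instrument configuration:
#: FITC with AF488, APC with AF647, APC-Cy7 with APC-eFluor780.
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "FITC": "FITC_AF488",
    "AF488": "FITC_AF488",
    "PE": "PE",
    "PE-CF594": "PE-CF594",
    "PerCP-Cy5.5": "PerCP-Cy5.5",
    "PE-Cy7": "PE-Cy7",
    "APC": "APC_AF647",
    "AF647": "APC_AF647",
    "AF700": "AF700",
    "APC-Cy7": "APC-Cy7_APC-eF780",
    "APC-eFluor780": "APC-Cy7_APC-eF780",
    "VioBlue": "VioBlue",
    "BV510": "BV510",
    "BV605": "BV605",
    "BV650": "BV650",
    "BV711": "BV711",
}


def load_panel(path) -> Panel:
    """Load and validate a panel from a YAML config.

    Expected keys: ``entries`` (list of {antigen, fluorochrome, dilution,
    combined_group, target}), ``channel_map``, ``viability_channel`` and
    optionally ``scatter_params``.
    """
    with open(path, "r") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # report the offending line
            mark = getattr(exc, "problem_mark", None)
            line = f" (line {mark.line + 1})" if mark is not None else ""
            raise PanelError(f"cannot parse panel file {path}{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise PanelError(f"panel file {path} must contain a mapping")
    entries = tuple(
        AntibodyEntry(
            antigen=str(row["antigen"]),
            fluorochrome=str(row["fluorochrome"]),
            dilution=float(row.get("dilution", 1.0)),
            combined_group=row.get("combined_group"),
            target_note=str(row.get("target", "")),
        )
        for row in raw.get("entries", [])
    )
    channel_map = {str(k): str(v) for k, v in raw.get("channel_map", {}).items()}
    return Panel(
        entries=entries,
        channel_map=channel_map,
        viability_channel=str(raw.get("viability_channel", VIABILITY_CHANNEL)),
        scatter_params=tuple(raw.get("scatter_params", SCATTER_PARAMS)),
    )


def default_panel() -> Panel:
    """The packaged 25-antibody / 13-detector murine lung panel."""
    ref = importlib.resources.files("lungflow.data").joinpath("panel_lung.yaml")
    with importlib.resources.as_file(ref) as p:
        return load_panel(p)


def detector_channels(panel: Panel) -> set[str]:
    """Distinct detector channels occupied by antibodies (viability and
    scatter excluded)."""
    return {panel.entry_channel(e) for e in panel.entries}


def marker_readouts(panel: Panel) -> list[str]:
    """One readout per antigen, with combined groups collapsed to a single
    joint readout (e.g. ``CD64/MerTK``)."""
    return [name for name, _ in panel._readout_groups()]


def parameter_count(panel: Panel) -> int:
    """Marker readouts + viability dye + forward and side scatter."""
    return len(marker_readouts(panel)) + 1 + 2


@dataclass
class SharingReport:
    """Outcome of the channel-sharing resolvability check."""

    channel_readouts: dict[str, list[str]]
    conflicts: list[tuple[str, tuple[str, str], str]] = field(default_factory=list)

    @property
    def resolvable(self) -> bool:
        return not self.conflicts


def check_sharing(panel: Panel, tree: "GatingTree") -> SharingReport:
    """Verify that no gating path interrogates two co-channel readouts.

    Walks every root-to-terminal path of *tree* and records, per path, which
    marker readouts the path's gate selections actually depend on.  Two
    distinct readouts sharing one detector conflict when both constrain the
    same path, unless the earlier one was pinned to its negative side (its
    dye then contributes no signal and the channel is free for the later
    marker), or the two are one combined readout.
    """
    readout_chan = panel.readout_channels()
    chan_readouts = panel.channel_readouts()
    tree_markers = tree.marker_axes()
    unknown = sorted(m for m in tree_markers if m not in readout_chan)
    if unknown:
        raise PanelError(f"gating tree references unknown markers: {unknown}")

    shared = {c for c, rs in chan_readouts.items() if len(rs) > 1}
    conflicts: list[tuple[str, tuple[str, str], str]] = []
    seen: set[tuple[str, str, str, str]] = set()

    def walk(node, constrained: list[tuple[str, str, str]]) -> None:
        # constrained: (readout, side in {"+", "-", "mixed"}, node name)
        if node.gate is not None:
            for outcomes, child in node.distinct_children():
                step = []
                for axis, side in node.gate.axis_constraints(outcomes):
                    if axis not in readout_chan:
                        continue  # scatter / viability axis
                    chan = readout_chan[axis]
                    if chan in shared:
                        for prev_axis, prev_side, prev_node in constrained:
                            if (
                                prev_axis != axis
                                and readout_chan.get(prev_axis) == chan
                                and prev_side != "-"
                            ):
                                key = (chan, prev_axis, axis, node.name)
                                if key not in seen:
                                    seen.add(key)
                                    conflicts.append(
                                        (
                                            chan,
                                            (prev_axis, axis),
                                            f"{prev_node} -> {node.name}",
                                        )
                                    )
                    step.append((axis, side, node.name))
                # same-node pair on one channel (two axes of one gate)
                for i, (a1, _, n1) in enumerate(step):
                    for a2, _, _ in step[i + 1 :]:
                        if a1 != a2 and readout_chan[a1] == readout_chan[a2]:
                            key = (readout_chan[a1], a1, a2, node.name)
                            if key not in seen:
                                seen.add(key)
                                conflicts.append(
                                    (readout_chan[a1], (a1, a2), node.name)
                                )
                walk(child, constrained + step)
            # unassigned fall-through ends the path; nothing more to check

    walk(tree.root, [])
    return SharingReport(channel_readouts=chan_readouts, conflicts=conflicts)
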