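"""Declarative hierarchical gating: gates, trees, FMO thresholds, labeling.

Gating operates on arcsinh-transformed compensated fluorescence (cofactor
150); scatter parameters are gated raw.  Marker cutpoints are derived from
fluorescence-minus-one controls as a high percentile (default 99.5) of the
channel within the gate's parent population; scatter and viability
cutpoints are fixed configuration values.  Ties at a cutpoint go to the
negative side (half-open intervals, [low, high)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import yaml

from .compensation import DEFAULT_COFACTOR, arcsinh
from .events import LABEL_COLUMN, EventTable
from .panel import SCATTER_PARAMS, VIABILITY_CHANNEL

__all__ = [
    "Gate",
    "GatingNode",
    "GatingTree",
    "ThresholdSet",
    "GatingError",
    "derive_thresholds",
    "apply_tree",
]

#: Sentinel prefix for data-driven cutpoints: "data:p10" resolves to the
#: 10th percentile of the axis among events reaching the node.
_DATA_PREFIX = "data:p"

GATE_KINDS = ("threshold1d", "interval1d", "rectangle2d", "quadrant2d",
              "ratio_fsc_w")


class GatingError(ValueError):
    pass


@dataclass(frozen=True)
class Gate:
    """A 1-D or 2-D gate over event parameters.

    ``cutpoints`` holds one element per axis: a float (fixed), ``None``
    (derived from the ThresholdSet), a ``data:pNN`` string (percentile of
    the events reaching the node), or a (lo, hi) pair for interval /
    rectangle kinds (``None``/``inf`` bounds allowed).
    """

    kind: str
    axes: tuple[str, ...]
    cutpoints: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise GatingError(f"unknown gate kind {self.kind!r}")
        need = 2 if self.kind in ("rectangle2d", "quadrant2d") else 1
        if len(self.axes) != need or len(self.cutpoints) != need:
            raise GatingError(
                f"{self.kind} needs {need} axes and cutpoints, got "
                f"{self.axes}/{self.cutpoints}"
            )

    def outcomes(self) -> tuple[str, ...]:
        if self.kind == "quadrant2d":
            return ("++", "+-", "-+", "--")
        if self.kind in ("interval1d", "rectangle2d"):
            return ("in", "out")
        return ("+", "-")

    def evaluate(self, values: list[np.ndarray],
                 cuts: list) -> dict[str, np.ndarray]:
        """Outcome masks given resolved cutpoints (finite floats/pairs)."""
        if self.kind in ("threshold1d", "ratio_fsc_w"):
            pos = values[0] > cuts[0]
            return {"+": pos, "-": ~pos}
        if self.kind == "interval1d":
            lo, hi = cuts[0]
            inside = (values[0] >= lo) & (values[0] < hi)
            return {"in": inside, "out": ~inside}
        if self.kind == "rectangle2d":
            inside = np.ones(values[0].shape, bool)
            for v, (lo, hi) in zip(values, cuts):
                inside &= (v >= lo) & (v < hi)
            return {"in": inside, "out": ~inside}
        # quadrant2d
        xp = values[0] > cuts[0]
        yp = values[1] > cuts[1]
        return {
            "++": xp & yp,
            "+-": xp & ~yp,
            "-+": ~xp & yp,
            "--": ~xp & ~yp,
        }

    def axis_constraints(self, outcomes: frozenset[str]):
        """Which axes a child selection depends on, and to which side.

        Returns (axis, side) pairs with side in {"+", "-", "mixed"}; an axis
        whose sign varies freely over the claimed outcomes (the selection
        factorizes without it) is omitted.
        """
        if self.kind in ("threshold1d", "ratio_fsc_w"):
            if outcomes >= {"+", "-"}:
                return []
            return [(self.axes[0], next(iter(outcomes)))]
        if self.kind == "interval1d":
            return [] if outcomes >= {"in", "out"} else [(self.axes[0], "mixed")]
        if self.kind == "rectangle2d":
            if outcomes >= {"in", "out"}:
                return []
            return [(a, "mixed") for a in self.axes]
        signs = [ {o[i] for o in outcomes} for i in range(2) ]
        full = {"".join(p) for p in product(*signs)}
        if full == set(outcomes):
            out = []
            for i, s in enumerate(signs):
                if len(s) == 1:
                    out.append((self.axes[i], next(iter(s))))
            return out
        # joint truncation: both axes involved, neither pinned to one side
        return [(a, "mixed") for a in self.axes]


@dataclass
class GatingNode:
    """One node of the tree: either a gate with outcome-keyed children, or a
    terminal leaf (population label) / exclusion (pre-gate removal)."""

    name: str
    gate: Gate | None = None
    children: dict[str, "GatingNode"] = field(default_factory=dict)
    leaf_label: str | None = None
    exclusion: bool = False

    def distinct_children(self):
        """Yield (claimed outcomes, child) with shared children merged."""
        by_id: dict[int, tuple[set[str], GatingNode]] = {}
        order: list[int] = []
        for outcome, child in self.children.items():
            k = id(child)
            if k not in by_id:
                by_id[k] = (set(), child)
                order.append(k)
            by_id[k][0].add(outcome)
        for k in order:
            outs, child = by_id[k]
            yield frozenset(outs), child


@dataclass
class GatingTree:
    """Rooted gating tree; leaves carry the population labels."""

    root: GatingNode
    channel_of: dict[str, str]
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            raise GatingError("leaf labels must be unique")

    def iter_nodes(self):
        """Pre-order traversal (parents before children, each node once)."""
        seen: set[int] = set()

        def rec(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            yield node
            for _, child in node.distinct_children():
                yield from rec(child)

        yield from rec(self.root)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(n.leaf_label for n in self.iter_nodes()
                     if n.leaf_label and not n.exclusion)

    @property
    def exclusion_labels(self) -> tuple[str, ...]:
        return tuple(n.leaf_label for n in self.iter_nodes()
                     if n.leaf_label and n.exclusion)

    def marker_axes(self) -> set[str]:
        out = set()
        for n in self.iter_nodes():
            if n.gate:
                out |= {a for a in n.gate.axes if a in self.channel_of}
        return out

    def parents(self) -> dict[str, tuple[str, frozenset[str]] | None]:
        """Node name -> (parent name, claimed outcomes); root maps to None."""
        out: dict[str, tuple[str, frozenset[str]] | None] = {self.root.name: None}
        for n in self.iter_nodes():
            for outcomes, child in n.distinct_children():
                out[child.name] = (n.name, outcomes)
        return out

    def node(self, name: str) -> GatingNode:
        for n in self.iter_nodes():
            if n.name == name:
                return n
        raise GatingError(f"no node named {name!r}")

    # ------------------------------------------------------------------ yaml
    def to_dict(self) -> dict:
        def node_dict(n: GatingNode) -> dict:
            d: dict = {"name": n.name}
            if n.leaf_label:
                d["leaf"] = n.leaf_label
                if n.exclusion:
                    d["exclusion"] = True
                return d
            d["gate"] = {
                "kind": n.gate.kind,
                "axes": list(n.gate.axes),
                "cutpoints": [list(c) if isinstance(c, tuple) else c
                              for c in n.gate.cutpoints],
            }
            children = {}
            for outcomes, child in n.distinct_children():
                children["|".join(sorted(outcomes))] = node_dict(child)
            d["children"] = children
            return d

        return {
            "cofactor": self.cofactor,
            "channel_of": dict(self.channel_of),
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingTree":
        def build(nd: dict) -> GatingNode:
            if "leaf" in nd:
                return GatingNode(nd["name"], leaf_label=nd["leaf"],
                                  exclusion=bool(nd.get("exclusion", False)))
            g = nd["gate"]
            gate = Gate(
                g["kind"], tuple(g["axes"]),
                tuple(tuple(c) if isinstance(c, list) else c
                      for c in g["cutpoints"]),
            )
            node = GatingNode(nd["name"], gate=gate)
            for key, sub in nd.get("children", {}).items():
                child = build(sub)
                for outcome in key.split("|"):
                    node.children[outcome] = child
            return node

        return cls(root=build(d["root"]), channel_of=dict(d["channel_of"]),
                   cofactor=float(d.get("cofactor", DEFAULT_COFACTOR)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GatingTree":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ThresholdSet:
    """FMO-derived marker cutpoints, keyed by (node name, axis), on the
    arcsinh display scale; ``provenance`` records the FMO sample and the
    percentile used."""

    cutpoints: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: dict[tuple[str, str], dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.cutpoints.items():
            if not np.isfinite(v):
                raise GatingError(f"non-finite cutpoint for {key}")

    def frame(self) -> pd.DataFrame:
        rows = [
            {"node": k[0], "axis": k[1], "cutpoint": v,
             **self.provenance.get(k, {})}
            for k, v in sorted(self.cutpoints.items())
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# evaluation machinery


def _transformed(events: EventTable, tree: GatingTree) -> pd.DataFrame:
    """Fluorescence channels arcsinh-transformed, scatter untouched."""
    df = pd.DataFrame(index=events.data.index)
    for c in events.fluor_channels:
        df[c] = arcsinh(events.data[c].to_numpy(float), tree.cofactor)
    for c in events.scatter_params:
        df[c] = events.data[c].to_numpy(float)
    return df


def _axis_values(df_t: pd.DataFrame, tree: GatingTree, axis: str) -> np.ndarray:
    if axis in tree.channel_of:
        col = tree.channel_of[axis]
    elif axis in SCATTER_PARAMS or axis == VIABILITY_CHANNEL:
        col = axis
    else:
        raise GatingError(f"gate axis {axis!r} not found in event schema")
    if col not in df_t.columns:
        raise GatingError(f"event table lacks column {col!r} for axis {axis!r}")
    return df_t[col].to_numpy(float)


def _resolve_cuts(node: GatingNode, tree: GatingTree,
                  thresholds: ThresholdSet | None,
                  df_t: pd.DataFrame, mask: np.ndarray) -> list:
    cuts = []
    for axis, spec in zip(node.gate.axes, node.gate.cutpoints):
        if isinstance(spec, str) and spec.startswith(_DATA_PREFIX):
            pct = float(spec[len(_DATA_PREFIX):])
            vals = _axis_values(df_t, tree, axis)[mask]
            cuts.append(float(np.percentile(vals, pct)) if vals.size else 0.0)
        elif spec is None:
            key = (node.name, axis)
            if thresholds is None or key not in thresholds.cutpoints:
                raise GatingError(f"no cutpoint for {key}")
            cuts.append(thresholds.cutpoints[key])
        else:
            cuts.append(tuple(spec) if isinstance(spec, (tuple, list)) else
                        float(spec))
    return cuts


def _walk_mask(tree: GatingTree, df_t: pd.DataFrame,
               thresholds: ThresholdSet | None, target: str) -> np.ndarray:
    """Boolean mask of events reaching the named node."""
    parents = tree.parents()
    path: list[tuple[str, frozenset[str]]] = []
    cur = target
    while parents[cur] is not None:
        pname, outcomes = parents[cur]
        path.append((pname, outcomes))
        cur = pname
    mask = np.ones(len(df_t), bool)
    for pname, outcomes in reversed(path):
        node = tree.node(pname)
        cuts = _resolve_cuts(node, tree, thresholds, df_t, mask)
        values = [_axis_values(df_t, tree, a) for a in node.gate.axes]
        outcome_masks = node.gate.evaluate(values, cuts)
        sel = np.zeros(len(df_t), bool)
        for o in outcomes:
            sel |= outcome_masks[o]
        mask = mask & sel
    return mask


def derive_thresholds(
    tree: GatingTree,
    fmo_samples: dict[str, EventTable],
    percentile: float = 99.5,
) -> ThresholdSet:
    """Derive marker cutpoints from compensated FMO samples.

    For each (node, marker axis) lacking a fixed cutpoint, the cutpoint is
    the given percentile of that marker's channel (arcsinh scale) among the
    events of the axis's FMO sample that reach the node — i.e. the tail of
    the fully-stained-minus-one background within the parent gate.
    Processing is top-down so ancestor gates are always resolved first.
    """
    needed: list[tuple[GatingNode, str]] = []
    for node in tree.iter_nodes():
        if node.gate is None:
            continue
        for axis, spec in zip(node.gate.axes, node.gate.cutpoints):
            if spec is None and axis in tree.channel_of:
                needed.append((node, axis))
    missing = sorted({a for _, a in needed} - set(fmo_samples))
    if missing:
        raise GatingError(f"missing FMO samples for markers: {missing}")

    ts = ThresholdSet()
    caches: dict[str, pd.DataFrame] = {}
    for node, axis in needed:  # iter_nodes order: parents first
        df_t = caches.get(axis)
        if df_t is None:
            df_t = caches[axis] = _transformed(fmo_samples[axis], tree)
        parent_map = tree.parents()
        ref = node.name
        mask = _walk_mask(tree, df_t, ts, ref)
        # a gate's parent population can be empty in the control-tissue FMO
        # (e.g. the tumor-cell branch in healthy lung); fall back to the
        # nearest non-empty ancestor population
        while not mask.any() and parent_map[ref] is not None:
            ref = parent_map[ref][0]
            mask = _walk_mask(tree, df_t, ts, ref)
        if not mask.any():
            raise GatingError(
                f"no FMO events reach node {node.name!r} for marker {axis!r}"
            )
        vals = _axis_values(df_t, tree, axis)[mask]
        ts.cutpoints[(node.name, axis)] = float(np.percentile(vals, percentile))
        ts.provenance[(node.name, axis)] = {
            "fmo": fmo_samples[axis].metadata.get("sample_id", axis),
            "percentile": percentile,
            "n_parent_events": int(mask.sum()),
            "parent_node": ref,
        }
    return ts


def apply_tree(
    events: EventTable,
    tree: GatingTree,
    thresholds: ThresholdSet | None = None,
) -> tuple[EventTable, pd.DataFrame]:
    """Assign every event exactly one terminal label and tabulate the tree.

    Labels are leaf names, pre-gate exclusion labels (debris / dead /
    doublet / bead) or ``unassigned@<node>`` for events stranded at an
    internal node.  The population table reports per-node counts and
    percent-of-parent.  Deterministic given inputs.
    """
    df_t = _transformed(events, tree)
    n = len(df_t)
    labels = np.full(n, "", dtype=object)
    rows: list[dict] = []

    def rec(node: GatingNode, mask: np.ndarray, parent: str | None,
            parent_count: int) -> None:
        count = int(mask.sum())
        pct = 100.0 * count / parent_count if parent_count else np.nan
        kind = ("exclusion" if node.exclusion
                else "leaf" if node.leaf_label else "node")
        rows.append({"name": node.name, "parent": parent,
                     "label": node.leaf_label, "kind": kind,
                     "count": count, "percent_of_parent": pct})
        if node.leaf_label is not None:
            labels[mask] = node.leaf_label
            return
        cuts = _resolve_cuts(node, tree, thresholds, df_t, mask)
        values = [_axis_values(df_t, tree, a) for a in node.gate.axes]
        outcome_masks = node.gate.evaluate(values, cuts)
        claimed = np.zeros(n, bool)
        for outcomes, child in node.distinct_children():
            sel = np.zeros(n, bool)
            for o in outcomes:
                sel |= outcome_masks[o]
            sel &= mask
            claimed |= sel
            rec(child, sel, node.name, count)
        rest = mask & ~claimed
        rcount = int(rest.sum())
        rows.append({"name": f"unassigned@{node.name}",
                         "parent": node.name,
                         "label": f"unassigned@{node.name}",
                         "kind": "unassigned", "count": rcount,
                         "percent_of_parent":
                             100.0 * rcount / count if count else np.nan})
        labels[rest] = f"unassigned@{node.name}"

    rec(tree.root, np.ones(n, bool), None, n)
    out = events.copy()
    out.data[LABEL_COLUMN] = labels
    table = pd.DataFrame(rows)
    return out, table
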