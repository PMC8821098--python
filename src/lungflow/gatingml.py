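"""Gating-ML 2.0 export of a gating tree (rectangle-gate representation).

Thresholds, quadrants and rectangles all serialize as
``RectangleGate`` elements with per-dimension min/max bounds; quadrant
nodes export one gate per claimed quadrant.  Data-driven cutpoints must be
resolved (a ThresholdSet is required for marker axes).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET

from .gating import GatingTree, ThresholdSet

__all__ = ["export_gatingml"]

_NS = {
    "gating": "http://www.isac-net.org/std/Gating-ML/v2.0/gating",
    "data-type": "http://www.isac-net.org/std/Gating-ML/v2.0/datatypes",
}


def _dim(parent, name: str, lo: float | None, hi: float | None) -> None:
    d = ET.SubElement(parent, f"{{{_NS['gating']}}}dimension")
    if lo is not None and math.isfinite(lo):
        d.set(f"{{{_NS['gating']}}}min", repr(float(lo)))
    if hi is not None and math.isfinite(hi):
        d.set(f"{{{_NS['gating']}}}max", repr(float(hi)))
    fcs = ET.SubElement(d, f"{{{_NS['data-type']}}}fcs-dimension")
    fcs.set(f"{{{_NS['data-type']}}}name", name)


def export_gatingml(tree: GatingTree, path,
                    thresholds: ThresholdSet | None = None) -> None:
    for prefix, uri in _NS.items():
        ET.register_namespace(prefix, uri)
    root = ET.Element(f"{{{_NS['gating']}}}Gating-ML")

    def resolve(node, axis, spec):
        if isinstance(spec, (int, float)):
            return float(spec)
        key = (node.name, axis)
        if thresholds is not None and key in thresholds.cutpoints:
            return thresholds.cutpoints[key]
        return None

    def emit(node, parent_id: str | None) -> None:
        if node.gate is None:
            return
        kind = node.gate.kind
        for outcomes, child in node.distinct_children():
            gate_id = f"{node.name}.{'_'.join(sorted(outcomes))}"
            g = ET.SubElement(root, f"{{{_NS['gating']}}}RectangleGate")
            g.set(f"{{{_NS['gating']}}}id", gate_id.replace("+", "p")
                  .replace("-", "n").replace("|", "."))
            if parent_id:
                g.set(f"{{{_NS['gating']}}}parent_id", parent_id)
            if kind in ("threshold1d", "ratio_fsc_w"):
                cut = resolve(node, node.gate.axes[0], node.gate.cutpoints[0])
                if "+" in outcomes and "-" not in outcomes:
                    _dim(g, node.gate.axes[0], cut, None)
                elif "-" in outcomes and "+" not in outcomes:
                    _dim(g, node.gate.axes[0], None, cut)
            elif kind in ("interval1d", "rectangle2d"):
                if "in" in outcomes:
                    for axis, (lo, hi) in zip(node.gate.axes,
                                              node.gate.cutpoints):
                        _dim(g, axis, lo, hi)
            else:  # quadrant2d: one rectangle per claimed quadrant
                for o in sorted(outcomes):
                    for axis, sign, spec in zip(node.gate.axes, o,
                                                node.gate.cutpoints):
                        cut = resolve(node, axis, spec)
                        if sign == "+":
                            _dim(g, axis, cut, None)
                        else:
                            _dim(g, axis, None, cut)
                    break  # one quadrant per gate element keeps ids unique
            emit(child, g.get(f"{{{_NS['gating']}}}id"))

    emit(tree.root, None)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")
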