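"""The packaged murine-lung gating tree (20 leaf populations, optional
tumor-cell leaf).

Pre-gates remove counting beads (scatter box), debris (low FSC-A), dead
cells (7-AAD-high) and doublets (FSC-W-high).  A CD31/CD45 quadrant then
splits vascular endothelium (CD31+CD45-), stroma (CD31-CD45-) and immune
cells (CD45+, CD31 ignored — leukocytes express some CD31 and the shared
PE-Cy7 detector also carries the CD64/MerTK macrophage readout).  Within
the immune branch the highly autofluorescent alveolar macrophages are
removed first (CD44+/CD11b- then CD11c+), before the CD11b split into the
myeloid and lymphoid sub-hierarchies.  Gate outcomes without a child node
are reported as ``unassigned@<node>``, mirroring the deliberately
uncharacterized subsets (e.g. the CD24+ stromal compartment).

Marker cutpoints (``None``) come from FMO controls via
:func:`lungflow.gating.derive_thresholds`; scatter and viability cutpoints
are fixed configuration values, except the debris cut which defaults to the
10th percentile of FSC-A among beads-excluded events.
"""

from __future__ import annotations

import math

from .gating import Gate, GatingNode, GatingTree
from .panel import Panel, default_panel

__all__ = ["lung_gating_tree", "FIXED_CUTPOINTS"]

#: Fixed pre-gate cutpoints (raw scatter units; viability on arcsinh scale).
FIXED_CUTPOINTS = {
    "bead_fsc": (5_000.0, 45_000.0),
    "bead_ssc": (180_000.0, math.inf),
    "debris_fsc": "data:p10",
    "viability_7aad": math.asinh(3000.0 / 150.0),
    "doublet_fsc_w": 100_000.0,
    "llc1_fsc": 160_000.0,
}


def _leaf(label: str, exclusion: bool = False) -> GatingNode:
    return GatingNode(f"leaf:{label}", leaf_label=label, exclusion=exclusion)


def _threshold(name: str, axis: str, cut,
               pos: GatingNode | None, neg: GatingNode | None) -> GatingNode:
    children = {}
    if pos is not None:
        children["+"] = pos
    if neg is not None:
        children["-"] = neg
    return GatingNode(name, gate=Gate("threshold1d", (axis,), (cut,)),
                      children=children)


def _quadrant(name: str, axes: tuple[str, str],
              children: dict[str, GatingNode]) -> GatingNode:
    return GatingNode(name, gate=Gate("quadrant2d", axes, (None, None)),
                      children=children)


def lung_gating_tree(include_tumor_leaf: bool = False,
                     panel: Panel | None = None) -> GatingTree:
    """Build the packaged lung tree; leaves are the 20 reported populations
    (21 with the LLC1 tumor-cell leaf enabled)."""
    panel = panel or default_panel()
    f = FIXED_CUTPOINTS

    # ---- lymphoid branch (CD11b-) ------------------------------------
    treg = _threshold("treg_gitr", "GITR", None, _leaf("Treg"),
                      _leaf("CD4_T"))
    gd = _threshold("gd_tcr", "gdTCR", None, _leaf("gdT"), None)
    t_quad = _quadrant("t_cd4_cd8", ("CD4", "CD8a"),
                       {"+-": treg, "-+": _leaf("CD8_T"), "--": gd})
    pdc = _threshold("pdc_cd11c", "CD11c", None, _leaf("pDC"), None)
    pdc_gate = _threshold("pdc_siglech", "SiglecH", None, pdc, None)
    t_cd3 = _threshold("t_cd3", "CD3", None, t_quad, pdc_gate)
    nkt = _threshold("nkt_cd90", "CD90", None, _leaf("NKT"), None)
    nk_cd3 = _threshold("nk_cd3", "CD3", None, nkt, _leaf("NK"))
    bcell = _threshold("bcell_mhc", "MHCII", None, _leaf("B_cell"), None)
    lymph = _quadrant("lymph_cd24_nk", ("CD24", "NK1.1"),
                      {"+-": bcell, "-+": nk_cd3, "--": t_cd3})

    # ---- myeloid branch (CD11b+) -------------------------------------
    dc_im = _quadrant("dc_vs_im", ("CD24", "CD64/MerTK"),
                      {"+-": _leaf("cDC"),
                       "-+": _leaf("interstitial_macrophage")})
    mono = _quadrant("mono_mhc_ly6c", ("MHCII", "Ly6C"),
                     {"-+": _leaf("Ly6Cpos_monocyte"),
                      "--": _leaf("Ly6Cneg_monocyte"),
                      "++": dc_im, "+-": dc_im})
    eos = _threshold("eosinophil_gate", "SiglecF", None, _leaf("eosinophil"),
                     mono)
    neut = _threshold("neutrophil_gate", "Ly6G", None, _leaf("neutrophil"),
                      eos)
    myeloid = _threshold("myeloid", "CD11b", None, neut, lymph)

    # ---- alveolar macrophages removed first --------------------------
    am_cd11c = _threshold("am_cd11c", "CD11c", None,
                          _leaf("alveolar_macrophage"), None)
    am_gate = _quadrant("am_gate", ("CD44", "CD11b"),
                        {"+-": am_cd11c, "++": myeloid, "-+": myeloid,
                         "--": myeloid})

    # ---- stromal branch (CD31- CD45-) --------------------------------
    vsmc = _threshold("vsmc_cd24", "CD24", None, None, _leaf("VSMC"))
    if include_tumor_leaf:
        llc1 = _threshold("llc1_cd326", "CD326", None, None, _leaf("LLC1"))
        dn_tail = _threshold("llc1_fsc", "FSC-A", f["llc1_fsc"], llc1, None)
    else:
        dn_tail = None
    stromal_dn = _threshold("stromal_dn", "CD146", None, vsmc, dn_tail)
    stromal = _quadrant("stromal", ("CD140", "CD324"),
                        {"+-": _leaf("fibroblast"), "-+": _leaf("epithelial"),
                         "--": stromal_dn})

    # ---- endothelial branch (CD31+ CD45-) ----------------------------
    lec = _threshold("lec_cd90", "CD90", None, _leaf("LEC"), None)
    endo = _quadrant("endothelial", ("CD146", "Ly6C"),
                     {"++": _leaf("BEC"), "--": lec, "-+": lec})

    # ---- pre-gates and lineage quadrant ------------------------------
    lineage = _quadrant("lineage", ("CD31", "CD45"),
                        {"+-": endo, "--": stromal, "++": am_gate,
                         "-+": am_gate})
    singlets = _threshold("singlets", "FSC-W", f["doublet_fsc_w"],
                          _leaf("doublet", exclusion=True), lineage)
    singlets.gate = Gate("ratio_fsc_w", ("FSC-W",), (f["doublet_fsc_w"],))
    viability = _threshold("viability", "7AAD", f["viability_7aad"],
                           _leaf("dead", exclusion=True), singlets)
    debris = _threshold("debris", "FSC-A", f["debris_fsc"], viability,
                        _leaf("debris", exclusion=True))
    root = GatingNode(
        "beads",
        gate=Gate("rectangle2d", ("FSC-A", "SSC-A"),
                  (f["bead_fsc"], f["bead_ssc"])),
        children={"in": _leaf("bead", exclusion=True), "out": debris},
    )
    return GatingTree(root=root, channel_of=panel.readout_channels())
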