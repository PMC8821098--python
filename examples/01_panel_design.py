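"""Panel design: 24 readouts on 13 detectors, and why that is legal.

Loads the packaged murine lung panel, prints the design counts, and runs
the channel-sharing check against the packaged gating tree: every detector
used by several markers must only ever be interrogated on cells where at
most one of those markers can be present.
"""

import lungflow as lf

panel = lf.default_panel()
tree = lf.lung_gating_tree(include_tumor_leaf=True)

print(f"antibody entries : {len(panel.entries)}")
print(f"detector channels: {len(lf.detector_channels(panel))}")
print(f"marker readouts  : {len(lf.marker_readouts(panel))}"
      "  (CD64+MerTK pooled as one macrophage readout)")
print(f"total parameters : {lf.parameter_count(panel)}"
      "  (readouts + 7-AAD viability + FSC + SSC)")

report = lf.check_sharing(panel, tree)
print("\nshared detectors and their markers:")
for chan, readouts in sorted(report.channel_readouts.items()):
    if len(readouts) > 1:
        print(f"  {chan:20s} {', '.join(readouts)}")
print(f"\nresolvable by the gating hierarchy: {report.resolvable} "
      f"({len(report.conflicts)} conflicts)")
# A resolvable panel means e.g. CD146 (endothelium), GITR (Tregs) and
# SiglecH (pDCs) can share one dye: no gating path ever reads two of them.
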