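"""Spillover estimation from single-stain beads, with the higher-peak rule.

Simulates one compensation-bead acquisition (5000 beads per detector,
15% measurement CV), estimates the 14x14 spillover matrix and compares it
to the generator's ground truth.  The APC-Cy7/APC-eF780 channel pools
three antibodies with unequal bead affinities and shows two positive
peaks; the estimator keeps the higher-intensity one.
"""

import numpy as np

import lungflow as lf

panel = lf.default_panel()
spill = lf.default_spillover()

beads = lf.simulate_comp_beads(panel, spill, seed=1, n_beads=5000)
est = lf.estimate_spillover(beads)

err = np.abs(est.matrix.to_numpy() - spill.matrix).max()
print(f"max |estimated - true| spillover entry: {err:.5f}")
# anything below 0.01 (one percentage point of spillover) is inaudible in
# downstream gating.

for chan, d in est.diagnostics.items():
    if d["positive_peaks"] > 1:
        print(f"bimodal bead channel: {chan} "
              f"({d['positive_peaks']} peaks; kept the peak at "
              f"{d['chosen_peak_median']:.0f} a.u. from "
              f"{d['n_positive_used']} beads)")

comp = est.matrix.loc["APC-Cy7_APC-eF780", "PE-Cy7"]
true = spill.frame().loc["APC-Cy7_APC-eF780", "PE-Cy7"]
print(f"APC-Cy7 -> PE-Cy7 coefficient: estimated {comp:.4f} vs true "
      f"{true:.4f} (the dim tandem-variant peak would have implied "
      f"{1.5 * true:.4f})")
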