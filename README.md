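# lungflow

Multispectral lung cytometry in silico: simulation, spillover
compensation, hierarchical gating and absolute quantification for a
13-detector murine lung panel that reads **24 surface-marker readouts with
only 13 fluorescence detectors** through deliberate fluorochrome reuse.

## The problem

Whole-lung phenotyping needs immune, vascular, stromal and epithelial
populations from one tube, but a basic cytometer has few detectors. The
panel modeled here assigns several antibodies to dyes read in a single
detector (e.g. CD146-AF488 for endothelium, GITR-FITC for Tregs and
SiglecH-FITC for pDCs all land in one channel) and relies on a
hierarchical gating tree to guarantee that no two co-channel markers are
ever interrogated on the same cells. Combined with a viability dye and two
scatter parameters this yields 27 parameters, resolving 20 lung
populations — plus, in tumor models, an FSC-high lineage-negative LLC1
tumor-cell population — and converts gated events into absolute densities
(cells per mg tissue) with spiked-in counting beads, compared across
tumor models by one-way ANOVA with Dunnett's many-to-one test.

No event-level data exist for this design, so the package ships a seeded
synthetic generator (lognormal marker expression by level class,
population-specific autofluorescence, linear spillover with measurement
noise, debris/dead/doublet/bead contaminants, FMO and compensation-bead
controls) and validates every stage against the generator's hidden truth.
See `docs/methods.md` for the full model.

## Worked example

```python
import lungflow as lf
from lungflow.pipeline import (make_spillover_estimate, make_thresholds,
                               process_sample, recall_precision)

panel = lf.default_panel()                      # packaged 25-antibody panel
tree = lf.lung_gating_tree(include_tumor_leaf=True)
print(len(lf.detector_channels(panel)),         # 13
      len(lf.marker_readouts(panel)),           # 24
      lf.parameter_count(panel),                # 27
      len(lf.lung_gating_tree().leaf_labels))   # 20

spill = lf.default_spillover()                  # ground-truth mixing
comp = make_spillover_estimate(panel, spill, seed=1)   # from 13 bead tubes
profiles = lf.default_profiles()
thresholds = make_thresholds(tree, profiles, spill, comp, seed=1)

sample = lf.simulate_sample(profiles, lf.condition_presets()["control"],
                            50_000, spill, seed=1)
labeled, pop_table = process_sample(sample, comp, tree, thresholds)
rp = recall_precision(labeled)
print(round(rp.recall.median(), 3))             # 0.99
```

The printed numbers mean: the packaged panel occupies 13 detectors with 24
readouts (27 total parameters) and the tree resolves 20 populations; after
bead-estimated compensation and FMO thresholding, the median per-population
recall against the generator's hidden labels on a healthy 50k-event sample
is 0.990 (`examples/03_simulate_and_gate.py` prints the full per-leaf
table). `examples/04_tumor_quantification.py` runs control vs the
intravenous LLC1 model (5 mice each) and stars exactly the expected shifts:

```
LLC1      0 → 1639 cells/mg  p<0.0001 ****
NKT     920 → 2716           p=0.0063 **
Treg    757 → 2396           p=0.0005 ***
VSMC   1079 → 2425           p=0.0093 **
```

Each example in `examples/` is a short narrative script for one
capability: panel design and channel-sharing resolvability, compensation
with the bimodal higher-peak rule, simulate-and-gate, and tumor-model
quantification.

## Command line

A thin CLI wraps the library: `lungflow simulate | beads | compensate |
thresholds | gate | quantify | report | run-all`. The full pipeline is
deterministic from one seed:

```sh
lungflow run-all --preset control --preset intravenous \
    --seed 7 --n-events 20000 --n-mice 5 --out results/
```

writes the estimated spillover matrix, FMO thresholds, per-sample
population tables, tidy counts and a Dunnett comparison table (plus a
plain-text log with output hashes); repeating the command reproduces every
table byte for byte.

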