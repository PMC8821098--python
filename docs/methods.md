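# Methods

`lungflow` reimplements, entirely in silico, a multispectral flow-cytometry
workflow for whole-lung phenotyping in mice: a 25-antibody panel read as 24
marker readouts with only 13 fluorescence detectors, resolved by a
hierarchical gating tree, FMO-derived thresholds, bead-based spillover
compensation and counting-bead absolute quantification. Because no event
data are deposited for this design, the package ships a seeded synthetic
generator that emulates the statistical structure the gating strategy
assumes, so every stage can be validated against hidden ground truth.

## Panel model and channel sharing

The panel is a list of `(antigen, fluorochrome, dilution)` entries plus a
fluorochrome→detector merge map (FITC merges with AF488, APC with AF647,
APC-Cy7 with APC-eFluor780). Listing the panel as a single master stain,
duplicate compartment rows collapse to 25 unique entries occupying exactly
13 detectors. CD64 and MerTK are flagged as one *combined group*: both
antibodies carry the same dye and their summed signal is one macrophage
readout, giving 24 readouts; with the 7-AAD viability dye and two scatter
parameters the panel reads 27 parameters.

`check_sharing` verifies the design's central trick — fluorochrome reuse —
against a gating tree. For every root-to-leaf path it collects the marker
axes that the path's gate selections actually depend on (an axis whose sign
varies freely over a child's claimed quadrants, such as CD31 for the
CD45⁺ immune branch, does not constrain the path). Two readouts sharing a
detector conflict if both constrain one path, unless the earlier one was
pinned to its negative side (its dye then contributes no signal) or the two
form a combined group. The packaged tree has zero conflicts; the test suite
cross-checks this against a brute-force path-enumeration oracle.

## Synthetic event generator

**Expression model.** Each readout of each population is assigned a class
`neg / low / int / high`, mapped to lognormal medians of 1 / 300 / 2000 /
15000 arbitrary units with a within-class CV of 0.35. These locations
spread the classes over the arcsinh (cofactor 150) display range the gating
module uses, with deliberate overlap between neighbouring classes.
A combined readout (CD64/MerTK) contributes one draw per pooled antibody,
i.e. twice the class signal — the reason the design pools two macrophage
markers on a dye whose detector also carries a deliberately bright CD31
stain.

**Autofluorescence.** Per-channel exponential baseline (scale 50 a.u.),
multiplied by a per-population factor: ×8 for alveolar macrophages (the
notoriously autofluorescent class, and the reason the tree removes them
first), ×2 for interstitial macrophages, ×1 otherwise, ×0 for beads.

**Spillover.** A deterministic 14×14 matrix with unit diagonal and
laser-block structure: up to 10% into the next redder detector of the same
excitation laser, 3–4% two steps or upstream, plus cross-laser terms for
dyes emitting in another laser's band (PE-Cy7 ↔ APC-Cy7 tandems, PerCP ↔
red dyes). The 7-AAD row is identity (its dye is not unmixed from other
channels) while other dyes do leak into its detector. Observed events are
`true @ S` followed by multiplicative lognormal noise (CV 0.15 per channel,
independent) — so compensation can never be exact, which is what makes the
FMO thresholds meaningful.

**Event classes.** A sample mixes live singlets of the 20 populations
(weights = baseline frequency × condition multiplier, renormalized), LLC1
tumor cells at the preset's tumor fraction, plus 10% debris (small
scatter), 5% dead cells (7-AAD high) and 3% doublets (two summed live
events with FSC-W ×1.8) among cellular events, and counting beads. Bead
events enter at the tube ratio `beads_added : total_cells`, with total cell
density = 50 000 cells/mg × tissue mass (10 mg, 10 000 beads by default),
so the bead-normalized counts recover per-mg densities. Beads are bright in
every channel and sit in a distinctive scatter region (low FSC, very high
SSC).

**Condition presets.** Only the *direction* of each condition's
reported shift is encoded; magnitudes default to a uniform ×3: the transgenic Kras model
raises epithelium, alveolar macrophages, cDCs, BECs, LECs and Tregs (its
tumor is a CD324⁺ epithelial expansion, no LLC1 events); the intratracheal
model raises NKT cells only; the intravenous model raises VSMCs, NKT cells
and Tregs with 6% LLC1 events; the tumor-relapse model raises fibroblasts,
both monocyte subsets, neutrophils, pDCs, Tregs and NKT cells with 5%
LLC1. Mouse-to-mouse biological variation is a per-population lognormal
factor (CV 0.3 by default in experiment runs).

**Compensation beads.** One pooled single-stain sample per detector: half
negative (baseline only), half positive at 20 000 a.u. pushed through the
true spillover row. The APC-Cy7/APC-eF780 channel pools three antibodies
(CD3, Ly6G, CD117-eF780) with unequal bead affinities: half of its positive
beads sit at 0.45× intensity and carry a perturbed (tandem-variant)
spillover signature with 1.5× off-diagonals. Selecting the
higher-intensity peak therefore recovers the matrix the main stain actually
follows; selecting the dim peak would mis-compensate by up to ~50% of the
affected coefficients.

## Spillover estimation and compensation

Per bead sample, events are split into negative/positive by an exhaustive
1-D minimum-within-class-variance threshold on arcsinh-transformed
intensities. Multimodality of the positive cluster is detected by
Silverman-bandwidth kernel density smoothing; a second mode counts only if
the valley between modes drops below 70% of the smaller peak (guarding
against density ripples), and the **highest-intensity** mode is kept.
Spillover into channel *j* is `(median_j(pos) − median_j(neg)) /
(median_i(pos) − median_i(neg))`, rows normalized to unit diagonal; medians
are robust to the generator's heavy tails. Channels without a bead sample
(only the viability detector) get an identity row. Compensation multiplies
the fluorescence block by the inverse matrix; negative values are permitted
and the operation is documented as non-idempotent.

With the default 5000 beads/channel and noise CV 0.15, the maximum absolute
entry error is ~0.002 (10-seed worst case; the packaged check requires
< 0.01). One caveat quantified in the tests: comparing *medians* of
compensated events against noiseless truth is biased by ~1% extra on dim
channels dominated by spill-in from a ≫ brighter channel — an intrinsic
property of unmixing under multiplicative noise (it persists with the exact
true matrix), so the round-trip test uses a 2% band on signal-dominant
channels and 3% on dim positives.

## Gating

Gating operates on arcsinh(x/150)-transformed compensated intensities;
scatter is gated raw. Gates are thresholds, intervals, rectangles and
quadrants; ties at a cutpoint go to the negative side (half-open
intervals). Each tree node owns one gate; children claim outcome sets
(a child may claim several quadrants, e.g. the immune branch takes both
CD31 quadrants of the CD31/CD45 gate). Outcomes without a child yield
`unassigned@<node>` labels, mirroring deliberately uncharacterized subsets
such as the CD24⁺ stromal compartment.

The packaged tree: bead scatter box → debris (FSC-A below the 10th
percentile of beads-excluded events, data-driven) → 7-AAD⁺ dead removal
(fixed cut at 3000 a.u.) → doublet removal (FSC-W > 100 000) → CD31/CD45
quadrant → endothelial (CD146⁺Ly6C⁺ BEC; CD146⁻CD90⁺ LEC), stromal
(CD140⁺CD324⁻ fibroblast; CD324⁺CD140⁻ epithelial; double-negative CD146⁺
CD24⁻ VSMC; optionally FSC-high CD326⁻ LLC1) and immune branches. The
immune branch removes CD44⁺CD11b⁻CD11c⁺ alveolar macrophages first, then
splits on CD11b into the myeloid chain (Ly6G⁺ neutrophils, SiglecF⁺
eosinophils, MHCII⁻Ly6C± monocytes, MHCII⁺CD24⁺CD64/MerTK⁻ cDCs,
MHCII⁺CD24⁻CD64/MerTK⁺ interstitial macrophages) and the lymphoid chain
(CD24⁺MHCII⁺ B cells, NK1.1⁺CD3⁻ NK, NK1.1⁺CD3⁺CD90⁺ NKT, CD3⁺ T subsets
with CD4⁺GITR⁺ Tregs and CD4⁻CD8⁻γδTCR⁺ γδ T cells, and CD3⁻SiglecH⁺CD11c⁺
pDCs).

**FMO thresholds.** For every marker axis, the cutpoint is the 99.5th
percentile (configurable) of that channel among the events of the marker's
FMO control that reach the gate's node — the fully-stained-minus-one
background *within the parent gate*. This self-calibrates each gate's
false-positive rate to ~0.5% against whatever co-channel background its
parent population carries. When a parent population is empty in the
healthy-tissue FMO (the tumor-cell branch), the threshold falls back to
the nearest non-empty ancestor population, recorded in the provenance.
Thresholds are derived top-down so ancestor gates are always resolved
first.

**Design choices where the source design is ambiguous.** Tregs are gated
CD4⁺GITR⁺ — the reading consistent with GITR biology (regulatory T cells
express GITR at high levels) where the design's gate descriptions
contradict each other. Epithelium is gated CD324⁺/CD140⁻ with CD326
carried as a confirmatory, non-gating marker (the two epithelial adhesion
markers are used interchangeably in the design); CD326 *is* gated,
negatively, in the LLC1 leaf. The pDC
gate uses SiglecH⁺ then CD11c⁺; MHCII-intermediate is treated as
descriptive. The alveolar-macrophage gate interrogates CD44 and CD11b
first and confirms CD11c within the CD44⁺CD11b⁻ subset — within that
parent the BV711 detector is free of CD4 and CD326 signal, which is the
only ordering that keeps the shared detector readable.

## Quantification and statistics

`cells/mg = raw events / bead events × beads added / tissue mass`; bead
events are identified by the scatter gate *before* live/dead exclusion, so
staining artifacts cannot bias the denominator. Group comparison is
one-way ANOVA across conditions followed by Dunnett's many-to-one test of
every model against the control (`scipy.stats.dunnett`, two-sided),
unbalanced group sizes allowed; stars follow p ≤ 0.05/0.01/0.001/0.0001.
Degenerate all-identical data reports p = 1. At the default study
conditions (×3 effects, 5 mice/group, biological CV 0.3) the pipeline's
null type-I error is ≈ 5% and the power for a ×3 shift is ≈ 1.

## What the generator does and does not emulate

It reproduces the features the gating strategy relies on: class-separable
but overlapping lognormal expression, population-specific
autofluorescence, linear spillover with imperfect (noisy) compensation,
channel sharing, pre-gate contaminants and counting beads. It does **not**
model optics or photon statistics, acquisition-time drift, cell-cycle or
DNA content, antibody titration chemistry, marker-expression continua
(activation states, CD44 memory-T heterogeneity — lymphoid CD44 is modeled
negative so the alveolar-macrophage pre-gate stays clean), doublet
coincidence rates by size, or batch effects. Passing tests therefore
demonstrate the *pipeline logic* — resolvability, compensation,
thresholding, quantification — not performance on real instruments.

## Problem sizes and numerical choices

Packaged checks use 5000 beads/channel over 10 seeds for compensation
recovery; five 100 000-event healthy samples (each with its own bead and
FMO setup at 30 000 events per control) for population recovery; five
joint experiments of 25 mice × 20 000 events for direction recovery; 100
count-level datasets for null calibration. Matrix singularity is guarded
at condition number 10⁸; the debris percentile, arcsinh cofactor (150),
viability cut (3000 a.u.), doublet cut (100 000) and the LLC1 FSC cut
(160 000) are fixed configuration values exposed in
`lungflow.lung_tree.FIXED_CUTPOINTS`. All randomness flows from explicit
seeds through named stage sub-seeds (`lungflow.pipeline.stage_seed`); no
global random state is touched.

## Known limitations

The Gating-ML export flattens multi-quadrant children to one rectangle per
gate element and is intended for interoperability smoke tests, not
round-tripping. FCS support is a minimal float32 list-mode 3.1
reader/writer with label sidecars; CSV is the canonical format. Recall is
reported against *all* simulated events of a population, so pre-gate
losses (≲1%) count against it; interstitial-macrophage recall (~0.95) and
eosinophil precision (~0.9) are the weakest figures, both caused by
alveolar-macrophage autofluorescence leaking through the CD11b gate —
faithful to a well-known artifact of real lung cytometry.
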