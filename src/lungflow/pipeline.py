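"""High-level pipeline: beads -> spillover -> FMO thresholds -> gating ->
quantification, with deterministic per-stage seeding."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compensation import SpilloverEstimate, apply_compensation, estimate_spillover
from .events import LABEL_COLUMN, TRUTH_COLUMN, EventTable
from .gating import GatingTree, ThresholdSet, apply_tree, derive_thresholds
from .lung_tree import lung_gating_tree
from .panel import Panel, default_panel
from .profiles import (
    POPULATIONS,
    ConditionPreset,
    PopulationProfile,
    condition_presets,
    default_profiles,
    mouse_jitter,
)
from .quantify import PopulationCounts, absolute_counts, compare_to_control
from .simulate import (
    SpilloverModel,
    default_spillover,
    simulate_comp_beads,
    simulate_fmo,
    simulate_sample,
)

__all__ = [
    "stage_seed",
    "make_spillover_estimate",
    "make_thresholds",
    "process_sample",
    "run_experiment",
    "recall_precision",
]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic sub-seed (< 2^31) for a named pipeline stage."""
    ss = np.random.SeedSequence([int(seed), abs(hash_stage(stage))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_stage(stage: str) -> int:
    # stable across processes (unlike builtin hash)
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def make_spillover_estimate(
    panel: Panel,
    spill: SpilloverModel,
    seed: int,
    n_beads: int = 5000,
) -> SpilloverEstimate:
    beads = simulate_comp_beads(panel, spill, stage_seed(seed, "beads"),
                                n_beads=n_beads)
    return estimate_spillover(beads)


def make_thresholds(
    tree: GatingTree,
    profiles: list[PopulationProfile],
    spill: SpilloverModel,
    comp,
    seed: int,
    n_fmo: int = 30_000,
    percentile: float = 99.5,
    panel: Panel | None = None,
) -> ThresholdSet:
    """Simulate one healthy FMO control per gated marker, compensate with
    the estimated matrix and derive the cutpoints."""
    panel = panel or default_panel()
    control = condition_presets()["control"]
    fmos: dict[str, EventTable] = {}
    for i, marker in enumerate(sorted(tree.marker_axes())):
        raw = simulate_fmo(profiles, control, marker, n_fmo, spill,
                           stage_seed(seed, f"fmo:{marker}"), panel=panel)
        fmos[marker] = apply_compensation(raw, comp)
    return derive_thresholds(tree, fmos, percentile=percentile)


def process_sample(sample: EventTable, comp, tree: GatingTree,
                   thresholds: ThresholdSet):
    """Compensate, gate and tabulate one sample."""
    labeled, pop_table = apply_tree(apply_compensation(sample, comp), tree,
                                    thresholds)
    return labeled, pop_table


def recall_precision(labeled: EventTable,
                     populations=POPULATIONS) -> pd.DataFrame:
    """Per-population recall and precision of gated labels against the
    generator's hidden truth (all simulated events in the denominator of
    recall, so pre-gate losses count against it)."""
    truth = labeled.data[TRUTH_COLUMN].to_numpy()
    pred = labeled.data[LABEL_COLUMN].to_numpy()
    rows = []
    for pop in populations:
        t = truth == pop
        p = pred == pop
        tp = int((t & p).sum())
        rows.append({
            "population": pop,
            "n_true": int(t.sum()),
            "n_called": int(p.sum()),
            "recall": tp / t.sum() if t.any() else np.nan,
            "precision": tp / p.sum() if p.any() else np.nan,
        })
    return pd.DataFrame(rows)


def run_experiment(
    presets: list[ConditionPreset],
    seed: int,
    *,
    n_mice: int = 5,
    n_events: int = 20_000,
    n_fmo: int = 30_000,
    n_beads: int = 5000,
    biological_cv: float = 0.3,
    include_tumor_leaf: bool = True,
    percentile: float = 99.5,
    profiles: list[PopulationProfile] | None = None,
    spill: SpilloverModel | None = None,
    panel: Panel | None = None,
    control_name: str = "control",
):
    """Full in-silico experiment: one compensation + threshold setup, then
    ``n_mice`` samples per condition, gated and quantified.

    Returns (counts, comparisons, context dict).  Comparisons are None when
    fewer than two conditions are provided or the control is absent.
    """
    panel = panel or default_panel()
    profiles = profiles or default_profiles()
    spill = spill or default_spillover()
    tree = lung_gating_tree(include_tumor_leaf=include_tumor_leaf, panel=panel)
    comp = make_spillover_estimate(panel, spill, seed, n_beads=n_beads)
    thresholds = make_thresholds(tree, profiles, spill, comp, seed,
                                 n_fmo=n_fmo, percentile=percentile,
                                 panel=panel)
    populations = list(tree.leaf_labels)
    counts: list[PopulationCounts] = []
    pop_tables: dict[str, pd.DataFrame] = {}
    for preset in presets:
        for m in range(n_mice):
            s = stage_seed(seed, f"sample:{preset.name}:{m}")
            cond = preset
            if biological_cv > 0:
                jrng = np.random.default_rng(stage_seed(
                    seed, f"jitter:{preset.name}:{m}"))
                cond = mouse_jitter(preset, biological_cv, jrng)
            sample = simulate_sample(
                profiles, cond, n_events, spill, s, panel=panel,
                sample_id=f"{preset.name}_m{m + 1}",
            )
            labeled, pop_table = process_sample(sample, comp, tree, thresholds)
            pop_tables[f"{preset.name}_m{m + 1}"] = pop_table
            counts.append(absolute_counts(labeled, populations=populations))
    comparisons = None
    names = {p.name for p in presets}
    if len(names) >= 2 and control_name in names and n_mice >= 2:
        comparisons = compare_to_control(counts, control_name)
    context = {
        "tree": tree, "thresholds": thresholds, "comp": comp,
        "pop_tables": pop_tables, "panel": panel,
    }
    return counts, comparisons, context
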