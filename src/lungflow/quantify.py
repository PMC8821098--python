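"""Absolute quantification with counting beads and control-vs-model
statistics.

Cells per mg tissue = raw events / bead events x beads added / tissue mass.
Group comparisons follow the one-way ANOVA + Dunnett many-to-one design:
each condition is tested against the control with multiplicity-adjusted
p-values and the usual star codes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import LABEL_COLUMN, EventTable

__all__ = [
    "QuantifyError",
    "PopulationCounts",
    "GroupComparison",
    "absolute_counts",
    "compare_to_control",
    "comparisons_to_frame",
    "counts_to_frame",
    "star_code",
    "plot_counts",
]

BEAD_LABEL = "bead"
_EXCLUDED = {"bead", "debris", "dead", "doublet"}


class QuantifyError(ValueError):
    pass


@dataclass
class PopulationCounts:
    """Per-sample absolute counts (cells per mg tissue) per population."""

    sample_id: str
    condition: str
    cells_per_mg: dict[str, float]
    raw_counts: dict[str, int]
    bead_events: int
    beads_added: float
    tissue_mass_mg: float


def star_code(p: float) -> str:
    """Significance stars: p<=0.05 *, <=0.01 **, <=0.001 ***, <=0.0001 ****."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def absolute_counts(
    labeled: EventTable,
    beads_added: float | None = None,
    tissue_mass_mg: float | None = None,
    populations: list[str] | None = None,
) -> PopulationCounts:
    """Convert gated event counts to cells per mg via the counting standard.

    Bead events are identified by the ``bead`` label (beads enter the count
    before any live/dead exclusion).  Pre-gate exclusions and unassigned
    events are never counted as populations.
    """
    if LABEL_COLUMN not in labeled.data.columns:
        raise QuantifyError("events are not labeled; run apply_tree first")
    meta = labeled.metadata
    beads_added = beads_added if beads_added is not None else meta.get(
        "beads_added")
    tissue_mass_mg = (tissue_mass_mg if tissue_mass_mg is not None
                      else meta.get("tissue_mass_mg"))
    if not beads_added or beads_added <= 0:
        raise QuantifyError("beads_added must be positive")
    if not tissue_mass_mg or tissue_mass_mg <= 0:
        raise QuantifyError("tissue_mass_mg must be positive")

    labels = labeled.data[LABEL_COLUMN]
    bead_events = int((labels == BEAD_LABEL).sum())
    if bead_events == 0:
        raise QuantifyError("no bead events: cannot normalize to cells/mg")

    counts = labels.value_counts().to_dict()
    if populations is None:
        populations = sorted(
            k for k in counts
            if k not in _EXCLUDED and not str(k).startswith("unassigned@")
        )
    raw = {p: int(counts.get(p, 0)) for p in populations}
    factor = beads_added / bead_events / tissue_mass_mg
    return PopulationCounts(
        sample_id=str(meta.get("sample_id", "sample")),
        condition=str(meta.get("condition", "unknown")),
        cells_per_mg={p: raw[p] * factor for p in populations},
        raw_counts=raw,
        bead_events=bead_events,
        beads_added=float(beads_added),
        tissue_mass_mg=float(tissue_mass_mg),
    )


@dataclass
class GroupComparison:
    """Dunnett-adjusted comparison of one population across conditions."""

    population: str
    means: dict[str, float]
    sems: dict[str, float]
    n: dict[str, int]
    anova_p: float
    pvalues: dict[str, float] = field(default_factory=dict)  # vs control
    stars: dict[str, str] = field(default_factory=dict)


def compare_to_control(
    counts: list[PopulationCounts],
    control_name: str = "control",
) -> list[GroupComparison]:
    """One-way ANOVA across conditions, then Dunnett many-to-one tests of
    every condition against the control, per population.

    Group sizes may be unbalanced.  Two identical groups of identical
    values are reported as no difference (p = 1).
    """
    by_cond: dict[str, list[PopulationCounts]] = {}
    for c in counts:
        by_cond.setdefault(c.condition, []).append(c)
    if control_name not in by_cond:
        raise QuantifyError(f"missing control condition {control_name!r}")
    if len(by_cond) < 2:
        raise QuantifyError("need at least two conditions")
    for cond, group in by_cond.items():
        if len(group) < 2:
            raise QuantifyError(
                f"condition {cond!r} has {len(group)} sample(s); need >= 2"
            )
    populations = sorted({p for c in counts for p in c.cells_per_mg})
    treat_names = [c for c in sorted(by_cond) if c != control_name]

    out: list[GroupComparison] = []
    for pop in populations:
        groups = {
            cond: np.array([s.cells_per_mg.get(pop, 0.0) for s in samples])
            for cond, samples in by_cond.items()
        }
        ctrl = groups[control_name]
        treats = [groups[t] for t in treat_names]
        flat = np.concatenate([ctrl] + treats)
        if np.allclose(flat, flat[0]):
            anova_p = 1.0
            pvals = {t: 1.0 for t in treat_names}
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anova_p = float(stats.f_oneway(ctrl, *treats).pvalue)
                res = stats.dunnett(*treats, control=ctrl)
            pvals = {
                t: float(np.clip(p, 0.0, 1.0))
                for t, p in zip(treat_names, np.atleast_1d(res.pvalue))
            }
            if math.isnan(anova_p):
                anova_p = 1.0
            pvals = {t: 1.0 if math.isnan(p) else p for t, p in pvals.items()}
        out.append(GroupComparison(
            population=pop,
            means={c: float(g.mean()) for c, g in groups.items()},
            sems={c: float(g.std(ddof=1) / math.sqrt(len(g)))
                  for c, g in groups.items()},
            n={c: len(g) for c, g in groups.items()},
            anova_p=anova_p,
            pvalues=pvals,
            stars={t: star_code(p) for t, p in pvals.items()},
        ))
    return out


def counts_to_frame(counts: list[PopulationCounts]) -> pd.DataFrame:
    """Tidy sample x population x cells_per_mg table."""
    rows = [
        {"sample_id": c.sample_id, "condition": c.condition, "population": p,
         "raw_events": c.raw_counts.get(p, 0), "cells_per_mg": v,
         "bead_events": c.bead_events, "beads_added": c.beads_added,
         "tissue_mass_mg": c.tissue_mass_mg}
        for c in counts
        for p, v in sorted(c.cells_per_mg.items())
    ]
    return pd.DataFrame(rows)


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for cond in sorted(c.means):
            rows.append({
                "population": c.population,
                "condition": cond,
                "mean_cells_per_mg": c.means[cond],
                "sem": c.sems[cond],
                "n": c.n[cond],
                "anova_p": c.anova_p,
                "dunnett_p_vs_control": c.pvalues.get(cond, np.nan),
                "stars": c.stars.get(cond, ""),
            })
    return pd.DataFrame(rows)


def plot_counts(comparisons: list[GroupComparison], path,
                control_name: str = "control") -> None:
    """Bar plot of mean +- SEM cells/mg per population and condition, with
    significance stars over the bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pops = [c.population for c in comparisons]
    conds = sorted(comparisons[0].means) if comparisons else []
    fig, ax = plt.subplots(figsize=(max(8, 0.6 * len(pops) * len(conds)), 4))
    width = 0.8 / max(1, len(conds))
    x = np.arange(len(pops))
    for i, cond in enumerate(conds):
        means = [c.means[cond] for c in comparisons]
        sems = [c.sems[cond] for c in comparisons]
        bars = ax.bar(x + i * width, means, width, yerr=sems, capsize=2,
                      label=cond)
        for j, c in enumerate(comparisons):
            s = c.stars.get(cond, "")
            if s:
                ax.text(x[j] + i * width, means[j] + sems[j], s,
                        ha="center", va="bottom", fontsize=7)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(pops, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("cells per mg tissue")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
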