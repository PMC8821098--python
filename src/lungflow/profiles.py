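"""Population expression profiles and tumor-condition presets.

Each of the 20 lung populations is described by a per-readout expression
class (neg / low / int / high), a scatter profile and an autofluorescence
scale.  The classes map to strictly increasing lognormal location
parameters; neighbouring classes overlap, which is what makes the
FMO-derived thresholds and the gate ordering matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LEVEL_MEANLOG",
    "EXPRESSION_CV",
    "PopulationProfile",
    "ConditionPreset",
    "POPULATIONS",
    "AUXILIARY",
    "default_profiles",
    "condition_presets",
    "mouse_jitter",
]

#: Lognormal location (natural log of the class median, arbitrary
#: fluorescence units) per expression class.  Strictly increasing.
LEVEL_MEANLOG: dict[str, float] = {
    "neg": 0.0,                 # median 1 a.u. — buried in autofluorescence
    "low": math.log(300.0),
    "int": math.log(2000.0),
    "high": math.log(15000.0),
}

#: Coefficient of variation of per-event expression within a class.
EXPRESSION_CV = 0.35

#: The 20 lung populations of the packaged gating tree, in report order.
POPULATIONS: tuple[str, ...] = (
    "BEC",
    "LEC",
    "fibroblast",
    "epithelial",
    "VSMC",
    "alveolar_macrophage",
    "neutrophil",
    "eosinophil",
    "Ly6Cpos_monocyte",
    "Ly6Cneg_monocyte",
    "cDC",
    "interstitial_macrophage",
    "B_cell",
    "NK",
    "NKT",
    "CD4_T",
    "CD8_T",
    "Treg",
    "gdT",
    "pDC",
)

#: Auxiliary event classes generated alongside the populations.
AUXILIARY: tuple[str, ...] = ("LLC1", "debris", "dead", "bead")


@dataclass(frozen=True)
class PopulationProfile:
    """Statistical description of one event class.

    ``marker_levels`` maps readout name -> expression class; readouts not
    listed are negative.  ``scatter_profile`` maps each scatter parameter to
    (median, CV).  ``baseline_frequency`` is the fraction of live singlets
    in healthy lung (0 for auxiliary classes).  ``bead_signal`` marks
    counting beads: a uniform bright signal in every channel instead of
    antibody staining.
    """

    name: str
    marker_levels: dict[str, str] = field(default_factory=dict)
    scatter_profile: dict[str, tuple[float, float]] = field(default_factory=dict)
    autofluorescence_scale: float = 1.0
    baseline_frequency: float = 0.0
    bead_signal: float | None = None
    bead_cv: float = 0.10

    def __post_init__(self) -> None:
        for marker, lvl in self.marker_levels.items():
            if lvl not in LEVEL_MEANLOG:
                raise ValueError(f"{self.name}/{marker}: unknown level {lvl!r}")
        if self.autofluorescence_scale < 0:
            raise ValueError(f"{self.name}: autofluorescence_scale must be >= 0")
        if not 0.0 <= self.baseline_frequency <= 1.0:
            raise ValueError(f"{self.name}: baseline_frequency outside [0, 1]")


# Scatter archetypes: (median, CV) for FSC-A / FSC-W / SSC-A.
def _scatter(fsc: float, ssc: float, fsc_cv: float = 0.15, ssc_cv: float = 0.30,
             w: float = 70_000.0, w_cv: float = 0.08):
    return {
        "FSC-A": (fsc, fsc_cv),
        "FSC-W": (w, w_cv),
        "SSC-A": (ssc, ssc_cv),
    }


_LYMPHOID = _scatter(60_000, 30_000)
_MYELOID = _scatter(90_000, 60_000)
_STRUCTURAL = _scatter(110_000, 70_000, fsc_cv=0.18)


def default_profiles() -> list[PopulationProfile]:
    """Profiles for the 20 lung populations plus LLC1 tumor cells, debris,
    dead cells and counting beads.

    Expression assignments follow the panel's gating logic: e.g. alveolar
    macrophages are CD44-high / CD11b-neg / CD11c-high and by far the most
    autofluorescent class; LLC1 cells are large (high FSC) and negative for
    CD45, CD324, CD326, CD90 and CD31.  Immune cells carry a low level of
    CD31, which the CD31/CD45 quadrant ignores by design.
    """
    imm = {"CD45": "high", "CD31": "low"}
    profs = [
        PopulationProfile(
            "BEC",
            {"CD31": "high", "CD146": "high", "Ly6C": "high", "CD24": "int"},
            _STRUCTURAL, baseline_frequency=0.12,
        ),
        PopulationProfile(
            "LEC",
            {"CD31": "high", "CD90": "high"},
            _STRUCTURAL, baseline_frequency=0.01,
        ),
        PopulationProfile(
            "fibroblast",
            {"CD140": "high", "CD90": "int"},
            _STRUCTURAL, baseline_frequency=0.08,
        ),
        PopulationProfile(
            "epithelial",
            {"CD324": "high", "CD326": "high", "CD24": "int", "CD117": "int"},
            _STRUCTURAL, baseline_frequency=0.08,
        ),
        PopulationProfile(
            "VSMC",
            {"CD146": "high"},
            _STRUCTURAL, baseline_frequency=0.02,
        ),
        PopulationProfile(
            "alveolar_macrophage",
            imm | {"CD44": "high", "CD11c": "high", "CD64/MerTK": "low",
                   "MHCII": "low", "SiglecF": "int"},
            _scatter(150_000, 120_000, fsc_cv=0.18, ssc_cv=0.20),
            autofluorescence_scale=8.0, baseline_frequency=0.10,
        ),
        PopulationProfile(
            "neutrophil",
            imm | {"CD11b": "high", "Ly6G": "high", "Ly6C": "int", "CD44": "low"},
            _scatter(90_000, 90_000, ssc_cv=0.25), baseline_frequency=0.05,
        ),
        PopulationProfile(
            "eosinophil",
            imm | {"CD11b": "high", "SiglecF": "high", "CD44": "low"},
            _scatter(95_000, 110_000, ssc_cv=0.25), baseline_frequency=0.02,
        ),
        PopulationProfile(
            "Ly6Cpos_monocyte",
            imm | {"CD11b": "high", "Ly6C": "high", "CD64/MerTK": "low",
                   "CD44": "low"},
            _MYELOID, baseline_frequency=0.04,
        ),
        PopulationProfile(
            "Ly6Cneg_monocyte",
            imm | {"CD11b": "high", "CD64/MerTK": "low", "CD44": "low"},
            _MYELOID, baseline_frequency=0.04,
        ),
        PopulationProfile(
            "cDC",
            imm | {"CD11b": "high", "MHCII": "high", "CD24": "high",
                   "CD11c": "int", "CD117": "low", "CD44": "low"},
            _MYELOID, baseline_frequency=0.02,
        ),
        PopulationProfile(
            "interstitial_macrophage",
            imm | {"CD11b": "high", "MHCII": "high", "CD64/MerTK": "int",
                   "CD11c": "int", "CD44": "int"},
            _MYELOID, autofluorescence_scale=2.0, baseline_frequency=0.03,
        ),
        PopulationProfile(
            "B_cell",
            imm | {"CD24": "high", "MHCII": "high"},
            _LYMPHOID, baseline_frequency=0.15,
        ),
        PopulationProfile(
            "NK",
            imm | {"NK1.1": "high"},
            _LYMPHOID, baseline_frequency=0.04,
        ),
        PopulationProfile(
            "NKT",
            imm | {"NK1.1": "high", "CD3": "high", "CD90": "high"},
            _LYMPHOID, baseline_frequency=0.02,
        ),
        PopulationProfile(
            "CD4_T",
            imm | {"CD3": "high", "CD90": "high", "CD4": "high"},
            _LYMPHOID, baseline_frequency=0.08,
        ),
        PopulationProfile(
            "CD8_T",
            imm | {"CD3": "high", "CD90": "high", "CD8a": "high"},
            _LYMPHOID, baseline_frequency=0.06,
        ),
        PopulationProfile(
            "Treg",
            imm | {"CD3": "high", "CD90": "high", "CD4": "high",
                   "GITR": "high"},
            _LYMPHOID, baseline_frequency=0.02,
        ),
        PopulationProfile(
            "gdT",
            imm | {"CD3": "high", "CD90": "high", "gdTCR": "high"},
            _LYMPHOID, baseline_frequency=0.01,
        ),
        PopulationProfile(
            "pDC",
            imm | {"SiglecH": "high", "CD11c": "int", "MHCII": "int",
                   "CD90": "low"},
            _LYMPHOID, baseline_frequency=0.01,
        ),
        # --- auxiliary classes -------------------------------------------
        PopulationProfile(
            "LLC1",
            {"CD44": "int", "CD117": "low", "CD24": "low"},
            _scatter(220_000, 100_000, fsc_cv=0.12, ssc_cv=0.25),
        ),
        PopulationProfile(
            "debris",
            {},
            _scatter(15_000, 8_000, fsc_cv=0.40, ssc_cv=0.50, w=50_000, w_cv=0.20),
        ),
        PopulationProfile(
            "dead",
            {"7AAD": "high"},
            _scatter(70_000, 50_000, fsc_cv=0.20),
        ),
        PopulationProfile(
            "bead",
            {},
            _scatter(25_000, 250_000, fsc_cv=0.05, ssc_cv=0.05, w=30_000,
                     w_cv=0.05),
            autofluorescence_scale=0.0, bead_signal=3000.0,
        ),
    ]
    freqs = sum(p.baseline_frequency for p in profs)
    assert abs(freqs - 1.0) < 1e-9
    return profs


@dataclass(frozen=True)
class ConditionPreset:
    """Abundance shifts of one experimental condition.

    ``abundance_multiplier`` scales the per-mg density of each listed
    population (unlisted populations keep factor 1); ``tumor_cell_fraction``
    is the fraction of live singlet cells that are LLC1-like.
    """

    name: str
    abundance_multiplier: dict[str, float] = field(default_factory=dict)
    tumor_cell_fraction: float = 0.0

    def multiplier(self, population: str) -> float:
        return self.abundance_multiplier.get(population, 1.0)

    def elevated(self) -> set[str]:
        """Populations whose density this condition raises above control."""
        up = {p for p, m in self.abundance_multiplier.items() if m > 1.0}
        if self.tumor_cell_fraction > 0:
            up.add("LLC1")
        return up


#: Default effect size for all condition-elevated populations.
DEFAULT_EFFECT = 3.0


def condition_presets(effect: float = DEFAULT_EFFECT) -> dict[str, ConditionPreset]:
    """The four lung-tumor condition presets plus healthy control.

    Only the *direction* of each condition's reported shift is encoded;
    magnitudes
    default to a uniform x3 effect.  The transgenic Kras model carries its
    tumor burden as a CD324+ epithelial expansion (no injected LLC1 cells);
    the metastatic models carry LLC1-like events.
    """
    e = float(effect)
    return {
        "control": ConditionPreset("control"),
        "krasLA2": ConditionPreset(
            "krasLA2",
            {"epithelial": e, "alveolar_macrophage": e, "cDC": e,
             "BEC": e, "LEC": e, "Treg": e},
        ),
        "intratracheal": ConditionPreset(
            "intratracheal",
            {"NKT": e},
        ),
        "intravenous": ConditionPreset(
            "intravenous",
            {"VSMC": e, "NKT": e, "Treg": e},
            tumor_cell_fraction=0.06,
        ),
        "tumor_relapse": ConditionPreset(
            "tumor_relapse",
            {"fibroblast": e, "Ly6Cpos_monocyte": e, "Ly6Cneg_monocyte": e,
             "neutrophil": e, "pDC": e, "Treg": e, "NKT": e},
            tumor_cell_fraction=0.05,
        ),
    }


def mouse_jitter(condition: ConditionPreset, cv: float,
                 rng: np.random.Generator,
                 populations: tuple[str, ...] = POPULATIONS) -> ConditionPreset:
    """Per-animal biological variation: multiply every population's density
    by an independent lognormal factor with the given CV."""
    if cv <= 0:
        return condition
    sdlog = math.sqrt(math.log1p(cv * cv))
    mult = dict(condition.abundance_multiplier)
    for p in populations:
        mult[p] = mult.get(p, 1.0) * float(
            np.exp(rng.normal(-0.5 * sdlog**2, sdlog))
        )
    return replace(condition, name=condition.name, abundance_multiplier=mult)
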