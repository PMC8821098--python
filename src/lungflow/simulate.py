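"""Seeded synthetic cytometry samples: full stains, FMO controls and
compensation beads.

The generator emulates the statistical structure the gating strategy
assumes: lognormal per-readout expression by level class, co-channel
readouts summing within a detector, per-population autofluorescence
baselines, linear spillover mixing, multiplicative measurement noise, and
configurable fractions of debris, dead cells, doublets and counting beads.
All randomness flows from a single explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import TRUTH_COLUMN, EventTable
from .panel import (
    DETECTOR_CHANNELS,
    FLUOR_CHANNELS,
    SCATTER_PARAMS,
    VIABILITY_CHANNEL,
    Panel,
    default_panel,
)
from .profiles import (
    EXPRESSION_CV,
    LEVEL_MEANLOG,
    POPULATIONS,
    ConditionPreset,
    PopulationProfile,
)

__all__ = [
    "SpilloverModel",
    "EventFractions",
    "default_spillover",
    "simulate_sample",
    "simulate_fmo",
    "simulate_comp_beads",
    "simulate_counts",
    "BASE_DENSITY",
]

#: Total live-cell density of healthy lung used to convert baseline
#: frequencies into per-mg densities (cells per mg tissue).
BASE_DENSITY = 50_000.0


def _sdlog(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class SpilloverModel:
    """Ground-truth linear channel mixing.

    ``matrix`` rows give the fraction of each channel's dye signal detected
    in every channel (unit diagonal, diagonally dominant).  ``noise_cv`` is
    the CV of multiplicative per-channel measurement noise.
    ``low_peak_matrix``, when set, is the mixing used by the low-intensity
    compensation-bead peak of bimodal channels (a tandem-variant signature).
    """

    matrix: np.ndarray
    channels: tuple[str, ...] = FLUOR_CHANNELS
    noise_cv: float = 0.15
    low_peak_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.channels),) * 2:
            raise ValueError("spillover matrix shape does not match channels")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal must be exactly 1")
        if np.any((m - np.diag(np.diag(m))) < 0) or np.any(
            (m - np.diag(np.diag(m))) >= 1
        ):
            raise ValueError("off-diagonal spillover must lie in [0, 1)")
        object.__setattr__(self, "matrix", m)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.channels,
                            columns=self.channels)


#: Laser groups with within-group emission order; dyes leak mostly into
#: redder detectors of their own excitation laser.
_LASER_GROUPS: tuple[tuple[str, ...], ...] = (
    ("VioBlue", "BV510", "BV605", "BV650", "BV711"),      # violet 405 nm
    ("FITC_AF488", "7AAD", "PerCP-Cy5.5"),                # blue 488 nm
    ("PE", "PE-CF594", "PE-Cy7"),                         # yellow-green 561 nm
    ("APC_AF647", "AF700", "APC-Cy7_APC-eF780"),          # red 633 nm
)

#: Cross-laser spill of dyes whose emission lands in another laser's
#: detector band (e.g. both Cy7 tandems emit near 780 nm).
_CROSS_LASER: dict[tuple[str, str], float] = {
    ("PE-Cy7", "APC-Cy7_APC-eF780"): 0.08,
    ("APC-Cy7_APC-eF780", "PE-Cy7"): 0.05,
    ("PerCP-Cy5.5", "APC_AF647"): 0.04,
    ("APC_AF647", "PerCP-Cy5.5"): 0.02,
    ("PerCP-Cy5.5", "AF700"): 0.03,
    ("AF700", "PerCP-Cy5.5"): 0.02,
    ("PE", "BV605"): 0.02,
    ("FITC_AF488", "BV510"): 0.02,
    ("7AAD", "PE-CF594"): 0.03,
}

# within-laser spill by emission-order offset (down-chain = redder)
_WITHIN = {1: 0.10, 2: 0.03, -1: 0.04, -2: 0.01}


def default_spillover(noise_cv: float = 0.15) -> SpilloverModel:
    """Deterministic 14x14 spillover with laser-block structure: up to 10%
    into the next redder detector of the same laser, small terms upstream
    and across lasers.  The viability dye's own row is identity (7-AAD is
    not unmixed out of other channels, but other dyes do leak into its
    detector)."""
    chans = FLUOR_CHANNELS
    n = len(chans)
    m = np.eye(n)
    for group in _LASER_GROUPS:
        for a, ci in enumerate(group):
            for b, cj in enumerate(group):
                if a != b and (b - a) in _WITHIN:
                    m[chans.index(ci), chans.index(cj)] = _WITHIN[b - a]
    for (ci, cj), s in _CROSS_LASER.items():
        m[chans.index(ci), chans.index(cj)] = s
    via = chans.index(VIABILITY_CHANNEL)
    m[via, :] = 0.0
    m[via, via] = 1.0
    # tandem-variant signature of the APC-Cy7/APC-eF780 low-affinity peak:
    # 50% stronger leakage out of that channel.
    low = m.copy()
    k = chans.index("APC-Cy7_APC-eF780")
    low[k, :] *= 1.5
    low[k, k] = 1.0
    return SpilloverModel(matrix=m, channels=chans, noise_cv=noise_cv,
                         low_peak_matrix=low)


@dataclass(frozen=True)
class EventFractions:
    """Fractions of cellular events that are debris, dead or doublets."""

    debris: float = 0.10
    dead: float = 0.05
    doublet: float = 0.03

    def __post_init__(self) -> None:
        if min(self.debris, self.dead, self.doublet) < 0 or (
            self.debris + self.dead + self.doublet
        ) >= 1:
            raise ValueError("event fractions must be >= 0 and sum below 1")


def _readout_sources(panel: Panel) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Signal sources (panel readouts + viability dye), their channel
    mapping matrix (sources x channels) and per-source stain multiplicity.

    A combined readout (two antibodies deliberately on one dye, e.g.
    CD64/MerTK) contributes the summed signal of its antibodies — the
    panel's rationale for pooling markers on one fluorochrome."""
    readout_chan = panel.readout_channels()
    antigens = panel.readout_antigens()
    sources = sorted(readout_chan) + [VIABILITY_CHANNEL]
    mapping = np.zeros((len(sources), len(FLUOR_CHANNELS)))
    mult = np.ones(len(sources))
    for i, s in enumerate(sources):
        chan = readout_chan.get(s, VIABILITY_CHANNEL)
        mapping[i, FLUOR_CHANNELS.index(chan)] = 1.0
        mult[i] = float(len(antigens.get(s, (s,))))
    return sources, mapping, mult


def _level_matrix(profiles: list[PopulationProfile],
                  sources: list[str]) -> np.ndarray:
    lvl = np.zeros((len(profiles), len(sources)))
    for pi, prof in enumerate(profiles):
        for si, s in enumerate(sources):
            cls = prof.marker_levels.get(s, "neg")
            lvl[pi, si] = LEVEL_MEANLOG[cls]
    return lvl


def _mixture(profiles: list[PopulationProfile], condition: ConditionPreset,
             tissue_mass_mg: float, beads_added: float):
    """Per-mg densities, live-singlet weights and the bead event fraction."""
    by_name = {p.name: p for p in profiles}
    dens = {
        p.name: BASE_DENSITY * p.baseline_frequency * condition.multiplier(p.name)
        for p in profiles
        if p.baseline_frequency > 0
    }
    d_pops = sum(dens.values())
    if d_pops <= 0:
        raise ValueError("profiles carry no baseline frequency mass")
    tcf = condition.tumor_cell_fraction
    if tcf > 0:
        if "LLC1" not in by_name:
            raise ValueError("tumor_cell_fraction > 0 but no LLC1 profile")
        dens["LLC1"] = tcf / (1.0 - tcf) * d_pops
    total = sum(dens.values())
    weights = {k: v / total for k, v in dens.items()}
    p_bead = beads_added / (beads_added + total * tissue_mass_mg)
    return dens, weights, p_bead


def simulate_sample(
    profiles: list[PopulationProfile],
    condition: ConditionPreset,
    n_events: int,
    spill: SpilloverModel,
    seed: int,
    *,
    panel: Panel | None = None,
    omit_readouts: frozenset[str] | set[str] = frozenset(),
    fractions: EventFractions | None = None,
    beads_added: float = 10_000.0,
    tissue_mass_mg: float = 10.0,
    autofluorescence: float = 50.0,
    sample_id: str | None = None,
    include_truth: bool = True,
) -> EventTable:
    """Simulate one acquired sample under a condition preset.

    Event classes (beads, debris, dead, doublets, live singlets of each
    population) are drawn from the tube composition implied by per-mg
    densities and the number of counting beads spiked in.  Identical
    arguments and seed give identical output.
    """
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    panel = panel or default_panel()
    fractions = fractions or EventFractions()
    rng = np.random.default_rng(seed)

    sources, mapping, mult = _readout_sources(panel)
    omit = set(omit_readouts)
    unknown = omit - set(sources)
    if unknown:
        raise ValueError(f"unknown readouts to omit: {sorted(unknown)}")

    by_name = {p.name: p for p in profiles}
    _, weights, p_bead = _mixture(profiles, condition, tissue_mass_mg,
                                  beads_added)
    live_names = sorted(weights)
    live_w = np.array([weights[k] for k in live_names])

    p_cell = 1.0 - p_bead
    live_total = 1.0 - fractions.debris - fractions.dead - fractions.doublet
    categories = ["bead", "debris", "dead", "doublet"] + live_names
    probs = np.array(
        [p_bead,
         p_cell * fractions.debris,
         p_cell * fractions.dead,
         p_cell * fractions.doublet]
        + list(p_cell * live_total * live_w)
    )
    probs = probs / probs.sum()
    label_idx = rng.choice(len(categories), size=n_events, p=probs)

    # profile per category (doublets synthesised from two live parents)
    cat_profiles: list[PopulationProfile] = []
    for c in categories:
        if c == "doublet":
            cat_profiles.append(by_name["dead"])  # placeholder, replaced below
        else:
            if c not in by_name:
                raise ValueError(f"no profile named {c!r}")
            cat_profiles.append(by_name[c])

    lvl = _level_matrix(cat_profiles, sources)
    sdlog = _sdlog(EXPRESSION_CV)
    n_src = len(sources)

    def draw_true(cat_rows: np.ndarray) -> np.ndarray:
        """True per-channel signal (specific + autofluorescence) for events
        whose category indices are cat_rows."""
        k = len(cat_rows)
        spec = np.exp(lvl[cat_rows] + sdlog * rng.standard_normal((k, n_src)))
        spec = spec * mult[None, :]
        for s in omit:
            spec[:, sources.index(s)] = 0.0
        bead_rows = np.array([cat_profiles[c].bead_signal is not None
                              for c in cat_rows])
        chan = spec @ mapping
        if bead_rows.any():
            bsig = np.array([cat_profiles[c].bead_signal or 0.0
                             for c in cat_rows])[bead_rows]
            bcv = _sdlog(cat_profiles[categories.index("bead")].bead_cv)
            chan[bead_rows] = np.exp(
                np.log(bsig)[:, None]
                + bcv * rng.standard_normal((int(bead_rows.sum()),
                                             len(FLUOR_CHANNELS)))
            )
        af_scale = np.array([cat_profiles[c].autofluorescence_scale
                             for c in cat_rows])
        af = rng.exponential(1.0, (k, len(FLUOR_CHANNELS))) * (
            autofluorescence * af_scale[:, None]
        )
        return chan + af

    def draw_scatter(cat_rows: np.ndarray) -> np.ndarray:
        k = len(cat_rows)
        out = np.empty((k, len(SCATTER_PARAMS)))
        for j, par in enumerate(SCATTER_PARAMS):
            med = np.array([cat_profiles[c].scatter_profile[par][0]
                            for c in cat_rows])
            cv = np.array([cat_profiles[c].scatter_profile[par][1]
                           for c in cat_rows])
            out[:, j] = np.exp(np.log(med)
                               + _sdlog_vec(cv) * rng.standard_normal(k))
        return out

    true_chan = draw_true(label_idx)
    scatter = draw_scatter(label_idx)

    # doublets: sum of two random live singlets, FSC-W scaled by 1.8
    dbl = np.flatnonzero(label_idx == categories.index("doublet"))
    if dbl.size:
        parents = rng.choice(len(live_names), size=(dbl.size, 2), p=live_w)
        off = len(categories) - len(live_names)
        p1 = draw_true(parents[:, 0] + off)
        p2 = draw_true(parents[:, 1] + off)
        true_chan[dbl] = p1 + p2
        s1 = draw_scatter(parents[:, 0] + off)
        s2 = draw_scatter(parents[:, 1] + off)
        ssum = s1 + s2
        w_idx = SCATTER_PARAMS.index("FSC-W")
        ssum[:, w_idx] = 1.8 * 0.5 * (s1[:, w_idx] + s2[:, w_idx])
        scatter[dbl] = ssum

    observed = true_chan @ spill.matrix
    if spill.noise_cv > 0:
        observed = observed * np.exp(
            _sdlog(spill.noise_cv)
            * rng.standard_normal(observed.shape)
        )

    data = pd.DataFrame(observed, columns=list(FLUOR_CHANNELS))
    for j, par in enumerate(SCATTER_PARAMS):
        data[par] = scatter[:, j]
    if include_truth:
        data[TRUTH_COLUMN] = [categories[i] for i in label_idx]

    meta = {
        "sample_id": sample_id or f"{condition.name}_s{seed}",
        "condition": condition.name,
        "seed": int(seed),
        "n_events": int(n_events),
        "tissue_mass_mg": float(tissue_mass_mg),
        "beads_added": float(beads_added),
        "noise_cv": float(spill.noise_cv),
        "omitted_readouts": sorted(omit),
        "compensated": False,
    }
    return EventTable(data, meta)


def _sdlog_vec(cv: np.ndarray) -> np.ndarray:
    return np.sqrt(np.log1p(cv * cv))


def simulate_fmo(
    profiles: list[PopulationProfile],
    condition: ConditionPreset,
    omit_readout: str,
    n_events: int,
    spill: SpilloverModel,
    seed: int,
    **kwargs,
) -> EventTable:
    """Fluorescence-minus-one control: the full stain with one readout's
    specific signal removed (its channel keeps autofluorescence and
    spillover from other dyes)."""
    panel = kwargs.get("panel") or default_panel()
    kwargs["panel"] = panel
    readouts = set(panel.readout_channels())
    if omit_readout not in readouts:
        raise ValueError(f"{omit_readout!r} is not a readout of the panel")
    table = simulate_sample(
        profiles, condition, n_events, spill, seed,
        omit_readouts={omit_readout}, **kwargs,
    )
    table.metadata["fmo"] = omit_readout
    return table


def simulate_comp_beads(
    panel: Panel,
    spill: SpilloverModel,
    seed: int,
    *,
    n_beads: int = 5000,
    positive_fraction: float = 0.5,
    intensity: float = 20_000.0,
    baseline: float = 20.0,
    bimodal: dict[str, tuple[float, float]] | None = None,
) -> dict[str, EventTable]:
    """Single-stain compensation bead samples, one per detector channel.

    Antibodies sharing a channel are pooled into one control.  ``bimodal``
    maps channel -> (fraction at the low peak, low-peak intensity); by
    default the APC-Cy7/APC-eF780 channel (CD3, Ly6G and CD117 pooled) shows
    two positive peaks, the lower of which carries the tandem-variant
    spillover signature.  Pass ``bimodal={}`` for uniformly unimodal beads.
    """
    if bimodal is None:
        bimodal = (
            {"APC-Cy7_APC-eF780": (0.5, 0.45 * intensity)}
            if spill.low_peak_matrix is not None
            else {}
        )
    rng = np.random.default_rng(seed)
    chans = list(FLUOR_CHANNELS)
    noise_sd = _sdlog(spill.noise_cv) if spill.noise_cv > 0 else 0.0
    bead_scatter = {"FSC-A": (25_000.0, 0.05), "FSC-W": (30_000.0, 0.05),
                    "SSC-A": (250_000.0, 0.05)}

    out: dict[str, EventTable] = {}
    for channel in sorted(DETECTOR_CHANNELS, key=DETECTOR_CHANNELS.index):
        ci = chans.index(channel)
        n_pos = int(round(n_beads * positive_fraction))
        n_neg = n_beads - n_pos
        rows = np.zeros((n_beads, len(chans)))
        status = np.array(["negative"] * n_neg + ["positive"] * n_pos)
        if channel in bimodal:
            frac_low, low_int = bimodal[channel]
            n_low = int(round(n_pos * frac_low))
            row_low = (spill.low_peak_matrix if spill.low_peak_matrix
                       is not None else spill.matrix)[ci]
            rows[n_neg:n_neg + n_low] = low_int * row_low
            rows[n_neg + n_low:] = intensity * spill.matrix[ci]
        else:
            rows[n_neg:] = intensity * spill.matrix[ci]
        sig = rows * np.exp(0.15 * rng.standard_normal((n_beads, 1)))
        obs = sig + rng.exponential(baseline, (n_beads, len(chans)))
        if noise_sd > 0:
            obs = obs * np.exp(noise_sd * rng.standard_normal(obs.shape))
        data = pd.DataFrame(obs, columns=chans)
        for par, (med, cv) in bead_scatter.items():
            data[par] = np.exp(np.log(med)
                               + _sdlog(cv) * rng.standard_normal(n_beads))
        data[TRUTH_COLUMN] = status
        out[channel] = EventTable(
            data,
            {"sample_id": f"beads_{channel}", "channel": channel,
             "seed": int(seed), "compensated": False},
        )
    return out


def simulate_counts(
    profiles: list[PopulationProfile],
    condition: ConditionPreset,
    n_samples: int,
    seed: int,
    *,
    n_events: int = 20_000,
    biological_cv: float = 0.3,
    beads_added: float = 10_000.0,
    tissue_mass_mg: float = 10.0,
    fractions: EventFractions | None = None,
):
    """Per-sample population counts drawn directly at the counting stage.

    Short-circuits event synthesis and gating: per-mouse densities (with
    lognormal biological variation) are converted to Poisson event counts
    and bead-normalized cells/mg exactly as the full pipeline would.  Used
    to calibrate the group-comparison statistics (type-I error, power)
    without the cost of event-level simulation.
    """
    from .profiles import mouse_jitter
    from .quantify import PopulationCounts

    fractions = fractions or EventFractions()
    rng = np.random.default_rng(seed)
    live_frac = 1.0 - fractions.debris - fractions.dead - fractions.doublet
    out = []
    for i in range(n_samples):
        cond_i = mouse_jitter(condition, biological_cv, rng)
        _, weights, p_bead = _mixture(profiles, cond_i, tissue_mass_mg,
                                      beads_added)
        n_bead = max(1, int(rng.poisson(n_events * p_bead)))
        raw = {
            pop: int(rng.poisson(n_events * (1 - p_bead) * live_frac * w))
            for pop, w in sorted(weights.items())
        }
        factor = beads_added / n_bead / tissue_mass_mg
        out.append(PopulationCounts(
            sample_id=f"{condition.name}_m{i + 1}",
            condition=condition.name,
            cells_per_mg={p: r * factor for p, r in raw.items()},
            raw_counts=raw,
            bead_events=n_bead,
            beads_added=float(beads_added),
            tissue_mass_mg=float(tissue_mass_mg),
        ))
    return out
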