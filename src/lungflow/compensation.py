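"""Spillover estimation from single-stain beads and linear compensation.

Per channel, beads are split into negative and positive clusters by a 1-D
two-class partition (minimum within-class variance on arcsinh-transformed
intensities).  If the positive cluster is multimodal — pooled antibodies
with unequal bead affinities — the mode with the HIGHER intensity is used
for the coefficients.  Coefficients are ratios of median differences, which
is robust to the heavy tails the simulator produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .events import EventTable
from .panel import FLUOR_CHANNELS, VIABILITY_CHANNEL

__all__ = [
    "CompensationError",
    "SpilloverEstimate",
    "estimate_spillover",
    "apply_compensation",
    "save_spillover",
    "load_spillover",
    "arcsinh",
    "DEFAULT_COFACTOR",
]

DEFAULT_COFACTOR = 150.0


class CompensationError(ValueError):
    pass


def arcsinh(x, cofactor: float = DEFAULT_COFACTOR):
    """Display transform used for clustering and gating."""
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


@dataclass
class SpilloverEstimate:
    """Estimated spillover matrix plus per-channel diagnostics."""

    matrix: pd.DataFrame
    diagnostics: dict[str, dict] = field(default_factory=dict)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)


def _variance_split(values: np.ndarray) -> float:
    """Threshold minimizing total within-class variance (1-D 2-means)."""
    x = np.sort(values)
    n = x.size
    if n < 4:
        raise CompensationError("too few events to split")
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # size of lower class
    lower_var = csq[:-1] - csum[:-1] ** 2 / k
    upper_var = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - k)
    total = lower_var + upper_var
    # avoid degenerate splits at the extreme tails
    lo = max(1, n // 100)
    best = int(np.argmin(total[lo - 1 : n - lo]) + lo - 1)
    return 0.5 * (x[best] + x[best + 1])


def _higher_peak_mask(pos_t: np.ndarray) -> tuple[np.ndarray, int]:
    """Detect multimodality of the positive cluster by Silverman-bandwidth
    kernel density smoothing; return a mask selecting the highest-intensity
    mode and the number of modes found."""
    if pos_t.size < 10 or np.ptp(pos_t) < 1e-9:
        return np.ones(pos_t.size, bool), 1
    kde = gaussian_kde(pos_t, bw_method="silverman")
    grid = np.linspace(pos_t.min(), pos_t.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    peaks = peaks[dens[peaks] >= 0.15 * dens.max()]
    # a genuine second mode needs a clear valley, not a density ripple
    keep_peaks = [int(peaks[0])] if peaks.size else []
    for p in peaks[1:]:
        prev = keep_peaks[-1]
        valley_d = dens[prev:p + 1].min()
        if valley_d < 0.7 * min(dens[prev], dens[p]):
            keep_peaks.append(int(p))
        elif dens[p] > dens[prev]:
            keep_peaks[-1] = int(p)
    if len(keep_peaks) <= 1:
        return np.ones(pos_t.size, bool), max(1, len(keep_peaks))
    top, prev = keep_peaks[-1], keep_peaks[-2]
    valley = grid[prev + np.argmin(dens[prev:top + 1])]
    return pos_t > valley, len(keep_peaks)


def estimate_spillover(
    beads: dict[str, EventTable],
    channels: tuple[str, ...] = FLUOR_CHANNELS,
    cofactor: float = DEFAULT_COFACTOR,
) -> SpilloverEstimate:
    """Estimate the spillover matrix from single-stain bead samples.

    ``beads`` maps stained channel -> bead events.  Channels without a bead
    sample (by default only the viability detector) get an identity row.
    Coefficient into channel j = (median_j(pos) - median_j(neg)) /
    (median_i(pos) - median_i(neg)), rows normalized to unit diagonal.
    """
    n = len(channels)
    mat = np.eye(n)
    diagnostics: dict[str, dict] = {}
    for channel, table in beads.items():
        if channel not in channels:
            raise CompensationError(f"unknown bead channel {channel!r}")
        i = channels.index(channel)
        values = table.data[channel].to_numpy(float)
        t = arcsinh(values, cofactor)
        cut = _variance_split(t)
        pos = t > cut
        if pos.sum() < 10 or (~pos).sum() < 10:
            raise CompensationError(
                f"no separable positive bead population in {channel}"
            )
        keep, n_modes = _higher_peak_mask(t[pos])
        pos_idx = np.flatnonzero(pos)[keep]
        neg_idx = np.flatnonzero(~pos)
        med_pos = table.data.iloc[pos_idx][list(channels)].median().to_numpy()
        med_neg = table.data.iloc[neg_idx][list(channels)].median().to_numpy()
        denom = med_pos[i] - med_neg[i]
        if denom <= 0 or arcsinh(med_pos[i], cofactor) - arcsinh(
            med_neg[i], cofactor
        ) < 0.5:
            raise CompensationError(
                f"no separable positive bead population in {channel}"
            )
        row = (med_pos - med_neg) / denom
        row[i] = 1.0
        row = np.clip(row, 0.0, None)
        mat[i] = row
        diagnostics[channel] = {
            "positive_peaks": n_modes,
            "chosen_peak_median": float(med_pos[i]),
            "negative_median": float(med_neg[i]),
            "n_positive_used": int(pos_idx.size),
        }
    if np.linalg.cond(mat) > 1e8:
        raise CompensationError("estimated spillover matrix is singular")
    frame = pd.DataFrame(mat, index=list(channels), columns=list(channels))
    return SpilloverEstimate(matrix=frame, diagnostics=diagnostics)


def _as_matrix(spill, channels: list[str]) -> np.ndarray:
    if isinstance(spill, SpilloverEstimate):
        spill = spill.matrix
    if isinstance(spill, pd.DataFrame):
        missing = [c for c in channels if c not in spill.columns]
        if missing:
            raise CompensationError(f"spillover matrix lacks channels {missing}")
        return spill.loc[channels, channels].to_numpy(float)
    m = np.asarray(getattr(spill, "matrix", spill), dtype=float)
    if m.shape != (len(channels), len(channels)):
        raise CompensationError(
            f"spillover matrix shape {m.shape} does not match "
            f"{len(channels)} event channels"
        )
    return m


def apply_compensation(events: EventTable, spill) -> EventTable:
    """Unmix observed intensities: fluorescence columns are replaced by
    observed @ inverse(spillover).  Scatter and label columns are untouched;
    negative values are permitted after compensation.  Not idempotent for a
    non-identity matrix."""
    channels = events.fluor_channels
    m = _as_matrix(spill, channels)
    if np.linalg.cond(m) > 1e8:
        raise CompensationError("spillover matrix is singular")
    inv = np.linalg.inv(m)
    out = events.copy()
    comp = events.data[channels].to_numpy(float) @ inv
    out.data[channels] = comp
    out.metadata["compensated"] = True
    return out


def save_spillover(matrix, path) -> None:
    """Write a spillover matrix as CSV with channel-name header row/column."""
    if isinstance(matrix, SpilloverEstimate):
        matrix = matrix.matrix
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix), index=list(FLUOR_CHANNELS),
                              columns=list(FLUOR_CHANNELS))
    matrix.to_csv(path, float_format="%.10g", index_label="channel")


def load_spillover(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "channel"
    if list(df.index) != list(df.columns):
        raise CompensationError("spillover CSV row/column channels differ")
    return df
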