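"""Flow-cytometry event processing.

Event tables are plain pandas DataFrames with an ``acquisition_time`` column
(seconds) and named fluorescence channel columns (``indo_405``, ``indo_485``,
``irfp713``, ``mtagbfp``, stain channels ...).  The pipeline is: gate T
cell / presenting-cell conjugates on two marker channels, compute the
ratiometric Indo-1 calcium readout per event, bin into 2-s time bins, and hand
the mean trace to the gamma-survival fitting machinery.  ppERK-style
per-timepoint samples are summarized by background-subtracted medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics_fit import DecayTrace, time_to_half_max

__all__ = [
    "DensityMatrix",
    "gate_conjugates",
    "indo1_ratio",
    "density_timecourse",
    "mean_trace",
    "median_timecourse",
]

TIME_COL = "acquisition_time"


@dataclass
class DensityMatrix:
    """Per-time-bin histograms of the Indo-1 ratio, stacked as columns."""

    time_bin_edges: np.ndarray  # (n_t + 1,)
    ratio_bin_edges: np.ndarray  # (n_r + 1,)
    counts: np.ndarray  # (n_r, n_t)
    empty_time_bins: np.ndarray  # boolean, (n_t,)

    @property
    def density(self) -> np.ndarray:
        """Column-normalized density (each non-empty time bin sums to 1)."""
        totals = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)


def gate_conjugates(events: pd.DataFrame, thresholds: dict[str, float]) -> tuple[pd.DataFrame, float]:
    """Retain events above every marker threshold (double-positive gating).

    Returns the gated table and the gated fraction.  Gating is idempotent.
    """
    for channel in thresholds:
        if channel not in events.columns:
            raise KeyError(f"marker channel {channel!r} missing from event table")
    mask = np.ones(len(events), dtype=bool)
    for channel, thr in thresholds.items():
        mask &= events[channel].to_numpy() >= thr
    fraction = float(mask.mean()) if len(events) else 0.0
    return events.loc[mask].reset_index(drop=True), fraction


def indo1_ratio(
    events: pd.DataFrame,
    backgrounds: tuple[float, float] = (0.0, 0.0),
    channels: tuple[str, str] = ("indo_405", "indo_485"),
) -> tuple[pd.Series, pd.Series, int]:
    """Per-event Indo-1 ratio after per-channel background subtraction.

    ratio = (indo_405 - bg405) / (indo_485 - bg485).  Events whose
    background-subtracted denominator is non-positive are dropped and counted
    (never silently discarded).  Returns (ratios, times, n_dropped).
    """
    ch_num, ch_den = channels
    for channel in (ch_num, ch_den):
        if channel not in events.columns:
            raise KeyError(f"Indo channel {channel!r} missing from event table")
    num = events[ch_num].to_numpy(dtype=float) - backgrounds[0]
    den = events[ch_den].to_numpy(dtype=float) - backgrounds[1]
    keep = den > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all events have non-positive background-subtracted denominator")
    ratios = pd.Series(num[keep] / den[keep], name="indo1_ratio")
    times = pd.Series(events.loc[keep, TIME_COL].to_numpy(dtype=float), name=TIME_COL)
    return ratios, times, n_dropped


def density_timecourse(
    ratios: pd.Series,
    times: pd.Series,
    time_bin_width: float = 2.0,
    n_ratio_bins: int = 100,
) -> DensityMatrix:
    """2-s x 100-bin density matrix of the ratio time course.

    The ratio axis spans the robust 1st-99th percentile range; empty time
    bins are flagged, not interpolated.
    """
    r = np.asarray(ratios, dtype=float)
    t = np.asarray(times, dtype=float)
    lo, hi = np.percentile(r, [1, 99])
    if hi <= lo:
        lo, hi = r.min(), r.min() + 1.0
    ratio_edges = np.linspace(lo, hi, n_ratio_bins + 1)
    t_end = np.ceil(t.max() / time_bin_width) * time_bin_width
    time_edges = np.arange(0.0, t_end + time_bin_width, time_bin_width)
    counts, _, _ = np.histogram2d(np.clip(r, lo, hi), t, bins=[ratio_edges, time_edges])
    empty = counts.sum(axis=0) == 0
    return DensityMatrix(time_bin_edges=time_edges, ratio_bin_edges=ratio_edges, counts=counts, empty_time_bins=empty)


def mean_trace(ratios: pd.Series, times: pd.Series, bin_width: float = 2.0, t_zero: float = 0.0) -> DecayTrace:
    """Per-time-bin mean ratio as a :class:`DecayTrace` (bin centers as times).

    Empty bins are dropped and listed in the trace metadata.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    t_end = np.ceil(t.max() / bin_width) * bin_width
    edges = np.arange(0.0, t_end + bin_width, bin_width)
    idx = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=r, minlength=len(edges) - 1)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    means = sums[nonempty] / counts[nonempty]
    return DecayTrace(
        times=centers[nonempty],
        values=means,
        t_zero=t_zero,
        unit="s",
        meta={"empty_bins": centers[~nonempty].tolist(), "bin_width": bin_width},
    )


def median_timecourse(
    samples: dict[float, pd.DataFrame],
    channel: str,
    background: float = 0.0,
    t_zero: float | None = None,
) -> pd.Series:
    """Background-subtracted median stain intensity per timepoint.

    ``samples`` maps timepoint (minutes) to a gated event table.  Empty
    samples are flagged as NaN (missing points), never imputed.  The
    post-illumination half-life of the series is the time for the median to
    fall to 50% of its maximum (see :func:`half_life_from_medians`).
    """
    out = {}
    for tp in sorted(samples):
        table = samples[tp]
        if len(table) == 0:
            out[tp] = np.nan
            continue
        if channel not in table.columns:
            raise KeyError(f"stain channel {channel!r} missing at timepoint {tp}")
        out[tp] = max(float(table[channel].median()) - background, 0.0)
    series = pd.Series(out, name=channel)
    series.index.name = "time_min"
    series.attrs["t_zero"] = t_zero
    return series


def half_life_from_medians(medians: pd.Series, t_zero: float) -> float:
    """Time for the post-illumination median to fall to 50% of its maximum."""
    clean = medians.dropna()
    return time_to_half_max(clean.index.values.astype(float), clean.values, t_start=t_zero)
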