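"""Cellular assay quantification: tail accumulation and organelle redistribution.

Two readouts of motor-driven transport in cells are computed: the
background-subtracted ratio of cell-tail to perinuclear motor intensity, and
the time course of the periphery/perinuclear ratio of an organelle marker
from center-to-tip linescans binned into 100 equal-width bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import LinescanSeries

__all__ = [
    "IntensityTriple",
    "tail_ratio",
    "tail_ratio_table",
    "bin_linescan",
    "bin_linescan_series",
    "periphery_ratio_timecourse",
]


@dataclass(frozen=True)
class IntensityTriple:
    """Mean intensities of the cell-tail tip, perinuclear area and background."""

    tail_mean: float
    perinuclear_mean: float
    background_mean: float

    @property
    def flagged(self) -> bool:
        """True when the background exceeds a region mean (suspect measurement)."""
        return (self.background_mean > self.tail_mean
                or self.background_mean > self.perinuclear_mean)


def tail_ratio(triple: IntensityTriple) -> float:
    """Background-subtracted tail/perinuclear intensity ratio.

    Raises when the perinuclear signal does not exceed the background (the
    ratio is undefined and the cell must be excluded).
    """
    denom = triple.perinuclear_mean - triple.background_mean
    if denom <= 0:
        raise ValueError("perinuclear intensity does not exceed background; cell excluded")
    return (triple.tail_mean - triple.background_mean) / denom


def tail_ratio_table(triples: np.ndarray | list) -> pd.DataFrame:
    """Per-cell tail ratios from (tail, perinuclear, background) rows.

    Cells with a non-positive background-subtracted perinuclear signal are
    flagged and excluded (ratio NaN) rather than silently dropped.
    """
    rows = []
    for i, (tail, peri, bg) in enumerate(np.asarray(triples, dtype=float)):
        t = IntensityTriple(tail, peri, bg)
        try:
            r = tail_ratio(t)
            excluded = False
        except ValueError:
            r, excluded = math.nan, True
        rows.append({"cell_id": i, "tail": tail, "perinuclear": peri,
                     "background": bg, "ratio": r, "excluded": excluded})
    return pd.DataFrame(rows)


def bin_linescan(positions: np.ndarray, intensities: np.ndarray,
                 n_bins: int = 100) -> pd.DataFrame:
    """Bin one normalised linescan profile into equal-width position bins.

    Bins are half-open [i/n, (i+1)/n) with the final bin closed at 1.
    Returns per-bin mean +/- SEM and count; empty bins appear with NaN mean.
    """
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if np.any((positions < 0) | (positions > 1)):
        raise ValueError("normalised positions must lie in [0, 1]")
    idx = np.minimum((positions * n_bins).astype(int), n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    total = np.bincount(idx, weights=intensities, minlength=n_bins)
    total2 = np.bincount(idx, weights=intensities ** 2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
        var1 = np.where(count > 1,
                        np.maximum(total2 - count * mean ** 2, 0.0) / np.maximum(count - 1, 1),
                        np.nan)
        sem = np.sqrt(var1 / count)
    return pd.DataFrame({
        "bin_index": np.arange(n_bins),
        "bin_center": (np.arange(n_bins) + 0.5) / n_bins,
        "mean": mean,
        "sem": sem,
        "n": count,
    })


def bin_linescan_series(series: list[LinescanSeries], n_bins: int = 100) -> pd.DataFrame:
    """Tidy binned profiles for many cells and timepoints."""
    frames = []
    for s in series:
        for t, pos, inten in zip(s.times, s.positions, s.intensities):
            df = bin_linescan(pos, inten, n_bins=n_bins)
            df.insert(0, "time_min", t)
            df.insert(0, "cell_id", s.cell_id)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def periphery_ratio_timecourse(binned: pd.DataFrame,
                               periphery: tuple[float, float] = (0.8, 1.0),
                               perinuclear: tuple[float, float] = (0.0, 0.2),
                               ) -> pd.DataFrame:
    """Periphery/perinuclear intensity ratio over time, aggregated over cells.

    Per cell and timepoint the mean binned intensity over the periphery
    window (0.8-1.0 by default) is divided by the mean over the perinuclear
    window (0.0-0.2); ratios are then averaged across cells (mean +/- SEM).
    Timepoints for which a cell has an empty window are skipped for that
    cell with a warning.
    """
    import warnings

    def window_mean(df: pd.DataFrame, lo: float, hi: float) -> float:
        sel = df[(df.bin_center >= lo) & (df.bin_center <= hi) & df["mean"].notna()]
        if sel.empty:
            return math.nan
        return float(sel["mean"].mean())

    per_cell = []
    for (cell, t), df in binned.groupby(["cell_id", "time_min"]):
        outer = window_mean(df, *periphery)
        inner = window_mean(df, *perinuclear)
        if math.isnan(outer) or math.isnan(inner) or inner == 0:
            warnings.warn(f"cell {cell} t={t}: empty intensity window, skipped")
            continue
        per_cell.append({"cell_id": cell, "time_min": t, "ratio": outer / inner})
    if not per_cell:
        raise ValueError("no timepoint has populated periphery and perinuclear windows")
    df = pd.DataFrame(per_cell)
    out = df.groupby("time_min")["ratio"].agg(
        ratio_mean="mean",
        sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else math.nan,
        n_cells="size",
    ).reset_index()
    return out
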