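"""Kymograph track segmentation and motility statistics.

Tracks are hand-traced polylines of (frame, x_px) vertices.  Each
inter-vertex segment is labelled by its plus-end-directed speed against a
25 nm/s threshold (run toward plus end, run toward minus end, or pause), and
tracks are classified as static, diffusing or processive.  Only processive
(plus-end-directed) tracks contribute dwell time, run length and
pause-corrected speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import KymoCalibration, TrackROI

__all__ = [
    "Phase",
    "TrackStats",
    "segment_track",
    "classify_track",
    "track_statistics",
    "analyze_tracks",
    "landing_rate",
    "plus_end_decoration",
]

#: speed threshold separating translocation from pausing, nm/s
PAUSE_SPEED = 25.0
#: minimum total run length of a non-static motor, nm
STATIC_RUN_LENGTH = 500.0
#: excursion (2 px at 162 nm/px) defining bidirectional/diffusive motion, nm
BIDIRECTIONAL_EXCURSION = 324.0


@dataclass(frozen=True)
class Phase:
    """A maximal constant-behaviour stretch of a track."""

    start_s: float
    end_s: float
    displacement_nm: float  # plus-end-directed displacement
    speed_nm_s: float
    label: str  # run_plus / run_minus / pause

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TrackStats:
    """Per-track motility statistics (processive tracks only)."""

    track_class: str
    dwell_time_s: float
    run_length_nm: float
    pause_time_s: float
    pause_corrected_speed_nm_s: float
    reached_plus_end: bool = False
    censored: bool = False


def _plus_positions(roi: TrackROI, cal: KymoCalibration) -> tuple[np.ndarray, np.ndarray]:
    """Times (s) and plus-end-directed positions (nm) of the vertices."""
    t = roi.vertices[:, 0] * cal.s_per_frame
    x = roi.vertices[:, 1] * cal.nm_per_pixel * cal.plus_end_direction
    return t, x


def segment_track(roi: TrackROI, cal: KymoCalibration = KymoCalibration()) -> list[Phase]:
    """Label inter-vertex segments and merge adjacent same-label segments.

    A segment is a run toward the plus (minus) end if its plus-end-directed
    speed exceeds +25 nm/s (falls below -25 nm/s) and a pause otherwise.
    """
    t, x = _plus_positions(roi, cal)
    if len(t) < 2:
        raise ValueError("cannot segment a single-vertex track")
    phases: list[Phase] = []
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        v = (x[i + 1] - x[i]) / dt
        if v > PAUSE_SPEED:
            label = "run_plus"
        elif v < -PAUSE_SPEED:
            label = "run_minus"
        else:
            label = "pause"
        if phases and phases[-1].label == label:
            prev = phases[-1]
            disp = prev.displacement_nm + (x[i + 1] - x[i])
            dur = t[i + 1] - prev.start_s
            phases[-1] = Phase(prev.start_s, t[i + 1], disp, disp / dur, label)
        else:
            phases.append(Phase(t[i], t[i + 1], x[i + 1] - x[i], v, label))
    return phases


def _excursions(x: np.ndarray) -> tuple[float, float]:
    """Largest plus-ward run-up and minus-ward drawdown of a position series."""
    runup = float(np.max(x - np.minimum.accumulate(x)))
    drawdown = float(np.max(np.maximum.accumulate(x) - x))
    return runup, drawdown


def _run_length(phases: list[Phase]) -> float:
    """Total distance covered during run phases, nm."""
    return float(sum(abs(p.displacement_nm) for p in phases
                     if p.label in ("run_plus", "run_minus")))


def classify_track(roi: TrackROI, phases: list[Phase],
                   cal: KymoCalibration = KymoCalibration(),
                   speed_definition: str = "path",
                   excursion_mode: str = "single") -> str:
    """Classify a segmented track as static, diffusing or processive.

    Rules, applied in order: a motor whose average speed is below 25 nm/s or
    whose total run length is below 500 nm is static; a non-static motor
    that moved bidirectionally by at least 324 nm (2 px) in each direction,
    or whose net motion is toward the minus end, is diffusing; the rest are
    processive (plus-end-directed).

    ``speed_definition``: "path" (default) uses total distance covered per
    unit time, "net" uses the net plus-ward displacement per unit time.
    ``excursion_mode``: "single" (default) requires one >=324-nm excursion in
    each direction; "cumulative" sums backward and forward travel instead.
    """
    t, x = _plus_positions(roi, cal)
    total_time = t[-1] - t[0]
    run_length = _run_length(phases)
    net = x[-1] - x[0]
    if speed_definition == "path":
        avg_speed = float(np.sum(np.abs(np.diff(x)))) / total_time
    elif speed_definition == "net":
        avg_speed = abs(net) / total_time
    else:
        raise ValueError("speed_definition must be 'path' or 'net'")
    if avg_speed < PAUSE_SPEED or run_length < STATIC_RUN_LENGTH:
        return "static"
    if excursion_mode == "single":
        plus_exc, minus_exc = _excursions(x)
    elif excursion_mode == "cumulative":
        dx = np.diff(x)
        plus_exc = float(dx[dx > 0].sum())
        minus_exc = float(-dx[dx < 0].sum())
    else:
        raise ValueError("excursion_mode must be 'single' or 'cumulative'")
    if (plus_exc >= BIDIRECTIONAL_EXCURSION and minus_exc >= BIDIRECTIONAL_EXCURSION) or net < 0:
        return "diffusing"
    return "processive"


def track_statistics(roi: TrackROI, phases: list[Phase],
                     cal: KymoCalibration = KymoCalibration(),
                     track_class: str = "processive",
                     n_frames: int | None = None,
                     reached_plus_end: bool = False) -> TrackStats:
    """Dwell time, run length, pause time and pause-corrected speed.

    Dwell time is the total time on the microtubule (until the plus end or
    the end of the recording); run length is the total distance covered; the
    pause-corrected speed divides run length by dwell time minus pause time.
    Tracks lasting to the final frame are flagged censored.
    """
    t, _ = _plus_positions(roi, cal)
    dwell = float(t[-1] - t[0])
    run_length = _run_length(phases)
    pause = float(sum(p.duration_s for p in phases if p.label == "pause"))
    moving = dwell - pause
    if moving > 0:
        speed = run_length / moving
    else:
        speed = math.nan  # flagged: zero moving time
    censored = n_frames is not None and roi.vertices[-1, 0] >= n_frames - 1
    return TrackStats(
        track_class=track_class,
        dwell_time_s=dwell,
        run_length_nm=run_length,
        pause_time_s=pause,
        pause_corrected_speed_nm_s=speed,
        reached_plus_end=reached_plus_end,
        censored=censored,
    )


def analyze_tracks(tracks: list[TrackROI], cal: KymoCalibration = KymoCalibration(),
                   speed_definition: str = "path",
                   n_frames: int | None = None) -> pd.DataFrame:
    """Segment, classify and summarise a set of tracks into a tidy table."""
    rows = []
    for i, roi in enumerate(tracks):
        phases = segment_track(roi, cal)
        cls = classify_track(roi, phases, cal, speed_definition=speed_definition)
        stats = track_statistics(roi, phases, cal, track_class=cls, n_frames=n_frames)
        rows.append({
            "track_id": i,
            "mt_id": roi.mt_id,
            "day": roi.day,
            "true_class": roi.label,
            "class": cls,
            "dwell_time_s": stats.dwell_time_s,
            "run_length_nm": stats.run_length_nm,
            "pause_time_s": stats.pause_time_s,
            "pause_corrected_speed_nm_s": stats.pause_corrected_speed_nm_s,
            "censored": stats.censored,
        })
    return pd.DataFrame(rows)


def landing_rate(tracks: list[TrackROI], mt_lengths_um: dict[int, float],
                 observation_time_s: float,
                 motor_concentration_nM: float | None = None) -> pd.DataFrame:
    """New-track appearances per um of microtubule per second.

    ``mt_lengths_um`` maps microtubule id to its length; every microtubule in
    the map is reported, including those without landings.  If a motor
    concentration is given the rate is additionally normalised per nM.
    """
    counts: dict[int, int] = {mt: 0 for mt in mt_lengths_um}
    days: dict[int, str | None] = {mt: None for mt in mt_lengths_um}
    for roi in tracks:
        if roi.mt_id not in counts:
            raise KeyError(f"track references unknown microtubule {roi.mt_id}")
        counts[roi.mt_id] += 1
        days[roi.mt_id] = roi.day
    rows = []
    for mt, length in mt_lengths_um.items():
        if length <= 0:
            raise ValueError(f"microtubule {mt} has non-positive length")
        rate = counts[mt] / (length * observation_time_s)
        row = {"mt_id": mt, "day": days[mt], "n_landings": counts[mt],
               "rate_per_um_per_s": rate}
        if motor_concentration_nM:
            row["rate_per_um_per_s_per_nM"] = rate / motor_concentration_nM
        rows.append(row)
    return pd.DataFrame(rows)


def plus_end_decoration(decorated: list[bool] | np.ndarray,
                        alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Fraction of microtubules with a motor-decorated plus end, with CI.

    Uses the exact (Clopper-Pearson) binomial interval.
    """
    from statsmodels.stats.proportion import proportion_confint

    decorated = np.asarray(decorated, dtype=bool)
    if decorated.size == 0:
        raise ValueError("empty microtubule set")
    k = int(decorated.sum())
    n = decorated.size
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return k / n, (float(lo), float(hi))
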