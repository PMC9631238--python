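"""Force-event analysis of trap traces.

Implements the run-event pipeline: baseline correction, conversion of bead
displacement to force, detection of force-generating events (>=0.5 pN for
>=200 ms on a 100-ms-smoothed trace), automated stall scoring (plateaus held
within one 8-nm step before a >=24-nm backslip or a return to the trap
center, >=10 ms), force-velocity binning, microtubule-encounter counting,
restart-time extraction and exponential-mixture fitting of restart times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .simulate import TrapTrace

__all__ = [
    "AnalysisConfig",
    "ForceEvent",
    "Stall",
    "TriexpFit",
    "ReassignedCounts",
    "correct_baseline",
    "force_series",
    "detect_events",
    "detect_stalls",
    "stall_force_by_min_time",
    "count_events_per_encounter",
    "force_velocity",
    "extract_restart_times",
    "fit_exponential_mixture",
    "fit_triexponential",
    "fit_triexponential_cdf",
    "reassign_fast_detachments",
    "analyze_trace",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants of the run-event analysis.

    Defaults mirror the published pipeline: events above 0.5 pN lasting more
    than 200 ms on a 2000-point (100 ms at 20 kHz) smoothed trace; the
    force-velocity relation from 200-point (10 ms) smoothed data in 0.5-pN
    bins; stalls of at least 10 ms holding within one 8-nm step; backslips of
    at least 24 nm; detachment when the bead returns to within 1.2 pN of the
    trap center; restarts within 100 ms merged into the same MT encounter.
    """

    event_force_threshold: float = 0.5
    event_min_duration: float = 0.200
    event_smooth_window: int = 2000
    fv_smooth_window: int = 200
    fv_bin_width: float = 0.5
    stall_min_duration: float = 0.010
    stall_fluctuation_limit: float = 8.0
    backslip_min_distance: float = 24.0
    detach_force_cutoff: float = 1.2
    encounter_restart_window: float = 0.1
    baseline_window_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("event_force_threshold", "event_min_duration",
                     "fv_bin_width", "stall_min_duration",
                     "stall_fluctuation_limit", "backslip_min_distance",
                     "detach_force_cutoff", "encounter_restart_window",
                     "baseline_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.event_smooth_window < 1 or self.fv_smooth_window < 1:
            raise ValueError("smoothing windows must be at least 1 sample")


@dataclass
class Stall:
    """A force plateau held within one 8-nm step for at least 10 ms."""

    start: int
    end: int  # half-open sample interval
    mean_force: float
    duration: float


@dataclass
class ForceEvent:
    """A supra-threshold force excursion of at least the minimum duration."""

    start: int
    end: int  # half-open
    peak_force: float
    duration: float
    stalls: list[Stall] = field(default_factory=list)
    end_reason: str = "below_threshold"  # or detachment / record_end


# --------------------------------------------------------------------------- #
# baseline and force
# --------------------------------------------------------------------------- #

def force_series(trace: TrapTrace) -> np.ndarray:
    """Force in pN: trap stiffness times bead displacement.

    Positive force corresponds to bead displacement in the motor's travel
    direction (away from the trap center).
    """
    if trace.trap_stiffness is None or trace.trap_stiffness <= 0:
        raise ValueError("trace is missing a positive trap stiffness")
    return trace.trap_stiffness * trace.position


def correct_baseline(trace: TrapTrace, config: AnalysisConfig = AnalysisConfig()) -> TrapTrace:
    """Remove slow baseline drift estimated from sub-threshold samples only.

    A running median over ``baseline_window_s`` windows (hopped every fifth
    of a window) of the samples whose smoothed force lies below the event
    threshold is interpolated across the trace and subtracted.  Windows fully
    occupied by events inherit the interpolated baseline of their
    neighbours.  The estimated baseline summary is stored in
    ``metadata['baseline_nm']`` for audit.
    """
    fs = trace.sample_rate
    n = trace.n_samples
    win = int(round(config.baseline_window_s * fs))
    if n < win:
        raise ValueError("trace shorter than the baseline window")
    force = force_series(trace)
    smooth_w = min(config.event_smooth_window, n)
    smoothed = uniform_filter1d(force, size=smooth_w, mode="nearest")
    quiet = smoothed < config.event_force_threshold
    if not np.any(quiet):
        raise ValueError("no sub-threshold samples: baseline has no support")

    hop = max(1, win // 5)
    centers, medians = [], []
    for start in range(0, n, hop):
        lo = max(0, start - win // 2)
        hi = min(n, start + win // 2)
        seg = trace.position[lo:hi][quiet[lo:hi]]
        if seg.size:
            centers.append(start)
            medians.append(float(np.median(seg)))
    baseline = np.interp(np.arange(n), centers, medians)
    meta = dict(trace.metadata)
    meta["baseline_nm"] = {"centers": centers, "medians": medians}
    return TrapTrace(
        position=trace.position - baseline,
        sample_rate=fs,
        trap_stiffness=trace.trap_stiffness,
        ground_truth=trace.ground_truth,
        metadata=meta,
    )


# --------------------------------------------------------------------------- #
# event and stall detection
# --------------------------------------------------------------------------- #

def detect_events(force: np.ndarray, config: AnalysisConfig,
                  sample_rate: float) -> list[ForceEvent]:
    """Find force-generating events on the smoothed force series.

    Contiguous intervals of the boxcar-smoothed force above
    ``event_force_threshold`` become events if they last at least
    ``event_min_duration``; the peak force is the maximum of the smoothed
    series inside the event.  Events are non-overlapping, ordered, with
    half-open [start, end) sample indices.
    """
    force = np.asarray(force, dtype=float)
    if config.event_smooth_window > force.size:
        raise ValueError("smoothing window longer than the trace")
    smoothed = uniform_filter1d(force, size=config.event_smooth_window, mode="nearest")
    above = smoothed >= config.event_force_threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(force.size)
    min_samples = int(round(config.event_min_duration * sample_rate))
    events = []
    for s, e in zip(starts, ends):
        if e - s < max(min_samples, 1) or e - s == min_samples:
            # "lasting more than" the minimum: strictly longer intervals only
            continue
        events.append(ForceEvent(
            start=int(s), end=int(e),
            peak_force=float(np.max(smoothed[s:e])),
            duration=(e - s) / sample_rate,
            end_reason="record_end" if e == force.size else "below_threshold",
        ))
    return events


def _release_indices(disp: np.ndarray, min_backslip_nm: float) -> np.ndarray:
    """Indices where a forward excursion releases.

    A release is the last running-maximum sample before the displacement
    falls by at least ``min_backslip_nm`` below its running maximum; the
    terminal running maximum of the interval is always included (the bead
    ultimately returns toward the trap center at the event end).
    """
    runmax = np.maximum.accumulate(disp)
    dd = runmax - disp
    at_max = np.flatnonzero(dd <= 1e-9)
    if at_max.size == 0:
        return np.array([], dtype=int)
    crossings = np.flatnonzero((dd[1:] >= min_backslip_nm) & (dd[:-1] < min_backslip_nm)) + 1
    peaks = at_max[np.searchsorted(at_max, crossings) - 1] if crossings.size else np.array([], dtype=int)
    peaks = np.unique(np.concatenate([peaks, [at_max[-1]]]))
    return peaks.astype(int)


def detect_stalls(event: ForceEvent, force: np.ndarray, config: AnalysisConfig,
                  sample_rate: float, trap_stiffness: float,
                  smoothed: np.ndarray | None = None) -> list[Stall]:
    """Score stalls within one event.

    For every release point (a >=24-nm backslip or the terminal return
    toward the trap center) the maximal preceding interval whose force
    excursion stays within ``stall_fluctuation_limit`` (8 nm) times the trap
    stiffness is taken; intervals shorter than ``stall_min_duration`` are
    dropped.  The mean force over the interval is the stall force.
    """
    if smoothed is None:
        smoothed = uniform_filter1d(np.asarray(force, dtype=float),
                                    size=min(config.event_smooth_window, len(force)),
                                    mode="nearest")
    seg = smoothed[event.start:event.end]
    disp = seg / trap_stiffness
    tol = config.stall_fluctuation_limit  # nm
    min_samples = max(1, int(round(config.stall_min_duration * sample_rate)))
    stalls: list[Stall] = []
    for p in _release_indices(disp, config.backslip_min_distance):
        hi = p + 1
        lo = p
        cur_min = disp[p]
        cur_max = disp[p]
        while lo > 0:
            v = disp[lo - 1]
            new_min = min(cur_min, v)
            new_max = max(cur_max, v)
            if new_max - new_min > tol:
                break
            cur_min, cur_max = new_min, new_max
            lo -= 1
        if hi - lo >= min_samples:
            stalls.append(Stall(
                start=event.start + lo,
                end=event.start + hi,
                mean_force=float(np.mean(seg[lo:hi])),
                duration=(hi - lo) / sample_rate,
            ))
    # de-duplicate overlapping plateaus from adjacent releases
    out: list[Stall] = []
    for s in sorted(stalls, key=lambda s: s.start):
        if out and s.start < out[-1].end:
            if s.duration > out[-1].duration:
                out[-1] = s
            continue
        out.append(s)
    return out


def stall_force_by_min_time(stalls: list[Stall],
                            min_times: list[float]) -> pd.DataFrame:
    """Mean +/- SEM stall force for stalls lasting at least each cutoff."""
    rows = []
    forces = np.array([s.mean_force for s in stalls])
    durations = np.array([s.duration for s in stalls])
    for mt in min_times:
        sel = forces[durations >= mt]
        rows.append({
            "min_time_s": mt,
            "mean_force_pN": float(sel.mean()) if sel.size else math.nan,
            "sem_pN": float(sel.std(ddof=1) / math.sqrt(sel.size)) if sel.size > 1 else math.nan,
            "n": int(sel.size),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# encounters and restart kinetics
# --------------------------------------------------------------------------- #

def count_events_per_encounter(events: list[ForceEvent], steps,
                               config: AnalysisConfig,
                               sample_rate: float) -> list[int]:
    """Forward excursions per microtubule encounter.

    Each event contributes one excursion per >=24-nm cumulative backslip
    (from the classified step list) plus its terminal release.  Events whose
    gap to the next event is within ``encounter_restart_window`` belong to
    the same encounter ("restarted immediately": a long backslip, not a
    detachment).
    """
    from .steps import backslip_distances

    if not events:
        return []
    big = [(t, d) for d, t in backslip_distances(steps)
           if d >= config.backslip_min_distance]
    counts = []
    current = 0
    for i, ev in enumerate(events):
        t0, t1 = ev.start / sample_rate, ev.end / sample_rate
        n_big = sum(1 for t, _ in big if t0 <= t < t1)
        current += n_big + 1
        last = i == len(events) - 1
        gap = math.inf if last else (events[i + 1].start - ev.end) / sample_rate
        if last or gap > config.encounter_restart_window or ev.end_reason == "record_end":
            counts.append(current)
            current = 0
    return counts


def extract_restart_times(events: list[ForceEvent], config: AnalysisConfig,
                          sample_rate: float) -> list[float]:
    """Lags between the end of a detachment-terminated event and the next event."""
    lags = []
    for prev, nxt in zip(events[:-1], events[1:]):
        if prev.end_reason == "record_end":
            continue
        lags.append((nxt.start - prev.end) / sample_rate)
    return lags


# --------------------------------------------------------------------------- #
# force-velocity
# --------------------------------------------------------------------------- #

def force_velocity(traces: list[TrapTrace],
                   config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Binned force-velocity relation.

    Per run (event), position and force are smoothed with the 10-ms boxcar;
    within every 0.5-pN force bin the velocity is the least-squares slope of
    displacement versus time over the samples of that run falling in the
    bin.  Per-run slopes are then averaged per bin (mean +/- SEM).  Bins
    with fewer than two samples in a run are omitted for that run.
    """
    bw = config.fv_bin_width
    per_bin: dict[int, list[float]] = {}
    found_any = False
    for trace in traces:
        force = force_series(trace)
        events = detect_events(force, config, trace.sample_rate)
        if not events:
            continue
        found_any = True
        w = min(config.fv_smooth_window, trace.n_samples)
        pos_s = uniform_filter1d(trace.position, size=w, mode="nearest")
        force_s = uniform_filter1d(force, size=w, mode="nearest")
        t = trace.times()
        for ev in events:
            f_seg = force_s[ev.start:ev.end]
            bins = np.floor(f_seg / bw).astype(int)
            for b in np.unique(bins):
                sel = bins == b
                if sel.sum() < 2:
                    continue
                ts = t[ev.start:ev.end][sel]
                ys = pos_s[ev.start:ev.end][sel]
                if np.ptp(ts) <= 0:
                    continue
                slope = np.polyfit(ts, ys, 1)[0]
                per_bin.setdefault(int(b), []).append(float(slope))
    if not found_any:
        raise ValueError("no events found in any trace")
    rows = []
    for b in sorted(per_bin):
        v = np.array(per_bin[b])
        rows.append({
            "force_bin_pN": (b + 0.5) * bw,
            "mean_velocity_nm_s": float(v.mean()),
            "sem_nm_s": float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan,
            "n_runs": int(v.size),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# exponential-mixture restart fitting
# --------------------------------------------------------------------------- #

@dataclass
class TriexpFit:
    """Exponential-mixture fit of restart times.

    Components are reported sorted by half-time ascending; ``model_table``
    compares 1/2/3-component fits by BIC and ``preferred_k`` is the argmin.
    """

    fractions: np.ndarray
    half_times: np.ndarray
    log_likelihood: float
    n_components: int
    bic: float
    converged: bool
    model_table: pd.DataFrame | None = None
    preferred_k: int | None = None


def _em_exponential_mixture(times: np.ndarray, k: int, rng: np.random.Generator,
                            n_starts: int = 8, max_iter: int = 1000,
                            tol: float = 1e-10):
    """Maximum-likelihood exponential mixture by EM with multi-start."""
    n = times.size
    best = None
    quantiles = np.quantile(times, (np.arange(k) + 0.5) / k)
    for start in range(n_starts):
        lam = 1.0 / np.maximum(quantiles, 1e-12)
        if start > 0:
            lam = lam * rng.lognormal(0.0, 0.7, size=k)
        a = np.full(k, 1.0 / k)
        prev_ll = -math.inf
        converged = False
        for _ in range(max_iter):
            log_p = np.log(a)[None, :] + np.log(lam)[None, :] - times[:, None] * lam[None, :]
            m = log_p.max(axis=1, keepdims=True)
            p = np.exp(log_p - m)
            norm = p.sum(axis=1, keepdims=True)
            ll = float(np.sum(m.ravel() + np.log(norm.ravel())))
            r = p / norm
            a = r.mean(axis=0)
            lam = r.sum(axis=0) / np.maximum((r * times[:, None]).sum(axis=0), 1e-300)
            if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
                converged = True
                break
            prev_ll = ll
        if best is None or ll > best[0]:
            best = (ll, a.copy(), lam.copy(), converged)
    ll, a, lam, converged = best
    order = np.argsort(1.0 / lam)
    return ll, a[order], lam[order], converged


def fit_exponential_mixture(times, k: int, seed: int = 0,
                            n_starts: int = 8) -> TriexpFit:
    """Fit a k-component exponential mixture to waiting times by MLE (EM)."""
    times = np.asarray(times, dtype=float)
    if times.size < 30:
        raise ValueError("at least 30 waiting times are required")
    if np.any(times <= 0):
        raise ValueError("waiting times must be positive")
    rng = np.random.default_rng(seed)
    ll, a, lam, converged = _em_exponential_mixture(times, k, rng, n_starts)
    n_params = 2 * k - 1
    bic = n_params * math.log(times.size) - 2.0 * ll
    return TriexpFit(
        fractions=a, half_times=math.log(2) / lam, log_likelihood=ll,
        n_components=k, bic=bic, converged=converged,
    )


def fit_triexponential(times, seed: int = 0, n_starts: int = 8) -> TriexpFit:
    """Three-component MLE fit with a 1/2/3-component BIC comparison.

    Raises on fewer than 30 waits; a fit that fails to converge from every
    start is returned flagged (``converged=False``), never silently replaced.
    """
    fits = {k: fit_exponential_mixture(times, k, seed=seed + k, n_starts=n_starts)
            for k in (1, 2, 3)}
    table = pd.DataFrame([
        {"k": k, "log_likelihood": f.log_likelihood, "bic": f.bic,
         "converged": f.converged}
        for k, f in fits.items()
    ])
    out = fits[3]
    out.model_table = table
    out.preferred_k = int(table.loc[table.bic.idxmin(), "k"])
    return out


def fit_triexponential_cdf(times, seed: int = 0) -> TriexpFit:
    """Least-squares fit of the empirical CDF to a 3-component mixture.

    Provided as an independent cross-check of the MLE route; parameters are
    optimised with scipy on the same mixture parameterisation.
    """
    from scipy.optimize import minimize

    times = np.asarray(times, dtype=float)
    if times.size < 30:
        raise ValueError("at least 30 waiting times are required")
    x = np.sort(times)
    ecdf = np.arange(1, x.size + 1) / x.size
    mle = fit_triexponential(times, seed=seed)

    def unpack(theta):
        z = np.exp(theta[:3])
        a = z / z.sum()
        lam = np.exp(theta[3:])
        return a, lam

    def loss(theta):
        a, lam = unpack(theta)
        model = 1.0 - np.sum(a[None, :] * np.exp(-x[:, None] * lam[None, :]), axis=1)
        return float(np.mean((model - ecdf) ** 2))

    theta0 = np.concatenate([np.log(np.maximum(mle.fractions, 1e-6)),
                             np.log(math.log(2) / mle.half_times)])
    res = minimize(loss, theta0, method="Nelder-Mead",
                   options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-12})
    a, lam = unpack(res.x)
    order = np.argsort(1.0 / lam)
    return TriexpFit(
        fractions=a[order], half_times=math.log(2) / lam[order],
        log_likelihood=math.nan, n_components=3, bic=math.nan,
        converged=bool(res.success),
    )


@dataclass
class ReassignedCounts:
    """Backslip/detachment tallies before and after fast-component reassignment."""

    detachments: float
    backslips: float
    adjusted_detachments: float
    adjusted_backslips: float
    original_ratio: float
    adjusted_ratio: float


def reassign_fast_detachments(fit: TriexpFit, detachment_count: float,
                              backslip_count: float) -> ReassignedCounts:
    """Move the fastest restart component from detachments to backslips.

    The fastest timescale of the restart mixture reflects long backslips in
    which the force transiently fell below the detachment cutoff; its
    fraction of the detachment tally is reassigned to backslips.  Refuses a
    degenerate fit whose two fastest half-times are not clearly separated.
    """
    a1 = float(fit.fractions[0])
    if a1 > 0 and fit.half_times.size >= 2:
        if fit.half_times[1] / fit.half_times[0] < 1.5:
            raise ValueError(
                "overlapping mixture components "
                f"(half-times {fit.half_times[0]:.3g} s and {fit.half_times[1]:.3g} s): "
                "fast-detachment reassignment is not identifiable"
            )
    moved = a1 * detachment_count
    adj_det = detachment_count - moved
    adj_back = backslip_count + moved
    return ReassignedCounts(
        detachments=detachment_count,
        backslips=backslip_count,
        adjusted_detachments=adj_det,
        adjusted_backslips=adj_back,
        original_ratio=backslip_count / detachment_count if detachment_count else math.inf,
        adjusted_ratio=adj_back / adj_det if adj_det else math.inf,
    )


# --------------------------------------------------------------------------- #
# one-stop trace analysis
# --------------------------------------------------------------------------- #

def analyze_trace(trace: TrapTrace, config: AnalysisConfig = AnalysisConfig(),
                  baseline: bool = True):
    """Run baseline correction, event, stall and restart analysis on a trace.

    Returns (corrected trace, events with stalls attached, restart lags).
    """
    if baseline:
        trace = correct_baseline(trace, config)
    force = force_series(trace)
    smoothed = uniform_filter1d(force, size=min(config.event_smooth_window, force.size),
                                mode="nearest")
    events = detect_events(force, config, trace.sample_rate)
    for ev in events:
        ev.stalls = detect_stalls(ev, force, config, trace.sample_rate,
                                  trace.trap_stiffness, smoothed=smoothed)
    restarts = extract_restart_times(events, config, trace.sample_rate)
    return trace, events, restarts
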