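"""Force-event pipeline tests on hand-built force series and simulated traces."""

from __future__ import annotations

import math

import numpy as np
import pytest

from motortrap.simulate import TrapTrace
from motortrap.steps import Step
from motortrap.trace_events import (
    AnalysisConfig,
    ForceEvent,
    TriexpFit,
    analyze_trace,
    correct_baseline,
    count_events_per_encounter,
    detect_events,
    detect_stalls,
    extract_restart_times,
    fit_exponential_mixture,
    fit_triexponential,
    fit_triexponential_cdf,
    force_series,
    force_velocity,
    reassign_fast_detachments,
    stall_force_by_min_time,
)

KAPPA = 0.065
FS = 1000.0
RAW_CFG = AnalysisConfig(event_smooth_window=1, baseline_window_s=0.5)


def _trace_from_force(force: np.ndarray, fs: float = FS) -> TrapTrace:
    return TrapTrace(position=np.asarray(force) / KAPPA, sample_rate=fs,
                     trap_stiffness=KAPPA)


# ------------------------------------------------------------------- force
def test_force_series_scales_position_by_stiffness():
    trace = TrapTrace(position=np.array([0.0, 100.0]), sample_rate=FS,
                      trap_stiffness=0.05)
    assert force_series(trace) == pytest.approx([0.0, 5.0])


def test_force_series_requires_stiffness():
    with pytest.raises(ValueError):
        TrapTrace(position=np.zeros(10), sample_rate=FS, trap_stiffness=None)
    trace = TrapTrace(position=np.zeros(10), sample_rate=FS, trap_stiffness=KAPPA)
    trace.trap_stiffness = None  # e.g. stripped by an external reader
    with pytest.raises(ValueError):
        force_series(trace)


# ------------------------------------------------------------------- events
def test_event_duration_threshold_is_strict():
    """Events must last MORE than 200 ms: a 200-sample pulse at 1 kHz fails,
    201 samples pass."""
    for n_pulse, expected in [(199, 0), (200, 0), (201, 1)]:
        f = np.zeros(2000)
        f[500:500 + n_pulse] = 2.0
        events = detect_events(f, RAW_CFG, FS)
        assert len(events) == expected, n_pulse
    [ev] = detect_events(np.pad(np.full(201, 2.0), (500, 500)), RAW_CFG, FS)
    assert (ev.start, ev.end) == (500, 701)
    assert ev.peak_force == pytest.approx(2.0)
    assert ev.end_reason == "below_threshold"


def test_event_running_to_record_end_flagged():
    f = np.zeros(1000)
    f[600:] = 1.0
    [ev] = detect_events(f, RAW_CFG, FS)
    assert ev.end == 1000 and ev.end_reason == "record_end"


def test_events_are_disjoint_and_ordered():
    f = np.zeros(5000)
    for s in (500, 1500, 3000):
        f[s:s + 400] = 1.0
    events = detect_events(f, RAW_CFG, FS)
    assert len(events) == 3
    for a, b in zip(events[:-1], events[1:]):
        assert a.end <= b.start


def test_smoothing_window_longer_than_trace_rejected():
    with pytest.raises(ValueError):
        detect_events(np.zeros(100), AnalysisConfig(), FS)


def test_smoothing_suppresses_brief_spikes():
    f = np.zeros(40000)
    f[10000:10040] = 50.0  # 2-ms spike: averaged to 1 pN over 100 ms but
    f[20000:26000] = 2.0   # the genuine 300-ms event survives smoothing
    cfg = AnalysisConfig(event_smooth_window=2000)
    events = detect_events(f, cfg, 20000.0)
    assert len(events) >= 1
    assert any(ev.start <= 20000 <= ev.end for ev in events)
    assert all(not (ev.start <= 10020 <= ev.end) for ev in events)


# ----------------------------------------------------------------- baseline
def test_linear_drift_removed_from_quiet_trace():
    n = 40000
    drift = np.linspace(0.0, 6.0, n)  # stays under the 0.5-pN threshold
    pos = drift.copy()
    pos[25000:31000] += 100.0  # one event riding on the drift
    trace = TrapTrace(position=pos, sample_rate=2000.0, trap_stiffness=KAPPA)
    corrected = correct_baseline(trace, AnalysisConfig(event_smooth_window=200,
                                                      baseline_window_s=2.0))
    quiet = np.ones(n, dtype=bool)
    quiet[25000:31000] = False
    assert np.max(np.abs(corrected.position[quiet][1000:-1000])) < 0.5
    # the event amplitude itself is preserved
    assert corrected.position[26000:30000].mean() == pytest.approx(100.0, abs=1.0)
    assert "baseline_nm" in corrected.metadata


def test_baseline_requires_length_and_quiet_support():
    short = TrapTrace(position=np.zeros(100), sample_rate=FS, trap_stiffness=KAPPA)
    with pytest.raises(ValueError):
        correct_baseline(short, AnalysisConfig(baseline_window_s=5.0))
    loud = TrapTrace(position=np.full(5000, 100.0), sample_rate=FS,
                     trap_stiffness=KAPPA)
    with pytest.raises(ValueError):
        correct_baseline(loud, AnalysisConfig(event_smooth_window=100,
                                              baseline_window_s=1.0))


# ------------------------------------------------------------------- stalls
def _ramp_hold(hold_pN, hold_s, ramp_rate=5.0, fs=FS):
    """Force ramp at ``ramp_rate`` pN/s up to a plateau, then release to 0."""
    ramp = np.arange(0.0, hold_pN, ramp_rate / fs)
    hold = np.full(int(hold_s * fs), hold_pN)
    return np.concatenate([ramp, hold, np.zeros(int(0.3 * fs))])


def test_single_stall_at_terminal_plateau():
    f = _ramp_hold(5.0, 0.5)
    [ev] = detect_events(f, RAW_CFG, FS)
    stalls = detect_stalls(ev, f, RAW_CFG, FS, KAPPA, smoothed=f)
    assert len(stalls) == 1
    s = stalls[0]
    # plateau plus the trailing 8 nm (= 0.52 pN = 104 ms of ramp at 5 pN/s)
    assert s.duration == pytest.approx(0.5 + 0.104, abs=0.01)
    assert 4.7 < s.mean_force <= 5.0
    assert ev.start <= s.start < s.end <= ev.end


def test_plateau_shorter_than_minimum_not_scored():
    cfg = AnalysisConfig(event_smooth_window=1, stall_min_duration=0.8)
    f = _ramp_hold(5.0, 0.5)
    [ev] = detect_events(f, cfg, FS)
    assert detect_stalls(ev, f, cfg, FS, KAPPA, smoothed=f) == []


def test_two_stalls_separated_by_big_backslip():
    fs = FS
    ramp1 = np.arange(0.0, 5.0, 5.0 / fs)
    hold1 = np.full(300, 5.0)
    drop = np.full(50, 5.0 - 24.0 * KAPPA)  # 24-nm backslip
    climb = np.arange(5.0 - 24.0 * KAPPA, 5.5, 5.0 / fs)
    hold2 = np.full(300, 5.5)
    f = np.concatenate([ramp1, hold1, drop, climb, hold2, np.zeros(300)])
    [ev] = detect_events(f, RAW_CFG, fs)
    stalls = detect_stalls(ev, f, RAW_CFG, fs, KAPPA, smoothed=f)
    assert len(stalls) == 2
    assert stalls[0].mean_force == pytest.approx(5.0, abs=0.3)
    assert stalls[1].mean_force == pytest.approx(5.5, abs=0.3)
    assert stalls[0].end <= stalls[1].start


def test_low_force_rampup_plateaus_not_stalls():
    """A slow monotonic ramp with no plateau yields only the short terminal
    stall window, not plateaus all along the ramp."""
    f = np.concatenate([np.arange(0.0, 6.0, 1.0 / FS), np.zeros(300)])
    [ev] = detect_events(f, RAW_CFG, FS)
    stalls = detect_stalls(ev, f, RAW_CFG, FS, KAPPA, smoothed=f)
    assert len(stalls) == 1
    assert stalls[0].mean_force > 5.4  # anchored at the release, not mid-ramp


def test_stall_force_by_min_time_table():
    f = _ramp_hold(5.0, 0.5)
    [ev] = detect_events(f, RAW_CFG, FS)
    stalls = detect_stalls(ev, f, RAW_CFG, FS, KAPPA, smoothed=f)
    df = stall_force_by_min_time(stalls, [0.01, 0.1, 10.0])
    assert list(df.min_time_s) == [0.01, 0.1, 10.0]
    assert df.n.iloc[0] == 1 and df.n.iloc[2] == 0
    assert math.isnan(df.mean_force_pN.iloc[2])


# ----------------------------------------------- encounters / restart times
def _ev(start, end, reason="below_threshold"):
    return ForceEvent(start=start, end=end, peak_force=3.0,
                      duration=(end - start) / FS, end_reason=reason)


def _bs(time_s, size):
    return Step(index=int(time_s * FS), time_s=time_s, size_nm=size,
                force_pN=3.0, post_force_pN=3.0 + size * KAPPA, t_score=99.0,
                label="backslip" if size < 0 else "forward")


def test_events_per_encounter_counts_big_backslips_and_merges_quick_restarts():
    events = [_ev(0, 1000), _ev(1050, 2000), _ev(3000, 4000)]
    steps = [_bs(0.5, -30.0), _bs(0.7, 8.2), _bs(3.5, -10.0)]
    counts = count_events_per_encounter(events, steps, AnalysisConfig(), FS)
    # encounter 1: event 1 (one 30-nm backslip -> 2 excursions) + event 2
    # restarting within 100 ms (1 excursion) = 3; encounter 2: 1 excursion
    assert counts == [3, 1]


def test_record_end_event_closes_its_encounter():
    events = [_ev(0, 1000, reason="record_end"), _ev(1050, 2000)]
    counts = count_events_per_encounter(events, [], AnalysisConfig(), FS)
    assert counts == [1, 1]


def test_restart_times_skip_record_end_gaps():
    events = [_ev(0, 1000), _ev(1050, 2000, reason="record_end"), _ev(2500, 3000)]
    lags = extract_restart_times(events, AnalysisConfig(), FS)
    assert lags == pytest.approx([0.05])


# ----------------------------------------------------------- force-velocity
def test_force_velocity_recovers_constant_slope():
    fs = 2000.0
    v = 77.0  # nm/s
    pos = np.concatenate([np.zeros(1000), np.arange(0, 154.0, v / fs),
                          np.full(1000, 154.0)])
    trace = TrapTrace(position=pos, sample_rate=fs, trap_stiffness=KAPPA)
    cfg = AnalysisConfig(event_smooth_window=10, fv_smooth_window=10)
    df = force_velocity([trace], cfg)
    mid = df[(df.force_bin_pN > 1.0) & (df.force_bin_pN < 9.0)]
    assert len(mid) >= 10
    assert np.allclose(mid.mean_velocity_nm_s, v, rtol=0.02)
    assert np.allclose(np.diff(df.force_bin_pN), 0.5)


def test_force_velocity_without_events_rejected():
    trace = TrapTrace(position=np.zeros(5000), sample_rate=FS, trap_stiffness=KAPPA)
    with pytest.raises(ValueError):
        force_velocity([trace], AnalysisConfig(event_smooth_window=100))


# ------------------------------------------------------- mixture fitting
def test_mixture_fit_input_validation():
    with pytest.raises(ValueError):
        fit_exponential_mixture(np.ones(10), k=1)
    with pytest.raises(ValueError):
        fit_exponential_mixture(np.concatenate([np.ones(40), [-1.0]]), k=1)


def test_single_exponential_recovered_and_preferred_by_bic():
    rng = np.random.default_rng(6)
    times = rng.exponential(0.3, size=600)
    fit1 = fit_exponential_mixture(times, k=1, seed=0)
    assert fit1.half_times[0] == pytest.approx(math.log(2) * 0.3, rel=0.15)
    assert fit1.fractions[0] == pytest.approx(1.0)
    full = fit_triexponential(times, seed=0)
    assert full.preferred_k == 1
    assert set(full.model_table.k) == {1, 2, 3}


def test_cdf_fit_agrees_with_mle_on_two_component_data():
    rng = np.random.default_rng(8)
    times = np.concatenate([rng.exponential(0.05, 700), rng.exponential(1.0, 300)])
    mle = fit_exponential_mixture(times, k=2, seed=1)
    cdf = fit_triexponential_cdf(times, seed=1)
    # the two dominant CDF-fit timescales bracket the MLE ones
    assert mle.half_times[0] == pytest.approx(math.log(2) * 0.05, rel=0.25)
    assert mle.half_times[1] == pytest.approx(math.log(2) * 1.0, rel=0.25)
    assert cdf.half_times.size == 3
    assert np.all(np.diff(cdf.half_times) >= 0)


def test_reassignment_moves_fast_fraction():
    fit = TriexpFit(fractions=np.array([0.3, 0.5, 0.2]),
                    half_times=np.array([0.05, 0.3, 1.5]),
                    log_likelihood=0.0, n_components=3, bic=0.0, converged=True)
    res = reassign_fast_detachments(fit, detachment_count=100.0, backslip_count=40.0)
    assert res.adjusted_detachments == pytest.approx(70.0)
    assert res.adjusted_backslips == pytest.approx(70.0)
    assert res.original_ratio == pytest.approx(0.4)
    assert res.adjusted_ratio == pytest.approx(1.0)


def test_reassignment_refuses_overlapping_components():
    fit = TriexpFit(fractions=np.array([0.5, 0.5]),
                    half_times=np.array([0.2, 0.25]),
                    log_likelihood=0.0, n_components=2, bic=0.0, converged=True)
    with pytest.raises(ValueError):
        reassign_fast_detachments(fit, 10.0, 10.0)


# ------------------------------------------------------------- integration
def test_analyze_trace_smoke(fast_config):
    from motortrap.simulate import simulate_trace

    trace = simulate_trace(fast_config)
    # the short record may lack quiet baseline support, so skip correction
    corrected, events, restarts = analyze_trace(trace, AnalysisConfig(),
                                                baseline=False)
    assert corrected.n_samples == trace.n_samples
    for ev in events:
        assert ev.duration > 0.2
        for s in ev.stalls:
            assert ev.start <= s.start < s.end <= ev.end
            assert s.duration >= 0.01
    assert all(lag >= 0 for lag in restarts)
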