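"""Simulator tests: kinetics, bead noise, determinism, and the KMC oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from motortrap.simulate import (
    KymoCalibration,
    MotorPath,
    SimConfig,
    balance_force,
    linescan_profile,
    render_bead_trace,
    simulate_kymo_tracks,
    simulate_linescan_series,
    simulate_motor_path,
    simulate_trace,
)

from oracles import kmc_motor_path


# --------------------------------------------------------------------- config
@pytest.mark.parametrize("field,value", [
    ("trap_stiffness", 0.0),
    ("trap_stiffness", -1.0),
    ("sample_rate", 0.0),
    ("step_size", -8.0),
    ("k_forward_0", 0.0),
    ("slip_speed", 0.0),
])
def test_config_rejects_nonpositive_mechanics(field, value):
    with pytest.raises(ValueError):
        SimConfig(**{field: value})


def test_config_rejects_bad_reattachment_mixture():
    with pytest.raises(ValueError):
        SimConfig(reattach_rate_components=((0.5, 1.0), (0.4, 2.0)))
    with pytest.raises(ValueError):
        SimConfig(reattach_rate_components=((0.5, 1.0), (0.5, -2.0)))


def test_config_requires_integer_sample_count():
    with pytest.raises(ValueError):
        SimConfig(sample_rate=3.0, duration=0.5)


# ----------------------------------------------------------------- motor path
def test_pure_forward_staircase_when_only_stepping_channel_open():
    cfg = SimConfig(duration=2.0, k_backslip_0=0.0, k_detach=0.0,
                    forward_load_distance=1e-12, seed=3)
    path = simulate_motor_path(cfg)
    assert all(k == "forward_step" for k in path.kinds)
    increments = np.diff(np.concatenate([[0.0], path.positions]))
    assert np.allclose(increments, cfg.step_size)
    assert np.all(np.diff(path.times) > 0)


def test_same_seed_reproduces_identical_path_and_trace():
    cfg = SimConfig(duration=1.0, seed=99)
    a, b = simulate_trace(cfg), simulate_trace(cfg)
    assert a.ground_truth.kinds == b.ground_truth.kinds
    assert np.array_equal(a.ground_truth.times, b.ground_truth.times)
    assert np.array_equal(a.position, b.position)


def test_no_stepping_between_detach_and_reattach():
    cfg = SimConfig(duration=20.0, k_detach=3.0, seed=7)
    path = simulate_motor_path(cfg)
    detached = False
    for kind in path.kinds:
        if kind == "detach":
            detached = True
        elif kind == "reattach":
            detached = False
        elif detached:
            pytest.fail(f"event {kind} while detached")


def test_gillespie_event_counts_match_dense_time_kmc_oracle():
    """Gillespie and a 10-us discretised KMC agree on forward-step counts."""
    cfg = SimConfig(duration=1.0, k_forward_0=40.0, k_backslip_0=2.0,
                    k_detach=1.0, forward_load_distance=0.5,
                    backslip_load_distance=0.5, seed=0)
    n_paths = 1000
    rng_g = np.random.default_rng(10)
    rng_k = np.random.default_rng(11)
    counts_g = [sum(k == "forward_step" for k in simulate_motor_path(cfg, rng_g).kinds)
                for _ in range(n_paths)]
    counts_k = [sum(k == "forward_step" for k in kmc_motor_path(cfg, 1e-5, rng_k)[0])
                for _ in range(n_paths)]
    edges = np.quantile(counts_g, np.linspace(0, 1, 8))
    edges[0], edges[-1] = -np.inf, np.inf
    hg, _ = np.histogram(counts_g, bins=edges)
    hk, _ = np.histogram(counts_k, bins=edges)
    _, p, _, _ = sps.chi2_contingency(np.vstack([hg, hk]))
    assert p > 0.01


def test_balance_force_equalises_the_bell_propensities():
    cfg = SimConfig(k_forward_0=100.0, k_backslip_0=0.8)
    F = balance_force(cfg)
    kf = cfg.k_forward_0 * math.exp(-F * cfg.forward_load_distance / cfg.temperature_kT)
    kb = cfg.k_backslip_0 * math.exp(F * cfg.backslip_load_distance / cfg.temperature_kT)
    assert kf == pytest.approx(kb, rel=1e-12)


def test_mean_plateau_force_matches_kmc_oracle():
    """The Gillespie plateau force agrees with the dense-time oracle."""
    kT = 4.06
    d_f = kT * math.log(2.0) / 1.5  # forward rate halves every 1.5 pN
    cfg = SimConfig(duration=10.0, k_forward_0=100.0, forward_load_distance=d_f,
                    k_detach=0.05, seed=21)

    def plateau_mean(forces, kinds):
        f = np.array([F for F, k in zip(forces, kinds) if k == "forward_step"])
        return f[len(f) // 2:].mean()  # discard the ramp-up half

    path = simulate_motor_path(cfg)
    kinds_k, _, pos_k = kmc_motor_path(cfg, 1e-6, np.random.default_rng(5))
    forces_k = cfg.effective_stiffness * pos_k
    m_g = plateau_mean(path.forces, path.kinds)
    m_k = plateau_mean(forces_k, kinds_k)
    assert m_g > 1.0  # the motor builds force against the trap
    assert m_g == pytest.approx(m_k, rel=0.15)


# -------------------------------------------------------------- bead rendering
def test_zero_temperature_trace_is_lowpass_filtered_staircase():
    cfg = SimConfig(duration=0.5, temperature_kT=0.0, k_backslip_0=0.0,
                    k_detach=0.0, k_forward_0=20.0, forward_load_distance=1e-9,
                    seed=2)
    trace = simulate_trace(cfg)
    motor = trace.ground_truth.position_at(trace.times())
    target = motor * cfg.linkage_transmission
    # relaxation time is ~2.3 us << one 50-us sample, so the bead tracks the
    # filtered staircase to within a tiny fraction of a step
    assert np.all(np.diff(trace.position) >= -1e-9)
    assert np.max(np.abs(trace.position - target)) < 0.01 * cfg.step_size


def test_stationary_bead_variance_matches_ou_closed_form():
    cfg = SimConfig(duration=50.0, seed=8)
    path = MotorPath(times=np.array([]), kinds=[], positions=np.array([]),
                     forces=np.array([]), duration=cfg.duration,
                     step_size=cfg.step_size)
    trace = render_bead_trace(path, cfg, np.random.default_rng(4))
    expected = cfg.temperature_kT / (cfg.linkage_stiffness + cfg.trap_stiffness)
    assert trace.n_samples >= 1_000_000
    assert np.var(trace.position) == pytest.approx(expected, rel=0.05)


def test_force_is_stiffness_times_displacement_for_parked_motor():
    cfg = SimConfig(duration=5.0, linkage_stiffness=650.0, seed=8)
    path = MotorPath(times=np.array([1e-6]), kinds=["forward_step"],
                     positions=np.array([100.0]),
                     forces=np.array([cfg.effective_stiffness * 100.0]),
                     duration=cfg.duration, step_size=cfg.step_size)
    trace = render_bead_trace(path, cfg, np.random.default_rng(9))
    mean_force = cfg.trap_stiffness * trace.position[1000:].mean()
    assert mean_force == pytest.approx(6.5, rel=0.01)


# ------------------------------------------------------------------ kymograph
def test_single_processive_track_has_configured_slope():
    cal = KymoCalibration()
    [track] = simulate_kymo_tracks(
        [("processive", dict(speed_sd=0.0, pause_prob=0.0, max_runs=1), 1)],
        cal, seed=1)
    (f0, x0), (f1, x1) = track.vertices[0], track.vertices[-1]
    slope = (x1 - x0) * cal.nm_per_pixel / ((f1 - f0) * cal.s_per_frame)
    assert slope == pytest.approx(800.0, rel=1e-9)


def test_static_population_with_zero_jitter_has_zero_run_length():
    from motortrap.kymo import segment_track, _run_length
    tracks = simulate_kymo_tracks([("static", dict(jitter_px=0.0), 5)], seed=2)
    for roi in tracks:
        assert _run_length(segment_track(roi)) == 0.0


def test_empty_population_list_rejected():
    with pytest.raises(ValueError):
        simulate_kymo_tracks([])


def test_kymo_tracks_deterministic_under_seed():
    pops = [("processive", {}, 3), ("diffusing", {}, 3)]
    a = simulate_kymo_tracks(pops, seed=42)
    b = simulate_kymo_tracks(pops, seed=42)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.vertices, rb.vertices)


# ------------------------------------------------------------------ linescans
def test_linescan_negative_rate_rejected_and_two_timepoints_required():
    with pytest.raises(ValueError):
        simulate_linescan_series(1, [0, 10], transport_rate=-0.1)
    with pytest.raises(ValueError):
        simulate_linescan_series(1, [0])


def test_linescan_total_intensity_conserved_over_time():
    series = simulate_linescan_series(5, np.arange(0, 22, 2.0), seed=3)
    for s in series:
        totals = [float(np.sum(i)) for i in s.intensities]
        assert np.allclose(totals, totals[0], rtol=1e-9)


def test_zero_transport_rate_keeps_profile_constant():
    [s] = simulate_linescan_series(1, [0.0, 20.0], transport_rate=0.0,
                                   noise_sd=0.0, seed=0)
    assert np.allclose(s.intensities[0], s.intensities[1])


def test_initial_profile_periphery_is_25_percent_dimmer():
    x = np.linspace(0.0, 1.0, 501)
    prof = linescan_profile(x, alpha=0.0)
    peri = prof[x >= 0.8].mean()
    inner = prof[x <= 0.2].mean()
    assert peri / inner == pytest.approx(0.75, abs=1e-12)
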