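"""Stochastic ground-truth generators for the trap/motility/redistribution pipeline.

The central object is a load-dependent stepping motor attached to a trapped bead
through an elastic linkage.  Kinetics follow a Bell model: the forward-stepping
rate decreases exponentially with load, the probability of slipping backward in
a weakly bound state increases with load, and detachment returns the bead to the
trap center.  Re-binding waits are drawn from a configurable exponential mixture
so that restart-time analyses have a known answer.

All generators are deterministic under a fixed seed.  Child seeds for repeated
traces are derived from the root seed with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "SimConfig",
    "MotorPath",
    "TrapTrace",
    "KymoCalibration",
    "TrackROI",
    "LinescanSeries",
    "simulate_motor_path",
    "render_bead_trace",
    "simulate_trace",
    "simulate_kymo_tracks",
    "simulate_linescan_series",
    "simulate_intensity_triples",
    "sample_exponential_mixture",
    "sample_bell_steps",
    "balance_force",
    "linescan_profile",
]

#: Thermal energy at the experimental room temperature of 22 degC, pN nm.
KT_ROOM = 4.06


# --------------------------------------------------------------------------- #
# configuration and containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SimConfig:
    """Mechanical and kinetic parameters of the trapped-bead motor simulation.

    Units: stiffnesses pN/nm, rates 1/s, distances nm, times s, drag pN s/nm.

    The defaults emulate a processive kinesin-3 recorded at 20 kHz in a trap of
    0.065 pN/nm: 8.2-nm lattice steps, an unloaded stepping rate of ~110/s
    (~900 nm/s), load-promoted backslips rendered as continuous slips toward
    the trap center, and a three-component exponential re-binding mixture.
    """

    trap_stiffness: float = 0.065
    linkage_stiffness: float = 2.0
    sample_rate: float = 20_000.0
    temperature_kT: float = KT_ROOM
    bead_drag: float = 4.7e-6
    step_size: float = 8.2
    k_forward_0: float = 110.0
    forward_load_distance: float = 2.5
    k_backslip_0: float = 0.5
    backslip_load_distance: float = 1.5
    backslip_reengage_rate: float = 75.0
    slip_speed: float = 1500.0
    k_detach: float = 0.8
    reattach_rate_components: tuple[tuple[float, float], ...] = (
        (0.31, math.log(2) / 0.074),
        (0.39, math.log(2) / 0.300),
        (0.30, math.log(2) / 1.500),
    )
    duration: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "trap_stiffness": self.trap_stiffness,
            "linkage_stiffness": self.linkage_stiffness,
            "sample_rate": self.sample_rate,
            "bead_drag": self.bead_drag,
            "step_size": self.step_size,
            "k_forward_0": self.k_forward_0,
            "backslip_reengage_rate": self.backslip_reengage_rate,
            "slip_speed": self.slip_speed,
            "duration": self.duration,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        for name, value in {
            "temperature_kT": self.temperature_kT,
            "forward_load_distance": self.forward_load_distance,
            "backslip_load_distance": self.backslip_load_distance,
            "k_backslip_0": self.k_backslip_0,
            "k_detach": self.k_detach,
        }.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")
        fracs = [f for f, _ in self.reattach_rate_components]
        rates = [r for _, r in self.reattach_rate_components]
        if not fracs or any(f <= 0 or f > 1 for f in fracs):
            raise ValueError("reattachment fractions must lie in (0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("reattachment fractions must sum to 1")
        if any(r <= 0 for r in rates):
            raise ValueError("reattachment rates must be strictly positive")
        n = self.sample_rate * self.duration
        if abs(n - round(n)) > 1e-6:
            raise ValueError("sample_rate * duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.duration))

    @property
    def effective_stiffness(self) -> float:
        """Series stiffness of linkage + trap seen by the motor, pN/nm."""
        kl, kt = self.linkage_stiffness, self.trap_stiffness
        return kl * kt / (kl + kt)

    @property
    def linkage_transmission(self) -> float:
        """Fraction of motor displacement transmitted to the bead."""
        kl, kt = self.linkage_stiffness, self.trap_stiffness
        return kl / (kl + kt)


def balance_force(config: SimConfig) -> float:
    """Load at which the forward and backslip propensities are equal (pN).

    Solves k_f0 exp(-F d_f / kT) = k_b0 exp(+F d_b / kT).
    """
    if config.k_backslip_0 <= 0:
        return math.inf
    num = config.temperature_kT * math.log(config.k_forward_0 / config.k_backslip_0)
    return num / (config.forward_load_distance + config.backslip_load_distance)


@dataclass
class MotorPath:
    """Ground-truth event sequence of a simulated motor.

    ``kinds`` uses the vocabulary forward_step / backslip_start / backslip_end /
    detach / reattach; ``positions`` is the motor position immediately after
    each event and ``forces`` the corresponding trap load on the motor.
    """

    times: np.ndarray
    kinds: list[str]
    positions: np.ndarray
    forces: np.ndarray
    duration: float
    step_size: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.kinds):
            raise ValueError("times and kinds must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def position_at(self, t: np.ndarray) -> np.ndarray:
        """Motor position at arbitrary times.

        Position is piecewise constant between events except during slips,
        where it ramps linearly from the backslip_start to the backslip_end
        position.
        """
        seg_t0 = [0.0]
        seg_x0 = [0.0]
        seg_v = [0.0]
        pos = 0.0
        slip_from: tuple[float, float] | None = None
        for time, kind, x_after in zip(self.times, self.kinds, self.positions):
            if kind == "backslip_start":
                slip_from = (time, pos)
                continue
            if kind == "backslip_end" and slip_from is not None:
                t0, x0 = slip_from
                dt = time - t0
                v = (x_after - x0) / dt if dt > 0 else 0.0
                seg_t0.append(t0)
                seg_x0.append(x0)
                seg_v.append(v)
                slip_from = None
            seg_t0.append(time)
            seg_x0.append(float(x_after))
            seg_v.append(0.0)
            pos = float(x_after)
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(np.asarray(seg_t0), t, side="right") - 1
        idx = np.clip(idx, 0, len(seg_t0) - 1)
        t0 = np.asarray(seg_t0)[idx]
        x0 = np.asarray(seg_x0)[idx]
        v = np.asarray(seg_v)[idx]
        return x0 + v * (t - t0)


@dataclass
class TrapTrace:
    """A bead-position time series with the metadata needed to analyse it."""

    position: np.ndarray
    sample_rate: float
    trap_stiffness: float
    ground_truth: MotorPath | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("trace contains non-finite samples")
        if self.trap_stiffness is None or self.sample_rate <= 0 or self.trap_stiffness <= 0:
            raise ValueError("sample_rate and trap_stiffness must be positive")

    @property
    def n_samples(self) -> int:
        return self.position.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


# --------------------------------------------------------------------------- #
# motor path simulation (Gillespie)
# --------------------------------------------------------------------------- #

def sample_exponential_mixture(
    rng: np.random.Generator,
    components: tuple[tuple[float, float], ...],
    size: int = 1,
) -> np.ndarray:
    """Draw waits from a mixture of exponentials given (fraction, rate) pairs."""
    fracs = np.array([f for f, _ in components])
    rates = np.array([r for _, r in components])
    which = rng.choice(len(fracs), size=size, p=fracs / fracs.sum())
    return rng.exponential(1.0 / rates[which])


def simulate_motor_path(config: SimConfig, rng: np.random.Generator | None = None) -> MotorPath:
    """Exact stochastic simulation of the stepping/slipping/detaching motor.

    The propensities are constant between events (they depend only on the
    current motor position), so the standard Gillespie algorithm is exact.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    keff = config.effective_stiffness
    kT = config.temperature_kT
    lattice = config.step_size

    t = 0.0
    x = 0.0
    times: list[float] = []
    kinds: list[str] = []
    positions: list[float] = []
    state = "attached"
    slip_start_time = 0.0
    slip_start_pos = 0.0

    while t < config.duration:
        if state == "attached":
            force = keff * x
            kf = config.k_forward_0 * math.exp(-force * config.forward_load_distance / kT) if kT > 0 else config.k_forward_0
            kb = config.k_backslip_0 * (math.exp(force * config.backslip_load_distance / kT) if kT > 0 else 1.0)
            kd = config.k_detach
            ktot = kf + kb + kd
            if ktot <= 0:
                break
            t += rng.exponential(1.0 / ktot)
            if t >= config.duration:
                break
            u = rng.random() * ktot
            if u < kf:
                x += lattice
                times.append(t); kinds.append("forward_step"); positions.append(x)
            elif u < kf + kb:
                times.append(t); kinds.append("backslip_start"); positions.append(x)
                slip_start_time, slip_start_pos = t, x
                state = "slipping"
            else:
                x = 0.0
                times.append(t); kinds.append("detach"); positions.append(x)
                state = "detached"
        elif state == "slipping":
            tau = rng.exponential(1.0 / config.backslip_reengage_rate)
            t_end = slip_start_time + tau
            if t_end >= config.duration:
                # truncate the slip at the end of the record
                reached = max(0.0, slip_start_pos - config.slip_speed * (config.duration - slip_start_time))
                times.append(config.duration); kinds.append("backslip_end"); positions.append(reached)
                x = reached
                t = config.duration
                break
            reached = max(0.0, slip_start_pos - config.slip_speed * tau)
            # re-engagement snaps to the nearest lattice site
            x = round(reached / lattice) * lattice
            t = t_end
            times.append(t); kinds.append("backslip_end"); positions.append(x)
            state = "attached"
        else:  # detached
            wait = float(sample_exponential_mixture(rng, config.reattach_rate_components, 1)[0])
            t += wait
            if t >= config.duration:
                break
            times.append(t); kinds.append("reattach"); positions.append(0.0)
            state = "attached"

    times_arr = np.asarray(times)
    pos_arr = np.asarray(positions)
    return MotorPath(
        times=times_arr,
        kinds=kinds,
        positions=pos_arr,
        forces=keff * pos_arr,
        duration=config.duration,
        step_size=lattice,
    )


# --------------------------------------------------------------------------- #
# bead rendering (OU noise around the filtered motor position)
# --------------------------------------------------------------------------- #

def render_bead_trace(
    path: MotorPath,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TrapTrace:
    """Render a sampled bead trace from a motor path.

    The bead relaxes toward ``motor_position * k_link / (k_link + k_trap)``
    with rate (k_link + k_trap) / drag and carries Ornstein-Uhlenbeck thermal
    noise of stationary variance kT / (k_link + k_trap).  The zero-temperature
    limit is the deterministic low-pass-filtered staircase.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples
    dt = 1.0 / config.sample_rate
    k_tot = config.linkage_stiffness + config.trap_stiffness
    tau = config.bead_drag / k_tot
    a = math.exp(-dt / tau)
    sigma = math.sqrt(config.temperature_kT / k_tot)

    t = np.arange(n) * dt
    mean = path.position_at(t) * config.linkage_transmission

    w = rng.standard_normal(n) * (sigma * math.sqrt(1.0 - a * a))
    # deviation recursion d[n] = a d[n-1] + a (mean[n-1]-mean[n]) + w[n-1]
    u = np.empty(n)
    u[0] = rng.standard_normal() * sigma  # start in the stationary distribution
    u[1:] = a * (mean[:-1] - mean[1:]) + w[:-1]
    dev = lfilter([1.0], [1.0, -a], u)
    bead = mean + dev

    return TrapTrace(
        position=bead,
        sample_rate=config.sample_rate,
        trap_stiffness=config.trap_stiffness,
        ground_truth=path,
        metadata={
            "seed": config.seed,
            "linkage_stiffness_pN_per_nm": config.linkage_stiffness,
            "temperature_kT_pN_nm": config.temperature_kT,
        },
    )


def simulate_trace(config: SimConfig) -> TrapTrace:
    """Convenience wrapper: path + bead rendering from one seeded generator."""
    root = np.random.SeedSequence(config.seed)
    path_ss, bead_ss = root.spawn(2)
    path = simulate_motor_path(config, np.random.default_rng(path_ss))
    return render_bead_trace(path, config, np.random.default_rng(bead_ss))


# --------------------------------------------------------------------------- #
# kymograph track generator
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class KymoCalibration:
    """Pixel and frame calibration of a kymograph, defaults per the TIRF setup."""

    nm_per_pixel: float = 162.0
    s_per_frame: float = 0.2
    plus_end_direction: int = 1

    def __post_init__(self) -> None:
        if self.nm_per_pixel <= 0 or self.s_per_frame <= 0:
            raise ValueError("calibration scales must be positive")
        if self.plus_end_direction not in (-1, 1):
            raise ValueError("plus_end_direction must be +1 or -1")


@dataclass
class TrackROI:
    """A hand-traced kymograph track: ordered (frame, x_px) vertices."""

    vertices: np.ndarray  # shape (n, 2): frame, x_px
    mt_id: int = 0
    label: str | None = None  # ground-truth class when generated
    intensity: np.ndarray | None = None
    day: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("a track needs at least two (frame, x_px) vertices")
        if np.any(np.diff(self.vertices[:, 0]) <= 0):
            raise ValueError("vertex frames must be strictly increasing")


_KYMO_DEFAULTS = {
    "processive": dict(
        speed_nm_s=800.0, speed_sd=100.0, speed_min=500.0, run_mean_s=2.5,
        run_min_s=1.0, pause_prob=0.4, pause_mean_s=1.0, pause_min_s=0.2,
        max_runs=6,
    ),
    "static": dict(duration_mean_s=10.0, jitter_px=0.15, vertex_every=10),
    "diffusing": dict(diffusion_um2_s=0.1, duration_mean_s=15.0, duration_min_s=8.0),
}


def simulate_kymo_tracks(
    populations: list[tuple[str, dict, int]],
    calibration: KymoCalibration = KymoCalibration(),
    seed: int = 0,
    n_frames: int = 900,
) -> list[TrackROI]:
    """Generate kymograph tracks for processive/static/diffusing populations.

    ``populations`` is a list of (class_name, parameter overrides, count); the
    ground-truth class is retained on each :class:`TrackROI`.
    """
    if not populations:
        raise ValueError("population list must not be empty")
    rng = np.random.default_rng(seed)
    cal = calibration
    tracks: list[TrackROI] = []
    mt = 0
    for cls, params, count in populations:
        if cls not in _KYMO_DEFAULTS:
            raise ValueError(f"unknown track class {cls!r}")
        p = {**_KYMO_DEFAULTS[cls], **(params or {})}
        for _ in range(count):
            start_frame = int(rng.integers(0, max(1, n_frames // 3)))
            x0 = rng.uniform(5.0, 60.0)
            if cls == "processive":
                verts = [(start_frame, x0)]
                frame, x = start_frame, x0
                n_runs = int(rng.integers(1, p["max_runs"] + 1))
                for i in range(n_runs):
                    v = max(p["speed_min"], rng.normal(p["speed_nm_s"], p["speed_sd"]))
                    dur = max(p["run_min_s"], rng.exponential(p["run_mean_s"]))
                    nfr = max(1, int(round(dur / cal.s_per_frame)))
                    frame += nfr
                    x += cal.plus_end_direction * v * nfr * cal.s_per_frame / cal.nm_per_pixel
                    verts.append((frame, x))
                    if i < n_runs - 1 and rng.random() < p["pause_prob"]:
                        pdur = max(p["pause_min_s"], rng.exponential(p["pause_mean_s"]))
                        frame += max(1, int(round(pdur / cal.s_per_frame)))
                        verts.append((frame, x))
            elif cls == "static":
                dur = max(2.0, rng.exponential(p["duration_mean_s"]))
                nfr = max(2, int(round(dur / cal.s_per_frame)))
                frames = np.arange(start_frame, start_frame + nfr + 1, p["vertex_every"])
                if len(frames) < 2:
                    frames = np.array([start_frame, start_frame + nfr])
                xs = x0 + rng.normal(0.0, p["jitter_px"], size=len(frames))
                verts = list(zip(frames, xs))
            else:  # diffusing
                dur = max(p["duration_min_s"], rng.exponential(p["duration_mean_s"]))
                nfr = max(5, int(round(dur / cal.s_per_frame)))
                sd_px = math.sqrt(2.0 * p["diffusion_um2_s"] * 1e6 * cal.s_per_frame) / cal.nm_per_pixel
                xs = x0 + np.cumsum(np.concatenate([[0.0], rng.normal(0.0, sd_px, size=nfr)]))
                frames = np.arange(start_frame, start_frame + nfr + 1)
                verts = list(zip(frames, xs))
            tracks.append(TrackROI(vertices=np.array(verts), mt_id=mt, label=cls))
            mt += 1
    return tracks


# --------------------------------------------------------------------------- #
# cell linescan and intensity-triple generators
# --------------------------------------------------------------------------- #

@dataclass
class LinescanSeries:
    """Center-to-tip intensity profiles of one cell over time.

    ``positions`` are normalised (0 = cell centre, 1 = tip); one profile per
    entry of ``times`` (minutes).
    """

    cell_id: int
    times: np.ndarray
    positions: list[np.ndarray]
    intensities: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions) or len(self.times) != len(self.intensities):
            raise ValueError("one position/intensity array is required per timepoint")


def linescan_profile(x: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form mitochondrial profile after a fraction ``alpha`` of transport.

    The initial profile is flat at 1 over the perinuclear window [0, 0.2],
    flat at 0.75 over the periphery [0.8, 1] (25% dimmer) and linear between.
    The final profile has the same total mass but a periphery/perinuclear
    ratio of 1.6.  Intermediate times interpolate linearly, which conserves
    mass exactly.
    """
    x = np.asarray(x, dtype=float)

    def piecewise(inner: float, outer: float) -> np.ndarray:
        y = np.empty_like(x)
        y[x <= 0.2] = inner
        y[x >= 0.8] = outer
        mid = (x > 0.2) & (x < 0.8)
        y[mid] = inner + (outer - inner) * (x[mid] - 0.2) / 0.6
        return y

    start = piecewise(1.0, 0.75)
    # same mass (integral 0.875 on [0,1]) redistributed peripherally, ratio 1.6
    a = 0.875 / (0.5 * (1.0 + 1.6))
    end = piecewise(a, 1.6 * a)
    return (1.0 - alpha) * start + alpha * end


def simulate_linescan_series(
    n_cells: int,
    timepoints: np.ndarray | list[float],
    transport_rate: float = 0.05,
    seed: int = 0,
    n_points: int = 200,
    noise_sd: float = 0.02,
) -> list[LinescanSeries]:
    """Generate per-cell linescan series with a known mass-conserving shift.

    ``transport_rate`` is the fraction of the full redistribution completed per
    minute (clipped at 1).  Noise is mean-subtracted per profile so the total
    intensity of each cell's profile is conserved over time to machine
    precision; a per-cell amplitude factor models expression-level variation.
    """
    if transport_rate < 0:
        raise ValueError("transport_rate must be non-negative")
    times = np.asarray(timepoints, dtype=float)
    if times.size < 2:
        raise ValueError("at least two timepoints are required")
    rng = np.random.default_rng(seed)
    x = (np.arange(n_points) + 0.5) / n_points
    series = []
    for cell in range(n_cells):
        amp = float(rng.lognormal(0.0, 0.2))
        positions, intensities = [], []
        for t in times:
            alpha = min(1.0, transport_rate * t)
            prof = amp * linescan_profile(x, alpha)
            if noise_sd > 0:
                eps = rng.normal(0.0, noise_sd * amp, size=n_points)
                prof = prof + eps - eps.mean()
            positions.append(x.copy())
            intensities.append(prof)
        series.append(LinescanSeries(cell_id=cell, times=times.copy(),
                                     positions=positions, intensities=intensities))
    return series


def simulate_intensity_triples(
    n_cells: int,
    true_ratio: float = 1.6,
    background: float = 50.0,
    perinuclear: float = 150.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Tail/perinuclear/background intensity triples with a known true ratio.

    Returns an (n, 3) array of (tail, perinuclear, background) means with
    additive Gaussian measurement noise.
    """
    rng = np.random.default_rng(seed)
    tail = background + true_ratio * (perinuclear - background)
    base = np.array([tail, perinuclear, background])
    return base + rng.normal(0.0, noise_sd, size=(n_cells, 3))


# --------------------------------------------------------------------------- #
# direct step sampling for balance-force studies
# --------------------------------------------------------------------------- #

def sample_bell_steps(
    n: int,
    crossing_force: float,
    seed: int = 0,
    force_range: tuple[float, float] = (2.0, 8.0),
    load_distance_sum: float = 4.0,
    kT: float = KT_ROOM,
    step_size: float = 8.2,
):
    """Sample forward/backslip steps whose rate ratio crosses 1 at a set force.

    The forward:backslip propensity ratio is exp((F* - F) d / kT).  Forces are
    drawn uniformly over ``force_range``; each step is forward with probability
    k_f / (k_f + k_b).  Returns a list of :class:`motortrap.steps.Step` with
    classes assigned, suitable for :func:`motortrap.steps.fore_back_balance`.
    """
    from .steps import Step  # local import avoids a cycle at module load

    rng = np.random.default_rng(seed)
    forces = rng.uniform(*force_range, size=n)
    log_ratio = (crossing_force - forces) * load_distance_sum / kT
    p_forward = 1.0 / (1.0 + np.exp(-log_ratio))
    forward = rng.random(n) < p_forward
    steps = []
    for i, (f, fwd) in enumerate(zip(forces, forward)):
        steps.append(Step(
            index=i * 1000,
            time_s=i * 0.05,
            size_nm=step_size if fwd else -step_size,
            force_pN=float(f),
            post_force_pN=float(f + (step_size if fwd else -step_size) * 0.065),
            t_score=100.0,
            label="forward" if fwd else "backslip",
        ))
    return steps
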