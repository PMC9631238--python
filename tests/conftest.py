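"""Shared fixtures: fast simulation configs and hand-built trace/track helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from motortrap.simulate import KymoCalibration, SimConfig, TrackROI, TrapTrace


@pytest.fixture
def fast_config() -> SimConfig:
    """Default mechanics, shortened record for quick tests."""
    return SimConfig(duration=5.0, seed=12345)


def balanced_config(balance_pN: float, duration: float = 12.0, seed: int = 0,
                    **overrides) -> SimConfig:
    """A SimConfig whose forward/backslip propensities cross at ``balance_pN``."""
    base = SimConfig()
    d_sum = base.forward_load_distance + base.backslip_load_distance
    kb0 = base.k_forward_0 * math.exp(-balance_pN * d_sum / base.temperature_kT)
    return SimConfig(duration=duration, seed=seed, k_backslip_0=kb0,
                     k_detach=overrides.pop("k_detach", 0.3), **overrides)


def make_staircase(rng: np.random.Generator, n_steps: int, sample_rate: float = 2000.0,
                   kappa: float = 0.065, min_sep: int = 150, max_sep: int = 400,
                   size_range: tuple[float, float] = (5.5, 12.0),
                   offset_nm: float = 20.0, noise_sd: float = 0.0,
                   ) -> tuple[TrapTrace, np.ndarray, np.ndarray]:
    """A synthetic staircase trace with known step indices and sizes.

    The baseline offset keeps every step above the 1-pN minimum-force rule.
    Returns (trace, true step indices, true step sizes).
    """
    seps = rng.integers(min_sep, max_sep, size=n_steps + 1)
    idx = np.cumsum(seps)[:-1]
    sizes = rng.uniform(*size_range, size=n_steps)
    n = int(idx[-1] + seps[-1]) if n_steps else int(seps[0])
    y = np.full(n, offset_nm)
    for i, s in zip(idx, sizes):
        y[i:] += s
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    trace = TrapTrace(position=y, sample_rate=sample_rate, trap_stiffness=kappa)
    return trace, idx, sizes


#: exact-arithmetic calibration used by the hand-built classification fixtures
FIXTURE_CAL = KymoCalibration(nm_per_pixel=1.0, s_per_frame=0.25, plus_end_direction=1)


def edge_case_tracks() -> list[tuple[TrackROI, str]]:
    """Hand-built tracks probing every classification boundary.

    With 1 nm/px and 0.25 s/frame all speeds and distances below are exact
    in floating point.  Expected classes follow the rules: static when the
    average speed is below 25 nm/s or the total run length is below 500 nm;
    diffusing when bidirectional excursions reach 324 nm each way or net
    motion is minus-end-directed; otherwise processive.
    """
    def roi(*verts):
        return TrackROI(vertices=np.array(verts, dtype=float))

    cases = []
    # run lengths 399/400/500/501 nm at 99.75-125.25 nm/s (single run phase)
    for rl, expected in [(399, "static"), (400, "static"),
                         (500, "processive"), (501, "processive")]:
        cases.append((roi((0, 0), (16, rl)), expected))
    # uniform speeds 24/25/26 nm/s over 30 s (120 frames); 24 and 25 are not
    # "greater than 25" so every segment is a pause and the run length is 0
    for v, expected in [(24, "static"), (25, "static"), (26, "processive")]:
        cases.append((roi((0, 0), (120, v * 30)), expected))
    # minus-ward excursions of 323/324 nm between two 1000-nm plus-ward runs
    for exc, expected in [(323, "processive"), (324, "diffusing")]:
        cases.append((roi((0, 0), (8, 1000), (12, 1000 - exc), (20, 2000 - exc)),
                      expected))
    # purely minus-end-directed motion is diffusive by definition
    cases.append((roi((0, 0), (8, -1000)), "diffusing"))
    return cases
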