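"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package implementations they
check: an exact dynamic-programming changepoint segmentation for step
detection, and a dense-time discretised kinetic Monte Carlo simulation of
the motor reaction scheme for the Gillespie path generator.
"""

from __future__ import annotations

import math

import numpy as np


def changepoint_oracle(y: np.ndarray, penalty: float) -> list[int]:
    """Optimal piecewise-constant least-squares segmentation.

    Minimises sum of squared residuals + penalty * (number of segments)
    exactly by dynamic programming (optimal partitioning).  Returns the
    sorted changepoint indices: each is the first sample of a new segment.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    F = np.empty(n + 1)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for e in range(1, n + 1):
        s = np.arange(e)
        seg = (c2[e] - c2[s]) - (c1[e] - c1[s]) ** 2 / (e - s)
        total = F[:e] + penalty + seg
        i = int(np.argmin(total))
        F[e] = total[i]
        prev[e] = i
    cps = []
    e = n
    while e > 0:
        s = prev[e]
        if s > 0:
            cps.append(s)
        e = s
    return sorted(cps)


def segment_means(y: np.ndarray, changepoints: list[int]) -> np.ndarray:
    bounds = [0, *changepoints, len(y)]
    return np.array([np.mean(y[a:b]) for a, b in zip(bounds[:-1], bounds[1:])])


def kmc_motor_path(config, h: float, rng: np.random.Generator):
    """Dense-time kinetic Monte Carlo with timestep ``h`` (seconds).

    At every timestep each reaction channel fires with probability rate*h.
    The per-channel propensities mirror the motor scheme (Bell-model forward
    stepping, load-promoted slipping, detachment, mixture rebinding) but the
    time discretisation is independent of the Gillespie implementation.
    Waiting times are sampled geometrically, which is distributionally
    identical to stepping through every slot.  Returns (event kinds, event
    times, positions after each event).
    """
    kT = config.temperature_kT
    keff = config.effective_stiffness
    lattice = config.step_size
    fracs = np.array([f for f, _ in config.reattach_rate_components])
    rates = np.array([r for _, r in config.reattach_rate_components])

    t = 0.0
    x = 0.0
    state = "attached"
    kinds, times, positions = [], [], []
    slip_t0 = slip_x0 = 0.0
    while t < config.duration:
        if state == "attached":
            F = keff * x
            k = np.array([
                config.k_forward_0 * math.exp(-F * config.forward_load_distance / kT),
                config.k_backslip_0 * math.exp(F * config.backslip_load_distance / kT),
                config.k_detach,
            ])
            p = k * h
            p_tot = p.sum()
            if p_tot <= 0:
                break
            if p_tot >= 1:
                raise ValueError("timestep too coarse for these rates")
            m = rng.geometric(p_tot)  # number of slots until a reaction fires
            t += m * h
            if t >= config.duration:
                break
            channel = rng.choice(3, p=p / p_tot)
            if channel == 0:
                x += lattice
                kinds.append("forward_step")
            elif channel == 1:
                kinds.append("backslip_start")
                slip_t0, slip_x0 = t, x
                state = "slipping"
            else:
                x = 0.0
                kinds.append("detach")
                state = "detached"
            times.append(t)
            positions.append(x)
        elif state == "slipping":
            p = config.backslip_reengage_rate * h
            m = rng.geometric(p)
            t = slip_t0 + m * h
            if t >= config.duration:
                break
            reached = max(0.0, slip_x0 - config.slip_speed * (t - slip_t0))
            x = round(reached / lattice) * lattice
            kinds.append("backslip_end")
            times.append(t)
            positions.append(x)
            state = "attached"
        else:
            comp = rng.choice(len(fracs), p=fracs / fracs.sum())
            p = rates[comp] * h
            m = rng.geometric(p)
            t += m * h
            if t >= config.duration:
                break
            kinds.append("reattach")
            times.append(t)
            positions.append(0.0)
            state = "attached"
    return kinds, np.array(times), np.array(positions)
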