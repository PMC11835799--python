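"""Naive double-loop reference implementation of the swarmalator dynamics.

Written deliberately as scalar loops over agent pairs, term by term, so it
shares no vectorized code path with the package.  Used as the oracle for
equivalence tests of the production right-hand sides.
"""

import math

import numpy as np

from dirswarm.model_core import ModelParams, SwarmState, gaze_kernel_norm


def _omega(theta: float) -> float:
    return (1.0 + math.cos(theta)) / 2.0


def _upsilon(theta: float, c: float) -> float:
    return ((1.0 + math.cos(theta)) / 2.0) ** c / gaze_kernel_norm(c)


def _upsilon_prime(theta: float, c: float, normalized: bool) -> float:
    base = (1.0 + math.cos(theta)) / 2.0
    if base == 0.0:
        return 0.0
    val = (c * math.sin(theta) / 2.0) * base ** (c - 1.0)
    if normalized:
        val /= gaze_kernel_norm(c)
    return val


def naive_derivatives(state: SwarmState, params: ModelParams):
    """Return (velocity, gaze_rate, phase_rate) by scalar double loops."""
    n = state.n_agents
    p = params
    vel = np.zeros((n, 2))
    drate = np.zeros(n)
    prate = np.zeros(n)
    for j in range(n):
        xj = state.positions[j]
        norm_xj = math.hypot(xj[0], xj[1])
        if norm_xj > 0.0:
            guard = max(norm_xj, p.min_distance) if p.attraction_exponent < 1 else norm_xj
            vel[j] += -p.attraction_strength * xj * guard ** (p.attraction_exponent - 1.0)
        rep = np.zeros(2)
        pg = np.zeros(2)
        gz = 0.0
        vis = 0.0
        for k in range(n):
            if k == j:
                continue
            dx = state.positions[k] - state.positions[j]
            dist = max(math.hypot(dx[0], dx[1]), p.min_distance)
            w = 1.0 / dist
            unit = dx / dist
            alpha = math.atan2(dx[1], dx[0])
            dth = state.phases[k] - state.phases[j]
            rel = alpha - state.gazes[j]
            rep += w**p.repulsion_decay * unit
            pg += (
                w**p.pg_spatial_decay
                * _omega(dth)
                * _upsilon(rel, p.constriction)
                * unit
            )
            gz += (
                w**p.gaze_spatial_decay
                * _upsilon_prime(rel, p.constriction, p.normalized_gaze_derivative)
                * _omega(dth)
            )
            vis += w**p.visual_spatial_decay * _upsilon(rel, p.constriction) * math.sin(dth)
        vel[j] += -(p.repulsion_strength / n) * rep + (p.pg_attraction_strength / n) * pg
        drate[j] = (p.gaze_strength / n) * gz
        prate[j] = (
            state.spontaneous_freqs[j]
            + p.auditory_strength * math.sin(state.stimulus_phases[j] - state.phases[j])
            + (p.visual_strength / n) * vis
        )
    return vel, drate, prate
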