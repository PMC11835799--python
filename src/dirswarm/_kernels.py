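"""Compiled inner loop of the Euler integrator.

The pairwise right-hand side is O(N^2) but N is small (a dance floor of ~12
agents), so the per-step cost is dominated by interpreter overhead rather
than arithmetic.  This module holds a numba-compiled whole-run integration
loop used by the simulator when numba is importable; the pure-numpy stepper
remains the reference implementation and the fallback.  Both paths implement
exactly the same update, and the test suite compares them.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _wrap(a: float) -> float:
    w = (a + np.pi) % (2.0 * np.pi) - np.pi
    if w == -np.pi:
        return np.pi
    return w


@njit(cache=True)
def integrate_loop(
    positions,
    phases,
    gazes,
    omegas,
    stim,
    dt,
    A,
    a_exp,
    R,
    r_exp,
    P,
    p_exp,
    D,
    d_exp,
    U,
    V,
    v_exp,
    c,
    eps,
    norm_const,
    normalized_deriv,
    divergence_bound,
    out_pos,
    out_phase,
    out_gaze,
):
    """Fill (T, N, ...) output arrays by forward Euler; return the frame of
    divergence / non-finite state, or 0 on success."""
    n_steps = stim.shape[0] - 1
    n = positions.shape[0]
    out_pos[0] = positions
    out_phase[0] = phases
    out_gaze[0] = gazes
    vel = np.empty((n, 2))
    drate = np.empty(n)
    prate = np.empty(n)
    for step in range(1, n_steps + 1):
        for j in range(n):
            xj0 = positions[j, 0]
            xj1 = positions[j, 1]
            norm_xj = np.sqrt(xj0 * xj0 + xj1 * xj1)
            if norm_xj > 0.0:
                guard = norm_xj
                if a_exp < 1.0 and guard < eps:
                    guard = eps
                scale = A * guard ** (a_exp - 1.0)
                vel[j, 0] = -scale * xj0
                vel[j, 1] = -scale * xj1
            else:
                vel[j, 0] = 0.0
                vel[j, 1] = 0.0
            gz = 0.0
            vis = 0.0
            for k in range(n):
                if k == j:
                    continue
                dx0 = positions[k, 0] - xj0
                dx1 = positions[k, 1] - xj1
                dist = np.sqrt(dx0 * dx0 + dx1 * dx1)
                if dist < eps:
                    dist = eps
                w = 1.0 / dist
                u0 = dx0 / dist
                u1 = dx1 / dist
                alpha = np.arctan2(dx1, dx0)
                dth = phases[k] - phases[j]
                rel = alpha - gazes[j]
                omega_gate = 0.5 * (1.0 + np.cos(dth))
                base = 0.5 * (1.0 + np.cos(rel))
                base_c = base**c
                upsilon = base_c / norm_const
                if base > 0.0:
                    ups_d = 0.5 * c * np.sin(rel) * base_c / base
                else:
                    ups_d = 0.0
                if normalized_deriv:
                    ups_d /= norm_const
                rep = (R / n) * w**r_exp
                pg = (P / n) * w**p_exp * omega_gate * upsilon
                vel[j, 0] += (pg - rep) * u0
                vel[j, 1] += (pg - rep) * u1
                gz += w**d_exp * ups_d * omega_gate
                vis += w**v_exp * upsilon * np.sin(dth)
            drate[j] = (D / n) * gz
            prate[j] = omegas[j] + U * np.sin(stim[step - 1, j] - phases[j]) + (V / n) * vis
        for j in range(n):
            if not (
                np.isfinite(vel[j, 0])
                and np.isfinite(vel[j, 1])
                and np.isfinite(drate[j])
                and np.isfinite(prate[j])
            ):
                return -step
            positions[j, 0] += vel[j, 0] * dt
            positions[j, 1] += vel[j, 1] * dt
            gazes[j] = _wrap(gazes[j] + drate[j] * dt)
            phases[j] = _wrap(phases[j] + prate[j] * dt)
            if abs(positions[j, 0]) > divergence_bound or abs(positions[j, 1]) > divergence_bound:
                return step
        out_pos[step] = positions
        out_phase[step] = phases
        out_gaze[step] = gazes
    return 0
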