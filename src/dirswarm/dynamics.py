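"""Right-hand sides of the coupled swarmalator ODE system.

Three interlocking dynamics, all first order:

* translation — global attraction to the origin, pairwise repulsion, and
  phase-and-gaze-gated attraction toward peers that are in phase and in view;
* rotation — the gaze azimuth is pulled toward proximal, phase-similar peers
  through the derivative of the gaze kernel;
* oscillation — the phase advances at the spontaneous frequency, entrained
  both to the external stimulus (auditory) and to visible peers (visual).

Every operation is vectorized over agents; pairwise sums exclude the
self-term exactly.  A naive double-loop reference used in the test suite
checks the vectorized forms term by term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    ModelParams,
    PairwiseGeometry,
    SwarmState,
    gaze_coupling,
    gaze_coupling_derivative,
    pairwise_geometry,
    phase_coupling,
)

__all__ = [
    "Derivatives",
    "attraction_velocity",
    "repulsion_velocity",
    "phase_gaze_velocity",
    "total_velocity",
    "gaze_rate",
    "auditory_phase_rate",
    "visual_phase_rate",
    "total_phase_rate",
    "evaluate_derivatives",
    "fused_rates",
]


@dataclass
class Derivatives:
    """Per-agent time derivatives, with the individual terms retrievable.

    ``velocity = v_attraction + v_repulsion + v_phase_gaze`` and
    ``phase_rate = spontaneous + auditory + visual`` hold exactly.
    """

    v_attraction: np.ndarray
    v_repulsion: np.ndarray
    v_phase_gaze: np.ndarray
    gaze_rate: np.ndarray
    phase_auditory: np.ndarray
    phase_visual: np.ndarray
    spontaneous: np.ndarray

    @property
    def velocity(self) -> np.ndarray:
        return self.v_attraction + self.v_repulsion + self.v_phase_gaze

    @property
    def phase_rate(self) -> np.ndarray:
        return self.spontaneous + self.phase_auditory + self.phase_visual


def _unit_vectors(state: SwarmState, geom: PairwiseGeometry) -> np.ndarray:
    """(N, N, 2) array of eps-guarded unit vectors from agent j to agent k."""
    diff = state.positions[None, :, :] - state.positions[:, None, :]
    dist = np.where(geom.offdiag, geom.distances, 1.0)
    return diff / dist[..., None]


def attraction_velocity(state: SwarmState, params: ModelParams) -> np.ndarray:
    """Global attraction toward the origin: ``-A * x * |x|**(a - 1)``."""
    a = params.attraction_exponent
    norms = np.linalg.norm(state.positions, axis=1)
    if a < 1.0:
        norms = np.maximum(norms, params.min_distance)
        scale = norms ** (a - 1.0)
    else:
        scale = np.where(norms > 0.0, norms ** (a - 1.0), 0.0)
    return -params.attraction_strength * state.positions * scale[:, None]


def repulsion_velocity(
    state: SwarmState, geom: PairwiseGeometry, params: ModelParams
) -> np.ndarray:
    """Pairwise repulsion keeping agents from coalescing.

    ``-(R / N) * sum_{k != j} w_kj**r * (x_k - x_j) / |x_k - x_j|``
    """
    n = state.n_agents
    if n == 1:
        return np.zeros((1, 2))
    w = geom.proximities**params.repulsion_decay
    w = np.where(geom.offdiag, w, 0.0)
    units = _unit_vectors(state, geom)
    return -(params.repulsion_strength / n) * np.einsum("jk,jkc->jc", w, units)


def phase_gaze_velocity(
    state: SwarmState, geom: PairwiseGeometry, params: ModelParams
) -> np.ndarray:
    """Attraction toward peers gated by phase similarity and visual field.

    ``(P / N) * sum_{k != j} w_kj**p * Omega(th_k - th_j) *
    Upsilon(alpha_kj - delta_j) * unit(j -> k)``
    """
    n = state.n_agents
    if n == 1:
        return np.zeros((1, 2))
    w = geom.proximities**params.pg_spatial_decay
    omega = phase_coupling(state.phases[None, :] - state.phases[:, None])
    upsilon = gaze_coupling(geom.azimuths - state.gazes[:, None], params.constriction)
    weight = np.where(geom.offdiag, w * omega * upsilon, 0.0)
    units = _unit_vectors(state, geom)
    return (params.pg_attraction_strength / n) * np.einsum("jk,jkc->jc", weight, units)


def total_velocity(
    state: SwarmState, geom: PairwiseGeometry, params: ModelParams
) -> np.ndarray:
    """Sum of attraction, repulsion, and phase-gaze attraction terms."""
    return (
        attraction_velocity(state, params)
        + repulsion_velocity(state, geom, params)
        + phase_gaze_velocity(state, geom, params)
    )


def gaze_rate(state: SwarmState, geom: PairwiseGeometry, params: ModelParams) -> np.ndarray:
    """Rotation rate of the gaze azimuth toward proximal, phase-similar peers.

    ``(D / N) * sum_{k != j} w_kj**d * Upsilon'(alpha_kj - delta_j) *
    Omega(th_k - th_j)``
    """
    n = state.n_agents
    if n == 1:
        return np.zeros(1)
    w = geom.proximities**params.gaze_spatial_decay
    omega = phase_coupling(state.phases[None, :] - state.phases[:, None])
    upsilon_d = gaze_coupling_derivative(
        geom.azimuths - state.gazes[:, None],
        params.constriction,
        normalized=params.normalized_gaze_derivative,
    )
    weight = np.where(geom.offdiag, w * upsilon_d * omega, 0.0)
    return (params.gaze_strength / n) * weight.sum(axis=1)


def auditory_phase_rate(state: SwarmState, params: ModelParams) -> np.ndarray:
    """Entrainment to the external stimulus: ``U * sin(phi_j - th_j)``."""
    return params.auditory_strength * np.sin(state.stimulus_phases - state.phases)


def visual_phase_rate(
    state: SwarmState, geom: PairwiseGeometry, params: ModelParams
) -> np.ndarray:
    """Entrainment to visible peers.

    ``(V / N) * sum_{k != j} w_kj**v * Upsilon(alpha_kj - delta_j) *
    sin(th_k - th_j)``
    """
    n = state.n_agents
    if n == 1:
        return np.zeros(1)
    w = geom.proximities**params.visual_spatial_decay
    upsilon = gaze_coupling(geom.azimuths - state.gazes[:, None], params.constriction)
    sin_diff = np.sin(state.phases[None, :] - state.phases[:, None])
    weight = np.where(geom.offdiag, w * upsilon * sin_diff, 0.0)
    return (params.visual_strength / n) * weight.sum(axis=1)


def total_phase_rate(
    state: SwarmState, geom: PairwiseGeometry, params: ModelParams
) -> np.ndarray:
    """Phase rate: spontaneous frequency plus auditory and visual entrainment."""
    return (
        state.spontaneous_freqs
        + auditory_phase_rate(state, params)
        + visual_phase_rate(state, geom, params)
    )


def _pow(w: np.ndarray, e: float) -> np.ndarray:
    if e == 1.0:
        return w
    if e == 2.0:
        return w * w
    return w**e


def fused_rates(
    state: SwarmState, params: ModelParams, geom: PairwiseGeometry | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-pass evaluation of (velocity, gaze rate, phase rate).

    Numerically identical to summing the modular terms, but shares the
    pairwise arrays (distances, kernels, unit vectors) across all three
    dynamics — the hot path of the Euler integrator.
    """
    from .model_core import gaze_kernel_norm

    n = state.n_agents
    p = params
    if geom is None:
        geom = pairwise_geometry(state.positions, p.min_distance)
    x, theta, delta = state.positions, state.phases, state.gazes

    # attraction to origin
    norms = np.linalg.norm(x, axis=1)
    if p.attraction_exponent < 1.0:
        scale = np.maximum(norms, p.min_distance) ** (p.attraction_exponent - 1.0)
    elif p.attraction_exponent == 1.0:
        scale = np.ones(n)
    else:
        scale = np.where(norms > 0.0, norms ** (p.attraction_exponent - 1.0), 0.0)
    vel = -p.attraction_strength * x * scale[:, None]

    if n > 1:
        w = geom.proximities
        off = geom.offdiag
        diff = x[None, :, :] - x[:, None, :]
        dist_safe = np.where(off, geom.distances, 1.0)
        units = diff / dist_safe[..., None]

        dtheta = theta[None, :] - theta[:, None]
        omega_k = 0.5 * (1.0 + np.cos(dtheta))
        rel = geom.azimuths - delta[:, None]
        base = 0.5 * (1.0 + np.cos(rel))
        c = p.constriction
        base_c = base**c
        norm_const = gaze_kernel_norm(float(c))
        upsilon = base_c / norm_const
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            base_cm1 = np.where(base > 0.0, base_c / base, 0.0)
        upsilon_d = 0.5 * c * np.sin(rel) * base_cm1
        upsilon_d = np.where(base == 0.0, 0.0, upsilon_d)
        if p.normalized_gaze_derivative:
            upsilon_d = upsilon_d / norm_const

        rep_w = np.where(off, _pow(w, p.repulsion_decay), 0.0)
        pg_w = np.where(off, _pow(w, p.pg_spatial_decay) * omega_k * upsilon, 0.0)
        vel += np.einsum(
            "jk,jkc->jc",
            p.pg_attraction_strength / n * pg_w - p.repulsion_strength / n * rep_w,
            units,
        )
        gz_w = np.where(off, _pow(w, p.gaze_spatial_decay) * upsilon_d * omega_k, 0.0)
        drate = (p.gaze_strength / n) * gz_w.sum(axis=1)
        vis_w = np.where(off, _pow(w, p.visual_spatial_decay) * upsilon * np.sin(dtheta), 0.0)
        visual = (p.visual_strength / n) * vis_w.sum(axis=1)
    else:
        drate = np.zeros(1)
        visual = np.zeros(1)

    prate = (
        state.spontaneous_freqs
        + p.auditory_strength * np.sin(state.stimulus_phases - theta)
        + visual
    )
    return vel, drate, prate


def evaluate_derivatives(
    state: SwarmState, params: ModelParams, geom: PairwiseGeometry | None = None
) -> Derivatives:
    """Evaluate every term of the dynamics at one state.

    Computes the pairwise geometry once and shares it across all terms.
    """
    if geom is None:
        geom = pairwise_geometry(state.positions, params.min_distance)
    return Derivatives(
        v_attraction=attraction_velocity(state, params),
        v_repulsion=repulsion_velocity(state, geom, params),
        v_phase_gaze=phase_gaze_velocity(state, geom, params),
        gaze_rate=gaze_rate(state, geom, params),
        phase_auditory=auditory_phase_rate(state, params),
        phase_visual=visual_phase_rate(state, geom, params),
        spontaneous=state.spontaneous_freqs.copy(),
    )
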