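"""Domain types, angle conventions, and coupling kernels of the directional swarmalator model.

A directional swarmalator is an agent that simultaneously swarms (moves in
the plane under attraction/repulsion), oscillates (carries a phase entrained
to an external beat and to visible peers), and gazes (carries a heading that
restricts which peers it attends to).  This module holds the shared state
containers, the angle conventions used throughout the package, pairwise
geometry, and the two coupling kernels:

* the phase coupling function ``Omega(theta) = (1 + cos theta) / 2``, a raised
  cosine that is 1 for phase-aligned pairs and 0 for antiphase pairs;
* the gaze coupling function ``Upsilon(theta; c)``, the same raised cosine
  taken to the power of the *constriction* exponent ``c`` and normalized so
  its integral over a full turn is 1.  Larger ``c`` narrows the effective
  visual field around the gaze direction.

Angle convention: radians, counterclockwise positive, azimuths measured from
the +x axis, all wrapped to the half-open interval ``(-pi, pi]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import integrate

__all__ = [
    "ModelParams",
    "SwarmState",
    "PairwiseGeometry",
    "wrap_angle",
    "pairwise_geometry",
    "phase_coupling",
    "gaze_coupling",
    "gaze_coupling_derivative",
    "gaze_kernel_norm",
]

#: Mean spontaneous bounce frequency: the 120 BPM tactus, i.e. 2 Hz.
DEFAULT_FREQ_MEAN = 2.0 * np.pi * 2.0
#: Spread of spontaneous frequencies across agents (rad/s).
DEFAULT_FREQ_SD = 0.2


@dataclass
class ModelParams:
    """All coupling constants and exponents of the directional swarmalator model.

    Defaults are the fixed values used for model fitting, with the two fitted
    rotational parameters (``constriction`` and ``gaze_strength``) at their
    rounded optimum of 0.25 each.

    Parameters
    ----------
    attraction_strength : float
        Global attraction toward the origin, ``A`` (s^-1).
    attraction_exponent : float
        Growth exponent ``a`` of attraction with distance from origin.
    repulsion_strength : float
        Pairwise repulsion strength ``R`` (s^-1).
    repulsion_decay : float
        Spatial decay exponent ``r`` of repulsion (acts on proximity).
    pg_attraction_strength : float
        Phase-and-gaze-dependent attraction strength ``P`` (s^-1).
    pg_spatial_decay : float
        Spatial decay exponent ``p`` of phase-and-gaze attraction.
    gaze_strength : float
        Rotational coupling strength (s^-1); the fitted quantity usually
        written ``g`` and entering the gaze equation as ``D``.
    gaze_spatial_decay : float
        Spatial decay exponent ``d`` of rotational coupling.
    auditory_strength : float
        Entrainment strength ``U`` to the external stimulus (s^-1).
    visual_strength : float
        Entrainment strength ``V`` to visible peers (s^-1).
    visual_spatial_decay : float
        Spatial decay exponent ``v`` of visual entrainment.
    constriction : float
        Gaze-kernel exponent ``c`` >= 0; larger narrows the visual field.
    freq_mean, freq_sd : float
        Mean and SD of the Normal distribution of spontaneous angular
        frequencies (rad/s).
    min_distance : float
        Collision guard ``eps``: pairwise distances are clipped below at this
        value so proximities never overflow.
    normalized_gaze_derivative : bool
        If True, divide the gaze-kernel derivative by the same normalization
        constant as the kernel itself (sensitivity-analysis variant); the
        default uses the unnormalized closed form.
    """

    attraction_strength: float = 0.1
    attraction_exponent: float = 1.0
    repulsion_strength: float = 1.5
    repulsion_decay: float = 2.0
    pg_attraction_strength: float = 0.5
    pg_spatial_decay: float = 1.0
    gaze_strength: float = 0.25
    gaze_spatial_decay: float = 1.0
    auditory_strength: float = 0.8
    visual_strength: float = 0.4
    visual_spatial_decay: float = 1.0
    constriction: float = 0.25
    freq_mean: float = DEFAULT_FREQ_MEAN
    freq_sd: float = DEFAULT_FREQ_SD
    min_distance: float = 1e-6
    normalized_gaze_derivative: bool = False

    def __post_init__(self) -> None:
        nonneg = (
            "attraction_strength",
            "repulsion_strength",
            "pg_attraction_strength",
            "gaze_strength",
            "auditory_strength",
            "visual_strength",
            "constriction",
            "freq_sd",
            "min_distance",
        )
        for name in nonneg:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    def with_fit_params(self, c: float, g: float) -> "ModelParams":
        """Return a copy with constriction ``c`` and gaze strength ``g`` replaced."""
        return replace(self, constriction=float(c), gaze_strength=float(g))


@dataclass
class SwarmState:
    """Instantaneous state of the whole swarm.

    Arrays are aligned by agent index: ``positions`` is (N, 2); ``phases``,
    ``gazes``, ``spontaneous_freqs``, ``stimulus_phases`` and ``group_ids``
    are (N,).  Angles are radians; gazes are kept wrapped to (-pi, pi].
    """

    positions: np.ndarray
    phases: np.ndarray
    gazes: np.ndarray
    spontaneous_freqs: np.ndarray
    stimulus_phases: np.ndarray
    group_ids: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        for name in ("phases", "gazes", "spontaneous_freqs", "stimulus_phases"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        self.group_ids = np.atleast_1d(np.asarray(self.group_ids, dtype=int))
        n = self.positions.shape[0]
        if self.positions.shape != (n, 2):
            raise ValueError(f"positions must be (N, 2), got {self.positions.shape}")
        for name in ("phases", "gazes", "spontaneous_freqs", "stimulus_phases", "group_ids"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        for name in ("positions", "phases", "gazes", "spontaneous_freqs", "stimulus_phases"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SwarmState":
        return SwarmState(
            positions=self.positions.copy(),
            phases=self.phases.copy(),
            gazes=self.gazes.copy(),
            spontaneous_freqs=self.spontaneous_freqs.copy(),
            stimulus_phases=self.stimulus_phases.copy(),
            group_ids=self.group_ids.copy(),
        )


@dataclass
class PairwiseGeometry:
    """Pairwise distances, proximities, and azimuths for one swarm snapshot.

    Entry ``[j, k]`` refers to the pair (observer j, target k):
    ``azimuths[j, k]`` is the angle of the vector from agent j to agent k.
    Proximity is inverse distance, ``w[j, k] = 1 / max(|x_k - x_j|, eps)``.
    Diagonal entries are masked: distances/proximities are 0 there and must
    never enter a sum over ``k != j``.
    """

    distances: np.ndarray
    proximities: np.ndarray
    azimuths: np.ndarray
    offdiag: np.ndarray = field(repr=False)


def wrap_angle(angle):
    """Wrap angle(s) to the half-open interval ``(-pi, pi]``.

    Accepts scalars or arrays; preserves shape.  Non-finite input is rejected.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_angle requires finite input")
    # map to [-pi, pi) then flip the boundary so -pi lands on +pi
    wrapped = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@lru_cache(maxsize=64)
def _offdiag_mask(n: int) -> np.ndarray:
    mask = ~np.eye(n, dtype=bool)
    mask.setflags(write=False)
    return mask


def pairwise_geometry(positions: np.ndarray, min_distance: float = 1e-6) -> PairwiseGeometry:
    """Compute pairwise distances, proximities, and azimuths for ``positions``.

    Distances are clipped below at ``min_distance`` so coincident agents do
    not produce infinite proximities.  Azimuths use the two-argument
    arctangent, counterclockwise from the +x axis.
    """
    x = np.atleast_2d(np.asarray(positions, dtype=float))
    n = x.shape[0]
    diff = x[None, :, :] - x[:, None, :]  # diff[j, k] = x_k - x_j
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    offdiag = _offdiag_mask(n)
    dist_clipped = np.maximum(dist, min_distance)
    prox = np.where(offdiag, 1.0 / dist_clipped, 0.0)
    azim = np.arctan2(diff[..., 1], diff[..., 0])
    return PairwiseGeometry(
        distances=np.where(offdiag, dist_clipped, 0.0),
        proximities=prox,
        azimuths=azim,
        offdiag=offdiag,
    )


def phase_coupling(phase_diff):
    """Raised-cosine phase coupling ``Omega(theta) = (1 + cos theta) / 2``.

    1 for phase-aligned pairs, 0 for antiphase; even and 2*pi-periodic.
    """
    return 0.5 * (1.0 + np.cos(phase_diff))


@lru_cache(maxsize=128)
def gaze_kernel_norm(c: float) -> float:
    """Normalization constant of the gaze kernel: integral of the raised
    cosine to the power ``c`` over a full turn.

    Closed form for c = 0 (2*pi) and c = 1 (pi); adaptive quadrature
    otherwise, cached per constriction value.
    """
    if c < 0:
        raise ValueError(f"constriction must be >= 0, got {c}")
    if c == 0.0:
        return 2.0 * np.pi
    if c == 1.0:
        return np.pi
    val, _ = integrate.quad(
        lambda t: (0.5 * (1.0 + np.cos(t))) ** c, -np.pi, np.pi, limit=200
    )
    return val


def gaze_coupling(angle, c: float):
    """Normalized gaze kernel ``Upsilon(theta; c)``.

    The raised cosine to the power ``c``, divided by its integral over
    ``(-pi, pi]`` so that the kernel is a density on the circle regardless of
    ``c``.  ``c = 0`` gives the uniform density 1/(2*pi) (panoramic vision);
    increasing ``c`` concentrates the kernel around 0 (narrow visual field).
    """
    if c < 0:
        raise ValueError(f"constriction must be >= 0, got {c}")
    base = 0.5 * (1.0 + np.cos(angle))
    return base**c / gaze_kernel_norm(float(c))


def gaze_coupling_derivative(angle, c: float, normalized: bool = False):
    """Angular derivative kernel driving gaze rotation.

    The default is the closed form
    ``(c * sin(theta) / 2) * ((1 + cos theta) / 2)**(c - 1)``
    with a positive sign, so gaze rotates *toward* attractive targets.  With
    ``normalized=True`` the result is additionally divided by the gaze-kernel
    normalization constant, making it (up to sign) the exact derivative of
    :func:`gaze_coupling`.

    Values at the exact rear direction (theta = pi), where the closed form is
    0 * inf for c < 1, are defined as 0 by odd symmetry.
    """
    if c < 0:
        raise ValueError(f"constriction must be >= 0, got {c}")
    theta = np.asarray(angle, dtype=float)
    base = 0.5 * (1.0 + np.cos(theta))
    sin_t = np.sin(theta)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = 0.5 * c * sin_t * base ** (c - 1.0)
    out = np.where(base == 0.0, 0.0, out)
    if normalized:
        out = out / gaze_kernel_norm(float(c))
    if np.ndim(angle) == 0:
        return float(out)
    return out
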