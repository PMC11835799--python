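"""Synthetic silent-disco scenarios for tests, examples, and calibration checks.

The reference setting is a silent disco: 12 dancers split into two stimulus
groups, each group hearing a 120 BPM bounce beat where the second group's
beat is phase-shifted (90 or 180 degrees) or sped up.  These generators
produce (a) random initial swarm configurations, (b) synthetic head-marker
recordings of agents bouncing to their beat, and (c) complete calibration
scenarios with known ground-truth rotational parameters.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_core import ModelParams, SwarmState, wrap_angle
from .simulator import StimulusSchedule, run_simulation

__all__ = [
    "ScenarioSpec",
    "build_schedule",
    "generate_initial_config",
    "generate_bounce_markers",
    "generate_calibration_scenario",
    "generate_calibration_suite",
]

#: SD of the initial phase jitter around the assigned stimulus phase (rad).
PHASE_JITTER_SD = 0.2


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic silent-disco scenario.

    Defaults emulate the reference setting: 12 agents in two groups of 6,
    120 BPM beat, the second group phase-shifted by 180 degrees.  Setting
    ``freq_ratio != 1`` instead gives the second group a sped-up beat.
    ``arena_radius`` bounds the uniform disc of initial positions; 3 length
    units keeps interagent distances of order 1 under the default
    attraction/repulsion balance.
    """

    n_agents: int = 12
    group_sizes: Optional[Sequence[int]] = None
    bpm: float = 120.0
    phase_shift_deg: float = 180.0
    freq_ratio: float = 1.0
    arena_radius: float = 3.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            half = self.n_agents // 2
            self.group_sizes = (half, self.n_agents - half)
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if sum(self.group_sizes) != self.n_agents:
            raise ValueError("group sizes must sum to n_agents")
        if not self.bpm > 0:
            raise ValueError(f"bpm must be > 0, got {self.bpm}")
        if not self.freq_ratio > 0:
            raise ValueError(f"freq_ratio must be > 0, got {self.freq_ratio}")

    @property
    def beat_hz(self) -> float:
        return self.bpm / 60.0

    @property
    def group_ids(self) -> np.ndarray:
        return np.repeat(
            np.arange(1, len(self.group_sizes) + 1), self.group_sizes
        )


def build_schedule(spec: ScenarioSpec) -> StimulusSchedule:
    """Stimulus schedule for a scenario: group 1 hears the unshifted beat,
    group 2 the phase-shifted (and optionally sped-up) one."""
    f1 = spec.beat_hz
    freqs = {1: f1}
    offsets = {1: 0.0}
    if len(spec.group_sizes) > 1:
        freqs[2] = f1 * spec.freq_ratio
        offsets[2] = np.deg2rad(spec.phase_shift_deg)
    return StimulusSchedule(group_freqs_hz=freqs, group_offsets_rad=offsets)


def generate_initial_config(
    spec: ScenarioSpec, params: Optional[ModelParams] = None
) -> SwarmState:
    """Random initial swarm state for a scenario.

    Positions uniform in a disc of ``arena_radius``; gazes uniform on the
    circle; phases at the assigned stimulus phase at t = 0 plus small
    Gaussian jitter; spontaneous frequencies Normal(freq_mean, freq_sd).
    Deterministic per ``spec.seed``.
    """
    params = params or ModelParams()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_agents
    radii = spec.arena_radius * np.sqrt(rng.uniform(size=n))
    angles = rng.uniform(-np.pi, np.pi, size=n)
    positions = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    gazes = rng.uniform(-np.pi, np.pi, size=n)
    group_ids = spec.group_ids
    schedule = build_schedule(spec)
    stim0 = schedule.phases_at(group_ids, 0.0)
    phases = wrap_angle(stim0 + rng.normal(0.0, PHASE_JITTER_SD, size=n))
    omegas = rng.normal(params.freq_mean, params.freq_sd, size=n)
    return SwarmState(
        positions=positions,
        phases=phases,
        gazes=gazes,
        spontaneous_freqs=omegas,
        stimulus_phases=stim0,
        group_ids=group_ids,
    )


def generate_bounce_markers(
    spec: ScenarioSpec,
    duration: float = 10.0,
    rate: float = 120.0,
    bounce_amplitude: float = 0.05,
    marker_halfwidth: float = 0.08,
    drift_sd: float = 0.1,
    noise_sd: float = 0.0,
):
    """Synthetic two-marker head recordings of agents bouncing to their beat.

    Each agent's head midpoint drifts slowly in the horizontal plane while
    its vertical coordinate oscillates sinusoidally at the agent's stimulus
    frequency and offset, ``z = z0 + amplitude * sin(phi(t))``, so the
    recoverable bounce phase equals the stimulus phase.  The two markers sit
    at a fixed horizontal half-width either side of the midpoint,
    perpendicular to a per-agent facing direction.  Optional Gaussian noise
    of ``noise_sd`` is added to every coordinate.  Deterministic per seed.

    Returns a :class:`~dirswarm.empirical.MarkerSeries`.
    """
    from .empirical import MarkerSeries  # deferred: avoids import cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_agents
    times = np.arange(int(round(duration * rate)) + 1) / rate
    t_frames = times.size
    schedule = build_schedule(spec)
    group_ids = spec.group_ids

    base = generate_initial_config(spec)
    centers = base.positions  # (N, 2)
    facing = base.gazes  # (N,)
    # slow horizontal drift: smoothed random walk around the initial center
    drift = rng.normal(0.0, drift_sd / np.sqrt(rate), size=(t_frames, n, 2)).cumsum(axis=0)
    midpoints = centers[None, :, :] + drift

    phi = np.stack([schedule.phases_at(group_ids, t) for t in times])  # unwrapped not needed
    z = 1.6 + bounce_amplitude * np.sin(phi)  # head height ~1.6 length units

    # marker offset: perpendicular-left of facing is facing + 90 deg
    perp = facing + 0.5 * np.pi
    offset = marker_halfwidth * np.column_stack([np.cos(perp), np.sin(perp)])  # (N, 2)
    left_h = midpoints + offset[None, :, :]
    right_h = midpoints - offset[None, :, :]
    left = np.concatenate([left_h, z[:, :, None]], axis=-1)
    right = np.concatenate([right_h, z[:, :, None]], axis=-1)
    if noise_sd > 0:
        left = left + rng.normal(0.0, noise_sd, size=left.shape)
        right = right + rng.normal(0.0, noise_sd, size=right.shape)
    return MarkerSeries(
        times=times,
        agent_ids=np.arange(n),
        group_ids=group_ids,
        left=left,
        right=right,
    )


def generate_calibration_scenario(
    spec: ScenarioSpec,
    c_true: float,
    g_true: float,
    seed: Optional[int] = None,
    params: Optional[ModelParams] = None,
    duration: float = 60.0,
    dt: float = 1.0 / 120.0,
    average_last_s: float = 0.0,
    dataset_id: str = "synthetic",
):
    """Build a calibration dataset with known ground-truth (c, g).

    Simulates a scenario from a random initial configuration under
    ``(c_true, g_true)`` and packages the target metrics (end-of-run, or
    averaged over the trailing ``average_last_s`` seconds) together with the
    initial state and schedule, so the composite error at the generating
    parameters is exactly zero.
    """
    from .calibration import (
        CalibrationDataset,
        CalibrationTargets,
        SimSettings,
        evaluate_configuration_metrics,
    )

    if not (0.0 <= c_true and 0.0 <= g_true):
        raise ValueError("c_true and g_true must be >= 0")
    base_params = (params or ModelParams()).with_fit_params(c_true, g_true)
    if seed is not None:
        spec = ScenarioSpec(**{**spec.__dict__, "seed": seed})
    initial = generate_initial_config(spec, base_params)
    schedule = build_schedule(spec)
    settings = SimSettings(duration=duration, dt=dt, average_last_s=average_last_s)
    sv, rho, chi = evaluate_configuration_metrics(initial, schedule, base_params, settings)
    dataset = CalibrationDataset(
        dataset_id=dataset_id,
        initial_state=initial,
        schedule=schedule,
        target_spatial_variance=sv,
        target_rho=rho,
        target_chi=chi,
    )
    return CalibrationTargets(datasets=[dataset], sim_settings=settings)


def generate_calibration_suite(
    c_true: float,
    g_true: float,
    seed: int,
    base_spec: Optional[ScenarioSpec] = None,
    phase_shifts_deg: Sequence[float] = (90.0, 180.0, 90.0, 180.0),
    params: Optional[ModelParams] = None,
    duration: float = 60.0,
    dt: float = 1.0 / 120.0,
    average_last_s: float = 0.0,
):
    """Multi-dataset calibration targets with known ground-truth (c, g).

    Emulates a joint fit over several recordings: one dataset per entry of
    ``phase_shifts_deg`` (default four — two 90-degree and two 180-degree
    phase-shift conditions), each with its own derived seed, initial
    configuration, and spontaneous frequencies.  Fitting jointly over
    several independent configurations is what pins down both rotational
    parameters; a single dataset's three summary metrics generally do not.
    """
    from .calibration import CalibrationTargets, SimSettings

    base_spec = base_spec or ScenarioSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(phase_shifts_deg))
    datasets = []
    for i, (shift, child) in enumerate(zip(phase_shifts_deg, child_seeds)):
        spec = ScenarioSpec(
            **{
                **base_spec.__dict__,
                "phase_shift_deg": float(shift),
                "seed": int(child % (2**31)),
            }
        )
        single = generate_calibration_scenario(
            spec, c_true, g_true, params=params, duration=duration, dt=dt,
            average_last_s=average_last_s, dataset_id=f"shift{int(shift)}_{i}",
        )
        datasets.append(single.datasets[0])
    return CalibrationTargets(
        datasets=datasets,
        sim_settings=SimSettings(duration=duration, dt=dt, average_last_s=average_last_s),
    )
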