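"""Stimulus schedules and fixed-step Euler integration of the swarmalator ODEs.

The external stimulus is a per-group beat: each group hears a metronome-like
rhythm with its own frequency and phase offset (the silent-disco
manipulation).  The stimulus phase is not integrated — it is re-evaluated
from the schedule at every step, so it tracks the beat exactly.

Integration is forward Euler at a fixed step, 1/120 s by default to match
120 Hz motion capture; a 60 s run therefore spans 7201 frames.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from ._kernels import HAVE_NUMBA, integrate_loop
from .dynamics import fused_rates
from .model_core import gaze_kernel_norm
from .model_core import ModelParams, SwarmState, pairwise_geometry, wrap_angle

__all__ = [
    "StimulusSchedule",
    "Trajectory",
    "stimulus_phase",
    "euler_step",
    "run_simulation",
    "write_state_csv",
    "read_state_csv",
]

DEFAULT_DT = 1.0 / 120.0
DEFAULT_DIVERGENCE_BOUND = 1e3

STATE_COLUMNS = [
    "time_s",
    "agent_id",
    "group_id",
    "x",
    "y",
    "theta_rad",
    "delta_rad",
    "omega_rad_s",
    "phi_rad",
]


@dataclass
class StimulusSchedule:
    """Per-group beat frequency (Hz) and phase offset (rad).

    ``group_freqs_hz`` and ``group_offsets_rad`` are keyed by group id; every
    agent's group id must appear in both.  120 BPM corresponds to 2 Hz.
    """

    group_freqs_hz: Mapping[int, float]
    group_offsets_rad: Mapping[int, float]

    def __post_init__(self) -> None:
        self.group_freqs_hz = {int(k): float(v) for k, v in self.group_freqs_hz.items()}
        self.group_offsets_rad = {
            int(k): float(wrap_angle(v)) for k, v in self.group_offsets_rad.items()
        }
        if set(self.group_freqs_hz) != set(self.group_offsets_rad):
            raise ValueError("frequency and offset group ids must match")
        for gid, f in self.group_freqs_hz.items():
            if not f > 0:
                raise ValueError(f"beat frequency for group {gid} must be > 0, got {f}")

    def _agent_arrays(self, group_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        freqs = np.array([self._freq(g) for g in np.asarray(group_ids)])
        offs = np.array([self.group_offsets_rad[int(g)] for g in np.asarray(group_ids)])
        return freqs, offs

    def phases_at(self, group_ids: np.ndarray, t: float) -> np.ndarray:
        """Vectorized stimulus phase for each agent's group at time ``t``."""
        freqs, offs = self._agent_arrays(group_ids)
        return wrap_angle(2.0 * np.pi * freqs * t + offs)

    def phase_grid(self, group_ids: np.ndarray, times: np.ndarray) -> np.ndarray:
        """(T, N) stimulus phases for all agents across a whole time grid."""
        freqs, offs = self._agent_arrays(group_ids)
        return wrap_angle(
            2.0 * np.pi * freqs[None, :] * np.asarray(times)[:, None] + offs[None, :]
        )

    def _freq(self, group: int) -> float:
        try:
            return self.group_freqs_hz[int(group)]
        except KeyError:
            raise KeyError(f"unknown stimulus group id {group!r}") from None


def stimulus_phase(schedule: StimulusSchedule, group: int, t: float) -> float:
    """Beat phase ``wrap(2*pi*f_group*t + offset_group)`` at time ``t`` >= 0."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    f = schedule._freq(group)
    off = schedule.group_offsets_rad[int(group)]
    return float(wrap_angle(2.0 * np.pi * f * t + off))


@dataclass
class Trajectory:
    """Time-indexed record of a simulation run.

    ``times`` is (T,); ``positions`` is (T, N, 2); ``phases``, ``gazes`` and
    ``stimulus_phases`` are (T, N); ``spontaneous_freqs`` and ``group_ids``
    are (N,) (constant over the run).
    """

    times: np.ndarray
    positions: np.ndarray
    phases: np.ndarray
    gazes: np.ndarray
    stimulus_phases: np.ndarray
    spontaneous_freqs: np.ndarray
    group_ids: np.ndarray
    params: ModelParams
    seed: Optional[int] = None

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    def state_at(self, frame: int) -> SwarmState:
        """Reconstruct the :class:`SwarmState` at one frame index."""
        return SwarmState(
            positions=self.positions[frame].copy(),
            phases=self.phases[frame].copy(),
            gazes=self.gazes[frame].copy(),
            spontaneous_freqs=self.spontaneous_freqs.copy(),
            stimulus_phases=self.stimulus_phases[frame].copy(),
            group_ids=self.group_ids.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame-by-agent table using the state CSV schema."""
        t_frames, n = self.phases.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, n),
                "agent_id": np.tile(np.arange(n), t_frames),
                "group_id": np.tile(self.group_ids, t_frames),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "theta_rad": self.phases.ravel(),
                "delta_rad": self.gazes.ravel(),
                "omega_rad_s": np.tile(self.spontaneous_freqs, t_frames),
                "phi_rad": self.stimulus_phases.ravel(),
            }
        )


class SimulationDiverged(RuntimeError):
    """Raised when any agent leaves the configured arena bound."""


def _step_arrays(state: SwarmState, params: ModelParams, dt: float) -> None:
    """Advance positions, gazes, phases in place by one Euler step."""
    vel, drate, prate = fused_rates(state, params)
    for name, arr in (("velocity", vel), ("gaze rate", drate), ("phase rate", prate)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite {name} encountered in Euler step")
    state.positions += vel * dt
    state.gazes = _wrap_fast(state.gazes + drate * dt)
    state.phases = _wrap_fast(state.phases + prate * dt)


def _wrap_fast(a: np.ndarray) -> np.ndarray:
    """wrap_angle without the finiteness check (derivatives already checked)."""
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    w[w == -np.pi] = np.pi
    return w


def euler_step(
    state: SwarmState,
    schedule: StimulusSchedule,
    params: ModelParams,
    t: float,
    dt: float,
) -> SwarmState:
    """One forward-Euler step from time ``t`` to ``t + dt``.

    Positions, gazes and phases are advanced by their derivatives; the
    stimulus phase is re-evaluated from the schedule at ``t + dt`` rather
    than integrated.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    new = state.copy()
    _step_arrays(new, params, dt)
    new.stimulus_phases = schedule.phases_at(new.group_ids, t + dt)
    return new


def run_simulation(
    initial_state: SwarmState,
    schedule: StimulusSchedule,
    params: ModelParams,
    duration: float = 60.0,
    dt: float = DEFAULT_DT,
    seed: Optional[int] = None,
    divergence_bound: float = DEFAULT_DIVERGENCE_BOUND,
    engine: str = "auto",
) -> Trajectory:
    """Integrate the swarm for ``duration`` seconds with fixed step ``dt``.

    If the initial state's spontaneous frequencies are all zero they are
    drawn once from Normal(freq_mean, freq_sd) using ``seed``.  The run is
    deterministic given (inputs, seed).  Raises :class:`SimulationDiverged`
    naming the frame if any coordinate exceeds ``divergence_bound``.

    ``engine`` selects the integration loop: ``"compiled"`` (numba),
    ``"numpy"`` (reference stepper), or ``"auto"`` (compiled when
    available).  Both loops implement the identical update.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if engine not in ("auto", "compiled", "numpy"):
        raise ValueError(f"unknown engine {engine!r}")
    n_steps = int(round(duration / dt))
    state = initial_state.copy()
    if not np.any(state.spontaneous_freqs):
        rng = np.random.default_rng(seed)
        state.spontaneous_freqs = rng.normal(params.freq_mean, params.freq_sd, state.n_agents)

    n = state.n_agents
    times = np.arange(n_steps + 1) * dt
    positions = np.empty((n_steps + 1, n, 2))
    phases = np.empty((n_steps + 1, n))
    gazes = np.empty((n_steps + 1, n))
    stim = np.empty((n_steps + 1, n))

    stim[:] = schedule.phase_grid(state.group_ids, times)
    state.stimulus_phases = stim[0]
    positions[0], phases[0], gazes[0] = state.positions, state.phases, state.gazes

    use_compiled = engine == "compiled" or (engine == "auto" and HAVE_NUMBA)
    if engine == "compiled" and not HAVE_NUMBA:
        raise RuntimeError("compiled engine requested but numba is not importable")
    if use_compiled:
        p = params
        code = integrate_loop(
            state.positions,
            state.phases,
            state.gazes,
            state.spontaneous_freqs,
            stim,
            dt,
            p.attraction_strength,
            p.attraction_exponent,
            p.repulsion_strength,
            p.repulsion_decay,
            p.pg_attraction_strength,
            p.pg_spatial_decay,
            p.gaze_strength,
            p.gaze_spatial_decay,
            p.auditory_strength,
            p.visual_strength,
            p.visual_spatial_decay,
            p.constriction,
            p.min_distance,
            gaze_kernel_norm(float(p.constriction)),
            p.normalized_gaze_derivative,
            divergence_bound,
            positions,
            phases,
            gazes,
        )
        if code < 0:
            raise FloatingPointError(f"non-finite derivative encountered at frame {-code}")
        if code > 0:
            raise SimulationDiverged(
                f"position magnitude exceeded {divergence_bound} at frame {code}"
            )
    else:
        for i in range(1, n_steps + 1):
            _step_arrays(state, params, dt)
            state.stimulus_phases = stim[i]
            if np.max(np.abs(state.positions)) > divergence_bound:
                raise SimulationDiverged(
                    f"position magnitude exceeded {divergence_bound} at frame {i}"
                )
            positions[i], phases[i], gazes[i] = state.positions, state.phases, state.gazes
    return Trajectory(
        times=times,
        positions=positions,
        phases=phases,
        gazes=gazes,
        stimulus_phases=stim,
        spontaneous_freqs=state.spontaneous_freqs.copy(),
        group_ids=state.group_ids.copy(),
        params=params,
        seed=seed,
    )


def _header_comment(meta: Optional[dict] = None) -> str:
    payload = repr(sorted((meta or {}).items())).encode()
    digest = hashlib.sha256(payload).hexdigest()[:12]
    return f"# dirswarm {__version__} config_hash={digest}\n"


def write_state_csv(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a state table in the standard CSV schema with a metadata header."""
    missing = [c for c in STATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state table missing columns: {missing}")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(meta))
        df[STATE_COLUMNS].to_csv(fh, index=False)


def read_state_csv(path) -> pd.DataFrame:
    """Read a state CSV written by :func:`write_state_csv` (or compatible)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in STATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state CSV {path} missing columns: {missing}")
    return df


def trajectory_from_dataframe(df: pd.DataFrame, params: Optional[ModelParams] = None) -> Trajectory:
    """Rebuild a :class:`Trajectory` from a long-format state table."""
    df = df.sort_values(["time_s", "agent_id"], kind="stable")
    times = np.sort(df["time_s"].unique())
    agents = np.sort(df["agent_id"].unique())
    t_frames, n = times.size, agents.size
    if len(df) != t_frames * n:
        raise ValueError("state table is not a complete frame-by-agent grid")

    def grid(col):
        return df[col].to_numpy().reshape(t_frames, n)

    first = df.iloc[:n]
    return Trajectory(
        times=times,
        positions=np.stack([grid("x"), grid("y")], axis=-1),
        phases=grid("theta_rad"),
        gazes=grid("delta_rad"),
        stimulus_phases=np.nan_to_num(grid("phi_rad")),
        spontaneous_freqs=np.nan_to_num(first["omega_rad_s"].to_numpy(dtype=float)),
        group_ids=first["group_id"].to_numpy(dtype=int),
        params=params or ModelParams(),
    )
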