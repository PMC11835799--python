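"""Estimating swarmalator state variables from head-marker motion capture.

Each participant wears two reflective markers on the head (left and right).
From these the model's observable state is recovered:

* position — the horizontal midpoint of the two markers;
* gaze azimuth — the right-to-left marker vector rotated by -90 deg, so the
  gaze points out of the face (configurable to +90 deg for mirrored rigs);
* oscillation phase — the argument of the analytic signal of the vertical
  head velocity.  In spontaneous dance the vertical head velocity tends to
  lock to the tactus-level beat, so its instantaneous Hilbert phase serves
  as the bounce phase.

Input is a long-format TSV/CSV with columns ``time_s, agent_id, group_id,
marker (L|R), x, y, z`` on a uniform time grid (nominally 120 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .model_core import wrap_angle
from .simulator import STATE_COLUMNS, write_state_csv

__all__ = [
    "MarkerSeries",
    "EmpiricalStateSeries",
    "read_marker_series",
    "write_marker_series",
    "estimate_position_gaze",
    "estimate_phase_hilbert",
    "empirical_states",
]

MARKER_COLUMNS = ["time_s", "agent_id", "group_id", "marker", "x", "y", "z"]

#: Seconds trimmed at each end of the Hilbert phase estimate (end effects).
EDGE_TRIM_S = 0.5


@dataclass
class MarkerSeries:
    """Uniformly sampled left/right head-marker coordinates per agent.

    ``left`` and ``right`` are (T, N, 3) arrays in the order of
    ``agent_ids``; ``times`` is (T,) seconds.
    """

    times: np.ndarray
    agent_ids: np.ndarray
    group_ids: np.ndarray
    left: np.ndarray
    right: np.ndarray

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def n_agents(self) -> int:
        return self.agent_ids.shape[0]


@dataclass
class EmpiricalStateSeries:
    """Per-frame model state estimated from markers.

    ``positions`` (T, N, 2), ``gazes`` (T, N), ``phases`` (T, N); ``valid``
    flags frames outside the Hilbert edge-trim window.
    """

    times: np.ndarray
    agent_ids: np.ndarray
    group_ids: np.ndarray
    positions: np.ndarray
    gazes: np.ndarray
    phases: np.ndarray
    valid: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        t_frames, n = self.phases.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, n),
                "agent_id": np.tile(self.agent_ids, t_frames),
                "group_id": np.tile(self.group_ids, t_frames),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "theta_rad": self.phases.ravel(),
                "delta_rad": self.gazes.ravel(),
                "omega_rad_s": np.nan,
                "phi_rad": np.nan,
            }
        )

    def write_csv(self, path) -> None:
        write_state_csv(self.to_dataframe(), path, meta={"source": "empirical"})


def read_marker_series(path, max_gap_frames: int = 12, time_tol: float = 1e-4) -> MarkerSeries:
    """Read and validate a marker TSV/CSV into a :class:`MarkerSeries`.

    Delimiter is inferred from the extension (``.tsv`` -> tab).  The time
    grid must be uniform within ``time_tol`` s.  Missing frames inside gaps
    of at most ``max_gap_frames`` are filled by linear interpolation;
    longer gaps raise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker file {path} missing column(s): {missing}")
    return _marker_series_from_df(df, max_gap_frames, time_tol)


def _marker_series_from_df(
    df: pd.DataFrame, max_gap_frames: int = 12, time_tol: float = 1e-4
) -> MarkerSeries:
    bad = set(df["marker"].unique()) - {"L", "R"}
    if bad:
        raise ValueError(f"marker labels must be L or R, got extra {sorted(bad)}")
    times = np.sort(df["time_s"].unique())
    if times.size < 2:
        raise ValueError("marker series needs at least 2 frames")
    steps = np.diff(times)
    if np.max(np.abs(steps - np.median(steps))) > time_tol:
        raise ValueError("non-uniform time grid beyond tolerance")
    agents = np.sort(df["agent_id"].unique())
    gid_map = df.drop_duplicates("agent_id").set_index("agent_id")["group_id"]
    t_frames, n = times.size, agents.size
    t_index = pd.Index(times, name="time_s")
    out = {}
    for side in ("L", "R"):
        arr = np.full((t_frames, n, 3), np.nan)
        sub = df[df["marker"] == side]
        for ai, agent in enumerate(agents):
            block = sub[sub["agent_id"] == agent].set_index("time_s")[["x", "y", "z"]]
            block = block.reindex(t_index)
            n_missing = int(block["x"].isna().sum())
            if n_missing:
                runs = _longest_nan_run(block["x"].isna().to_numpy())
                if runs > max_gap_frames:
                    raise ValueError(
                        f"agent {agent} marker {side}: gap of {runs} frames exceeds "
                        f"limit {max_gap_frames}"
                    )
                block = block.interpolate(method="index", limit_direction="both")
            arr[:, ai, :] = block.to_numpy()
        out[side] = arr
    return MarkerSeries(
        times=times,
        agent_ids=agents,
        group_ids=gid_map.loc[agents].to_numpy(dtype=int),
        left=out["L"],
        right=out["R"],
    )


def _longest_nan_run(mask: np.ndarray) -> int:
    longest = run = 0
    for m in mask:
        run = run + 1 if m else 0
        longest = max(longest, run)
    return longest


def write_marker_series(series: MarkerSeries, path) -> None:
    """Write a :class:`MarkerSeries` back to the long TSV/CSV schema."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for side, arr in (("L", series.left), ("R", series.right)):
        t_frames, n = arr.shape[:2]
        rows.append(
            pd.DataFrame(
                {
                    "time_s": np.repeat(series.times, n),
                    "agent_id": np.tile(series.agent_ids, t_frames),
                    "group_id": np.tile(series.group_ids, t_frames),
                    "marker": side,
                    "x": arr[:, :, 0].ravel(),
                    "y": arr[:, :, 1].ravel(),
                    "z": arr[:, :, 2].ravel(),
                }
            )
        )
    pd.concat(rows).sort_values(["time_s", "agent_id", "marker"]).to_csv(
        path, sep=sep, index=False
    )


def estimate_position_gaze(
    series: MarkerSeries, rotation_sign: int = -1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame horizontal position and gaze azimuth from the marker pair.

    Position is the horizontal midpoint of the left and right markers.  Gaze
    is the azimuth of the right-to-left vector rotated by ``rotation_sign *
    90`` degrees (the default -90 makes a person with the left marker at
    (-w, 0) and the right at (+w, 0) face +y).  Frames where the markers
    coincide are flagged and their gaze linearly interpolated from
    neighboring frames.
    """
    if rotation_sign not in (-1, 1):
        raise ValueError("rotation_sign must be -1 or +1")
    left_h = series.left[:, :, :2]
    right_h = series.right[:, :, :2]
    positions = 0.5 * (left_h + right_h)
    v = left_h - right_h  # right -> left
    # rotate by -90 deg: (vx, vy) -> (vy, -vx); by +90: (-vy, vx)
    if rotation_sign == -1:
        rotated = np.stack([v[..., 1], -v[..., 0]], axis=-1)
    else:
        rotated = np.stack([-v[..., 1], v[..., 0]], axis=-1)
    coincident = np.all(v == 0.0, axis=-1)
    gazes = np.arctan2(rotated[..., 1], rotated[..., 0])
    if np.any(coincident):
        warnings.warn(
            f"{int(coincident.sum())} coincident-marker frame(s); gaze interpolated",
            stacklevel=2,
        )
        for ai in range(series.n_agents):
            mask = coincident[:, ai]
            if not mask.any():
                continue
            if mask.all():
                raise ValueError(f"agent {series.agent_ids[ai]}: markers always coincident")
            good = ~mask
            # interpolate the unwrapped gaze to avoid +/-pi seams
            unwrapped = np.unwrap(gazes[good, ai])
            gazes[mask, ai] = wrap_angle(
                np.interp(series.times[mask], series.times[good], unwrapped)
            )
    return positions, gazes


def estimate_phase_hilbert(
    vertical_series: np.ndarray,
    sample_rate: float,
    band_hz: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous bounce phase from a vertical position series.

    The vertical velocity is computed by central differences and the phase
    is the argument of its analytic signal, ``angle(v + i * H(v))``.  An
    optional zero-phase Butterworth band-pass (off by default) can be
    applied to the velocity first.  Returns ``(phases, valid)`` where
    ``valid`` is False in the first and last 0.5 s (Hilbert end effects).
    Raises on a constant signal, whose phase is undefined.
    """
    z = np.asarray(vertical_series, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
        squeeze = True
    else:
        squeeze = False
    if z.shape[0] < int(2 * sample_rate):
        raise ValueError("need at least 2 s of data for phase estimation")
    if not np.all(np.isfinite(z)):
        raise ValueError("vertical series contains non-finite values")
    v = np.gradient(z, 1.0 / sample_rate, axis=0)
    if np.allclose(v, 0.0):
        raise ValueError("constant vertical signal: oscillation phase undefined")
    if band_hz is not None:
        lo, hi = band_hz
        sos = butter(2, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
        v = sosfiltfilt(sos, v, axis=0)
    analytic = hilbert(v, axis=0)
    phases = np.angle(analytic)
    trim = int(round(EDGE_TRIM_S * sample_rate))
    valid = np.ones(z.shape[0], dtype=bool)
    if trim > 0:
        valid[:trim] = False
        valid[-trim:] = False
    if squeeze:
        phases = phases[:, 0]
    return phases, valid


def empirical_states(
    series: MarkerSeries,
    rotation_sign: int = -1,
    band_hz: Optional[tuple[float, float]] = None,
) -> EmpiricalStateSeries:
    """Full marker-to-state pipeline: position, gaze, and bounce phase."""
    positions, gazes = estimate_position_gaze(series, rotation_sign)
    # bounce phase from the midpoint vertical coordinate of the two markers
    z_mid = 0.5 * (series.left[:, :, 2] + series.right[:, :, 2])
    phases, valid = estimate_phase_hilbert(z_mid, series.sample_rate, band_hz)
    return EmpiricalStateSeries(
        times=series.times,
        agent_ids=series.agent_ids,
        group_ids=series.group_ids,
        positions=positions,
        gazes=gazes,
        phases=phases,
        valid=valid,
    )
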