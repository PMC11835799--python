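"""Group-level measures of spatial, rotational, and oscillatory self-organization.

Six scalar measures summarize one swarm snapshot:

* circularity ``kappa`` — population SD of agent distances from the group
  centroid; 0 when the group forms a perfect circle;
* grouping coefficient ``rho`` — intracluster correlation of positions with
  clusters defined by shared auditory stimulus; 0 when stimulus groups are
  fully intermixed, 1 when each group has collapsed to a point;
* gaze locking ``gamma`` — mean cosine between each agent's gaze and the
  directions to every other agent; 1 when everyone faces everyone;
* centroidal alignment ``chi`` — mean cosine between each agent's gaze and
  the direction to the group centroid;
* phase coherence ``R`` — norm of the Kuramoto order parameter;
* local phase coherence ``R^sigma`` — Gaussian-kernel-weighted coherence
  emphasizing nearby agents; converges to ``R`` as the kernel width grows.

Spatial variance (mean squared distance from the centroid, the "group size"
used in calibration) is also provided.  :func:`measure_series` evaluates
everything per frame over a trajectory, globally and per stimulus group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import Trajectory

__all__ = [
    "MeasureConfig",
    "circularity",
    "grouping_coefficient",
    "gaze_locking",
    "centroidal_alignment",
    "phase_coherence",
    "local_phase_coherence",
    "spatial_variance",
    "measure_series",
]


@dataclass
class MeasureConfig:
    """Settings for trajectory-level measure evaluation.

    ``sigma`` is the Gaussian kernel width for local phase coherence (length
    units); ``per_group`` adds group-restricted columns; ``downsample``
    evaluates every k-th frame.
    """

    sigma: float = 1.0
    per_group: bool = True
    downsample: int = 1

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


def _positions(positions) -> np.ndarray:
    x = np.atleast_2d(np.asarray(positions, dtype=float))
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"positions must be (N, 2), got {x.shape}")
    return x


def circularity(positions) -> float:
    """Population SD of distances from the group centroid (``kappa`` >= 0)."""
    x = _positions(positions)
    if x.shape[0] < 2:
        raise ValueError("circularity requires at least 2 agents")
    d = np.linalg.norm(x - x.mean(axis=0), axis=1)
    return float(np.std(d))


def grouping_coefficient(positions, group_ids) -> float:
    """Intracluster correlation of positions across stimulus groups.

    Multivariate variance decomposition: ``rho = s_b^2 / (s_b^2 + s_w^2)``
    where the within-group variance sums squared distances of members from
    their group centroid and the between-group variance sums group-size
    weighted squared distances of group centroids from the global centroid,
    both divided by N.
    """
    x = _positions(positions)
    gids = np.asarray(group_ids)
    if gids.shape[0] != x.shape[0]:
        raise ValueError("group_ids length must match positions")
    groups = np.unique(gids)
    if groups.size < 2:
        raise ValueError("grouping coefficient requires at least 2 groups")
    n = x.shape[0]
    global_centroid = x.mean(axis=0)
    ss_within = 0.0
    ss_between = 0.0
    for g in groups:
        members = x[gids == g]
        if members.shape[0] == 0:
            raise ValueError(f"stimulus group {g} is empty")
        cg = members.mean(axis=0)
        ss_within += float(np.sum((members - cg) ** 2))
        ss_between += members.shape[0] * float(np.sum((cg - global_centroid) ** 2))
    total = ss_within + ss_between
    if total == 0.0:
        return 0.0  # all agents coincide: no spatial structure to attribute
    return ss_between / total


def gaze_locking(positions, gazes) -> float:
    """Mean cosine between gazes and directions to all other agents (``gamma``)."""
    x = _positions(positions)
    delta = np.asarray(gazes, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("gaze locking requires at least 2 agents")
    diff = x[None, :, :] - x[:, None, :]
    alpha = np.arctan2(diff[..., 1], diff[..., 0])
    cosines = np.cos(alpha - delta[:, None])
    off = ~np.eye(n, dtype=bool)
    return float(cosines[off].sum() / (n * (n - 1)))


def centroidal_alignment(positions, gazes) -> float:
    """Mean cosine between gazes and the direction to the group centroid (``chi``).

    Agents sitting exactly on the centroid have no defined direction to it;
    their terms are skipped with a warning.
    """
    x = _positions(positions)
    delta = np.asarray(gazes, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("centroidal alignment requires at least 2 agents")
    to_centroid = x.mean(axis=0) - x
    at_centroid = np.all(to_centroid == 0.0, axis=1)
    if np.all(at_centroid):
        raise ValueError("all agents at the centroid: alignment undefined")
    if np.any(at_centroid):
        warnings.warn(
            f"{int(at_centroid.sum())} agent(s) exactly at centroid; terms skipped",
            stacklevel=2,
        )
    eps_angle = np.arctan2(to_centroid[~at_centroid, 1], to_centroid[~at_centroid, 0])
    return float(np.mean(np.cos(eps_angle - delta[~at_centroid])))


def phase_coherence(phases) -> float:
    """Norm of the Kuramoto order parameter, ``R = |sum exp(i*theta)| / N``."""
    theta = np.atleast_1d(np.asarray(phases, dtype=float))
    return float(np.abs(np.exp(1j * theta).mean()))


def local_phase_coherence(positions, phases, sigma: float) -> float:
    """Spatially weighted phase coherence ``R^sigma``.

    Each agent's local coherence weights peers (including itself) by a
    Gaussian kernel of width ``sigma`` in distance; the global value is the
    mean over agents.  Large ``sigma`` recovers plain phase coherence.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = _positions(positions)
    theta = np.asarray(phases, dtype=float)
    sq_dist = np.sum((x[None, :, :] - x[:, None, :]) ** 2, axis=-1)
    kernel = np.exp(-sq_dist / (2.0 * sigma**2))
    phasors = np.exp(1j * theta)
    local = np.abs(kernel @ phasors) / kernel.sum(axis=1)
    return float(local.mean())


def spatial_variance(positions) -> float:
    """Mean squared distance from the global centroid ("group size")."""
    x = _positions(positions)
    if x.shape[0] < 2:
        raise ValueError("spatial variance requires at least 2 agents")
    return float(np.mean(np.sum((x - x.mean(axis=0)) ** 2, axis=1)))


def _frame_measures(pos, theta, delta, gids, config: MeasureConfig) -> dict:
    row = {
        "kappa": circularity(pos),
        "gamma": gaze_locking(pos, delta),
        "chi": centroidal_alignment(pos, delta),
        "R": phase_coherence(theta),
        "R_sigma": local_phase_coherence(pos, theta, config.sigma),
        "spatial_variance": spatial_variance(pos),
    }
    groups = np.unique(gids)
    row["rho"] = grouping_coefficient(pos, gids) if groups.size >= 2 else np.nan
    if config.per_group and groups.size >= 2:
        for g in groups:
            sel = gids == g
            if sel.sum() < 2:
                continue
            row[f"kappa_g{g}"] = circularity(pos[sel])
            row[f"gamma_g{g}"] = gaze_locking(pos[sel], delta[sel])
            row[f"chi_g{g}"] = centroidal_alignment(pos[sel], delta[sel])
            row[f"R_g{g}"] = phase_coherence(theta[sel])
            row[f"R_sigma_g{g}"] = local_phase_coherence(pos[sel], theta[sel], config.sigma)
            row[f"spatial_variance_g{g}"] = spatial_variance(pos[sel])
    return row


def measure_series(trajectory: Trajectory, config: MeasureConfig | None = None) -> pd.DataFrame:
    """Evaluate every measure per frame of a trajectory.

    Returns a DataFrame with one row per (optionally downsampled) frame,
    global columns ``kappa, rho, gamma, chi, R, R_sigma, spatial_variance``
    and, when enabled, the same measures restricted to each stimulus group,
    suffixed ``_g<id>``.
    """
    config = config or MeasureConfig()
    frames = range(0, trajectory.n_frames, config.downsample)
    gids = trajectory.group_ids
    rows = []
    for i in frames:
        row = {"time_s": float(trajectory.times[i])}
        row.update(
            _frame_measures(
                trajectory.positions[i], trajectory.phases[i], trajectory.gazes[i], gids, config
            )
        )
        rows.append(row)
    return pd.DataFrame(rows)
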