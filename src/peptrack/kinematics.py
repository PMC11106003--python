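"""Kinematic observables derived from a tracked trajectory.

Velocities come from forward differences between consecutive tracked points
(points are sparse and unevenly spaced, so each estimate stays local to one
inter-point interval); speed is the Euclidean norm sqrt(vx^2 + vy^2 + vz^2).
Static positioning precision is summarised by per-axis sample standard
deviations over a quiet window, and respiratory motion by the half
peak-to-peak envelope of the detrended coordinate on the relevant axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .simulate import GroundTruth
from .tracking import Trajectory

__all__ = [
    "VelocityEstimate",
    "StaticErrorReport",
    "velocities",
    "mean_speed",
    "static_error",
    "oscillation_envelope",
    "compare_to_truth",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class VelocityEstimate:
    """Velocity over one inter-point segment, stamped at its midpoint."""

    t: float
    vx: float
    vy: float
    vz: float

    @property
    def speed(self) -> float:
        return float(np.sqrt(self.vx**2 + self.vy**2 + self.vz**2))


@dataclass(frozen=True)
class StaticErrorReport:
    """Positioning scatter of tracked points over a quiet window."""

    t_start: float
    t_end: float
    sx: float
    sy: float
    sz: float
    n_points: int

    @property
    def mean_axis_sd(self) -> float:
        return (self.sx + self.sy + self.sz) / 3.0

    @property
    def rms3d(self) -> float:
        return float(np.sqrt(self.sx**2 + self.sy**2 + self.sz**2))


def velocities(traj: Trajectory) -> list[VelocityEstimate]:
    """Forward-difference velocity per consecutive-point segment."""
    if len(traj) < 2:
        raise InsufficientDataError("velocities need at least 2 tracked points")
    t = traj.t
    dt = np.diff(t)
    if (dt == 0).any():
        raise ValueError("duplicate trajectory timestamps")
    v = np.diff(traj.positions, axis=0) / dt[:, None]
    mid = 0.5 * (t[:-1] + t[1:])
    return [
        VelocityEstimate(t=float(m), vx=float(a), vy=float(b), vz=float(c))
        for m, (a, b, c) in zip(mid, v)
    ]


def velocities_frame(traj: Trajectory) -> pd.DataFrame:
    """Velocities as a tidy DataFrame (t_s, vx/vy/vz, speed in mm/s)."""
    vs = velocities(traj)
    return pd.DataFrame(
        {
            "t_s": [v.t for v in vs],
            "vx_mm_s": [v.vx for v in vs],
            "vy_mm_s": [v.vy for v in vs],
            "vz_mm_s": [v.vz for v in vs],
            "speed_mm_s": [v.speed for v in vs],
        }
    )


def mean_speed(traj: Trajectory, t_start: float, t_end: float) -> float:
    """Duration-weighted mean segment speed over [t_start, t_end].

    Segments are selected by their midpoints; weights are the segment
    durations, so a uniformly sampled constant-velocity trajectory returns
    its speed exactly.
    """
    vs = velocities(traj)
    dt = np.diff(traj.t)
    mid = np.array([v.t for v in vs])
    sel = (mid >= t_start) & (mid <= t_end)
    if sel.sum() < 1:
        raise InsufficientDataError(
            f"no trajectory segments with midpoint in [{t_start}, {t_end}] s"
        )
    speeds = np.array([v.speed for v in vs])[sel]
    return float(np.average(speeds, weights=dt[sel]))


def _window(traj: Trajectory, t_start: float, t_end: float) -> np.ndarray:
    sel = (traj.t >= t_start) & (traj.t <= t_end)
    return traj.positions[sel]


def static_error(traj: Trajectory, t_start: float, t_end: float) -> StaticErrorReport:
    """Per-axis sample SDs (ddof=1) of tracked points in a static window."""
    pos = _window(traj, t_start, t_end)
    if pos.shape[0] < 2:
        raise InsufficientDataError(
            f"static_error needs >= 2 points in [{t_start}, {t_end}] s"
        )
    sd = pos.std(axis=0, ddof=1)
    return StaticErrorReport(
        t_start=t_start,
        t_end=t_end,
        sx=float(sd[0]),
        sy=float(sd[1]),
        sz=float(sd[2]),
        n_points=int(pos.shape[0]),
    )


def oscillation_envelope(
    traj: Trajectory, axis: str, t_start: float, t_end: float
) -> float:
    """Half peak-to-peak excursion of the detrended coordinate (mm).

    The window mean is subtracted and half of (max - min) returned — an
    envelope of the periodic (breathing) motion, not a fitted amplitude.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    pos = _window(traj, t_start, t_end)
    if pos.shape[0] < 3:
        raise InsufficientDataError(
            f"oscillation_envelope needs >= 3 points in [{t_start}, {t_end}] s"
        )
    coord = pos[:, _AXES[axis]]
    detrended = coord - coord.mean()
    return float(0.5 * (detrended.max() - detrended.min()))


def compare_to_truth(
    traj: Trajectory, truth: GroundTruth
) -> tuple[np.ndarray, float]:
    """Per-point 3D error against the ground-truth motion, plus the RMS."""
    true_pos = truth.trajectory.position_at(traj.t)
    err = np.linalg.norm(traj.positions - true_pos, axis=1)
    return err, float(np.sqrt(np.mean(err**2))) if err.size else 0.0
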