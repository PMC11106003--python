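"""The Birmingham PEPT algorithm.

A particle position is estimated as the minimum distance point (MDP) of a
subset of time-consecutive lines of response: the point minimising the sum
of squared perpendicular distances to the lines. Corrupt LoRs (scatter,
randoms, background) do not pass near the particle, so the MDP is refined
iteratively by discarding the LoRs lying farthest from the current estimate;
the loop terminates when a fraction ``f`` (the f-factor) of the original
subset remains. Subsets are formed greedily from the time-ordered stream
with no overlap, with a sample-size schedule that trades temporal resolution
against positional precision.

The closed form: with unit directions ``d_i`` and anchor points ``a_i``,
the MDP solves ``[sum_i (I - d_i d_i^T)] p = sum_i (I - d_i d_i^T) a_i``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateGeometryError,
    DegenerateLoRError,
    EmptyTrajectoryError,
    InsufficientDataError,
)
from .geometry import LoR
from .listmode import ListModeStream

__all__ = [
    "ScheduleEntry",
    "TrackingConfig",
    "TrackedPoint",
    "Trajectory",
    "perpendicular_distance",
    "point_line_distances",
    "mdp",
    "locate",
    "partition_stream",
    "track",
]

logger = logging.getLogger(__name__)

#: condition number above which an LoR bundle is treated as rank-deficient
_MAX_CONDITION = 1e12


@dataclass(frozen=True)
class ScheduleEntry:
    """Sample size in force over [t_start_s, t_end_s)."""

    t_start_s: float
    t_end_s: float
    sample_size: int


@dataclass(frozen=True)
class TrackingConfig:
    """Birmingham-method parameters.

    ``schedule`` lists non-overlapping, ordered time intervals with the LoR
    sample size in force; ``f`` is the f-factor (fraction of each sample that
    survives trimming); ``discard_per_iteration`` is the fraction of current
    survivors dropped per iteration; ``min_lors`` the minimum usable final
    count. ``timestamp_mode`` is ``mean`` (mean surviving-LoR timestamp) or
    ``midpoint`` (centre of the sample's time window).
    """

    schedule: tuple[ScheduleEntry, ...]
    f: float = 0.1
    discard_per_iteration: float = 0.2
    min_lors: int = 10
    timestamp_mode: str = "mean"

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must contain at least one entry")
        entries = tuple(
            e if isinstance(e, ScheduleEntry) else ScheduleEntry(*e)
            for e in self.schedule
        )
        object.__setattr__(self, "schedule", entries)
        prev_end = -math.inf
        for e in entries:
            if e.t_end_s <= e.t_start_s:
                raise ValueError(f"empty schedule interval {e}")
            if e.t_start_s < prev_end:
                raise ValueError("schedule intervals overlap or are unordered")
            prev_end = e.t_end_s
        if not 0.0 < self.f <= 1.0:
            raise ValueError("f must be in (0, 1]")
        if not 0.0 < self.discard_per_iteration < 1.0:
            raise ValueError("discard_per_iteration must be in (0, 1)")
        if self.min_lors < 2:
            raise ValueError("min_lors must be >= 2")
        for e in entries:
            if e.sample_size < self.min_lors / self.f:
                raise ValueError(
                    f"sample_size {e.sample_size} below min_lors/f = "
                    f"{self.min_lors / self.f:.1f}"
                )
        if self.timestamp_mode not in ("mean", "midpoint"):
            raise ValueError("timestamp_mode must be 'mean' or 'midpoint'")

    @property
    def min_sample(self) -> int:
        """Smallest sample worth locating: ceil(min_lors / f)."""
        return math.ceil(self.min_lors / self.f)

    def sample_size_at(self, t: np.ndarray) -> np.ndarray:
        """Sample size in force at each time (last applicable entry)."""
        starts = np.array([e.t_start_s for e in self.schedule])
        sizes = np.array([e.sample_size for e in self.schedule])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(sizes) - 1)
        return sizes[idx]

    @classmethod
    def from_file(cls, path: str | Path) -> "TrackingConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        schedule = tuple(
            ScheduleEntry(
                t_start_s=float(e["t_start_s"]),
                t_end_s=float(e.get("t_end_s", math.inf)),
                sample_size=int(e["sample_size"]),
            )
            for e in data["schedule"]
        )
        kwargs = {k: data[k] for k in
                  ("f", "discard_per_iteration", "min_lors", "timestamp_mode")
                  if k in data}
        return cls(schedule=schedule, **kwargs)


@dataclass(frozen=True)
class TrackedPoint:
    """One located particle position with residual statistics."""

    t: float
    position: np.ndarray
    n_initial: int
    n_final: int
    rms_residual_mm: float
    error_estimate_mm: float


@dataclass
class Trajectory:
    """Time-ordered tracked points with provenance."""

    points: list[TrackedPoint]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.t
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("trajectory timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def t(self) -> np.ndarray:
        return np.array([p.t for p in self.points])

    @property
    def positions(self) -> np.ndarray:
        return (
            np.vstack([p.position for p in self.points])
            if self.points
            else np.zeros((0, 3))
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "x_mm": self.positions[:, 0] if self.points else [],
                "y_mm": self.positions[:, 1] if self.points else [],
                "z_mm": self.positions[:, 2] if self.points else [],
                "n_initial": [p.n_initial for p in self.points],
                "n_final": [p.n_final for p in self.points],
                "rms_residual_mm": [p.rms_residual_mm for p in self.points],
                "error_estimate_mm": [p.error_estimate_mm for p in self.points],
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.15g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        points = [
            TrackedPoint(
                t=row.t_s,
                position=np.array([row.x_mm, row.y_mm, row.z_mm]),
                n_initial=int(row.n_initial),
                n_final=int(row.n_final),
                rms_residual_mm=row.rms_residual_mm,
                error_estimate_mm=row.error_estimate_mm,
            )
            for row in df.itertuples()
        ]
        return cls(points=points, provenance={"source": str(path)})


# ---------------------------------------------------------------------- #
# geometry primitives


def perpendicular_distance(lor: LoR, p: np.ndarray) -> float:
    """Distance from ``p`` to the infinite line through the LoR endpoints."""
    p1 = np.asarray(lor.p1, dtype=float)
    p2 = np.asarray(lor.p2, dtype=float)
    d = p2 - p1
    norm = np.linalg.norm(d)
    if norm == 0:
        raise DegenerateLoRError("LoR endpoints coincide")
    return float(np.linalg.norm(np.cross(np.asarray(p, dtype=float) - p1, d / norm)))


def point_line_distances(p1: np.ndarray, p2: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised perpendicular distances from point ``p`` to lines (p1, p2)."""
    d = p2 - p1
    norms = np.linalg.norm(d, axis=1)
    if (norms == 0).any():
        raise DegenerateLoRError("LoR endpoints coincide")
    dhat = d / norms[:, None]
    w = p[None, :] - p1
    # |w x dhat| rather than sqrt(|w|^2 - (w.dhat)^2): the latter cancels
    # catastrophically for points near a line with distant anchors
    cross = np.cross(w, dhat)
    return np.linalg.norm(cross, axis=1)


def _mdp_arrays(p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, float]:
    d = p2 - p1
    norms = np.linalg.norm(d, axis=1)
    if (norms == 0).any():
        raise DegenerateLoRError("LoR endpoints coincide")
    dhat = d / norms[:, None]
    n = dhat.shape[0]
    # A = sum(I - d d^T), b = sum((I - d d^T) a)
    gram = dhat.T @ dhat
    a_mat = n * np.eye(3) - gram
    b = p1.sum(axis=0) - dhat.T @ np.einsum("ij,ij->i", dhat, p1)
    cond = np.linalg.cond(a_mat)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise DegenerateGeometryError(
            f"LoR bundle is rank-deficient (all lines near-parallel): "
            f"condition number {cond:.3g}"
        )
    point = np.linalg.solve(a_mat, b)
    dists = point_line_distances(p1, p2, point)
    return point, float(np.sqrt(np.mean(dists**2)))


def mdp(
    lors: Sequence[LoR] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, float]:
    """Minimum distance point of an LoR bundle and its RMS residual (mm).

    Accepts a sequence of :class:`LoR` or a ``(P1, P2)`` pair of (n, 3)
    endpoint arrays. Requires >= 2 lines with a non-singular normal matrix.
    """
    if isinstance(lors, tuple) and len(lors) == 2 and hasattr(lors[0], "shape"):
        p1 = np.asarray(lors[0], dtype=float).reshape(-1, 3)
        p2 = np.asarray(lors[1], dtype=float).reshape(-1, 3)
    else:
        p1 = np.vstack([l.p1 for l in lors]).astype(float)
        p2 = np.vstack([l.p2 for l in lors]).astype(float)
    if p1.shape[0] < 2:
        raise InsufficientDataError("MDP needs at least 2 LoRs")
    return _mdp_arrays(p1, p2)


# ---------------------------------------------------------------------- #
# the iterative locator


def locate(
    t: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    config: TrackingConfig,
    t_window: tuple[float, float] | None = None,
) -> TrackedPoint:
    """Locate one particle position from a time-consecutive LoR sample.

    Iteratively computes the MDP of the survivors and removes the
    ``discard_per_iteration`` share lying farthest from it (never dropping
    below ``ceil(f * n_initial)``; the final removal truncates to land
    exactly there). Distance ties break stably: the earlier event survives.
    """
    t = np.asarray(t, dtype=float)
    p1 = np.asarray(p1, dtype=float).reshape(-1, 3)
    p2 = np.asarray(p2, dtype=float).reshape(-1, 3)
    n0 = t.shape[0]
    if n0 < config.min_sample:
        raise InsufficientDataError(
            f"sample of {n0} LoRs is below min_lors/f = {config.min_sample}"
        )
    target = max(math.ceil(config.f * n0), config.min_lors, 2)

    idx = np.arange(n0)
    while True:
        point, rms = _mdp_arrays(p1[idx], p2[idx])
        n_surv = idx.size
        if n_surv <= target:
            break
        k = min(
            math.ceil(config.discard_per_iteration * n_surv), n_surv - target
        )
        dists = point_line_distances(p1[idx], p2[idx], point)
        order = np.argsort(dists, kind="stable")  # ties keep time order
        keep = np.ones(n_surv, dtype=bool)
        keep[order[n_surv - k :]] = False
        idx = idx[keep]

    if config.timestamp_mode == "midpoint" and t_window is not None:
        t_point = 0.5 * (t_window[0] + t_window[1])
    elif config.timestamp_mode == "midpoint":
        t_point = 0.5 * (float(t[0]) + float(t[-1]))
    else:
        t_point = float(t[idx].mean())

    return TrackedPoint(
        t=t_point,
        position=point,
        n_initial=n0,
        n_final=int(idx.size),
        rms_residual_mm=rms,
        error_estimate_mm=rms / math.sqrt(idx.size),
    )


def partition_stream(
    stream: ListModeStream, config: TrackingConfig
) -> list[tuple[int, int]]:
    """Greedy non-overlapping samples as (start, stop) index pairs.

    The sample size in force is that of the schedule interval containing
    each event's timestamp; a sample closes when it reaches that size. A
    trailing partial sample smaller than ``min_lors/f`` is dropped (logged).
    """
    n = len(stream)
    if n == 0:
        return []
    sizes = config.sample_size_at(stream.t)
    bounds: list[tuple[int, int]] = []
    start = 0
    count = 0
    for j in range(n):
        count += 1
        if count >= sizes[j]:
            bounds.append((start, j + 1))
            start = j + 1
            count = 0
    if count:
        if count >= config.min_sample:
            bounds.append((start, n))
        else:
            logger.info(
                "dropping trailing partial sample of %d LoRs (< %d)",
                count,
                config.min_sample,
            )
    return bounds


def track(stream: ListModeStream, config: TrackingConfig) -> Trajectory:
    """Apply the Birmingham method across a whole stream.

    Degenerate or undersized partitions are skipped with a warning; at least
    one successful location is required.
    """
    points: list[TrackedPoint] = []
    for start, stop in partition_stream(stream, config):
        try:
            pt = locate(
                stream.t[start:stop],
                stream.p1[start:stop],
                stream.p2[start:stop],
                config,
                t_window=(float(stream.t[start]), float(stream.t[stop - 1])),
            )
        except (DegenerateGeometryError, InsufficientDataError) as exc:
            logger.warning("skipping sample [%d:%d): %s", start, stop, exc)
            continue
        if points and pt.t <= points[-1].t:
            logger.warning(
                "skipping sample [%d:%d): non-increasing timestamp", start, stop
            )
            continue
        points.append(pt)
    if not points:
        raise EmptyTrajectoryError("no sample produced a valid location")
    return Trajectory(
        points=points,
        provenance={
            "source": stream.source,
            "f": config.f,
            "discard_per_iteration": config.discard_per_iteration,
            "min_lors": config.min_lors,
            "timestamp_mode": config.timestamp_mode,
            "schedule": [
                {
                    "t_start_s": e.t_start_s,
                    "t_end_s": e.t_end_s,
                    "sample_size": e.sample_size,
                }
                for e in config.schedule
            ],
        },
    )
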