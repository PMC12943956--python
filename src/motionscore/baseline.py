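"""Normal-movement baseline: mean trajectories and distance statistics.

The reference for scoring is built from a sample of normal motion
segments.  For each joint:

1. the mean trajectory length is the arithmetic mean of the segments'
   lengths, ``l_bar = sum(l_i) / n``;
2. each trajectory's elapsed times are linearly rescaled to that mean
   length, ``e' = e * l_bar / e_max`` (0 maps to 0, the end maps to
   ``l_bar``);
3. the rescaled trajectories are resampled by linear interpolation on a
   uniform grid spanning [0, l_bar];
4. the grid values are averaged pointwise, giving the mean normal
   trajectory ``M = {theta_bar_0, ..., theta_bar_lbar}``.

The combined baseline B stacks the per-joint means in feature-set order.
The same normal segments are then scored against B with multi-dimensional
DTW; the sample mean mu and sample standard deviation sigma (n - 1
convention) of those distances parameterize the Z-score used at assessment
time.  By default mu and sigma are computed in-sample on the segments
that built B; pass ``stats_segments`` to use a held-out set instead (the
in-sample convention slightly understates sigma, which is the overfitting
mechanism suspected for multi-angle shoulder flexion).

A baseline whose sigma is zero (e.g. built from identical segments) is
flagged degenerate; Z-scores against it are refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, ParameterError
from .kinematics import AngleTrajectory
from .pose_io import ExerciseSpec
from .segmentation import MotionSegment

_DEGENERATE_SIGMA = 1e-12


def mean_length(lengths: Sequence[float]) -> float:
    """Arithmetic mean of trajectory lengths (seconds)."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ParameterError("mean_length requires at least one length")
    if np.any(lengths <= 0):
        raise ParameterError("trajectory lengths must be positive")
    return float(lengths.mean())


def normalize_time(e_t: float, e_max: float, l_bar: float) -> float:
    """Rescale an elapsed time onto the mean-length axis: e' = e * l_bar / e_max."""
    if e_max <= 0:
        raise DataError("cannot normalize a zero-length trajectory")
    if not 0 <= e_t <= e_max:
        raise ParameterError(f"e_t={e_t} outside [0, {e_max}]")
    return float(e_t * l_bar / e_max)


def interpolate_angle(t: float, e_knots: np.ndarray,
                      theta_knots: np.ndarray) -> float:
    """Linear interpolation between bracketing knots; exact at knots."""
    e_knots = np.asarray(e_knots, dtype=float)
    theta_knots = np.asarray(theta_knots, dtype=float)
    if e_knots.size == 0:
        raise ParameterError("no knots to interpolate")
    if not e_knots[0] <= t <= e_knots[-1]:
        raise ParameterError(
            f"t={t} outside knot range [{e_knots[0]}, {e_knots[-1]}]")
    return float(np.interp(t, e_knots, theta_knots))


@dataclass
class MeanTrajectory:
    """Mean normal trajectory of one joint on a uniform grid over [0, l_bar]."""

    joint_label: str
    grid: np.ndarray
    values: np.ndarray
    l_bar: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise DataError("grid and values must have equal shape")
        if not np.all(np.isfinite(self.values)):
            raise DataError("mean trajectory values must be finite")


def mean_trajectory(trajs: Sequence[AngleTrajectory],
                    grid_step: Optional[float] = None) -> MeanTrajectory:
    """Average trajectories after rescaling each to the mean length.

    ``grid_step`` defaults to the median inter-sample interval of the
    inputs (about one frame at the recording rate).
    """
    if not trajs:
        raise ParameterError("mean_trajectory requires at least one trajectory")
    l_bar = mean_length([t.length for t in trajs])
    if grid_step is None:
        grid_step = default_grid_step(trajs)
    if grid_step <= 0:
        raise ParameterError("grid_step must be positive")
    n_pts = max(2, int(round(l_bar / grid_step)) + 1)
    grid = np.linspace(0.0, l_bar, n_pts)
    resampled = np.empty((len(trajs), n_pts))
    for i, t in enumerate(trajs):
        if t.length <= 0:
            raise DataError("cannot average a zero-length trajectory")
        e_prime = t.e * (l_bar / t.length)
        resampled[i] = np.interp(grid, e_prime, t.theta)
    return MeanTrajectory(joint_label=trajs[0].joint_label, grid=grid,
                          values=resampled.mean(axis=0), l_bar=l_bar)


def default_grid_step(trajs: Sequence[AngleTrajectory]) -> float:
    steps = np.concatenate([np.diff(t.e) for t in trajs if len(t.e) > 1])
    if steps.size == 0:
        raise DataError("trajectories too short to infer a grid step")
    return float(np.median(steps))


@dataclass
class Baseline:
    """Per-joint mean normal trajectories plus distance statistics.

    ``mu`` and ``sigma`` are the sample mean and sample SD of the DTW
    distances of the contributing normal segments to these means.
    """

    means: list[MeanTrajectory]
    mu: float
    sigma: float
    n_segments: int
    exercise: Optional[ExerciseSpec] = None
    degenerate: bool = False

    @property
    def joint_labels(self) -> tuple[str, ...]:
        return tuple(m.joint_label for m in self.means)

    def values_matrix(self) -> np.ndarray:
        """(n_grid, n_joints) matrix of mean angles in feature-set order."""
        return np.column_stack([m.values for m in self.means])

    @classmethod
    def from_stats(cls, mu: float, sigma: float) -> "Baseline":
        """A statistics-only baseline (no mean trajectories), usable for
        Z-score and score computation from published summary values."""
        return cls(means=[], mu=float(mu), sigma=float(sigma), n_segments=0,
                   degenerate=sigma <= _DEGENERATE_SIGMA)

    def to_dict(self) -> dict:
        return {
            "exercise": self.exercise.to_dict() if self.exercise else None,
            "means": [
                {"joint_label": m.joint_label, "l_bar": m.l_bar,
                 "grid": m.grid.tolist(), "values": m.values.tolist()}
                for m in self.means
            ],
            "mu": self.mu,
            "sigma": self.sigma,
            "n_segments": self.n_segments,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Baseline":
        return cls(
            means=[MeanTrajectory(m["joint_label"], np.asarray(m["grid"]),
                                  np.asarray(m["values"]), m["l_bar"])
                   for m in d["means"]],
            mu=d["mu"], sigma=d["sigma"], n_segments=d["n_segments"],
            exercise=(ExerciseSpec.from_dict(d["exercise"])
                      if d.get("exercise") else None),
            degenerate=d["degenerate"],
        )

    def save(self, path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "Baseline":
        with open(Path(path)) as fh:
            return cls.from_dict(json.load(fh))


def build_baseline(segments: Sequence[MotionSegment],
                   spec: Optional[ExerciseSpec] = None,
                   grid_step: Optional[float] = None,
                   dtw_config=None,
                   stats_segments: Optional[Sequence[MotionSegment]] = None,
                   ) -> Baseline:
    """Construct the baseline B and its distance statistics.

    Parameters
    ----------
    segments
        Normal motion segments sharing one feature set; their per-joint
        trajectories are averaged into the mean trajectories.
    stats_segments
        Segments whose distances to B define mu and sigma.  Defaults to
        ``segments`` (in-sample); pass a held-out set for honest spread.
    """
    from .assessment import DtwConfig, multi_dtw_distance  # avoid cycle

    if not segments:
        raise ParameterError("build_baseline requires at least one segment")
    labels = segments[0].joint_labels
    for s in segments[1:]:
        if s.joint_labels != labels:
            raise ParameterError(
                f"segments disagree on feature set: {s.joint_labels} vs {labels}")
    if grid_step is None:
        grid_step = default_grid_step([s.trajectories[0] for s in segments])
    means = [
        mean_trajectory([s.trajectories[j] for s in segments], grid_step)
        for j in range(len(labels))
    ]
    base = Baseline(means=means, mu=0.0, sigma=0.0,
                    n_segments=len(segments), exercise=spec)
    config = dtw_config if dtw_config is not None else DtwConfig()
    pool = stats_segments if stats_segments is not None else segments
    dists = np.array([multi_dtw_distance(s, base, config) for s in pool])
    base.mu = float(dists.mean())
    base.sigma = float(dists.std(ddof=1)) if len(dists) > 1 else 0.0
    base.degenerate = base.sigma <= _DEGENERATE_SIGMA
    return base
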