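"""Joint-angle kinematics from 2D landmarks.

The angle at a joint is the unsigned interior angle at a vertex point
between the vectors to two reference landmarks, obtained from the cosine
rule::

    D  = (x1 - xv)(x2 - xv) + (y1 - yv)(y2 - yv)
    M1 = sqrt((x1 - xv)^2 + (y1 - yv)^2)
    M2 = sqrt((x2 - xv)^2 + (y2 - yv)^2)
    J  = arccos(D / (M1 * M2)) * 180 / pi

J lies in [0, 180] degrees and is invariant to translation, rotation,
uniform scaling, and the image convention of y increasing downward.  The
cosine argument is clamped to [-1, 1] so that floating-point collinearity
cannot produce NaN.

Trajectories are smoothed with a centered moving average (default window
5 samples) before segmentation and assessment; at the boundaries the
window shrinks to the available samples so the output keeps the input's
length and time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .errors import DataError, DegenerateGeometryError, ParameterError
from .pose_io import AngleDefinition, LandmarkStream


class AngleSample(NamedTuple):
    e: float       # elapsed seconds from trajectory start
    theta: float   # angle in degrees


@dataclass
class AngleTrajectory:
    """One joint's angle as a function of elapsed time.

    ``e`` starts at 0 and is strictly increasing; the trajectory length is
    the maximum elapsed time (the last sample's ``e``).
    """

    joint_label: str
    e: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.e.shape != self.theta.shape or self.e.ndim != 1:
            raise DataError("e and theta must be 1-D arrays of equal length")
        n = len(self.e)
        if n:
            if self.e[0] != 0.0:
                raise DataError("trajectory must start at e = 0")
            if n > 1 and not np.all(np.diff(self.e) > 0):
                raise DataError("elapsed times must be strictly increasing")
            if not np.all(np.isfinite(self.theta)):
                raise DataError("angles must be finite")

    def __len__(self) -> int:
        return len(self.e)

    def __iter__(self) -> Iterator[AngleSample]:
        for ev, tv in zip(self.e, self.theta):
            yield AngleSample(float(ev), float(tv))

    @property
    def length(self) -> float:
        """Trajectory length in seconds (the maximum elapsed time)."""
        return float(self.e[-1]) if len(self.e) else 0.0


def joint_angle(vertex, p1, p2) -> float:
    """Interior angle in degrees at ``vertex`` between ``p1`` and ``p2``."""
    vertex = np.asarray(vertex, dtype=float)
    v1 = np.asarray(p1, dtype=float) - vertex
    v2 = np.asarray(p2, dtype=float) - vertex
    m1 = float(np.hypot(*v1))
    m2 = float(np.hypot(*v2))
    if m1 == 0.0 or m2 == 0.0:
        raise DegenerateGeometryError(
            "zero-magnitude vector: a reference point coincides with the vertex")
    cosj = np.clip(float(v1 @ v2) / (m1 * m2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosj)))


def angle_trajectory(stream: LandmarkStream,
                     angle: AngleDefinition) -> AngleTrajectory:
    """Compute one joint angle per frame; elapsed time is re-based to the
    first frame."""
    if len(stream) == 0:
        raise DataError("cannot compute an angle trajectory from an empty stream")
    v = stream.landmark_xy(angle.vertex)
    a = stream.landmark_xy(angle.ref1) - v
    b = stream.landmark_xy(angle.ref2) - v
    m1 = np.hypot(a[:, 0], a[:, 1])
    m2 = np.hypot(b[:, 0], b[:, 1])
    bad = np.nonzero((m1 == 0.0) | (m2 == 0.0))[0]
    if bad.size:
        raise DegenerateGeometryError(
            f"zero-magnitude vector at frame {int(stream.frame_index[bad[0]])} "
            f"for angle {angle.label!r} (vertex {angle.vertex})")
    cosj = np.clip(np.sum(a * b, axis=1) / (m1 * m2), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosj))
    return AngleTrajectory(joint_label=angle.label,
                           e=stream.time_s - stream.time_s[0],
                           theta=theta)


def smooth_trajectory(traj: AngleTrajectory, window: int = 5) -> AngleTrajectory:
    """Centered moving average with a window that shrinks at the boundaries,
    preserving length and time grid."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd positive integer, got {window}")
    n = len(traj)
    if window == 1 or n <= 1:
        return AngleTrajectory(traj.joint_label, traj.e.copy(), traj.theta.copy())
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(traj.theta)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return AngleTrajectory(traj.joint_label, traj.e.copy(), smoothed)
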