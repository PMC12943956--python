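"""Repetition detection: cut a continuous angle trajectory into motion
segments.

One motion segment is one exercise repetition.  Detection runs on the
smoothed primary joint angle only:

1. the rest angle is estimated as the median over an initial rest window;
2. *start of motion* is the first frame whose deviation from rest exceeds
   the onset threshold after having been within it;
3. the *trigger point* is the first frame after the repetition's extremum
   where the angle begins returning toward rest (in the source system this
   frame fires the game input);
4. the *end* is the first frame after the trigger where the angle returns
   to within a tolerance of the start angle — or, when the next repetition
   begins before the angle returns, the reversal point (local extremum)
   between the two repetitions.

Detection is direction-agnostic: an exercise may raise the monitored angle
(abduction, shoulder flexion) or shrink it (elbow flexion), so extrema are
found on the absolute deviation from rest.  Segments shorter than a
minimum duration are discarded.  The same frame ranges are then applied to
every angle in the feature set, so compensation angles are sliced, never
re-segmented.

All numeric thresholds are calibration knobs exposed via
:class:`SegmentationParams`; the defaults are tuned for full range-of-motion
upper-limb exercises sampled at webcam frame rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError, ValidationError
from .kinematics import AngleTrajectory, angle_trajectory, smooth_trajectory
from .pose_io import ExerciseSpec, LandmarkStream


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for repetition detection (degrees / seconds)."""

    rest_window_s: float = 0.5
    onset_threshold_deg: float = 10.0
    return_tolerance_deg: float = 5.0
    min_segment_s: float = 0.3
    min_peak_prominence_deg: float = 15.0
    smooth_window: int = 5          # samples; 1 disables smoothing

    def __post_init__(self) -> None:
        for name in ("rest_window_s", "onset_threshold_deg",
                     "return_tolerance_deg", "min_segment_s",
                     "min_peak_prominence_deg"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ParameterError("smooth_window must be an odd positive integer")

    def to_dict(self) -> dict:
        return {
            "rest_window_s": self.rest_window_s,
            "onset_threshold_deg": self.onset_threshold_deg,
            "return_tolerance_deg": self.return_tolerance_deg,
            "min_segment_s": self.min_segment_s,
            "min_peak_prominence_deg": self.min_peak_prominence_deg,
            "smooth_window": self.smooth_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        return cls(**d)


@dataclass(frozen=True)
class SegmentMarkers:
    """Frame indices delimiting one repetition (0-based, inclusive span)."""

    start_index: int
    trigger_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not self.start_index < self.trigger_index <= self.end_index:
            raise ValidationError(
                f"markers must satisfy start < trigger <= end, got "
                f"({self.start_index}, {self.trigger_index}, {self.end_index})")


@dataclass
class MotionSegment:
    """One repetition: per-joint angle trajectories re-based to e = 0 at
    the start frame, all sharing the same time grid."""

    markers: SegmentMarkers
    trajectories: list[AngleTrajectory]
    exercise: Optional[ExerciseSpec] = None
    label: str = "unknown"          # {normal, abnormal, unknown}

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValidationError("a segment needs at least one trajectory")
        e0 = self.trajectories[0].e
        for t in self.trajectories[1:]:
            if len(t.e) != len(e0) or not np.allclose(t.e, e0):
                raise ValidationError(
                    "all trajectories of a segment must share the same e-grid")

    @property
    def joint_labels(self) -> tuple[str, ...]:
        return tuple(t.joint_label for t in self.trajectories)

    def trajectory(self, joint_label: str) -> AngleTrajectory:
        for t in self.trajectories:
            if t.joint_label == joint_label:
                return t
        raise KeyError(joint_label)

    def subset(self, joint_labels: Sequence[str]) -> "MotionSegment":
        """A view of this segment restricted to the given joints, in order."""
        return MotionSegment(
            markers=self.markers,
            trajectories=[self.trajectory(lbl) for lbl in joint_labels],
            exercise=self.exercise,
            label=self.label,
        )

    def values_matrix(self) -> np.ndarray:
        """(n_samples, n_joints) angle matrix in feature-set order."""
        return np.column_stack([t.theta for t in self.trajectories])

    def to_dict(self) -> dict:
        return {
            "markers": {"start": self.markers.start_index,
                        "trigger": self.markers.trigger_index,
                        "end": self.markers.end_index},
            "label": self.label,
            "exercise": self.exercise.to_dict() if self.exercise else None,
            "trajectories": [
                {"joint_label": t.joint_label,
                 "e": t.e.tolist(), "theta": t.theta.tolist()}
                for t in self.trajectories
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotionSegment":
        m = d["markers"]
        return cls(
            markers=SegmentMarkers(m["start"], m["trigger"], m["end"]),
            trajectories=[
                AngleTrajectory(t["joint_label"],
                                np.asarray(t["e"]), np.asarray(t["theta"]))
                for t in d["trajectories"]
            ],
            exercise=(ExerciseSpec.from_dict(d["exercise"])
                      if d.get("exercise") else None),
            label=d.get("label", "unknown"),
        )


def save_segments(segments: Sequence[MotionSegment], path) -> None:
    with open(Path(path), "w") as fh:
        json.dump({"segments": [s.to_dict() for s in segments]}, fh)


def load_segments(path) -> list[MotionSegment]:
    with open(Path(path)) as fh:
        data = json.load(fh)
    return [MotionSegment.from_dict(d) for d in data["segments"]]


def estimate_rest_angle(traj: AngleTrajectory,
                        params: SegmentationParams = SegmentationParams()) -> float:
    """Median angle over the initial rest window."""
    if traj.length < params.rest_window_s:
        raise ParameterError(
            f"trajectory spans {traj.length:.3f} s, shorter than the "
            f"rest window of {params.rest_window_s:.3f} s")
    mask = traj.e - traj.e[0] <= params.rest_window_s
    return float(np.median(traj.theta[mask]))


def segment_stream(traj: AngleTrajectory,
                   params: SegmentationParams = SegmentationParams(),
                   ) -> list[SegmentMarkers]:
    """Detect repetition markers on a (smoothed) primary-angle trajectory.

    Returns an ordered, non-overlapping list; empty for flat input.
    """
    n = len(traj)
    if n < 3 or traj.length < params.rest_window_s:
        return []
    rest = estimate_rest_angle(traj, params)
    theta = traj.theta
    dev = np.abs(theta - rest)

    peaks, _ = find_peaks(dev,
                          prominence=params.min_peak_prominence_deg,
                          height=params.onset_threshold_deg)
    markers: list[SegmentMarkers] = []
    prev_end = -1
    for k, p in enumerate(peaks):
        p = int(p)
        lo = prev_end + 1
        if p <= lo:
            continue
        # Start of motion: first frame above onset after being within it.
        below = np.nonzero(dev[lo:p] <= params.onset_threshold_deg)[0]
        start = lo + int(below[-1]) + 1 if below.size else lo
        if start >= p:
            continue
        # Trigger: first frame after the extremum moving back toward rest.
        after = np.nonzero(dev[p + 1:] < dev[p])[0]
        if not after.size:
            break
        trigger = p + 1 + int(after[0])
        # End: return to the start angle, else the inter-repetition reversal.
        nxt = int(peaks[k + 1]) if k + 1 < len(peaks) else n - 1
        ret = np.nonzero(np.abs(theta[trigger:nxt + 1] - theta[start])
                         <= params.return_tolerance_deg)[0]
        if ret.size:
            end = trigger + int(ret[0])
        elif nxt > p + 1:
            end = p + 1 + int(np.argmin(dev[p + 1:nxt]))
        else:
            continue
        if end < trigger:
            continue
        prev_end = end
        if traj.e[end] - traj.e[start] < params.min_segment_s:
            continue
        markers.append(SegmentMarkers(start, trigger, end))
    return markers


def _slice(traj: AngleTrajectory, m: SegmentMarkers) -> AngleTrajectory:
    e = traj.e[m.start_index:m.end_index + 1]
    return AngleTrajectory(traj.joint_label,
                           e - e[0],
                           traj.theta[m.start_index:m.end_index + 1].copy())


def segment_trajectories(trajectories: Sequence[AngleTrajectory],
                         params: SegmentationParams = SegmentationParams(),
                         exercise: Optional[ExerciseSpec] = None,
                         label: str = "unknown") -> list[MotionSegment]:
    """Segment pre-extracted angle trajectories.

    The first trajectory is the primary angle and drives marker detection
    (after smoothing); every trajectory is smoothed and sliced on the same
    frame ranges.  All trajectories must share one time grid.
    """
    if not trajectories:
        return []
    smoothed = [smooth_trajectory(t, params.smooth_window) for t in trajectories]
    markers = segment_stream(smoothed[0], params)
    return [
        MotionSegment(markers=m,
                      trajectories=[_slice(t, m) for t in smoothed],
                      exercise=exercise, label=label)
        for m in markers
    ]


def extract_segments(stream: LandmarkStream, spec: ExerciseSpec,
                     params: SegmentationParams = SegmentationParams(),
                     label: str = "unknown") -> list[MotionSegment]:
    """Full pipeline for a landmark stream: compute the feature-set angles,
    smooth, detect markers on the primary angle, slice all angles."""
    if len(stream) == 0:
        return []
    trajs = [angle_trajectory(stream, a) for a in spec.feature_set]
    return segment_trajectories(trajs, params, exercise=spec, label=label)
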