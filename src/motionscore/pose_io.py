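"""Landmark-stream I/O and exercise configuration.

A landmark stream is a time-stamped sequence of whole-body poses following
the standard 33-point schema emitted by browser/webcam pose estimators
(nose, eyes, ears, shoulders, elbows, wrists, fingers, hips, legs).
Coordinates are normalized to image width/height with y increasing
downward; values slightly outside [0, 1] are legal because estimators
track points that leave the frame.  Only x and y are carried — monocular
depth estimates are too unreliable for joint-angle work and the assessment
method deliberately ignores them.

Two on-disk dialects are supported:

* CSV with header ``frame,time_s,x0,y0,...,x32,y32`` and optional
  trailing ``v0...v32`` visibility columns (one row per frame);
* JSON-lines with one object per frame:
  ``{"frame": i, "time_s": t, "points": [[x, y], ...], "visibility": [...]}``.

Visibility is carried through round-trips but ignored by all downstream
math.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, ValidationError

N_LANDMARKS = 33

#: The 33-point whole-body schema, in index order.
LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

LANDMARK_INDEX: dict[str, int] = {n: i for i, n in enumerate(LANDMARK_NAMES)}

EXERCISES = ("abduction", "shoulder_flexion", "elbow_flexion")
SIDES = ("left", "right")
FEATURE_SET_KINDS = ("single", "dual", "triple")

#: The schema's per-hand "index finger" point stands in for the finger
#: landmark used in the wrist angle (the source method does not name a
#: specific hand point; the index-finger tip is the natural choice).
INDEX_FINGER = "index"


def landmark_index(name: str) -> int:
    """Map a symbolic landmark name to its fixed schema position."""
    try:
        return LANDMARK_INDEX[name]
    except KeyError:
        raise ValidationError(f"unknown landmark name: {name!r}") from None


class LandmarkFrame(NamedTuple):
    """A single pose: frame counter, timestamp, and 33 (x, y) points."""

    frame_index: int
    time_s: float
    points: np.ndarray  # (33, 2)
    visibility: Optional[np.ndarray] = None


@dataclass(frozen=True)
class AngleDefinition:
    """A joint angle: the vertex landmark and the two landmarks whose
    vectors from the vertex subtend it."""

    vertex: str
    ref1: str
    ref2: str
    label: str  # one of {"shoulder", "elbow", "wrist"}

    def __post_init__(self) -> None:
        if len({self.vertex, self.ref1, self.ref2}) != 3:
            raise ValidationError(
                f"angle landmarks must be distinct, got "
                f"({self.vertex}, {self.ref1}, {self.ref2})"
            )
        for name in (self.vertex, self.ref1, self.ref2):
            landmark_index(name)

    def to_dict(self) -> dict:
        return {"vertex": self.vertex, "ref1": self.ref1,
                "ref2": self.ref2, "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "AngleDefinition":
        return cls(d["vertex"], d["ref1"], d["ref2"], d["label"])


def shoulder_angle(side: str) -> AngleDefinition:
    """Shoulder angle: vertex at the shoulder, subtended by elbow and hip."""
    _check_side(side)
    return AngleDefinition(f"{side}_shoulder", f"{side}_elbow",
                           f"{side}_hip", "shoulder")


def elbow_angle(side: str) -> AngleDefinition:
    """Elbow angle: vertex at the elbow, subtended by shoulder and wrist."""
    _check_side(side)
    return AngleDefinition(f"{side}_elbow", f"{side}_shoulder",
                           f"{side}_wrist", "elbow")


def wrist_angle(side: str) -> AngleDefinition:
    """Wrist angle: vertex at the wrist, subtended by index finger and elbow."""
    _check_side(side)
    return AngleDefinition(f"{side}_wrist", f"{side}_{INDEX_FINGER}",
                           f"{side}_elbow", "wrist")


def _check_side(side: str) -> None:
    if side not in SIDES:
        raise ParameterError(f"side must be one of {SIDES}, got {side!r}")


@dataclass(frozen=True)
class ExerciseSpec:
    """One assessed exercise: which joint angles to extract and in what
    order.  The first angle is the primary (segmentation) angle."""

    exercise: str
    side: str
    feature_set: tuple[AngleDefinition, ...]
    camera_orientation: str = "front"  # documentation only

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ParameterError(
                f"exercise must be one of {EXERCISES}, got {self.exercise!r}")
        _check_side(self.side)
        if not 1 <= len(self.feature_set) <= 3:
            raise ValidationError("feature_set length must be in {1, 2, 3}")

    @property
    def primary_angle(self) -> AngleDefinition:
        return self.feature_set[0]

    @property
    def joint_labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.feature_set)

    def to_dict(self) -> dict:
        return {
            "exercise": self.exercise,
            "side": self.side,
            "feature_set": [a.to_dict() for a in self.feature_set],
            "camera_orientation": self.camera_orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExerciseSpec":
        return cls(
            exercise=d["exercise"],
            side=d["side"],
            feature_set=tuple(AngleDefinition.from_dict(a)
                              for a in d["feature_set"]),
            camera_orientation=d.get("camera_orientation", "front"),
        )


def default_exercise_spec(exercise: str, side: str,
                          feature_set_kind: str = "single") -> ExerciseSpec:
    """Build the standard feature set for an exercise.

    Shoulder movements (abduction, shoulder flexion) use the shoulder angle
    as primary; elbow flexion uses the elbow angle.  ``dual`` adds the other
    of {shoulder, elbow}; ``triple`` additionally adds the wrist angle.
    Abduction is captured face-on; both flexions side-on.
    """
    if exercise not in EXERCISES:
        raise ParameterError(
            f"exercise must be one of {EXERCISES}, got {exercise!r}")
    _check_side(side)
    if feature_set_kind not in FEATURE_SET_KINDS:
        raise ParameterError(
            f"feature_set_kind must be one of {FEATURE_SET_KINDS}, "
            f"got {feature_set_kind!r}")

    if exercise == "elbow_flexion":
        primary, secondary = elbow_angle(side), shoulder_angle(side)
    else:
        primary, secondary = shoulder_angle(side), elbow_angle(side)

    if feature_set_kind == "single":
        feats = (primary,)
    elif feature_set_kind == "dual":
        feats = (primary, secondary)
    else:
        feats = (primary, secondary, wrist_angle(side))

    orientation = "front" if exercise == "abduction" else "side"
    return ExerciseSpec(exercise=exercise, side=side, feature_set=feats,
                        camera_orientation=orientation)


@dataclass
class LandmarkStream:
    """An ordered sequence of landmark frames with strictly increasing
    timestamps."""

    time_s: np.ndarray           # (n,)
    points: np.ndarray           # (n, 33, 2)
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    visibility: Optional[np.ndarray] = None        # (n, 33) in [0, 1]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        n = len(self.time_s)
        if self.frame_index is None:
            self.frame_index = np.arange(n)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.points.shape != (n, N_LANDMARKS, 2):
            raise ValidationError(
                f"points must have shape (n, {N_LANDMARKS}, 2); "
                f"got {self.points.shape} for n={n}")
        if n and not np.all(np.isfinite(self.points)):
            raise ValidationError("landmark coordinates must be finite")
        if n and not np.all(np.isfinite(self.time_s)):
            raise ValidationError("time_s must be finite")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time_s must be strictly increasing")
        if self.visibility is not None:
            self.visibility = np.asarray(self.visibility, dtype=float)
            if self.visibility.shape != (n, N_LANDMARKS):
                raise ValidationError(
                    f"visibility must have shape (n, {N_LANDMARKS})")

    def __len__(self) -> int:
        return len(self.time_s)

    def __iter__(self) -> Iterator[LandmarkFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def frame(self, i: int) -> LandmarkFrame:
        vis = None if self.visibility is None else self.visibility[i]
        return LandmarkFrame(int(self.frame_index[i]), float(self.time_s[i]),
                             self.points[i], vis)

    def landmark_xy(self, name: str) -> np.ndarray:
        """(n, 2) array of one named landmark's coordinates over time."""
        return self.points[:, landmark_index(name), :]


def _csv_columns(with_visibility: bool) -> list[str]:
    cols = ["frame", "time_s"]
    for i in range(N_LANDMARKS):
        cols += [f"x{i}", f"y{i}"]
    if with_visibility:
        cols += [f"v{i}" for i in range(N_LANDMARKS)]
    return cols


def read_landmark_stream(path, dialect: str = "csv") -> LandmarkStream:
    """Read a landmark stream from CSV or JSON-lines."""
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "jsonl":
        return _read_jsonl(path)
    raise ParameterError(f"dialect must be 'csv' or 'jsonl', got {dialect!r}")


def _read_csv(path: Path) -> LandmarkStream:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    plain = _csv_columns(False)
    with_vis = _csv_columns(True)
    cols = list(df.columns)
    if cols == with_vis:
        has_vis = True
    elif cols == plain:
        has_vis = False
    else:
        raise ValidationError(
            f"{path}: unexpected CSV header; expected "
            f"frame,time_s,x0,y0,...,x{N_LANDMARKS - 1},"
            f"y{N_LANDMARKS - 1}[,v0...v{N_LANDMARKS - 1}]")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if len(values):
        bad = np.nonzero(~np.isfinite(values).all(axis=1))[0]
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric or missing value on data line {bad[0] + 2}")
    n = len(df)
    pts = values[:, 2:2 + 2 * N_LANDMARKS].reshape(n, N_LANDMARKS, 2)
    vis = values[:, 2 + 2 * N_LANDMARKS:] if has_vis else None
    return LandmarkStream(time_s=values[:, 1], points=pts,
                          frame_index=values[:, 0].astype(int),
                          visibility=vis)


def _read_jsonl(path: Path) -> LandmarkStream:
    times, frames, pts, vis = [], [], [], []
    any_vis = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                frames.append(int(obj["frame"]))
                times.append(float(obj["time_s"]))
                p = np.asarray(obj["points"], dtype=float)
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if p.shape != (N_LANDMARKS, 2):
                raise ValidationError(
                    f"{path}: line {lineno}: expected {N_LANDMARKS} "
                    f"(x, y) points, got shape {p.shape}")
            pts.append(p)
            v = obj.get("visibility")
            if v is not None:
                any_vis = True
            vis.append(v)
    if not times:
        return LandmarkStream(time_s=np.empty(0),
                              points=np.empty((0, N_LANDMARKS, 2)))
    visibility = None
    if any_vis:
        visibility = np.array(
            [v if v is not None else [np.nan] * N_LANDMARKS for v in vis],
            dtype=float)
    return LandmarkStream(time_s=np.array(times),
                          points=np.stack(pts),
                          frame_index=np.array(frames),
                          visibility=visibility)


def write_landmark_stream(stream: LandmarkStream, path,
                          dialect: str = "csv") -> None:
    """Write a landmark stream; re-reading yields an equal stream
    (coordinates round-trip at 8 decimals)."""
    path = Path(path)
    if dialect == "csv":
        _write_csv(stream, path)
    elif dialect == "jsonl":
        _write_jsonl(stream, path)
    else:
        raise ParameterError(
            f"dialect must be 'csv' or 'jsonl', got {dialect!r}")


def _write_csv(stream: LandmarkStream, path: Path) -> None:
    n = len(stream)
    has_vis = stream.visibility is not None
    cols = _csv_columns(has_vis)
    data = np.empty((n, len(cols)))
    data[:, 0] = stream.frame_index
    data[:, 1] = stream.time_s
    data[:, 2:2 + 2 * N_LANDMARKS] = stream.points.reshape(n, 2 * N_LANDMARKS)
    if has_vis:
        data[:, 2 + 2 * N_LANDMARKS:] = stream.visibility
    df = pd.DataFrame(data, columns=cols)
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, index=False, float_format="%.8f")


def _write_jsonl(stream: LandmarkStream, path: Path) -> None:
    with open(path, "w") as fh:
        for f in stream:
            obj = {
                "frame": f.frame_index,
                "time_s": round(f.time_s, 8),
                "points": [[round(float(x), 8), round(float(y), 8)]
                           for x, y in f.points],
            }
            if f.visibility is not None:
                obj["visibility"] = [round(float(v), 8) for v in f.visibility]
            fh.write(json.dumps(obj) + "\n")
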