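"""Synthetic movement generator emulating the study protocol.

The recordings behind the original study are private, so validation runs
on simulated data with the same protocol structure: 12 participants x
3 exercises (abduction, shoulder flexion, elbow flexion) x 2 sides, each
contributing two rounds of normal movement and one round of abnormal
movement, 10 repetitions per round -> 216 clips, 2160 motion segments.

A repetition is a raised-cosine angle pulse from the rest angle to the
peak and back.  Normal repetitions last about one second and span the
full range of motion; abnormal repetitions emulate movement against a
resistance band: slow (uniform 2-3 s), reduced range of motion (70% of
normal by default), with a tremor sinusoid superimposed.  Per-repetition
jitter (duration +-10%, peak +-5%), Gaussian sample noise, and
per-participant Gaussian offsets on rest and peak angles (SD 5 degrees)
provide within- and between-subject variability.  A clip concatenates
repetitions separated by short rest plateaus, with a 3 s lead-in (the
observer's countdown) and a ~2 s trailing hold.

Landmark streams are produced by planar forward kinematics of a
shoulder-anchored arm emitting the full 33-point schema, constructed so
that recomputing the joint angles recovers the generating trajectories
to numerical precision.  All draws flow through a single seeded
generator, so output is bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ParameterError
from .kinematics import AngleTrajectory
from .pose_io import (LANDMARK_NAMES, N_LANDMARKS, ExerciseSpec,
                      LandmarkStream, landmark_index)

JOINT_LABELS = ("shoulder", "elbow", "wrist")


@dataclass(frozen=True)
class MovementParams:
    """Shape and noise parameters of simulated repetitions (degrees,
    seconds, Hz).  ``peak_angle_deg`` may be smaller than
    ``rest_angle_deg`` for joints whose exercise shrinks the angle
    (elbow flexion)."""

    rest_angle_deg: float = 15.0
    peak_angle_deg: float = 165.0
    rep_duration_s: float = 1.0
    abnormal_duration_range_s: tuple[float, float] = (2.0, 3.0)
    rom_fraction: float = 0.7           # abnormal range-of-motion fraction
    tremor_amplitude_deg: float = 3.0   # abnormal only
    tremor_freq_hz: float = 6.0
    noise_sd_deg: float = 0.5
    fps: float = 60.0
    inter_rep_rest_s: float = 0.4
    lead_in_s: float = 3.0
    trail_hold_s: float = 2.0
    duration_jitter: float = 0.1        # fractional, per repetition
    peak_jitter: float = 0.05           # fractional, per repetition
    participant_sd_deg: float = 5.0     # between-subject rest/peak offsets
    posture_lean_sd_deg: float = 0.0    # per-clip baseline offset (confound)

    def __post_init__(self) -> None:
        if self.rep_duration_s <= 0 or self.fps <= 0:
            raise ParameterError("durations and fps must be positive")
        if not 0 < self.rom_fraction <= 1:
            raise ParameterError("rom_fraction must be in (0, 1]")
        if self.tremor_amplitude_deg < 0 or self.noise_sd_deg < 0:
            raise ParameterError("amplitudes must be non-negative")
        lo, hi = self.abnormal_duration_range_s
        if not 0 < lo <= hi:
            raise ParameterError("abnormal duration range must be positive")

    @property
    def amplitude_deg(self) -> float:
        """Signed full range of motion (peak minus rest)."""
        return self.peak_angle_deg - self.rest_angle_deg

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["abnormal_duration_range_s"] = list(self.abnormal_duration_range_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MovementParams":
        d = dict(d)
        if "abnormal_duration_range_s" in d:
            d["abnormal_duration_range_s"] = tuple(d["abnormal_duration_range_s"])
        return cls(**d)


@dataclass(frozen=True)
class ProtocolPlan:
    """Bookkeeping of the data-collection protocol."""

    n_participants: int = 12
    exercises: tuple[str, ...] = ("abduction", "shoulder_flexion",
                                  "elbow_flexion")
    sides: tuple[str, ...] = ("left", "right")
    normal_rounds: int = 2
    abnormal_rounds: int = 1
    reps_per_round: int = 10

    def __post_init__(self) -> None:
        if min(self.n_participants, self.normal_rounds,
               self.abnormal_rounds, self.reps_per_round) < 1:
            raise ParameterError("plan counts must be positive integers")

    @property
    def n_clips(self) -> int:
        return (self.n_participants * len(self.exercises) * len(self.sides)
                * (self.normal_rounds + self.abnormal_rounds))

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "exercises": list(self.exercises),
            "sides": list(self.sides),
            "normal_rounds": self.normal_rounds,
            "abnormal_rounds": self.abnormal_rounds,
            "reps_per_round": self.reps_per_round,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolPlan":
        d = dict(d)
        for key in ("exercises", "sides"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


#: Rest/peak angles of the primary joint per exercise.  Shoulder exercises
#: open the shoulder angle from near-rest to near-full elevation; elbow
#: flexion closes the elbow angle from extended toward full flexion.
_PRIMARY_DEFAULTS: dict[str, tuple[float, float]] = {
    "abduction": (15.0, 165.0),
    "shoulder_flexion": (15.0, 160.0),
    "elbow_flexion": (170.0, 40.0),
}

#: Resting value and coupling of the non-primary ("compensation") angles:
#: each deviates from its base proportionally to the primary excursion,
#: emulating mild physiological coupling, and abnormal tremor bleeds into
#: them at half amplitude.
_SECONDARY_BASE: dict[str, float] = {"shoulder": 20.0, "elbow": 160.0,
                                     "wrist": 160.0}
_SECONDARY_COUPLING: dict[str, float] = {"shoulder": 0.10, "elbow": 0.08,
                                         "wrist": 0.05}
_SECONDARY_SIGN: dict[str, float] = {"shoulder": 1.0, "elbow": -1.0,
                                     "wrist": -1.0}
_SECONDARY_TREMOR_FRACTION = 0.5


def primary_joint(exercise: str) -> str:
    return "elbow" if exercise == "elbow_flexion" else "shoulder"


def default_movement_params(exercise: str, **overrides) -> MovementParams:
    """Movement parameters with the exercise's primary-joint rest/peak."""
    try:
        rest, peak = _PRIMARY_DEFAULTS[exercise]
    except KeyError:
        raise ParameterError(f"unknown exercise {exercise!r}") from None
    return MovementParams(rest_angle_deg=rest, peak_angle_deg=peak, **overrides)


def _rep_shape(params: MovementParams, condition: str,
               rng: np.random.Generator) -> tuple[float, float, float]:
    """Draw one repetition's (duration, signed amplitude, tremor phase)."""
    if condition == "abnormal":
        duration = rng.uniform(*params.abnormal_duration_range_s)
        amp = params.amplitude_deg * params.rom_fraction
    elif condition == "normal":
        duration = params.rep_duration_s * (
            1.0 + rng.uniform(-params.duration_jitter, params.duration_jitter))
        amp = params.amplitude_deg
    else:
        raise ParameterError(
            f"condition must be 'normal' or 'abnormal', got {condition!r}")
    amp *= 1.0 + rng.uniform(-params.peak_jitter, params.peak_jitter)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return duration, amp, phase


def _pulse(t: np.ndarray, duration: float) -> np.ndarray:
    """Raised-cosine shape on [0, duration]: 0 at the ends, 1 at the middle."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))


def generate_rep_profile(params: MovementParams, condition: str,
                         rng: np.random.Generator) -> AngleTrajectory:
    """One repetition's primary-angle trajectory sampled at ``fps``."""
    duration, amp, phase = _rep_shape(params, condition, rng)
    n = max(2, int(round(duration * params.fps)))
    n += n % 2  # even sample count puts a sample exactly on the peak
    t = np.arange(n + 1) / params.fps
    shape = _pulse(t, t[-1])
    theta = params.rest_angle_deg + amp * shape
    if condition == "abnormal" and params.tremor_amplitude_deg > 0:
        theta = theta + (params.tremor_amplitude_deg * shape
                         * np.sin(2.0 * np.pi * params.tremor_freq_hz * t + phase))
    if params.noise_sd_deg > 0:
        theta = theta + rng.normal(0.0, params.noise_sd_deg, theta.shape)
    return AngleTrajectory(joint_label="primary", e=t, theta=theta)


def _clip_profile(params: MovementParams, condition: str, n_reps: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free clip skeleton: (e, excursion fraction, tremor signal).

    The excursion fraction is the pulse shape in [0, 1] scaled by each
    repetition's jittered amplitude relative to the nominal full range,
    zero during rest plateaus.
    """
    fps = params.fps
    n_lead = int(round(params.lead_in_s * fps))
    n_rest = int(round(params.inter_rep_rest_s * fps))
    n_trail = int(round(params.trail_hold_s * fps))

    fraction_parts = [np.zeros(n_lead)]
    tremor_parts = [np.zeros(n_lead)]
    full = params.amplitude_deg
    for r in range(n_reps):
        duration, amp, phase = _rep_shape(params, condition, rng)
        n = max(2, int(round(duration * fps)))
        n += n % 2
        t = np.arange(n + 1) / fps
        shape = _pulse(t, t[-1])
        fraction_parts.append(shape * (amp / full))
        if condition == "abnormal" and params.tremor_amplitude_deg > 0:
            tremor_parts.append(
                params.tremor_amplitude_deg * shape
                * np.sin(2.0 * np.pi * params.tremor_freq_hz * t + phase))
        else:
            tremor_parts.append(np.zeros(n + 1))
        gap = n_rest if r < n_reps - 1 else n_trail
        fraction_parts.append(np.zeros(gap))
        tremor_parts.append(np.zeros(gap))
    if n_reps == 0:
        fraction_parts.append(np.zeros(n_trail))
        tremor_parts.append(np.zeros(n_trail))

    fraction = np.concatenate(fraction_parts)
    tremor = np.concatenate(tremor_parts)
    e = np.arange(len(fraction)) / fps
    return e, fraction, tremor


def generate_clip(params: MovementParams, condition: str, n_reps: int = 10,
                  rng: Optional[np.random.Generator] = None) -> AngleTrajectory:
    """A full clip of the primary angle: lead-in rest, ``n_reps``
    repetitions separated by rest plateaus, trailing hold."""
    if rng is None:
        rng = np.random.default_rng(0)
    e, fraction, tremor = _clip_profile(params, condition, n_reps, rng)
    theta = params.rest_angle_deg + params.amplitude_deg * fraction + tremor
    if params.posture_lean_sd_deg > 0:
        theta = theta + rng.normal(0.0, params.posture_lean_sd_deg)
    if params.noise_sd_deg > 0:
        theta = theta + rng.normal(0.0, params.noise_sd_deg, theta.shape)
    return AngleTrajectory(joint_label="primary", e=e, theta=theta)


def generate_clip_set(params: MovementParams, condition: str, exercise: str,
                      n_reps: int = 10,
                      rng: Optional[np.random.Generator] = None,
                      ) -> dict[str, AngleTrajectory]:
    """Trajectories for all three joints of one clip, sharing a time grid.

    The exercise's primary joint carries the repetition pulse; the other
    two joints sit near their resting values with a small excursion
    coupled to the primary movement (compensation), attenuated tremor in
    the abnormal condition, and independent sample noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    prim = primary_joint(exercise)
    e, fraction, tremor = _clip_profile(params, condition, n_reps, rng)
    lean = (rng.normal(0.0, params.posture_lean_sd_deg)
            if params.posture_lean_sd_deg > 0 else 0.0)

    out: dict[str, AngleTrajectory] = {}
    full = abs(params.amplitude_deg)
    for label in JOINT_LABELS:
        if label == prim:
            theta = (params.rest_angle_deg + params.amplitude_deg * fraction
                     + tremor + lean)
        else:
            base = _SECONDARY_BASE[label]
            excursion = (_SECONDARY_COUPLING[label] * _SECONDARY_SIGN[label]
                         * full * np.abs(fraction))
            theta = (base + excursion
                     + _SECONDARY_TREMOR_FRACTION * tremor + lean)
        if params.noise_sd_deg > 0:
            theta = theta + rng.normal(0.0, params.noise_sd_deg, theta.shape)
        out[label] = AngleTrajectory(joint_label=label, e=e.copy(), theta=theta)
    return out


@dataclass
class ClipRecord:
    """One simulated recording with its protocol metadata."""

    participant: int
    exercise: str
    side: str
    condition: str       # {normal, abnormal}
    round_index: int
    trajectories: dict[str, AngleTrajectory]


def generate_protocol_dataset(plan: Optional[ProtocolPlan] = None,
                              params: Optional[MovementParams] = None,
                              seed: int = 0) -> list[ClipRecord]:
    """Simulate the full protocol: every participant performs every
    exercise on both sides, normal rounds then one abnormal round.

    Per-participant Gaussian offsets (SD ``participant_sd_deg``) shift
    rest and peak angles, giving realistic between-subject variability.
    If ``params`` is given, its shape/noise settings apply to every
    exercise while rest/peak angles still come from the per-exercise
    defaults (one pair cannot fit all three movements).
    """
    plan = plan or ProtocolPlan()
    rng = np.random.default_rng(seed)
    clips: list[ClipRecord] = []
    for pid in range(plan.n_participants):
        rest_off = rng.normal(0.0, (params or MovementParams()).participant_sd_deg)
        peak_off = rng.normal(0.0, (params or MovementParams()).participant_sd_deg)
        for exercise in plan.exercises:
            if params is None:
                base = default_movement_params(exercise)
            else:
                rest, peak = _PRIMARY_DEFAULTS[exercise]
                base = replace(params, rest_angle_deg=rest, peak_angle_deg=peak)
            direction = 1.0 if base.amplitude_deg >= 0 else -1.0
            p = replace(base,
                        rest_angle_deg=base.rest_angle_deg + rest_off,
                        peak_angle_deg=base.peak_angle_deg + direction * peak_off)
            for side in plan.sides:
                rounds = (["normal"] * plan.normal_rounds
                          + ["abnormal"] * plan.abnormal_rounds)
                for ridx, condition in enumerate(rounds):
                    trajs = generate_clip_set(p, condition, exercise,
                                              plan.reps_per_round, rng)
                    clips.append(ClipRecord(participant=pid, exercise=exercise,
                                            side=side, condition=condition,
                                            round_index=ridx,
                                            trajectories=trajs))
    return clips


# ---------------------------------------------------------------------------
# Forward kinematics: angles -> 33-point landmark stream

def _rot(v: np.ndarray, deg: np.ndarray) -> np.ndarray:
    """Rotate 2-vectors by angles in degrees (counterclockwise in x-right,
    y-down image coordinates; the handedness is irrelevant for interior
    angles)."""
    rad = np.radians(deg)
    c, s = np.cos(rad), np.sin(rad)
    x, y = v[..., 0], v[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


#: Static base pose (normalized image coordinates, y down).
_BASE_POSE: dict[str, tuple[float, float]] = {
    "nose": (0.50, 0.12),
    "left_shoulder": (0.58, 0.32), "right_shoulder": (0.42, 0.32),
    "left_hip": (0.56, 0.62), "right_hip": (0.44, 0.62),
    "left_knee": (0.56, 0.80), "right_knee": (0.44, 0.80),
    "left_ankle": (0.56, 0.95), "right_ankle": (0.44, 0.95),
}

_UPPER_ARM = 0.16
_FOREARM = 0.15
_HAND = 0.07


def angles_to_landmarks(trajectories: Union[AngleTrajectory,
                                            Mapping[str, AngleTrajectory]],
                        spec: ExerciseSpec) -> LandmarkStream:
    """Planar forward kinematics: emit a 33-point landmark stream whose
    recomputed joint angles equal the given trajectories.

    Accepts the primary trajectory alone or a mapping of joint label to
    trajectory; missing elbow/wrist angles default to 165 and 160 degrees.
    The active arm is articulated from a fixed shoulder; all other
    landmarks hold a static plausible pose.
    """
    if isinstance(trajectories, AngleTrajectory):
        trajs = {primary_joint(spec.exercise): trajectories}
    else:
        trajs = dict(trajectories)
    prim = primary_joint(spec.exercise)
    if prim not in trajs:
        raise ParameterError(
            f"trajectories must include the primary joint {prim!r}")
    ref = trajs[prim]
    n = len(ref)

    def angle_series(label: str, default: float) -> np.ndarray:
        t = trajs.get(label)
        if t is None:
            return np.full(n, default)
        if len(t) != n or not np.allclose(t.e, ref.e):
            raise ParameterError(
                f"trajectory for {label!r} does not share the primary time grid")
        return t.theta

    theta_sh = angle_series("shoulder", 20.0)
    theta_el = angle_series("elbow", 165.0)
    theta_wr = angle_series("wrist", 160.0)

    side = spec.side
    points = np.empty((n, N_LANDMARKS, 2))
    # static scaffold: everything starts from the base pose, with unnamed
    # landmarks interpolated near the head
    static = np.full((N_LANDMARKS, 2), (0.5, 0.15))
    for name, xy in _BASE_POSE.items():
        static[landmark_index(name)] = xy
    # inactive arm hangs down
    other = "right" if side == "left" else "left"
    osh = np.array(_BASE_POSE[f"{other}_shoulder"])
    points[:] = static
    points[:, landmark_index(f"{other}_elbow")] = osh + (0.0, _UPPER_ARM)
    points[:, landmark_index(f"{other}_wrist")] = osh + (0.0, _UPPER_ARM + _FOREARM)
    for part in ("pinky", "index", "thumb"):
        points[:, landmark_index(f"{other}_{part}")] = (
            osh + (0.0, _UPPER_ARM + _FOREARM + _HAND))

    S = np.array(_BASE_POSE[f"{side}_shoulder"])
    H = np.array(_BASE_POSE[f"{side}_hip"])
    u = (H - S) / np.linalg.norm(H - S)          # shoulder-to-hip direction
    sign = 1.0 if side == "left" else -1.0       # mirror rotations across sides
    d1 = _rot(np.broadcast_to(u, (n, 2)), sign * theta_sh)
    E = S + _UPPER_ARM * d1
    d2 = _rot(-d1, -sign * theta_el)
    W = E + _FOREARM * d2
    d3 = _rot(-d2, sign * theta_wr)
    I = W + _HAND * d3

    points[:, landmark_index(f"{side}_elbow")] = E
    points[:, landmark_index(f"{side}_wrist")] = W
    points[:, landmark_index(f"{side}_index")] = I
    points[:, landmark_index(f"{side}_pinky")] = I
    points[:, landmark_index(f"{side}_thumb")] = W + 0.5 * _HAND * d3

    return LandmarkStream(time_s=ref.e.copy(), points=points)
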