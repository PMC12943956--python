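"""Scoring a motion segment against the normal baseline.

Three steps, composed by :func:`assess_segment`:

1. **Distance** — multi-dimensional dynamic time warping between the
   segment's joint-angle trajectories and the baseline's mean
   trajectories, ``d_alpha = Multi-DTW(alpha, B)``.  The default
   configuration uses dependent-mode DTW (one alignment over vector-valued
   samples, per-step cost the Euclidean norm of the per-joint angle
   differences, all joints equally weighted), the classic symmetric step
   pattern (diagonal/left/up), no warping-window band, and normalization
   by the optimal warping-path length so that distances read as mean
   per-step angular error in degrees rather than cumulative sums over a
   segment's frames.  Independent mode (mean of per-joint DTWs) and
   alternative local costs are available through :class:`DtwConfig`.
2. **Standardization** — ``Z_alpha = (d_alpha - mu) / sigma`` against the
   normal sample's distance statistics.
3. **Score** — ``S_alpha = 100 / max(Z_alpha, 1)``: a perfect 100 whenever
   the distance is within one SD of the normal mean, decaying
   hyperbolically beyond (50 at Z = 2, 25 at Z = 4); the score never
   reaches 0 exactly.

The DTW dynamic program is accumulated with a numba-compiled kernel when
numba is importable and a pure-NumPy/Python loop otherwise; both routes
compute identical recurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .baseline import Baseline
from .errors import DegenerateBaselineError, ParameterError, ValidationError
from .segmentation import MotionSegment

_MODES = ("dependent", "independent")
_COSTS = ("abs", "squared", "euclidean")
_NORMS = ("path_length", "none")


@dataclass(frozen=True)
class DtwConfig:
    """Knobs of the DTW variant used for baseline comparison."""

    multivariate_mode: str = "dependent"
    local_cost: str = "euclidean"
    path_normalization: str = "path_length"
    window_band: Optional[int] = None   # Sakoe-Chiba half-width in samples
    weights: Optional[tuple[float, ...]] = None  # per-joint, default equal

    def __post_init__(self) -> None:
        if self.multivariate_mode not in _MODES:
            raise ParameterError(f"multivariate_mode must be in {_MODES}")
        if self.local_cost not in _COSTS:
            raise ParameterError(f"local_cost must be in {_COSTS}")
        if self.path_normalization not in _NORMS:
            raise ParameterError(f"path_normalization must be in {_NORMS}")
        if self.window_band is not None and self.window_band < 0:
            raise ParameterError("window_band must be non-negative")

    def to_dict(self) -> dict:
        return {
            "multivariate_mode": self.multivariate_mode,
            "local_cost": self.local_cost,
            "path_normalization": self.path_normalization,
            "window_band": self.window_band,
            "weights": list(self.weights) if self.weights else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DtwConfig":
        w = d.get("weights")
        return cls(
            multivariate_mode=d.get("multivariate_mode", "dependent"),
            local_cost=d.get("local_cost", "euclidean"),
            path_normalization=d.get("path_normalization", "path_length"),
            window_band=d.get("window_band"),
            weights=tuple(w) if w else None,
        )


def _accumulate_py(cost: np.ndarray, band: int) -> np.ndarray:
    n, m = cost.shape
    D = np.full((n, m), np.inf)
    for i in range(n):
        if band >= 0:
            c = i * (m - 1) / max(n - 1, 1)
            jlo = max(0, int(np.ceil(c - band)))
            jhi = min(m - 1, int(np.floor(c + band)))
        else:
            jlo, jhi = 0, m - 1
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                best = 0.0
            else:
                best = np.inf
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
            D[i, j] = cost[i, j] + best
    return D


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _accumulate = njit(cache=False)(_accumulate_py)
except ImportError:  # pragma: no cover
    _accumulate = _accumulate_py


def _optimal_path_length(D: np.ndarray) -> int:
    """Length of the optimal warping path by backtracking; ties prefer the
    diagonal step (then the vertical), keeping the result deterministic."""
    i, j = D.shape[0] - 1, D.shape[1] - 1
    length = 1
    while i > 0 or j > 0:
        candidates = []
        if i > 0 and j > 0:
            candidates.append((D[i - 1, j - 1], 0, i - 1, j - 1))
        if i > 0:
            candidates.append((D[i - 1, j], 1, i - 1, j))
        if j > 0:
            candidates.append((D[i, j - 1], 2, i, j - 1))
        _, _, i, j = min(candidates, key=lambda c: (c[0], c[1]))
        length += 1
    return length


def _dtw_from_cost(cost: np.ndarray, config: DtwConfig) -> float:
    band = -1 if config.window_band is None else int(config.window_band)
    D = _accumulate(np.ascontiguousarray(cost, dtype=np.float64), band)
    total = float(D[-1, -1])
    if not np.isfinite(total):
        raise ParameterError(
            "warping band too narrow: no admissible path reaches the corner")
    if config.path_normalization == "path_length":
        return total / _optimal_path_length(D)
    return total


def _local_cost_1d(a: np.ndarray, b: np.ndarray, local_cost: str) -> np.ndarray:
    diff = a[:, None] - b[None, :]
    if local_cost == "squared":
        return diff * diff
    return np.abs(diff)  # 'abs' and 'euclidean' coincide in 1-D


def dtw_distance(a: Sequence[float], b: Sequence[float],
                 config: DtwConfig = DtwConfig()) -> float:
    """DTW between two scalar sequences (classic symmetric step pattern)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("DTW requires two nonempty sequences")
    return _dtw_from_cost(_local_cost_1d(a, b, config.local_cost), config)


def multi_dtw_distance(segment: MotionSegment, base: Baseline,
                       config: DtwConfig = DtwConfig()) -> float:
    """Multi-dimensional DTW between a segment and the baseline means.

    Dependent mode aligns vector-valued samples with a per-step cost equal
    to the (weighted) Euclidean norm across joints; independent mode
    averages per-joint scalar DTWs.  With a single joint both modes reduce
    exactly to :func:`dtw_distance`.
    """
    if segment.joint_labels != base.joint_labels:
        raise ValidationError(
            f"feature-set mismatch: segment has {segment.joint_labels}, "
            f"baseline has {base.joint_labels}")
    n_joints = len(base.joint_labels)
    if n_joints == 0:
        raise ValidationError("baseline carries no mean trajectories")
    weights = np.ones(n_joints) if config.weights is None \
        else np.asarray(config.weights, dtype=float)
    if weights.shape != (n_joints,):
        raise ParameterError("weights length must equal the joint count")

    X = segment.values_matrix()
    Y = base.values_matrix()
    if config.multivariate_mode == "independent":
        return float(np.average(
            [dtw_distance(X[:, j], Y[:, j], config) for j in range(n_joints)],
            weights=weights))
    if n_joints == 1:
        return dtw_distance(X[:, 0], Y[:, 0], config)
    Xw = X * weights
    Yw = Y * weights
    if config.local_cost == "squared":
        cost = cdist(Xw, Yw, metric="sqeuclidean")
    elif config.local_cost == "abs":
        cost = cdist(Xw, Yw, metric="cityblock")
    else:
        cost = cdist(Xw, Yw, metric="euclidean")
    return _dtw_from_cost(cost, config)


def z_score(d_alpha: float, base: Baseline) -> float:
    """Standardize a distance against the normal sample: (d - mu) / sigma."""
    if base.degenerate or base.sigma <= 0:
        raise DegenerateBaselineError(
            "baseline distance SD is zero; Z-scores are undefined")
    return (float(d_alpha) - base.mu) / base.sigma


def score_from_z(z_alpha: float) -> float:
    """Map a Z-score to the 0-100 scale: S = 100 / max(Z, 1)."""
    z = float(z_alpha)
    if not np.isfinite(z):
        raise ParameterError("Z-score must be finite")
    return 100.0 / max(z, 1.0)


@dataclass
class AssessmentResult:
    """Distance, Z-score and score of one segment against one baseline."""

    d_alpha: float
    z_alpha: float
    s_alpha: float
    segment_ref: Optional[str] = None
    baseline_ref: Optional[str] = None


def assess_segment(segment: MotionSegment, base: Baseline,
                   config: DtwConfig = DtwConfig(),
                   segment_ref: Optional[str] = None,
                   baseline_ref: Optional[str] = None) -> AssessmentResult:
    """Distance -> Z-score -> score for one motion segment."""
    d = multi_dtw_distance(segment, base, config)
    z = z_score(d, base)
    return AssessmentResult(d_alpha=d, z_alpha=z, s_alpha=score_from_z(z),
                            segment_ref=segment_ref, baseline_ref=baseline_ref)
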