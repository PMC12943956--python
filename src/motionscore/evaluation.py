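"""Experiment pipeline: subset split, feature variants, significance tests.

Mirrors the study's analysis: the normal segments of each exercise are
randomly split per participant into a baseline subset B and a test subset
N of equal size; all abnormal segments form subset A.  For each feature
variant the baseline (mean trajectories plus mu/sigma) is built from B
only, distances of all segments to it are computed, and the three subset
pairs (N-B, N-A, B-A) are compared with the independent-samples t-test
(pooled variance by default; Welch behind a flag) and the two-sided
Mann-Whitney U-test.  No multiple-testing correction is applied — raw
p-values are reported.  Left and right sides are pooled.

Feature variants: triple (primary + other of shoulder/elbow + wrist),
dual (primary + other), single (primary only), and the three individual
angles.

The experiment report also summarizes Z-scores and 0-100 scores per
subset for the single-angle variant and runs the closest-k abnormal
analysis (the k abnormal segments nearest the baseline, default k = 10),
reporting the mean and SD of their distance, Z-score, and score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assessment import DtwConfig, multi_dtw_distance, score_from_z, z_score
from .baseline import Baseline, build_baseline
from .errors import ParameterError, StatisticsError, ValidationError
from .segmentation import MotionSegment, SegmentationParams, segment_trajectories
from .synth import ClipRecord, JOINT_LABELS, primary_joint

PAIRS = (("N", "B"), ("N", "A"), ("B", "A"))
VARIANTS = ("triple", "dual", "single", "shoulder", "elbow", "wrist")


def variant_labels(exercise: str, variant: str) -> tuple[str, ...]:
    """Joint labels (in order) of a feature variant for an exercise."""
    prim = primary_joint(exercise)
    secondary = "elbow" if prim == "shoulder" else "shoulder"
    if variant == "triple":
        return (prim, secondary, "wrist")
    if variant == "dual":
        return (prim, secondary)
    if variant == "single":
        return (prim,)
    if variant in JOINT_LABELS:
        return (variant,)
    raise ParameterError(f"unknown feature variant {variant!r}")


@dataclass
class SegmentRecord:
    """A motion segment with its protocol metadata."""

    participant: int
    exercise: str
    side: str
    condition: str
    round_index: int
    segment: MotionSegment


def segment_dataset(clips: Sequence[ClipRecord],
                    params: SegmentationParams = SegmentationParams(),
                    ) -> list[SegmentRecord]:
    """Segment every clip on its primary angle; all three joint angles are
    sliced on the primary's markers."""
    records: list[SegmentRecord] = []
    for clip in clips:
        prim = primary_joint(clip.exercise)
        order = [prim] + [l for l in JOINT_LABELS if l != prim]
        trajs = [clip.trajectories[l] for l in order]
        for seg in segment_trajectories(trajs, params, label=clip.condition):
            records.append(SegmentRecord(
                participant=clip.participant, exercise=clip.exercise,
                side=clip.side, condition=clip.condition,
                round_index=clip.round_index, segment=seg))
    return records


@dataclass
class SubsetAssignment:
    """Maps each segment record (by position) to subset B, N, or A."""

    subsets: np.ndarray  # array of 'B'/'N'/'A', aligned with the records
    seed: int

    def indices(self, subset: str) -> np.ndarray:
        return np.nonzero(self.subsets == subset)[0]


def split_subsets(records: Sequence[SegmentRecord],
                  seed: int = 0) -> SubsetAssignment:
    """Per-participant random half/half split of normal segments into B
    and N; abnormal segments all go to A.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    subsets = np.array(["A"] * len(records), dtype=object)
    by_participant: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        if r.condition == "normal":
            by_participant.setdefault(r.participant, []).append(i)
    for pid in sorted(by_participant):
        idx = np.array(by_participant[pid])
        if len(idx) % 2:
            raise ValidationError(
                f"participant {pid} has an odd number of normal segments "
                f"({len(idx)}); cannot split evenly into B and N")
        perm = rng.permutation(len(idx))
        half = len(idx) // 2
        subsets[idx[perm[:half]]] = "B"
        subsets[idx[perm[half:]]] = "N"
    return SubsetAssignment(subsets=subsets, seed=seed)


def distance_table(records: Sequence[SegmentRecord],
                   assignment: SubsetAssignment,
                   variant: str = "single",
                   dtw_config: DtwConfig = DtwConfig(),
                   grid_step: Optional[float] = None,
                   ) -> tuple[pd.DataFrame, Baseline]:
    """Baseline from subset B only, then distances for every segment.

    Returns the per-segment table (columns: subset, participant, side,
    condition, distance) and the fitted baseline.
    """
    if not records:
        raise ParameterError("distance_table requires segment records")
    exercise = records[0].exercise
    labels = variant_labels(exercise, variant)
    b_idx = assignment.indices("B")
    if b_idx.size == 0:
        raise ParameterError("subset B is empty; cannot build a baseline")
    b_segments = [records[i].segment.subset(labels) for i in b_idx]
    base = build_baseline(b_segments, grid_step=grid_step,
                          dtw_config=dtw_config)
    rows = []
    for i, r in enumerate(records):
        d = multi_dtw_distance(r.segment.subset(labels), base, dtw_config)
        rows.append({"subset": assignment.subsets[i],
                     "participant": r.participant, "side": r.side,
                     "condition": r.condition, "distance": d})
    return pd.DataFrame(rows), base


def compare_subsets(group1: Sequence[float], group2: Sequence[float],
                    welch: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test and Mann-Whitney U-test.

    Returns ``(t_p, u_p)``.  The t-test pools variances unless ``welch``.
    The U-test applies the standard tie correction (scipy's default,
    exact for small tie-free samples).
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each group needs at least 2 observations")
    t_res = stats.ttest_ind(a, b, equal_var=not welch)
    u_res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(t_res.pvalue), float(u_res.pvalue)


@dataclass
class ExperimentReport:
    """Full analysis grid plus scoring summaries."""

    comparisons: pd.DataFrame       # exercise x variant x pair p-values
    distance_stats: pd.DataFrame    # exercise x variant x subset mean/SD
    score_summaries: pd.DataFrame   # exercise x subset Z/score summaries
    closest_abnormal: pd.DataFrame  # closest-k abnormal segment statistics
    degenerate: list[tuple[str, str]] = field(default_factory=list)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        self.distance_stats.to_csv(out / "distance_stats.csv", index=False)
        self.score_summaries.to_csv(out / "score_summaries.csv", index=False)
        self.closest_abnormal.to_csv(out / "closest_abnormal.csv", index=False)


def run_experiment(records: Sequence[SegmentRecord],
                   seed: int = 0,
                   dtw_config: DtwConfig = DtwConfig(),
                   variants: Sequence[str] = VARIANTS,
                   k_closest: int = 10,
                   welch: bool = False,
                   grid_step: Optional[float] = None) -> ExperimentReport:
    """Run the full analysis grid over every exercise present in the
    records: subset split, per-variant distances, pairwise tests, and
    single-angle Z/score summaries with the closest-k abnormal analysis."""
    exercises = sorted({r.exercise for r in records})
    comp_rows, dist_rows, score_rows, closest_rows = [], [], [], []
    degenerate: list[tuple[str, str]] = []

    for exercise in exercises:
        ex_records = [r for r in records if r.exercise == exercise]
        assignment = split_subsets(ex_records, seed=seed)
        for variant in variants:
            table, base = distance_table(ex_records, assignment, variant,
                                         dtw_config, grid_step)
            if base.degenerate:
                degenerate.append((exercise, variant))
            groups = {s: table.loc[table.subset == s, "distance"].to_numpy()
                      for s in ("B", "N", "A")}
            for s in ("B", "N", "A"):
                g = groups[s]
                dist_rows.append({
                    "exercise": exercise, "variant": variant, "subset": s,
                    "n": len(g),
                    "mean": g.mean() if len(g) else np.nan,
                    "sd": g.std(ddof=1) if len(g) > 1 else np.nan,
                })
            for g1, g2 in PAIRS:
                if len(groups[g1]) < 2 or len(groups[g2]) < 2:
                    t_p = u_p = np.nan
                else:
                    t_p, u_p = compare_subsets(groups[g1], groups[g2], welch)
                comp_rows.append({
                    "exercise": exercise, "variant": variant,
                    "pair": f"{g1}-{g2}", "t_p": t_p, "u_p": u_p,
                })
            if variant == "single":
                if base.degenerate:
                    continue  # Z-scores undefined against a zero-spread baseline
                z = np.array([z_score(d, base) for d in table.distance])
                s = np.array([score_from_z(v) for v in z])
                table = table.assign(z=z, score=s)
                for sub in ("B", "N", "A"):
                    part = table[table.subset == sub]
                    for metric in ("z", "score"):
                        vals = part[metric].to_numpy()
                        q1, med, q3 = (np.percentile(vals, [25, 50, 75])
                                       if len(vals) else (np.nan,) * 3)
                        score_rows.append({
                            "exercise": exercise, "subset": sub,
                            "metric": metric, "n": len(vals),
                            "mean": vals.mean() if len(vals) else np.nan,
                            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                            "q1": q1, "median": med, "q3": q3,
                        })
                abn = table[table.subset == "A"].nsmallest(k_closest, "distance")
                for metric in ("distance", "z", "score"):
                    vals = abn[metric].to_numpy()
                    closest_rows.append({
                        "exercise": exercise, "k": len(vals), "metric": metric,
                        "mean": vals.mean() if len(vals) else np.nan,
                        "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    })

    return ExperimentReport(
        comparisons=pd.DataFrame(comp_rows),
        distance_stats=pd.DataFrame(dist_rows),
        score_summaries=pd.DataFrame(score_rows),
        closest_abnormal=pd.DataFrame(closest_rows),
        degenerate=degenerate,
    )
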