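import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import motionscore as ms
from motionscore.errors import (DegenerateBaselineError, ParameterError,
                                ValidationError)
from motionscore.baseline import Baseline, MeanTrajectory

from conftest import make_segments

UNNORM = ms.DtwConfig(path_normalization="none", local_cost="abs")


def enumerate_paths(n, m):
    """All monotone warping paths from (0,0) to (n-1,m-1)."""
    def rec(i, j):
        if i == n - 1 and j == m - 1:
            yield ((i, j),)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                for rest in rec(ni, nj):
                    yield ((i, j),) + rest
    return rec(0, 0)


def brute_force_dtw(cost):
    """Minimum total cost over an exhaustive path enumeration."""
    n, m = cost.shape
    return min(sum(cost[i, j] for i, j in path)
               for path in enumerate_paths(n, m))


def toy_baseline(values, labels=("shoulder",), mu=1.0, sigma=0.5):
    """Baseline whose mean trajectories are the given (n, k) matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(labels) == 1:
        values = values.T
    grid = np.linspace(0, 1, values.shape[0])
    means = [MeanTrajectory(lbl, grid, values[:, j], 1.0)
             for j, lbl in enumerate(labels)]
    return Baseline(means=means, mu=mu, sigma=sigma, n_segments=2)


def toy_segment(values, labels=("shoulder",)):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(labels) == 1:
        values = values.T
    e = np.linspace(0, 1, values.shape[0])
    from motionscore.segmentation import MotionSegment, SegmentMarkers
    trajs = [ms.AngleTrajectory(lbl, e, values[:, j])
             for j, lbl in enumerate(labels)]
    return MotionSegment(
        markers=SegmentMarkers(0, 1, max(1, values.shape[0] - 1)),
        trajectories=trajs)


class TestDtwDistance:
    def test_identity_is_zero(self, rng):
        a = rng.uniform(0, 180, 30)
        assert ms.dtw_distance(a, a) == 0.0
        assert ms.dtw_distance(a, a, UNNORM) == 0.0

    def test_duplicate_element_warps_to_zero(self):
        assert ms.dtw_distance([1, 2, 3], [1, 2, 2, 3], UNNORM) == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            ms.dtw_distance([], [1.0])

    def test_against_exhaustive_path_oracle(self):
        """DP accumulation equals a brute-force enumeration over all
        monotone warping paths for 200 random small instances."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            n, m = rng.integers(1, 7, size=2)
            a = rng.uniform(0, 10, n)
            b = rng.uniform(0, 10, m)
            cost = np.abs(a[:, None] - b[None, :])
            assert ms.dtw_distance(a, b, UNNORM) == pytest.approx(
                brute_force_dtw(cost), abs=1e-10)

    @given(seed=st.integers(0, 300))
    def test_symmetry_and_nonnegativity_unnormalized(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 180, int(rng.integers(1, 12)))
        b = rng.uniform(0, 180, int(rng.integers(1, 12)))
        dab = ms.dtw_distance(a, b, UNNORM)
        assert dab >= 0
        assert dab == pytest.approx(ms.dtw_distance(b, a, UNNORM), abs=1e-10)

    def test_path_normalization_divides_by_path_length(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([6.0, 6.0, 6.0])
        # every step costs 6; the diagonal path has 3 steps
        assert ms.dtw_distance(a, b, UNNORM) == pytest.approx(18.0)
        assert ms.dtw_distance(a, b) == pytest.approx(6.0)

    def test_band_restricts_warping(self):
        a = [0, 0, 0, 10]
        b = [0, 10, 10, 10]
        wide = ms.dtw_distance(a, b, ms.DtwConfig(path_normalization="none",
                                                  local_cost="abs"))
        banded = ms.dtw_distance(a, b, ms.DtwConfig(
            path_normalization="none", local_cost="abs", window_band=0))
        assert banded >= wide


class TestMultiDtw:
    def test_segment_equal_to_baseline_means_is_zero(self):
        vals = np.column_stack([np.linspace(20, 90, 8),
                                np.linspace(160, 140, 8)])
        labels = ("shoulder", "elbow")
        assert ms.multi_dtw_distance(toy_segment(vals, labels),
                                     toy_baseline(vals, labels)) == 0.0

    def test_single_joint_reduces_to_scalar_dtw_bitwise(self, rng):
        a = rng.uniform(0, 180, 15)
        b = rng.uniform(0, 180, 12)
        for config in (ms.DtwConfig(), UNNORM,
                       ms.DtwConfig(multivariate_mode="independent")):
            d_multi = ms.multi_dtw_distance(toy_segment(a), toy_baseline(b),
                                            config)
            assert d_multi == ms.dtw_distance(a, b, config)

    def test_dependent_mode_against_multidimensional_oracle(self):
        """Dependent-mode multi-DTW equals brute-force enumeration with
        Euclidean per-step cost for joint counts up to 3."""
        rng = np.random.default_rng(99)
        labels3 = ("shoulder", "elbow", "wrist")
        for _ in range(60):
            k = int(rng.integers(1, 4))
            n, m = rng.integers(1, 6, size=2)
            X = rng.uniform(0, 180, (n, k))
            Y = rng.uniform(0, 180, (m, k))
            cost = np.linalg.norm(X[:, None, :] - Y[None, :, :], axis=2)
            labels = labels3[:k]
            got = ms.multi_dtw_distance(
                toy_segment(X, labels), toy_baseline(Y, labels),
                ms.DtwConfig(path_normalization="none"))
            assert got == pytest.approx(brute_force_dtw(cost), abs=1e-10)

    def test_independent_mode_averages_per_joint(self, rng):
        labels = ("shoulder", "elbow")
        X = rng.uniform(0, 180, (10, 2))
        Y = rng.uniform(0, 180, (8, 2))
        config = ms.DtwConfig(multivariate_mode="independent")
        got = ms.multi_dtw_distance(toy_segment(X, labels),
                                    toy_baseline(Y, labels), config)
        expect = np.mean([ms.dtw_distance(X[:, j], Y[:, j], config)
                          for j in range(2)])
        assert got == pytest.approx(expect, abs=1e-12)

    def test_joint_mismatch_rejected(self, rng):
        seg = toy_segment(rng.uniform(0, 1, 5), ("elbow",))
        base = toy_baseline(rng.uniform(0, 1, 5), ("shoulder",))
        with pytest.raises(ValidationError):
            ms.multi_dtw_distance(seg, base)

    def test_residual_amplification_never_decreases_distance(self, rng):
        """Scaling every sample's deviation from the baseline mean by
        k > 1 cannot reduce the DTW distance."""
        for _ in range(20):
            n = int(rng.integers(5, 15))
            mean = rng.uniform(40, 120, n)
            resid = rng.normal(0, 8, n)
            base = toy_baseline(mean)
            d1 = ms.multi_dtw_distance(toy_segment(mean + resid), base)
            for k in (1.5, 2.0, 4.0):
                dk = ms.multi_dtw_distance(toy_segment(mean + k * resid), base)
                assert dk >= d1 - 1e-9


class TestScoring:
    def test_z_score_examples(self):
        base = Baseline.from_stats(mu=3.0, sigma=1.5)
        assert ms.z_score(3.0, base) == 0.0
        assert ms.z_score(4.5, base) == 1.0

    def test_worked_example_from_published_summary(self):
        """Closest-10 abnormal shoulder-flexion segments: distance 1.9940
        against baseline mu 2.0120, sigma 1.4640 gives Z = -0.0123 and a
        perfect score."""
        base = Baseline.from_stats(mu=2.0120, sigma=1.4640)
        z = ms.z_score(1.9940, base)
        assert round(z, 4) == -0.0123
        assert ms.score_from_z(z) == 100.0

    def test_degenerate_baseline_refused(self):
        with pytest.raises(DegenerateBaselineError):
            ms.z_score(1.0, Baseline.from_stats(mu=1.0, sigma=0.0))

    @pytest.mark.parametrize("z,expected", [
        (-0.0123, 100.0), (1.0, 100.0), (2.0, 50.0), (4.0, 25.0),
        (-5.0, 100.0), (0.0, 100.0),
    ])
    def test_score_mapping(self, z, expected):
        assert ms.score_from_z(z) == pytest.approx(expected)

    @given(z1=st.floats(-50, 50), z2=st.floats(-50, 50))
    def test_score_monotone_nonincreasing_and_bounded(self, z1, z2):
        s1, s2 = ms.score_from_z(z1), ms.score_from_z(z2)
        assert 0 < s1 <= 100 and 0 < s2 <= 100
        if z1 <= z2:
            assert s1 >= s2

    def test_score_continuous_at_one(self):
        eps = 1e-9
        assert ms.score_from_z(1.0 - eps) == 100.0
        assert ms.score_from_z(1.0 + eps) == pytest.approx(100.0, abs=1e-6)

    def test_nonfinite_z_rejected(self):
        with pytest.raises(ParameterError):
            ms.score_from_z(np.nan)


class TestAssessSegment:
    def test_baseline_mean_segment_scores_perfect(self):
        vals = np.linspace(10, 150, 20)
        base = toy_baseline(vals, mu=2.0, sigma=0.8)
        res = ms.assess_segment(toy_segment(vals), base)
        assert res.d_alpha == 0.0
        assert res.z_alpha == pytest.approx(-2.0 / 0.8)
        assert res.s_alpha == 100.0

    def test_abnormal_segments_rarely_score_perfect(self):
        """Abnormal synthetic repetitions against a normal baseline score
        below 100 in at least 95% of seeded draws."""
        rng = np.random.default_rng(0)
        normal = make_segments(20, rng, reps_per_clip=10)
        base = ms.build_baseline([s.subset(["shoulder"]) for s in normal])
        below = 0
        n_draws = 200
        abnormal = make_segments(n_draws, rng, condition="abnormal",
                                 reps_per_clip=10)
        for seg in abnormal:
            res = ms.assess_segment(seg.subset(["shoulder"]), base)
            below += res.s_alpha < 100.0
        assert below >= 0.95 * n_draws
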