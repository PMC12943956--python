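import itertools
from collections import Counter

import numpy as np
import pytest

import motionscore as ms
from motionscore import evaluation as ev
from motionscore.errors import StatisticsError, ValidationError

from conftest import make_segments


@pytest.fixture(scope="module")
def small_records():
    plan = ms.ProtocolPlan(n_participants=2, reps_per_round=4)
    clips = ms.generate_protocol_dataset(plan, seed=11)
    return ev.segment_dataset(clips)


def records_for(records, exercise):
    return [r for r in records if r.exercise == exercise]


class TestSplitSubsets:
    def test_balanced_split_counts(self, small_records):
        ex = records_for(small_records, "abduction")
        a = ev.split_subsets(ex, seed=0)
        counts = Counter(a.subsets)
        n_normal = sum(r.condition == "normal" for r in ex)
        n_abnormal = len(ex) - n_normal
        assert counts["B"] == counts["N"] == n_normal // 2
        assert counts["A"] == n_abnormal
        # B and N are normal only; A is abnormal only
        for i, r in enumerate(ex):
            expected = "A" if r.condition == "abnormal" else ("B", "N")
            assert a.subsets[i] in expected

    def test_stratified_per_participant(self, small_records):
        ex = records_for(small_records, "elbow_flexion")
        a = ev.split_subsets(ex, seed=1)
        for pid in {r.participant for r in ex}:
            idx = [i for i, r in enumerate(ex)
                   if r.participant == pid and r.condition == "normal"]
            half = Counter(a.subsets[i] for i in idx)
            assert half["B"] == half["N"] == len(idx) // 2

    def test_deterministic_and_seed_sensitive(self, small_records):
        ex = records_for(small_records, "abduction")
        a0 = ev.split_subsets(ex, seed=0)
        a0b = ev.split_subsets(ex, seed=0)
        np.testing.assert_array_equal(a0.subsets, a0b.subsets)
        differs = sum(
            not np.array_equal(a0.subsets,
                               ev.split_subsets(ex, seed=s).subsets)
            for s in range(1, 11))
        assert differs == 10  # collision is astronomically unlikely

    def test_odd_participant_count_rejected(self, small_records):
        ex = records_for(small_records, "abduction")
        drop = next(i for i, r in enumerate(ex) if r.condition == "normal")
        with pytest.raises(ValidationError):
            ev.split_subsets(ex[:drop] + ex[drop + 1:], seed=0)


class TestVariantLabels:
    @pytest.mark.parametrize("exercise,variant,expected", [
        ("abduction", "single", ("shoulder",)),
        ("abduction", "dual", ("shoulder", "elbow")),
        ("elbow_flexion", "single", ("elbow",)),
        ("elbow_flexion", "triple", ("elbow", "shoulder", "wrist")),
        ("shoulder_flexion", "wrist", ("wrist",)),
    ])
    def test_mapping(self, exercise, variant, expected):
        assert ev.variant_labels(exercise, variant) == expected

    def test_unknown_variant(self):
        with pytest.raises(ms.ParameterError):
            ev.variant_labels("abduction", "quad")


class TestDistanceTable:
    def test_identical_baseline_segments_have_zero_distance(self, rng):
        segs = make_segments(1, rng, noise_sd_deg=0.0, duration_jitter=0.0,
                             peak_jitter=0.0, tremor_amplitude_deg=0.0)
        records = [
            ev.SegmentRecord(participant=p, exercise="abduction", side="left",
                             condition="normal", round_index=0,
                             segment=segs[0])
            for p in (0, 0, 1, 1)
        ]
        a = ev.split_subsets(records, seed=0)
        table, base = ev.distance_table(records, a, "single")
        assert base.degenerate
        np.testing.assert_allclose(
            table.loc[table.subset == "B", "distance"], 0.0, atol=1e-9)

    def test_single_variant_equals_primary_joint_distance(self, small_records):
        ex = records_for(small_records, "abduction")
        a = ev.split_subsets(ex, seed=2)
        t_single, base = ev.distance_table(ex, a, "single")
        t_shoulder, _ = ev.distance_table(ex, a, "shoulder")
        np.testing.assert_allclose(t_single.distance, t_shoulder.distance)

    def test_abnormal_mean_exceeds_normal_mean(self, small_records):
        for exercise in ("abduction", "shoulder_flexion", "elbow_flexion"):
            ex = records_for(small_records, exercise)
            a = ev.split_subsets(ex, seed=0)
            table, _ = ev.distance_table(ex, a, "single")
            g = table.groupby("subset")["distance"].mean()
            assert g["A"] > g["N"]


class TestCompareSubsets:
    def test_identical_groups_give_p_one(self, rng):
        g = rng.uniform(0, 5, 30)
        t_p, u_p = ev.compare_subsets(g, g.copy())
        assert t_p == pytest.approx(1.0)
        assert u_p == pytest.approx(1.0, abs=0.01)

    def test_same_distribution_rarely_significant(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t_p, u_p = ev.compare_subsets(rng.normal(2, 0.5, 240),
                                          rng.normal(2, 0.5, 240))
            hits += (t_p > 0.05) and (u_p > 0.05)
        assert hits >= 45  # p should exceed 0.05 in >= 90% of seeds

    def test_shifted_distribution_detected(self, rng):
        t_p, u_p = ev.compare_subsets(rng.normal(2, 0.5, 240),
                                      rng.normal(6, 2.0, 240))
        assert t_p < 1e-3 and u_p < 1e-3

    def test_small_groups_rejected(self):
        with pytest.raises(StatisticsError):
            ev.compare_subsets([1.0], [2.0, 3.0])

    def test_welch_flag_changes_unequal_variance_result(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(0.2, 3.0, 100)
        p_pooled, _ = ev.compare_subsets(a, b, welch=False)
        p_welch, _ = ev.compare_subsets(a, b, welch=True)
        assert p_pooled != p_welch

    def test_u_test_against_permutation_enumeration(self):
        """The U-test p-value matches an exhaustive permutation enumeration
        for tie-free groups of size <= 7."""
        rng = np.random.default_rng(3)
        for n1, n2 in [(3, 4), (5, 5), (6, 7), (4, 7)]:
            a = rng.uniform(0, 1, n1)
            b = rng.uniform(0, 1, n2)
            _, u_p = ev.compare_subsets(a, b)
            pooled = np.concatenate([a, b])
            u_obs = sum(x > y for x in a for y in b)
            n_tot = n1 * n2
            stats = []
            for comb in itertools.combinations(range(n1 + n2), n1):
                ga = pooled[list(comb)]
                gb = np.delete(pooled, list(comb))
                stats.append(sum(x > y for x in ga for y in gb))
            stats = np.asarray(stats)
            hi = max(u_obs, n_tot - u_obs)
            p_exact = (np.sum(stats >= hi) + np.sum(stats <= n_tot - hi)) \
                / len(stats)
            assert u_p == pytest.approx(min(1.0, p_exact), abs=1e-9)


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def report(self, small_records):
        return ev.run_experiment(small_records, seed=0)

    def test_grid_is_complete(self, report):
        assert len(report.comparisons) == 3 * 6 * 3
        cells = set(zip(report.comparisons.exercise,
                        report.comparisons.variant,
                        report.comparisons.pair))
        assert len(cells) == 54
        assert report.comparisons.t_p.between(0, 1).all()
        assert report.comparisons.u_p.between(0, 1).all()

    def test_baseline_subset_z_is_standardized(self, report):
        """In-sample mu/sigma make subset B's Z-scores mean 0, SD 1."""
        zb = report.score_summaries.query(
            "subset == 'B' and metric == 'z'")
        assert np.allclose(zb["mean"], 0.0, atol=1e-9)
        assert np.allclose(zb["sd"], 1.0, atol=1e-9)

    def test_closest_abnormal_summary_layout(self, report):
        ca = report.closest_abnormal
        assert set(ca.exercise) == {"abduction", "shoulder_flexion",
                                    "elbow_flexion"}
        assert set(ca.metric) == {"distance", "z", "score"}
        assert (ca.k <= 10).all()

    def test_degenerate_dataset_flags_but_does_not_crash(self, rng):
        segs = make_segments(1, rng, noise_sd_deg=0.0, duration_jitter=0.0,
                             peak_jitter=0.0, tremor_amplitude_deg=0.0)
        records = [
            ev.SegmentRecord(participant=p, exercise="abduction", side="left",
                             condition=c, round_index=0, segment=segs[0])
            for p in (0, 1) for c in ("normal", "normal", "normal", "normal",
                                      "abnormal", "abnormal")
        ]
        report = ev.run_experiment(records, seed=0,
                                   variants=("single", "shoulder"))
        assert ("abduction", "single") in report.degenerate

    def test_report_csvs_written(self, report, tmp_path):
        report.save(tmp_path)
        for name in ("comparisons", "distance_stats", "score_summaries",
                     "closest_abnormal"):
            assert (tmp_path / f"{name}.csv").exists()
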