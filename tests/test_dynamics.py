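import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cissat import (classify_overlap, compare_distance_distributions,
                    consecutive_overlap_fraction, reference_overlap,
                    transition_rates)
from cissat.dynamics import (CLASSES, ClassTrajectory, class_counts,
                             build_trajectory, distance_strength_summary,
                             overlap_frame, specificity_percentages)


class TestClassify:
    def test_membership_patterns(self):
        labels = classify_overlap({"g1", "g2"}, {"g2"}, {"g2", "g3"})
        assert labels == {"g1": "only_A", "g2": "ABC", "g3": "only_C"}

    def test_identical_sets_all_shared(self):
        labels = classify_overlap({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert set(labels.values()) == {"ABC"}

    def test_disjoint_sets_all_specific(self):
        labels = classify_overlap({"a"}, {"b"}, {"c"})
        assert labels == {"a": "only_A", "b": "only_B", "c": "only_C"}

    def test_pair_classes(self):
        labels = classify_overlap({"x", "y"}, {"x"}, {"y"})
        assert labels == {"x": "AB", "y": "CA"}

    def test_counts_partition_the_union(self):
        q_a, q_b, q_c = {"a", "b", "c"}, {"b", "d"}, {"c", "d", "e"}
        counts = class_counts(classify_overlap(q_a, q_b, q_c))
        assert sum(counts.values()) == len(q_a | q_b | q_c)


class TestOverlapFractions:
    @pytest.mark.parametrize("q_i, q_next, expected", [
        ({"a", "b"}, {"a", "b"}, 1.0),
        ({"a", "b"}, {"c"}, 0.0),
        ({"a", "b"}, {"b", "c", "d"}, 0.5),
    ])
    def test_consecutive(self, q_i, q_next, expected):
        assert consecutive_overlap_fraction(q_i, q_next) == expected

    def test_empty_earlier_set_is_missing(self):
        assert np.isnan(consecutive_overlap_fraction(set(), {"a"}))

    def test_reference_views(self):
        assert reference_overlap({"a"}, {"a", "b"}) == (1.0, 0.5)
        assert reference_overlap({"a"}, {"a"}) == (1.0, 1.0)
        q_i = {"a", "b", "c", "x"}
        q_ref = set(f"r{i}" for i in range(27)) | {"a", "b", "c"}
        assert reference_overlap(q_i, q_ref) == (0.75, 0.10)


class TestTransitionRates:
    def test_enumerated_example(self):
        rates = transition_rates({"g1": "only_A"},
                                 {"g1": "ABC", "g2": "only_B"}, delta_n=10)
        by_class = rates.set_index("class")
        assert by_class.at["only_A", "move_out"] == 1
        assert by_class.at["ABC", "move_in"] == 1
        assert by_class.at["ABC", "creation"] == 0
        assert by_class.at["only_B", "creation"] == 1
        assert by_class.at["only_B", "creation_rate"] == pytest.approx(0.1)

    def test_identical_memberships_give_zero_rates(self):
        membership = {"g1": "AB", "g2": "only_C"}
        rates = transition_rates(membership, dict(membership), delta_n=5)
        assert (rates[["creation", "deletion", "move_in", "move_out"]]
                .to_numpy() == 0).all()

    def test_deletion_counted_in_previous_class(self):
        rates = transition_rates({"g1": "BC"}, {}, delta_n=2)
        assert rates.set_index("class").at["BC", "deletion"] == 1

    @settings(max_examples=50, derandomize=True)
    @given(st.dictionaries(st.integers(0, 30),
                           st.sampled_from(CLASSES), max_size=25),
           st.dictionaries(st.integers(0, 30),
                           st.sampled_from(CLASSES), max_size=25))
    def test_bookkeeping_identity(self, previous, current):
        # count(i) = count(i-1) + creation + move_in - deletion - move_out
        rates = transition_rates(previous, current, delta_n=3)
        before = class_counts(previous)
        after = class_counts(current)
        for _, row in rates.iterrows():
            label = row["class"]
            assert after[label] == (before[label] + row["creation"]
                                    + row["move_in"] - row["deletion"]
                                    - row["move_out"])


class TestDistanceStrength:
    class _FakeEqtl:
        def __init__(self, transcript_id, distance_bp, p_value):
            self.transcript_id = transcript_id
            self.distance_bp = distance_bp
            self.p_value = p_value

    class _FakeScan:
        def __init__(self, eqtls):
            self.eqtls = eqtls

    def test_single_member_distance_in_mb(self):
        scans = {"A": self._FakeScan([self._FakeEqtl("g1", 500_000, 0.01)]),
                 "B": self._FakeScan([]), "C": self._FakeScan([])}
        summary = distance_strength_summary({"g1": "only_A"}, scans)
        row = summary[(summary["class"] == "only_A")
                      & (summary["tissue"] == "A")].iloc[0]
        assert row["mean_abs_delta_mb"] == pytest.approx(0.5)

    def test_mean_strength_is_mean_neglog10_p(self):
        scans = {"A": self._FakeScan([self._FakeEqtl("g1", 100, 0.01),
                                      self._FakeEqtl("g2", 200, 0.0001)]),
                 "B": self._FakeScan([]), "C": self._FakeScan([])}
        summary = distance_strength_summary({"g1": "only_A", "g2": "only_A"},
                                            scans)
        row = summary[(summary["class"] == "only_A")
                      & (summary["tissue"] == "A")].iloc[0]
        assert row["mean_neglog10_p"] == pytest.approx(3.0)

    def test_empty_class_is_missing_not_zero(self):
        scans = {"A": self._FakeScan([]), "B": self._FakeScan([]),
                 "C": self._FakeScan([])}
        summary = distance_strength_summary({}, scans)
        assert summary["mean_abs_delta_mb"].isna().all()


class TestMannWhitney:
    def test_exact_enumeration_fixture(self):
        # U = 0; two-sided exact p = 2 / C(6,3) = 0.1
        assert compare_distance_distributions([1, 2, 3], [4, 5, 6]) == \
            pytest.approx(0.1)

    def test_identical_samples_give_p_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        assert compare_distance_distributions(x, x) > 0.95

    def test_invariant_under_log_transform(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=40)
        y = rng.lognormal(mean=0.5, size=35)
        assert compare_distance_distributions(x, y) == pytest.approx(
            compare_distance_distributions(np.log10(x), np.log10(y)))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_distance_distributions([], [1.0])


class TestSpecificity:
    def _trajectory(self, membership):
        return ClassTrajectory(1, [50], [membership])

    def test_half_specific_half_shared(self):
        trajectory = self._trajectory({"g1": "only_A", "g2": "ABC"})
        row = specificity_percentages(trajectory, 1).set_index("tissue")
        assert row.at["A", "pct_specific"] == pytest.approx(50.0)
        assert row.at["A", "pct_shared_all"] == pytest.approx(50.0)

    def test_all_shared(self):
        trajectory = self._trajectory({"g1": "ABC", "g2": "ABC"})
        row = specificity_percentages(trajectory, 1).set_index("tissue")
        for tissue in "ABC":
            assert row.at[tissue, "pct_specific"] == 0.0
            assert row.at[tissue, "pct_shared_all"] == 100.0

    def test_no_detections_is_missing(self):
        trajectory = self._trajectory({"g1": "only_A"})
        row = specificity_percentages(trajectory, 1).set_index("tissue")
        assert np.isnan(row.at["B", "pct_specific"])

    def test_step_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            specificity_percentages(self._trajectory({}), 2)


class TestOnPipelineOutput:
    @pytest.fixture(scope="class")
    @staticmethod
    def series_result(small_cohort):
        from cissat import run_series
        return run_series(small_cohort, n_min=40, k=4, replicates=1,
                          n_permutations=5, seed=6)[0]

    def test_trajectory_counts_partition_detections(self, series_result):
        trajectory = build_trajectory(series_result)
        for step in range(1, trajectory.k + 1):
            union = set()
            for tissue in "ABC":
                union |= series_result.scans[(step, tissue)].eqtl_transcripts
            assert sum(class_counts(trajectory.memberships[step - 1])
                       .values()) == len(union)

    def test_rates_satisfy_bookkeeping_on_real_output(self, series_result):
        trajectory = build_trajectory(series_result)
        rates = trajectory.rates_frame()
        counts = trajectory.counts_frame().pivot(index="class",
                                                 columns="step",
                                                 values="count")
        for pair, group in rates.groupby("step_pair"):
            earlier, later = map(int, pair.split("-"))
            for _, row in group.iterrows():
                assert counts.at[row["class"], later] == (
                    counts.at[row["class"], earlier] + row["creation"]
                    + row["move_in"] - row["deletion"] - row["move_out"])

    def test_overlap_frame_values_in_unit_interval(self, series_result):
        frame = overlap_frame(series_result)
        values = frame["value"].dropna()
        assert ((values >= 0) & (values <= 1)).all()
        assert set(frame["level"]) == {"eqtl", "esnp"}
        assert set(frame["kind"]) == {"consecutive", "forward_ref",
                                      "backward_ref"}
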