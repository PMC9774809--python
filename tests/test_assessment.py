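import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from surgflow import (
    PhaseSegment,
    PhaseSet,
    WorkflowModel,
    collapse_runs,
    compare_workflows,
    compute_metrics,
    estimate_transition_matrix,
    evaluate_predictions,
    segments_from_timeline,
    wasserstein_categorical,
)

from conftest import make_timeline


class TestSegments:
    def test_run_length_encoding(self):
        segs = segments_from_timeline(make_timeline([0, 0, 1]))
        assert segs == [
            PhaseSegment(0, 0.0, 2.0),
            PhaseSegment(1, 2.0, 3.0),
        ]

    def test_single_run(self):
        segs = segments_from_timeline(make_timeline([3] * 10))
        assert segs == [PhaseSegment(3, 0.0, 10.0)]

    def test_alternating_unit_segments(self):
        segs = segments_from_timeline(make_timeline([0, 1, 0, 1]))
        assert [s.phase for s in segs] == [0, 1, 0, 1]
        assert all(s.duration == 1.0 for s in segs)

    def test_frame_duration_is_inverse_fps(self):
        segs = segments_from_timeline(make_timeline([0, 0, 1, 1], fps=4.0))
        assert segs[-1].end == pytest.approx(1.0)
        assert sum(s.duration for s in segs) == pytest.approx(4 / 4.0)

    def test_contiguity(self):
        segs = segments_from_timeline(make_timeline([0, 2, 2, 5, 5, 5, 1]))
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
            assert a.phase != b.phase


class TestMetrics:
    def test_worked_two_phase_example(self, phase_set):
        segs = [
            PhaseSegment(0, 0.0, 10.0),
            PhaseSegment(1, 10.0, 25.0),
            PhaseSegment(0, 25.0, 30.0),
        ]
        report = compute_metrics(segs, phase_set)
        assert report.total_time == pytest.approx(30.0)
        p1 = report.per_phase["preparation"]
        assert p1.total_time == pytest.approx(15.0)
        assert p1.n_occurrences == 2
        assert (p1.min_duration, p1.max_duration) == (5.0, 10.0)
        assert p1.mean_duration == pytest.approx(7.5)
        assert p1.occupancy_pct == pytest.approx(50.0)
        p2 = report.per_phase["calot_triangle_dissection"]
        assert p2.n_occurrences == 1
        assert p2.min_duration == p2.max_duration == p2.mean_duration == 15.0
        assert p2.occupancy_pct == pytest.approx(50.0)

    def test_single_segment_full_occupancy(self, phase_set):
        report = compute_metrics([PhaseSegment(3, 0.0, 60.0)], phase_set)
        assert report.per_phase["gallbladder_dissection"].occupancy_pct == 100.0
        assert report.per_phase["preparation"].occupancy_pct == 0.0

    def test_absent_phase_reports_zeros(self, phase_set):
        report = compute_metrics([PhaseSegment(0, 0.0, 5.0)], phase_set)
        pm = report.per_phase["gallbladder_extraction"]
        assert pm.n_occurrences == 0
        assert pm.total_time == pm.min_duration == pm.max_duration == 0.0

    def test_empty_segments_rejected(self, phase_set):
        with pytest.raises(ValueError):
            compute_metrics([], phase_set)

    def test_conservation_on_random_segments(self, phase_set, rng):
        for _ in range(20):
            n_seg = int(rng.integers(1, 15))
            phases, prev = [], -1
            for _ in range(n_seg):
                p = int(rng.integers(0, 7))
                while p == prev:
                    p = int(rng.integers(0, 7))
                phases.append(p)
                prev = p
            bounds = np.r_[0.0, np.cumsum(rng.uniform(0.5, 100.0, n_seg))]
            segs = [
                PhaseSegment(p, bounds[i], bounds[i + 1])
                for i, p in enumerate(phases)
            ]
            report = compute_metrics(segs, phase_set)
            total = sum(m.total_time for m in report.per_phase.values())
            occ = sum(m.occupancy_pct for m in report.per_phase.values())
            assert total == pytest.approx(report.total_time, abs=1e-9)
            assert occ == pytest.approx(100.0, abs=1e-9)


class TestCollapseRuns:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([0, 0, 1, 1, 2], [0, 1, 2]),
            ([0], [0]),
            ([1, 1, 1], [1]),
            ([0, 1, 0, 1], [0, 1, 0, 1]),
        ],
    )
    def test_examples(self, seq, expected):
        assert collapse_runs(seq) == expected

    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=1))
    @settings(max_examples=100, deadline=None)
    def test_no_adjacent_duplicates_and_first_preserved(self, seq):
        out = collapse_runs(seq)
        assert out[0] == seq[0]
        assert all(a != b for a, b in zip(out, out[1:]))
        # collapsing is idempotent
        assert collapse_runs(out) == out


class TestTransitionMatrix:
    def test_linear_chain(self, phase_set):
        model = estimate_transition_matrix([0, 1, 2], phase_set)
        assert model.matrix[0, 1] == 1.0
        assert model.matrix[1, 2] == 1.0
        assert 2 in model.terminal_phases

    def test_back_and_forth(self, phase_set):
        model = estimate_transition_matrix([0, 1, 0, 1], phase_set)
        assert model.matrix[0, 1] == 1.0  # 2 of 2 transitions
        assert model.matrix[1, 0] == 1.0  # 1 of 1

    def test_pooling_across_sequences(self, phase_set):
        model = estimate_transition_matrix([[0, 1], [0, 2]], phase_set)
        np.testing.assert_allclose(model.matrix[0, 1:3], [0.5, 0.5])

    def test_adjacent_duplicates_rejected(self, phase_set):
        with pytest.raises(ValueError, match="collapse_runs"):
            estimate_transition_matrix([0, 0, 1], phase_set)

    def test_matches_brute_force_tallies(self, rng):
        ps = PhaseSet(phases=("a", "b", "c", "d"))
        for _ in range(25):
            seqs = []
            for _ in range(int(rng.integers(1, 4))):
                seq = [int(rng.integers(0, 4))]
                for _ in range(int(rng.integers(0, 19))):
                    nxt = int(rng.integers(0, 4))
                    while nxt == seq[-1]:
                        nxt = int(rng.integers(0, 4))
                    seq.append(nxt)
                seqs.append(seq)
            model = estimate_transition_matrix(seqs, ps)
            counts = np.zeros((4, 4))
            for seq in seqs:
                for a, b in zip(seq, seq[1:]):
                    counts[a, b] += 1
            for i in range(4):
                if counts[i].sum() == 0:
                    assert i in model.terminal_phases
                else:
                    np.testing.assert_array_equal(
                        model.matrix[i], counts[i] / counts[i].sum()
                    )


class TestWorkflowModel:
    def test_nonzero_diagonal_rejected(self):
        m = np.zeros((3, 3))
        m[0, 0] = 0.5
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="self-transition"):
            WorkflowModel(matrix=m)

    def test_bad_row_sum_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = 0.4
        with pytest.raises(ValueError, match="row 0"):
            WorkflowModel(matrix=m)


class TestWasserstein:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert wasserstein_categorical(p, p) == 0.0

    def test_unit_spaced_deltas(self):
        p, q = np.zeros(5), np.zeros(5)
        p[1], q[3] = 1.0, 1.0
        assert wasserstein_categorical(p, q) == pytest.approx(2.0)

    def test_half_shift(self):
        d = wasserstein_categorical(
            np.array([0.5, 0.5, 0.0]), np.array([0.0, 0.5, 0.5])
        )
        assert d == pytest.approx(1.0)

    def test_mismatched_supports_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_categorical(np.ones(3) / 3, np.ones(4) / 4)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            p, q, r = rng.dirichlet(np.ones(n), size=3)
            dpq = wasserstein_categorical(p, q)
            assert dpq >= 0
            assert dpq == pytest.approx(wasserstein_categorical(q, p), abs=1e-12)
            assert dpq <= (
                wasserstein_categorical(p, r) + wasserstein_categorical(r, q) + 1e-12
            )

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            p, q = rng.dirichlet(np.ones(n), size=2)
            expected = scipy.stats.wasserstein_distance(
                np.arange(n), np.arange(n), p, q
            )
            assert wasserstein_categorical(p, q) == pytest.approx(expected, abs=1e-9)

    def test_epsilon_shift_moves_distance_by_epsilon(self):
        ref = np.array([0.5, 0.5, 0.0, 0.0])
        student = np.array([0.5, 0.4, 0.1, 0.0])
        base = wasserstein_categorical(ref, student)
        moved = np.array([0.5, 0.4, 0.0, 0.1])  # 0.1 mass one index further
        assert wasserstein_categorical(ref, moved) == pytest.approx(base + 0.1)


class TestCompareWorkflows:
    @staticmethod
    def _chain_model():
        m = np.zeros((7, 7))
        for i in range(6):
            m[i, i + 1] = 1.0
        return WorkflowModel(matrix=m)

    def test_self_comparison_is_zero(self):
        model = self._chain_model()
        cmp = compare_workflows(model, model)
        assert cmp.average_distance == 0.0
        assert all(d == 0.0 for d in cmp.per_phase_distance.values())
        assert cmp.excluded_phases == frozenset({6})

    def test_single_row_difference(self):
        ref = self._chain_model()
        m = ref.matrix.copy()
        m[0] = 0.0
        m[0, 2] = 1.0  # student jumps prep → clipping instead of prep → calot
        student = WorkflowModel(matrix=m)
        cmp = compare_workflows(ref, student)
        assert cmp.per_phase_distance[0] == pytest.approx(1.0)
        assert all(
            cmp.per_phase_distance[i] == 0.0 for i in cmp.per_phase_distance if i
        )
        assert cmp.average_distance == pytest.approx(1.0 / 6.0)

    def test_phase_terminal_in_student_only_is_excluded(self):
        ref = self._chain_model()
        m = ref.matrix.copy()
        m[5] = 0.0  # student never leaves cleaning/coagulation
        student = WorkflowModel(matrix=m)
        cmp = compare_workflows(ref, student)
        assert 5 in cmp.excluded_phases
        assert 5 not in cmp.per_phase_distance

    def test_all_rows_excluded_rejected(self):
        zero = WorkflowModel(matrix=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="no comparable rows"):
            compare_workflows(zero, zero)


class TestEvaluate:
    def test_perfect_prediction(self, phase_set):
        labels = [0, 1, 2, 3, 4, 5, 6, 0, 1]
        rep = evaluate_predictions(labels, labels, phase_set)
        assert rep.f1 == rep.precision == rep.recall == 1.0
        assert rep.accuracy == rep.jaccard == 1.0
        assert rep.avg_error_pct == 0.0
        assert rep.avg_error_per_phase_pct == 0.0

    def test_worked_confusion_example(self, phase_set):
        truth = [0, 0, 1, 1]
        pred = [0, 1, 1, 1]
        rep = evaluate_predictions(pred, truth, phase_set)
        assert rep.accuracy == pytest.approx(0.75)
        # macro over classes present in truth: F1 = mean(2/3, 0.8)
        assert rep.f1 == pytest.approx((2 / 3 + 0.8) / 2)
        assert rep.recall == pytest.approx((0.5 + 1.0) / 2)
        assert rep.precision == pytest.approx((1.0 + 2 / 3) / 2)
        assert rep.jaccard == pytest.approx((0.5 + 2 / 3) / 2)
        assert rep.avg_error_pct == pytest.approx(25.0)
        assert rep.avg_error_per_phase_pct == pytest.approx(25.0)
        assert rep.confusion[0, 0] == 1 and rep.confusion[0, 1] == 1
        assert rep.confusion[1, 1] == 2

    def test_total_failure(self, phase_set):
        rep = evaluate_predictions([2, 2, 2], [0, 0, 0], phase_set)
        assert rep.accuracy == 0.0
        assert rep.f1 == 0.0
        assert rep.avg_error_pct == 100.0

    def test_confusion_row_sums_equal_truth_counts(self, phase_set, rng):
        truth = rng.integers(0, 7, size=200)
        pred = rng.integers(0, 7, size=200)
        rep = evaluate_predictions(pred, truth, phase_set)
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1), np.bincount(truth, minlength=7)
        )
        assert rep.accuracy == pytest.approx(rep.confusion.trace() / 200)

    def test_length_mismatch_and_empty_rejected(self, phase_set):
        with pytest.raises(ValueError, match="length mismatch"):
            evaluate_predictions([0, 1], [0], phase_set)
        with pytest.raises(ValueError, match="empty"):
            evaluate_predictions([], [], phase_set)
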