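import numpy as np
import pytest

import peakbench as pb


def _window(wid, labels_spec, chrom="chrT"):
    """labels_spec: list of (start, end, type)."""
    labels = [
        pb.Label(pb.GenomicInterval(chrom, s, e), t, frozenset(), wid)
        for s, e, t in labels_spec
    ]
    lo = min(s for s, _, _ in labels_spec)
    hi = max(e for _, e, _ in labels_spec)
    return pb.Window(wid, pb.GenomicInterval(chrom, lo, hi), labels)


def _call_set(per_threshold_peaks, default=None, sample="s1", chrom="chrT"):
    """per_threshold_peaks: {threshold: [(start, end), ...]}."""
    calls = {
        (float(t), sample): pb.PeakCalls(
            sample, [pb.GenomicInterval(chrom, s, e) for s, e in peaks]
        )
        for t, peaks in per_threshold_peaks.items()
    }
    return pb.ThresholdedCallSet(
        "toy", tuple(sorted(per_threshold_peaks)), calls, default_threshold=default
    )


@pytest.fixture
def three_peak_windows():
    # three windows, each one peaks label plus one noPeaks label
    return [
        _window("w0", [(0, 100, "peaks"), (150, 250, "noPeaks")]),
        _window("w1", [(300, 400, "peaks"), (450, 550, "noPeaks")]),
        _window("w2", [(600, 700, "peaks"), (750, 850, "noPeaks")]),
    ]


@pytest.fixture
def toy_call_set():
    # threshold 1: over-calls everywhere (3 noPeaks fp); 2: perfect; 4: under-calls
    return _call_set(
        {
            1.0: [(0, 860)],
            2.0: [(10, 60), (310, 360), (610, 660)],
            4.0: [(10, 60)],
        },
        default=1.0,
    )


class TestTrain:
    def test_argmin_over_grid(self, toy_call_set, three_peak_windows):
        model = pb.train(toy_call_set, three_peak_windows)
        assert model.chosen_threshold == 2.0
        assert model.train_error.errors == 0
        assert {t: s.errors for t, s in model.per_threshold_errors.items()} == {
            1.0: 3, 2.0: 0, 4.0: 2,
        }

    def test_tie_break_prefers_largest_threshold(self, three_peak_windows):
        # thresholds 2 and 4 both perfect -> pick 4 (most conservative)
        cs = _call_set(
            {
                1.0: [(0, 860)],
                2.0: [(10, 60), (310, 360), (610, 660)],
                4.0: [(10, 60), (310, 360), (610, 660)],
            }
        )
        assert pb.train(cs, three_peak_windows).chosen_threshold == 4.0

    def test_chosen_threshold_minimizes_exhaustively(self, default_benchmark, default_call_set):
        b = default_benchmark
        model = pb.train(default_call_set, b.windows[:4], b.groups)
        best = min(s.errors for s in model.per_threshold_errors.values())
        assert model.train_error.errors == best
        assert all(
            s.errors >= model.train_error.errors
            for s in model.per_threshold_errors.values()
        )

    def test_empty_training_set_rejected(self, toy_call_set):
        with pytest.raises(pb.ValidationError):
            pb.train(toy_call_set, [])


class TestEvaluate:
    def test_equals_total_error_directly(self, toy_call_set, three_peak_windows):
        summary = pb.evaluate(toy_call_set, 2.0, three_peak_windows)
        direct = pb.total_error(
            toy_call_set.calls_at(2.0), pb.labels_of(three_peak_windows)
        )
        assert summary == direct
        assert summary.percent_error == 0.0

    def test_empty_calls_all_positive_labels_wrong(self):
        windows = [_window("w0", [(0, 100, "peaks"), (200, 300, "peaks")])]
        cs = _call_set({5.0: []})
        assert pb.evaluate(cs, 5.0, windows).percent_error == 100.0

    def test_off_grid_threshold_rejected(self, toy_call_set, three_peak_windows):
        with pytest.raises(pb.ThresholdError):
            pb.evaluate(toy_call_set, 3.0, three_peak_windows)


class TestAssignFolds:
    def test_balanced_and_deterministic(self, three_peak_windows):
        windows = three_peak_windows
        fa1 = pb.assign_folds(windows, 3, seed=5)
        fa2 = pb.assign_folds(windows, 3, seed=5)
        assert fa1.assignment == fa2.assignment
        assert sorted(fa1.assignment.values()) == [1, 2, 3]

    def test_eight_windows_four_folds_exactly_two_each(self, default_benchmark):
        fa = pb.assign_folds(default_benchmark.windows, 4, seed=0)
        sizes = np.bincount(list(fa.assignment.values()))[1:]
        assert sizes.tolist() == [2, 2, 2, 2]

    def test_nine_windows_four_folds_sizes(self):
        windows = [_window(f"w{i}", [(i * 100, i * 100 + 50, "peaks")]) for i in range(9)]
        for seed in range(1, 101):
            fa = pb.assign_folds(windows, 4, seed)
            sizes = sorted(np.bincount(list(fa.assignment.values()))[1:], reverse=True)
            assert sizes == [3, 2, 2, 2]

    def test_fewer_windows_than_folds_rejected(self, three_peak_windows):
        with pytest.raises(pb.ValidationError):
            pb.assign_folds(three_peak_windows, 4, seed=1)


class TestCrossValidate:
    def test_perfect_threshold_gives_zero_error(self, toy_call_set, three_peak_windows):
        result = pb.cross_validate(toy_call_set, three_peak_windows, 3, seed=1)
        assert result.trained_mean == 0.0
        assert all(f.chosen_threshold == 2.0 for f in result.folds)

    def test_leave_one_window_out(self, three_peak_windows, toy_call_set):
        result = pb.cross_validate(
            toy_call_set, three_peak_windows, k=3, seed=2, compare_default=False
        )
        assert len(result.folds) == 3

    def test_bit_reproducible(self, default_benchmark, default_call_set):
        b = default_benchmark
        r1 = pb.cross_validate(default_call_set, b.windows, 4, 1, b.groups)
        r2 = pb.cross_validate(default_call_set, b.windows, 4, 1, b.groups)
        assert r1.folds == r2.folds

    def test_missing_default_rejected(self, three_peak_windows):
        cs = _call_set({2.0: [(10, 60), (310, 360), (610, 660)]})
        with pytest.raises(pb.PeakBenchError):
            pb.cross_validate(cs, three_peak_windows, 3, 1, compare_default=True)


class TestRocLikeCurve:
    def test_empty_calls_at_origin_perfect_at_top_left(self, three_peak_windows):
        cs = _call_set(
            {
                2.0: [(10, 60), (310, 360), (610, 660)],  # perfect
                9.0: [],                                   # nothing called
            }
        )
        curve = pb.roc_like_curve(cs, three_peak_windows)
        by_t = {p.threshold: p for p in curve.points}
        assert (by_t[9.0].tpr, by_t[9.0].fpr) == (0.0, 0.0)
        assert (by_t[2.0].tpr, by_t[2.0].fpr) == (1.0, 0.0)

    def test_rates_match_error_by_type_recount(self, default_benchmark, default_call_set):
        b = default_benchmark
        labels = pb.labels_of(b.windows)
        curve = pb.roc_like_curve(default_call_set, b.windows, b.groups)
        for point in curve.points[:: max(1, len(curve.points) // 5)]:
            by_type = pb.error_by_type(
                pb.evaluate_labels(default_call_set.calls_at(point.threshold), labels, b.groups)
            )
            n_pos = sum(by_type[t].n_labels for t in pb.POSITIVE_LABEL_TYPES)
            n_fpc = sum(by_type[t].n_labels for t in pb.FP_CAPABLE_LABEL_TYPES)
            fn = sum(by_type[t].fn_total for t in pb.POSITIVE_LABEL_TYPES)
            fp = sum(by_type[t].fp_total for t in pb.FP_CAPABLE_LABEL_TYPES)
            assert point.tpr == pytest.approx(1 - fn / n_pos)
            assert point.fpr == pytest.approx(fp / n_fpc)
            assert 0.0 <= point.fpr <= 1.0 and 0.0 <= point.tpr <= 1.0

    def test_undefined_rates_rejected(self):
        windows = [_window("w0", [(0, 100, "noPeaks")])]  # no positive labels
        cs = _call_set({1.0: []})
        with pytest.raises(pb.ValidationError):
            pb.roc_like_curve(cs, windows)


class TestLearningCurve:
    def test_size_zero_is_default_threshold(self, default_benchmark, default_call_set):
        b = default_benchmark
        folds = pb.assign_folds(b.windows, 4, seed=1)
        points = pb.learning_curve(
            default_call_set, b.windows, folds, 1, max_train=2, n_orders=2,
            seed=1, groups=b.groups,
        )
        expected = pb.evaluate(
            default_call_set,
            default_call_set.default_threshold,
            folds.windows_in_fold(b.windows, 1),
            b.groups,
        ).percent_error
        assert points[0].per_order == (expected, expected)

    def test_full_size_matches_training_on_whole_pool(self, default_benchmark, default_call_set):
        b = default_benchmark
        folds = pb.assign_folds(b.windows, 4, seed=1)
        pool = folds.windows_not_in_fold(b.windows, 1)
        points = pb.learning_curve(
            default_call_set, b.windows, folds, 1, max_train=len(pool),
            n_orders=1, seed=3, groups=b.groups,
        )
        model = pb.train(default_call_set, pool, b.groups)
        expected = pb.evaluate(
            default_call_set, model.chosen_threshold,
            folds.windows_in_fold(b.windows, 1), b.groups,
        ).percent_error
        assert points[-1].per_order == (expected,)

    def test_max_train_beyond_pool_rejected(self, default_benchmark, default_call_set):
        folds = pb.assign_folds(default_benchmark.windows, 4, seed=1)
        with pytest.raises(pb.ValidationError):
            pb.learning_curve(
                default_call_set, default_benchmark.windows, folds, 1,
                max_train=7, n_orders=1, seed=1,
            )
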