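import numpy as np
import pytest

import peakbench as pb
from tests._oracle import brute_force_fp_fn, random_disjoint_peak, random_instance


def label(iv, label_type, groups=(), window_id="w0"):
    return pb.Label(iv, label_type, frozenset(groups), window_id)


def calls(*pairs, sample="s1", chrom="chrT"):
    return pb.PeakCalls(sample, [pb.GenomicInterval(chrom, s, e) for s, e in pairs])


class TestLabelErrorOne:
    @pytest.mark.parametrize(
        "label_type,region,peaks,fp,fn,k",
        [
            # noPeaks: any overlapping peak is a false positive
            ("noPeaks", (100, 200), [(150, 160)], 1, 0, 1),
            ("noPeaks", (100, 200), [], 0, 0, 0),
            ("noPeaks", (100, 200), [(200, 300)], 0, 0, 0),  # abutting, no overlap
            # peaks: zero overlapping peaks is the only error
            ("peaks", (100, 200), [], 0, 1, 0),
            ("peaks", (100, 200), [(10, 101)], 0, 0, 1),  # one shared base suffices
            ("peaks", (100, 200), [(110, 120), (150, 300)], 0, 0, 2),  # >= 1 is fine
            # peakStart: exactly one peak start in [start, end)
            ("peakStart", (100, 200), [(120, 150), (180, 400)], 1, 0, 2),
            ("peakStart", (100, 200), [(120, 400)], 0, 0, 1),
            ("peakStart", (100, 200), [(50, 400)], 0, 1, 0),   # spanning, no visible start
            ("peakStart", (100, 200), [(200, 300)], 0, 1, 0),  # start at end is outside
            ("peakStart", (100, 200), [(100, 300)], 0, 0, 1),  # start at region start counts
            # peakEnd: exactly one peak end in (start, end]
            ("peakEnd", (100, 200), [(50, 150)], 0, 0, 1),
            ("peakEnd", (100, 200), [(50, 200)], 0, 0, 1),   # end exactly at region end counts
            ("peakEnd", (100, 200), [(50, 100)], 0, 1, 0),   # end at region start is outside
            ("peakEnd", (100, 200), [(110, 130), (140, 160)], 1, 0, 2),
            ("peakEnd", (100, 200), [(50, 400)], 0, 1, 0),   # spanning, no visible end
        ],
    )
    def test_counting_rules(self, iv, label_type, region, peaks, fp, fn, k):
        result = pb.label_error_one(label(iv(*region), label_type), calls(*peaks))
        assert (result.fp, result.fn, result.observed_count) == (fp, fn, k)

    def test_overlapping_input_peaks_are_merged_before_counting(self, iv):
        # two overlapping intervals merge into one peak -> a single start
        result = pb.label_error_one(
            label(iv(100, 200), "peakStart"), calls((120, 300), (180, 400))
        )
        assert (result.fp, result.fn, result.observed_count) == (0, 0, 1)

    def test_calls_on_other_chromosome_count_zero(self, iv):
        other = pb.PeakCalls("s1", [pb.GenomicInterval("chrZ", 100, 200)])
        result = pb.label_error_one(label(iv(100, 200), "peaks"), other)
        assert (result.fp, result.fn) == (0, 1)

    def test_status_consistent(self, iv):
        assert pb.label_error_one(label(iv(0, 10), "noPeaks"), calls((5, 6))).status == "false-positive"
        assert pb.label_error_one(label(iv(0, 10), "peaks"), calls()).status == "false-negative"
        assert pb.label_error_one(label(iv(0, 10), "noPeaks"), calls()).status == "correct"


class TestTotalError:
    def test_empty_calls_only_positive_labels_fail(self, iv):
        labels = [
            label(iv(0, 100), "noPeaks"),
            label(iv(200, 300), "peaks"),
            label(iv(400, 500), "peakStart"),
        ]
        s = pb.total_error({"s1": calls()}, labels)
        assert (s.fp_total, s.fn_total, s.errors, s.n_labels) == (0, 2, 2, 3)
        assert s.percent_error == pytest.approx(100 * 2 / 3)

    def test_all_wrong_attains_upper_bound(self, iv):
        labels = [
            label(iv(0, 100), "noPeaks"),
            label(iv(200, 300), "peaks"),
            label(iv(400, 500), "peakStart"),
            label(iv(600, 700), "peakEnd"),
            label(iv(800, 900), "noPeaks"),
        ]
        bad = calls((50, 60), (850, 860))  # inside both noPeaks, nothing else
        s = pb.total_error({"s1": bad}, labels)
        assert s.errors == s.n_labels == 5

    def test_label_on_g_samples_contributes_g_entries(self, iv):
        by_sample = {"a1": calls(sample="a1"), "a2": calls(sample="a2"), "b1": calls(sample="b1")}
        groups = {"a1": "ga", "a2": "ga", "b1": "gb"}
        labels = [label(iv(0, 10), "peaks", groups={"ga"}), label(iv(20, 30), "noPeaks")]
        s = pb.total_error(by_sample, labels, groups)
        assert s.n_labels == 2 + 3  # peaks on 2 group-ga samples, noPeaks on all 3
        assert s.fn_total == 2

    def test_missing_sample_group_is_an_error_naming_it(self, iv):
        with pytest.raises(pb.MissingSampleError, match="ghost"):
            pb.total_error({"s1": calls()}, [label(iv(0, 10), "peaks", groups={"ghost"})])

    def test_group_name_matching_sample_id_directly(self, iv):
        s = pb.total_error(
            {"s1": calls((0, 5)), "s2": calls(sample="s2")},
            [label(iv(0, 10), "peaks", groups={"s1"})],
        )
        assert (s.errors, s.n_labels) == (0, 1)


class TestOracleEquivalence:
    def test_matches_base_resolution_recount(self):
        """Interval arithmetic equals a per-base scan on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            b, labels, pc = random_instance(rng)
            y = pc.to_binary("chrT", b)
            for lab in labels:
                got = pb.label_error_one(lab, pc)
                fp, fn, k = brute_force_fp_fn(lab, y)
                assert (got.fp, got.fn, got.observed_count) == (fp, fn, k)

    def test_monotone_under_added_peak(self):
        """Adding a new (disjoint) peak never decreases FP and never
        increases FN; an arbitrary merged interval still obeys the weak form
        (overlap-counting labels only).

        The strong form cannot hold for merged additions: merging two peaks
        into one can erase the visible boundary a peakStart/peakEnd region
        demands.
        """
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            b, labels, pc = random_instance(rng)
            before = pb.evaluate_labels({"s1": pc}, labels)
            extra = random_disjoint_peak(rng, pc, b)
            if extra is not None:
                after = pb.evaluate_labels({"s1": pc.with_peak(extra)}, labels)
                assert pb.summarize(after).fp_total >= pb.summarize(before).fp_total
                assert pb.summarize(after).fn_total <= pb.summarize(before).fn_total
                checked += 1
            # weak form for an arbitrary (possibly merging) added interval
            s = int(rng.integers(0, b - 1))
            e = min(b, s + int(rng.integers(1, b)))
            merged = pb.evaluate_labels({"s1": pc.with_peak(pb.GenomicInterval("chrT", s, e))}, labels)
            for r0, r1 in zip(before, merged):
                if r0.label.label_type == "noPeaks":
                    assert r1.fp >= r0.fp
                elif r0.label.label_type == "peaks":
                    assert r1.fn <= r0.fn
        assert checked >= 150

    def test_no_peaks_means_no_false_positives(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            b, labels, _ = random_instance(rng)
            s = pb.total_error({"s1": pb.PeakCalls("s1")}, labels)
            assert s.fp_total == 0
            assert s.fn_total == sum(1 for l in labels if l.is_positive)


class TestErrorByType:
    def test_partition_sums_to_global_totals(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            b, labels, pc = random_instance(rng)
            results = pb.evaluate_labels({"s1": pc}, labels)
            total = pb.summarize(results)
            by_type = pb.error_by_type(results)
            assert set(by_type) == set(pb.LABEL_TYPES)
            assert sum(s.fp_total for s in by_type.values()) == total.fp_total
            assert sum(s.fn_total for s in by_type.values()) == total.fn_total
            assert sum(s.n_labels for s in by_type.values()) == total.n_labels

    def test_absent_types_have_empty_summaries(self, iv):
        results = pb.evaluate_labels({"s1": calls()}, [label(iv(0, 10), "noPeaks")])
        by_type = pb.error_by_type(results)
        assert by_type["peaks"].n_labels == 0
        assert by_type["noPeaks"].n_labels == 1
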