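"""Label error of predicted peaks against annotated regions.

The error of a binary peak prediction ``y`` against a label set ``L`` is

    E(y, L) = FP(y, L) + FN(y, L)  in  {0, 1, ..., |L|},

where each label contributes at most one error.  With ``k`` the observed count
for a label region:

===========  =============================================  ==========  =========
label type   k counts ...                                   FP          FN
===========  =============================================  ==========  =========
noPeaks      peaks overlapping the region                   k >= 1      never
peaks        peaks overlapping the region                   never       k == 0
peakStart    peak starts p.start in [start, end)            k > 1       k == 0
peakEnd      peak ends   p.end   in (start, end]            k > 1       k == 0
===========  =============================================  ==========  =========

A ``peaks`` label accepts one *or more* overlapping peaks, so it can never be a
false positive; a ``noPeaks`` label asserts absence only, so it can never be a
false negative.  For peakEnd, ``p.end`` is exclusive, so the last covered base
is ``p.end - 1``: a peak ending exactly at the region's end coordinate counts.
A peak fully spanning a peakStart/peakEnd region with no boundary inside
counts as k = 0 (false negative): the region demands a visible boundary.

A label applying to g samples is scored once per sample and contributes g
entries to |L| (the same region labeled on 27 samples is 27 labels).
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np

from .exceptions import MissingSampleError
from .model import LABEL_TYPES, Label, PeakCalls

STATUS_CORRECT = "correct"
STATUS_FP = "false-positive"
STATUS_FN = "false-negative"


@dataclass(frozen=True)
class LabelResult:
    """FP/FN status of one label on one sample."""

    label: Label
    sample_id: str
    fp: int
    fn: int
    observed_count: int

    def __post_init__(self):
        if self.fp + self.fn > 1:
            raise AssertionError("a label is at most one error")

    @property
    def status(self) -> str:
        if self.fp:
            return STATUS_FP
        if self.fn:
            return STATUS_FN
        return STATUS_CORRECT


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregate FP/FN totals over a set of (label, sample) pairs."""

    fp_total: int
    fn_total: int
    n_labels: int

    @property
    def errors(self) -> int:
        """E = FP + FN."""
        return self.fp_total + self.fn_total

    @property
    def percent_error(self) -> float:
        """100 * E / |L|, or 0 for an empty label set."""
        if self.n_labels == 0:
            return 0.0
        return 100.0 * self.errors / self.n_labels

    def __add__(self, other: "ErrorSummary") -> "ErrorSummary":
        return ErrorSummary(
            self.fp_total + other.fp_total,
            self.fn_total + other.fn_total,
            self.n_labels + other.n_labels,
        )


def label_error_one(label: Label, calls: PeakCalls) -> LabelResult:
    """Score a single label against one sample's peak calls."""
    region = label.region
    starts, ends = calls.arrays_on(region.chrom)
    t = label.label_type
    if t in ("noPeaks", "peaks"):
        # peaks overlapping [start, end): start < region.end and end > region.start
        k = int(
            np.searchsorted(starts, region.end, side="left")
            - np.searchsorted(ends, region.start, side="right")
        )
        fp = int(t == "noPeaks" and k >= 1)
        fn = int(t == "peaks" and k == 0)
    elif t == "peakStart":
        k = int(
            np.searchsorted(starts, region.end, side="left")
            - np.searchsorted(starts, region.start, side="left")
        )
        fp, fn = int(k > 1), int(k == 0)
    else:  # peakEnd
        k = int(
            np.searchsorted(ends, region.end, side="right")
            - np.searchsorted(ends, region.start, side="right")
        )
        fp, fn = int(k > 1), int(k == 0)
    return LabelResult(label, calls.sample_id, fp, fn, k)


def _samples_for_label(
    label: Label,
    sample_ids: Iterable[str],
    groups: Mapping[str, str] | None,
) -> list[str]:
    sample_ids = list(sample_ids)
    if not label.sample_groups:
        return sample_ids
    matched = [s for s in sample_ids if label.applies_to(s, groups)]
    for g in label.sample_groups:
        if not any(s == g or (groups or {}).get(s) == g for s in sample_ids):
            raise MissingSampleError(
                f"label {label.region} ({label.label_type}) references sample group "
                f"{g!r}, which matches no scored sample"
            )
    return matched


def evaluate_labels(
    calls_by_sample: Mapping[str, PeakCalls],
    labels: Iterable[Label],
    groups: Mapping[str, str] | None = None,
) -> list[LabelResult]:
    """Per-(label, sample) results for every applicable pair.

    ``groups`` maps sample_id -> group name to resolve labels restricted to
    sample groups; a group name equal to a sample id always matches.
    """
    results: list[LabelResult] = []
    sample_ids = sorted(calls_by_sample)
    for label in labels:
        for sid in _samples_for_label(label, sample_ids, groups):
            results.append(label_error_one(label, calls_by_sample[sid]))
    return results


def summarize(results: Iterable[LabelResult]) -> ErrorSummary:
    fp = fn = n = 0
    for r in results:
        fp += r.fp
        fn += r.fn
        n += 1
    return ErrorSummary(fp, fn, n)


def total_error(
    calls_by_sample: Mapping[str, PeakCalls],
    labels: Iterable[Label],
    groups: Mapping[str, str] | None = None,
) -> ErrorSummary:
    """Total label error E = FP + FN of a multi-sample call set."""
    return summarize(evaluate_labels(calls_by_sample, labels, groups))


def error_by_type(results: Iterable[LabelResult]) -> dict[str, ErrorSummary]:
    """Partition results by label type; always returns all four types.

    The four summaries' FP/FN/|L| totals sum to the global totals.
    """
    acc = {t: [0, 0, 0] for t in LABEL_TYPES}
    for r in results:
        bucket = acc[r.label.label_type]
        bucket[0] += r.fp
        bucket[1] += r.fn
        bucket[2] += 1
    return {t: ErrorSummary(*vals) for t, vals in acc.items()}
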