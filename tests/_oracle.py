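"""Independent base-resolution oracle for label error.

Rasterizes peak calls to a binary vector y over [0, b) and counts overlaps,
peak starts and peak ends by scanning bases — a deliberately different
representation and algorithm from the interval-arithmetic implementation, so
the two can cross-check each other on random instances.
"""
from __future__ import annotations

import numpy as np

from peakbench.model import LABEL_TYPES, GenomicInterval, Label, PeakCalls


def brute_force_counts(label: Label, y: np.ndarray) -> int:
    """Observed count for one label by scanning the binary vector."""
    a, e = label.region.start, label.region.end
    b = len(y)
    t = label.label_type
    if t in ("noPeaks", "peaks"):
        # distinct maximal runs of 1s intersecting [a, e)
        k = 1 if y[a] else 0
        for i in range(a + 1, e):
            if y[i] and not y[i - 1]:
                k += 1
        return k
    if t == "peakStart":
        k = 0
        for i in range(a, e):
            if y[i] and (i == 0 or not y[i - 1]):
                k += 1
        return k
    # peakEnd: exclusive end j in (a, e]
    k = 0
    for j in range(a + 1, e + 1):
        if y[j - 1] and (j == b or not y[j]):
            k += 1
    return k


def brute_force_fp_fn(label: Label, y: np.ndarray) -> tuple[int, int, int]:
    k = brute_force_counts(label, y)
    t = label.label_type
    if t == "noPeaks":
        return int(k >= 1), 0, k
    if t == "peaks":
        return 0, int(k == 0), k
    return int(k > 1), int(k == 0), k


def brute_force_total(labels, calls: PeakCalls, b: int) -> tuple[int, int]:
    y = calls.to_binary(labels[0].region.chrom, b) if labels else np.zeros(b, np.int8)
    fp = fn = 0
    for lab in labels:
        f, n, _ = brute_force_fp_fn(lab, y)
        fp += f
        fn += n
    return fp, fn


def random_disjoint_peak(
    rng: np.random.Generator, calls: PeakCalls, b: int, chrom: str = "chrT"
) -> GenomicInterval | None:
    """A random interval that neither overlaps nor abuts any existing peak.

    Such an interval survives merging as a separate peak, so adding it is a
    genuine "one more peak" perturbation.  Returns None when the calls leave
    no room.
    """
    y = calls.to_binary(chrom, b)
    d = np.diff(np.concatenate(([1], y, [1])))
    zero_starts = np.flatnonzero(d == -1)
    zero_ends = np.flatnonzero(d == 1)
    candidates = []
    for zs, ze in zip(zero_starts, zero_ends):
        lo = zs if zs == 0 else zs + 1  # keep one empty base next to a peak
        hi = ze if ze == b else ze - 1
        if hi - lo >= 1:
            candidates.append((int(lo), int(hi)))
    if not candidates:
        return None
    lo, hi = candidates[int(rng.integers(len(candidates)))]
    s = int(rng.integers(lo, hi))
    e = int(rng.integers(s + 1, hi + 1))
    return GenomicInterval(chrom, s, e)


def random_instance(rng: np.random.Generator, chrom: str = "chrT"):
    """A random (b, labels, calls) instance: b <= 1000, <= 10 peaks, <= 10 labels."""
    b = int(rng.integers(50, 1001))
    intervals = []
    for _ in range(int(rng.integers(0, 11))):
        s = int(rng.integers(0, b - 1))
        e = min(b, s + int(rng.integers(1, max(2, b // 5))))
        intervals.append(GenomicInterval(chrom, s, e))
    calls = PeakCalls("s1", intervals)
    labels = []
    for i in range(int(rng.integers(1, 11))):
        s = int(rng.integers(0, b - 1))
        e = min(b, s + int(rng.integers(1, max(2, b // 3))))
        label_type = LABEL_TYPES[int(rng.integers(len(LABEL_TYPES)))]
        labels.append(Label(GenomicInterval(chrom, s, e), label_type, frozenset(), f"w{i}"))
    return b, labels, calls
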