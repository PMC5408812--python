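"""Core genomic data model.

Intervals, region labels, label windows, peak calls and coverage profiles, with
the elementary interval operations every other module builds on.

Coordinate convention
---------------------
All coordinates are 0-based, half-open ``[start, end)``, matching BED/bedGraph.
Overlap means a nonempty intersection: a single shared base suffices, and
abutting intervals (``a.end == b.start``) do not overlap.

A set of peak calls for one sample is equivalent to a binary vector
``y in {0,1}^b`` over the chromosome: the peaks are the maximal runs of 1s.
Because ``y`` cannot represent two abutting peaks, abutting intervals are
merged when a :class:`PeakCalls` is constructed, so "one peak" is well defined
for peak-start / peak-end counting.
"""
from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ChromosomeMismatchError, ValidationError

#: The four region label types. ``noPeaks`` asserts a region contains only
#: background noise; ``peaks`` asserts at least one overlapping peak (of any
#: size); ``peakStart``/``peakEnd`` assert exactly one peak start (resp. end)
#: inside the region.
LABEL_TYPES = ("noPeaks", "peaks", "peakStart", "peakEnd")

#: Types whose absence of support is a false negative.
POSITIVE_LABEL_TYPES = frozenset({"peaks", "peakStart", "peakEnd"})

#: Types that can produce a false positive ("peaks" cannot: any number >= 1 of
#: overlapping peaks is correct).
FP_CAPABLE_LABEL_TYPES = frozenset({"noPeaks", "peakStart", "peakEnd"})


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not isinstance(self.start, (int, np.integer)) or not isinstance(
            self.end, (int, np.integer)
        ):
            raise ValidationError(
                f"interval coordinates must be integers, got {self.start!r}-{self.end!r}"
            )
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base.

        Raises :class:`ChromosomeMismatchError` for intervals on different
        chromosomes: they are incomparable, not disjoint.
        """
        if self.chrom != other.chrom:
            raise ChromosomeMismatchError(
                f"cannot compare intervals on {self.chrom!r} and {other.chrom!r}"
            )
        return max(self.start, other.start) < min(self.end, other.end)

    def contains(self, other: "GenomicInterval") -> bool:
        if self.chrom != other.chrom:
            return False
        return self.start <= other.start and other.end <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Functional form of :meth:`GenomicInterval.overlaps`."""
    return a.overlaps(b)


@dataclass(frozen=True)
class Label:
    """A typed region label: the atom of supervision.

    ``sample_groups`` names the sample groups (e.g. cell types) the label
    applies to; the empty set means the label applies to every sample being
    scored.  A group name that equals a sample id matches that sample
    directly, so single-sample datasets need no group mapping.
    """

    region: GenomicInterval
    label_type: str
    sample_groups: frozenset[str] = frozenset()
    window_id: str = ""

    def __post_init__(self):
        if self.label_type not in LABEL_TYPES:
            raise ValidationError(
                f"unknown label type {self.label_type!r}; expected one of {LABEL_TYPES}"
            )
        object.__setattr__(self, "sample_groups", frozenset(self.sample_groups))

    @property
    def is_positive(self) -> bool:
        return self.label_type in POSITIVE_LABEL_TYPES

    def applies_to(self, sample_id: str, groups: Mapping[str, str] | None = None) -> bool:
        """Does this label apply to ``sample_id``?

        ``groups`` maps sample ids to group names. A label with an empty
        ``sample_groups`` applies to everything; otherwise the sample matches
        if its group, or its own id, is named.
        """
        if not self.sample_groups:
            return True
        if sample_id in self.sample_groups:
            return True
        if groups is not None and groups.get(sample_id) in self.sample_groups:
            return True
        return False


@dataclass
class Window:
    """A genomic interval grouping nearby labels; the unit of train/test splits.

    Each window is labeled as a unit (labels within a window are not
    independent of each other), so resampling for cross-validation is done
    over windows, never over individual labels.
    """

    id: str
    region: GenomicInterval
    labels: list[Label] = field(default_factory=list)

    def __post_init__(self):
        for lab in self.labels:
            if not self.region.contains(lab.region):
                raise ValidationError(
                    f"label {lab.region} outside window {self.id} region {self.region}"
                )


def labels_of(windows: Iterable[Window]) -> list[Label]:
    """All labels of a collection of windows, in window order."""
    return [lab for w in windows for lab in w.labels]


class PeakCalls:
    """The predicted peaks of one sample: sorted, disjoint, non-abutting.

    Internally stored per chromosome as sorted numpy start/end arrays, the
    maximal-run representation of the binary prediction vector. Overlapping or
    abutting input intervals are merged on construction.
    """

    __slots__ = ("sample_id", "_by_chrom")

    def __init__(self, sample_id: str, intervals: Iterable[GenomicInterval] = ()):
        self.sample_id = sample_id
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(by_chrom):
            pairs = sorted(by_chrom[chrom])
            starts: list[int] = []
            ends: list[int] = []
            for s, e in pairs:
                if ends and s <= ends[-1]:  # overlap or abutment: merge
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._by_chrom[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
    ) -> "PeakCalls":
        """Fast path for already sorted, disjoint, non-abutting arrays."""
        obj = cls.__new__(cls)
        obj.sample_id = sample_id
        obj._by_chrom = (
            {}
            if len(starts) == 0
            else {chrom: (np.asarray(starts, np.int64), np.asarray(ends, np.int64))}
        )
        return obj

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_chrom))

    def arrays_on(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays on ``chrom`` (empty arrays if none)."""
        if chrom not in self._by_chrom:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._by_chrom[chrom]

    @property
    def peaks(self) -> tuple[GenomicInterval, ...]:
        out = []
        for chrom in self.chroms:
            starts, ends = self._by_chrom[chrom]
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return tuple(out)

    def __len__(self) -> int:
        return sum(len(starts) for starts, _ in self._by_chrom.values())

    def __iter__(self):
        return iter(self.peaks)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakCalls):
            return NotImplemented
        if self.sample_id != other.sample_id or self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self._by_chrom[c][0], other._by_chrom[c][0])
            and np.array_equal(self._by_chrom[c][1], other._by_chrom[c][1])
            for c in self.chroms
        )

    def __repr__(self) -> str:
        return f"PeakCalls({self.sample_id!r}, {len(self)} peaks)"

    def with_peak(self, extra: GenomicInterval) -> "PeakCalls":
        """A new call set with one more interval merged in."""
        return PeakCalls(self.sample_id, list(self.peaks) + [extra])

    def to_binary(self, chrom: str, b: int) -> np.ndarray:
        """Paint the peaks on ``chrom`` onto a zero vector of length ``b``."""
        y = np.zeros(b, dtype=np.int8)
        starts, ends = self.arrays_on(chrom)
        for s, e in zip(starts, ends):
            y[s:e] = 1
        return y


def peaks_from_binary(y: Sequence[int] | np.ndarray, chrom: str = "chr1") -> tuple[GenomicInterval, ...]:
    """Maximal runs of 1s in a binary vector, as half-open intervals.

    The inverse of painting intervals onto a zero vector of the same length.
    """
    arr = np.asarray(y)
    if arr.ndim != 1 or len(arr) < 1:
        raise ValidationError("binary vector must be 1-dimensional and non-empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("binary vector entries must all be 0 or 1")
    d = np.diff(np.concatenate(([0], arr.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return tuple(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))


@dataclass(frozen=True)
class LabelViolation:
    """One violated labeling constraint; ``severity`` is 'error' or 'warning'."""

    severity: str
    window_id: str
    message: str


def _may_share_sample(a: Label, b: Label) -> bool:
    # An empty group set applies to all samples, hence shares with anything.
    if not a.sample_groups or not b.sample_groups:
        return True
    return bool(a.sample_groups & b.sample_groups)


def validate_labels(labels: Iterable[Label]) -> list[LabelViolation]:
    """Check the labeling constraints; violations are data, not exceptions.

    Errors: two labels overlapping on any shared sample.  Warnings: a window
    lacking a noPeaks label or lacking a positive (peaks/peakStart/peakEnd)
    label.  An empty result means the labels are valid.
    """
    labels = list(labels)
    violations: list[LabelViolation] = []
    by_chrom: dict[str, list[Label]] = {}
    for lab in labels:
        by_chrom.setdefault(lab.region.chrom, []).append(lab)
    for chrom_labels in by_chrom.values():
        chrom_labels.sort(key=lambda l: (l.region.start, l.region.end))
        for i, a in enumerate(chrom_labels):
            for b in itertools.islice(chrom_labels, i + 1, None):
                if b.region.start >= a.region.end:
                    break
                if _may_share_sample(a, b):
                    violations.append(
                        LabelViolation(
                            "error",
                            a.window_id,
                            f"labels {a.region} ({a.label_type}) and {b.region} "
                            f"({b.label_type}) overlap on a shared sample",
                        )
                    )
    seen: dict[str, set[str]] = {}
    order: list[str] = []
    for lab in labels:
        if lab.window_id not in seen:
            order.append(lab.window_id)
        seen.setdefault(lab.window_id, set()).add(lab.label_type)
    for wid in order:
        types = seen[wid]
        if "noPeaks" not in types:
            violations.append(
                LabelViolation("warning", wid, f"window {wid!r} has no noPeaks label")
            )
        if not types & POSITIVE_LABEL_TYPES:
            violations.append(
                LabelViolation(
                    "warning",
                    wid,
                    f"window {wid!r} has no positive (peaks/peakStart/peakEnd) label",
                )
            )
    return violations


class CoverageProfile:
    """Per-base aligned-read counts over one chromosome, run-length encoded.

    The signal ``x`` is a vector of nonnegative integer counts over ``[0, b)``;
    internally stored as run lengths and run values (adjacent equal values are
    compressed on construction, so equality is canonical).
    """

    __slots__ = ("sample_id", "chrom", "run_lengths", "run_values")

    def __init__(
        self,
        sample_id: str,
        chrom: str,
        run_lengths: Sequence[int] | np.ndarray,
        run_values: Sequence[int] | np.ndarray,
    ):
        lengths = np.asarray(run_lengths, dtype=np.int64)
        values = np.asarray(run_values, dtype=np.int64)
        if lengths.shape != values.shape or lengths.ndim != 1 or len(lengths) == 0:
            raise ValidationError("run lengths and values must be equal-length 1-d arrays")
        if (lengths <= 0).any():
            raise ValidationError("run lengths must be positive")
        if (values < 0).any():
            raise ValidationError("coverage counts must be nonnegative")
        # canonicalize: merge adjacent equal-valued runs
        if len(values) > 1:
            keep = np.concatenate(([True], values[1:] != values[:-1]))
            if not keep.all():
                idx = np.flatnonzero(keep)
                lengths = np.add.reduceat(lengths, idx)
                values = values[idx]
        self.sample_id = sample_id
        self.chrom = chrom
        self.run_lengths = lengths
        self.run_values = values

    @classmethod
    def from_array(cls, sample_id: str, chrom: str, values: np.ndarray) -> "CoverageProfile":
        arr = np.asarray(values)
        if arr.ndim != 1 or len(arr) == 0:
            raise ValidationError("coverage array must be 1-dimensional and non-empty")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.equal(np.mod(arr, 1), 0).all():
                raise ValidationError("coverage counts must be integers")
            arr = arr.astype(np.int64)
        change = np.flatnonzero(np.concatenate(([True], arr[1:] != arr[:-1])))
        lengths = np.diff(np.concatenate((change, [len(arr)])))
        return cls(sample_id, chrom, lengths, arr[change])

    @property
    def b(self) -> int:
        """Total represented length (number of base pairs)."""
        return int(self.run_lengths.sum())

    @property
    def total(self) -> int:
        """Sum of counts over all bases."""
        return int((self.run_lengths * self.run_values).sum())

    @property
    def mean(self) -> float:
        return self.total / self.b

    def to_array(self) -> np.ndarray:
        return np.repeat(self.run_values, self.run_lengths)

    def runs(self):
        """Yield (start, end, value) triples covering [0, b)."""
        pos = 0
        for length, value in zip(self.run_lengths, self.run_values):
            yield pos, pos + int(length), int(value)
            pos += int(length)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoverageProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.chrom == other.chrom
            and np.array_equal(self.run_lengths, other.run_lengths)
            and np.array_equal(self.run_values, other.run_values)
        )

    def __repr__(self) -> str:
        return f"CoverageProfile({self.sample_id!r}, {self.chrom!r}, b={self.b})"
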