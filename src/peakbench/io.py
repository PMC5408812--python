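"""File formats: labels, peak calls (BED/narrowPeak), coverage (bedGraph),
thresholded-call manifests, sample-group tables and result tables.

All coordinates on disk are 0-based half-open integers. Readers reject rather
than silently coerce malformed records, and every accepted file round-trips
bit-exact through its writer where a writer exists.  Writers are atomic
(temp-then-rename in the destination directory).

Label dialect
-------------
One label per line::

    chrom:start-end labelType [group ...]

Commas are permitted in numbers, ``#`` starts a comment, and a blank line ends
the current window.  A tab-separated alternative with columns
``chrom start end type groups window_id`` (groups comma-joined, may be empty)
is also accepted; the format is detected from the first data line.
"""
from __future__ import annotations

import os
import re
import tempfile
from collections.abc import Iterable, Mapping
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import ParseError, PeakBenchError, ThresholdError, ValidationError
from .model import (
    CoverageProfile,
    GenomicInterval,
    Label,
    LABEL_TYPES,
    PeakCalls,
    Window,
    validate_labels,
)
from .peak_error import ErrorSummary, LabelResult


@dataclass
class ThresholdedCallSet:
    """One algorithm's peak calls per sample at each threshold of a grid.

    ``thresholds`` is the strictly increasing grid of significance thresholds
    (low thresholds over-call, high thresholds under-call);
    ``default_threshold`` is the algorithm author's suggested value and, when
    present, is itself a grid point so it can be evaluated without
    interpolation.
    """

    algorithm: str
    thresholds: tuple[float, ...]
    calls: dict[tuple[float, str], PeakCalls] = field(default_factory=dict)
    default_threshold: float | None = None

    def __post_init__(self):
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError("thresholds must be strictly increasing")
        if (
            self.default_threshold is not None
            and float(self.default_threshold) not in self.thresholds
        ):
            raise ValidationError("default threshold must be one of the grid thresholds")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({sid for _, sid in self.calls}))

    def calls_at(self, threshold: float) -> dict[str, PeakCalls]:
        """All samples' calls at one grid threshold (exact match, no interpolation)."""
        if float(threshold) not in self.thresholds:
            raise ThresholdError(
                f"threshold {threshold} is not on the grid of {len(self.thresholds)} points"
            )
        return {
            sid: self.calls[(float(threshold), sid)]
            for sid in self.samples
            if (float(threshold), sid) in self.calls
        }


@contextmanager
def atomic_write(path):
    """Write to a temp file in the destination directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


# ---------------------------------------------------------------------------
# labels


_LABEL_RE = re.compile(r"^(\S+):([\d,]+)-([\d,]+)\s+(\S+)(?:\s+(.*))?$")


def _parse_coord(token: str, path, lineno: int) -> int:
    try:
        return int(token.replace(",", ""))
    except ValueError:
        raise ParseError(f"malformed coordinate {token!r}", path, lineno) from None


def _make_label(chrom, start, end, label_type, groups, window_id, path, lineno) -> Label:
    if label_type not in LABEL_TYPES:
        raise ParseError(
            f"unknown label type {label_type!r}; expected one of {', '.join(LABEL_TYPES)}",
            path,
            lineno,
        )
    if start >= end:
        raise ParseError(f"label start {start} >= end {end}", path, lineno)
    try:
        region = GenomicInterval(chrom, start, end)
    except ValidationError as exc:
        raise ParseError(str(exc), path, lineno) from None
    return Label(region, label_type, frozenset(groups), window_id)


def read_labels(path) -> list[Window]:
    """Parse a label file into windows.

    In the colon dialect, consecutive non-blank lines form one window; windows
    get sequential ids ``win0, win1, ...``.  In the TSV dialect the window_id
    column groups labels.  Overlap violations raise; incomplete windows
    (missing noPeaks or positive label) only produce warnings retrievable via
    :func:`peakbench.model.validate_labels`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    blocks: dict[str, list[Label]] = {}
    order: list[str] = []
    n_windows = 0
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            current = None
            continue
        if "\t" in line and ":" not in line.split("\t", 1)[0]:
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(
                    f"TSV label line needs 6 columns (chrom start end type groups window_id), got {len(cols)}",
                    path,
                    lineno,
                )
            chrom, start_s, end_s, label_type, groups_s, window_id = cols[:6]
            if chrom == "chrom" and label_type == "type":
                continue  # header
            start = _parse_coord(start_s, path, lineno)
            end = _parse_coord(end_s, path, lineno)
            groups = [g for g in groups_s.split(",") if g]
            wid = window_id
        else:
            m = _LABEL_RE.match(line)
            if m is None:
                raise ParseError(f"malformed label line {line!r}", path, lineno)
            chrom, start_s, end_s, label_type, rest = m.groups()
            start = _parse_coord(start_s, path, lineno)
            end = _parse_coord(end_s, path, lineno)
            groups = rest.split() if rest else []
            if current is None:
                current = f"win{n_windows}"
                n_windows += 1
            wid = current
        label = _make_label(chrom, start, end, label_type, groups, wid, path, lineno)
        if wid not in blocks:
            blocks[wid] = []
            order.append(wid)
        blocks[wid].append(label)

    violations = validate_labels([lab for wid in order for lab in blocks[wid]])
    overlap_errors = [v for v in violations if v.severity == "error"]
    if overlap_errors:
        raise ValidationError(
            f"{path}: " + "; ".join(v.message for v in overlap_errors)
        )
    windows = []
    for wid in order:
        labs = blocks[wid]
        region = GenomicInterval(
            labs[0].region.chrom,
            min(l.region.start for l in labs),
            max(l.region.end for l in labs),
        )
        windows.append(Window(wid, region, labs))
    return windows


def write_labels(windows: Iterable[Window], path) -> None:
    """Write windows in the colon dialect, blank line between windows."""
    with atomic_write(path) as fh:
        first = True
        for w in windows:
            if not first:
                fh.write("\n")
            first = False
            for lab in w.labels:
                groups = " ".join(sorted(lab.sample_groups))
                suffix = f" {groups}" if groups else ""
                fh.write(
                    f"{lab.region.chrom}:{lab.region.start}-{lab.region.end} "
                    f"{lab.label_type}{suffix}\n"
                )


# ---------------------------------------------------------------------------
# peaks (BED3 / narrowPeak)


def read_peaks(path, sample_id: str | None = None) -> PeakCalls:
    """Read peak calls from BED3+ or narrowPeak; only chrom/start/end are used.

    Overlapping or abutting intervals are merged; output is sorted.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    intervals = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise ParseError("BED line needs at least 3 columns", path, lineno)
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(
                f"non-integer coordinates {cols[1]!r}, {cols[2]!r}", path, lineno
            ) from None
        if start >= end:
            raise ParseError(f"chromStart {start} >= chromEnd {end}", path, lineno)
        intervals.append(GenomicInterval(chrom, start, end))
    return PeakCalls(sample_id, intervals)


def write_peaks(calls: PeakCalls, path) -> None:
    with atomic_write(path) as fh:
        for p in calls.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


# ---------------------------------------------------------------------------
# coverage (bedGraph)


def read_coverage(path, sample_id: str | None = None) -> CoverageProfile:
    """Read a single-chromosome bedGraph with integer values.

    Records must be sorted and non-overlapping; gaps are filled with zeros.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    chrom = None
    lengths: list[int] = []
    values: list[int] = []
    pos = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 4:
            raise ParseError("bedGraph line needs 4 columns", path, lineno)
        if chrom is None:
            chrom = cols[0]
        elif cols[0] != chrom:
            raise ParseError(
                f"multiple chromosomes in one coverage file ({chrom!r}, {cols[0]!r})",
                path,
                lineno,
            )
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError("non-integer coordinates", path, lineno) from None
        try:
            value_f = float(cols[3])
        except ValueError:
            raise ParseError(f"malformed value {cols[3]!r}", path, lineno) from None
        if not value_f.is_integer():
            raise ParseError(
                f"coverage counts must be integers, got {cols[3]}", path, lineno
            )
        value = int(value_f)
        if value < 0:
            raise ParseError(f"negative coverage {value}", path, lineno)
        if start >= end:
            raise ParseError(f"start {start} >= end {end}", path, lineno)
        if start < pos:
            raise ParseError(
                f"overlapping or unsorted record starting at {start} (previous end {pos})",
                path,
                lineno,
            )
        if start > pos:  # gap: fill with zeros
            lengths.append(start - pos)
            values.append(0)
        lengths.append(end - start)
        values.append(value)
        pos = end
    if not lengths:
        raise ParseError("coverage file contains no records", path)
    return CoverageProfile(sample_id, chrom, lengths, values)


def write_coverage(profile: CoverageProfile, path) -> None:
    """Write bedGraph; zero runs are written explicitly so b round-trips."""
    with atomic_write(path) as fh:
        for start, end, value in profile.runs():
            fh.write(f"{profile.chrom}\t{start}\t{end}\t{value}\n")


# ---------------------------------------------------------------------------
# sample groups


def read_groups(path) -> dict[str, str]:
    """TSV mapping sample_id -> group name (header optional)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ParseError("groups line needs 2 columns", path, lineno)
        if cols[0] == "sample_id" and cols[1] == "group":
            continue
        out[cols[0]] = cols[1]
    return out


def write_groups(groups: Mapping[str, str], path) -> None:
    with atomic_write(path) as fh:
        fh.write("sample_id\tgroup\n")
        for sid in sorted(groups):
            fh.write(f"{sid}\t{groups[sid]}\n")


# ---------------------------------------------------------------------------
# call manifests


MANIFEST_COLUMNS = ("algorithm", "threshold", "sample_id", "peak_file", "is_default")


def read_call_manifest(path) -> ThresholdedCallSet:
    """Load a TSV manifest of per-threshold, per-sample peak files.

    Columns: algorithm, threshold, sample_id, peak_file (relative to the
    manifest), is_default (0/1).  Thresholds are sorted on load; at most one
    threshold may be flagged default.
    """
    path = Path(path)
    try:
        # round_trip float parsing: thresholds must match their repr() bit-exactly
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot read manifest: {exc}", path) from None
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"manifest missing columns: {', '.join(missing)}", path)
    algorithms = sorted(set(df["algorithm"].astype(str)))
    if len(algorithms) != 1:
        raise ParseError(
            f"manifest must describe exactly one algorithm, found {algorithms}", path
        )
    pairs = list(zip(df["threshold"].astype(float), df["sample_id"].astype(str)))
    if len(pairs) != len(set(pairs)):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ParseError(f"duplicate (threshold, sample) rows: {dupes}", path)
    default_thresholds = sorted(set(df.loc[df["is_default"].astype(int) == 1, "threshold"].astype(float)))
    if len(default_thresholds) > 1:
        raise ParseError(
            f"at most one threshold may be flagged default, found {default_thresholds}",
            path,
        )
    calls = {}
    for row in df.itertuples(index=False):
        peak_path = path.parent / str(row.peak_file)
        if not peak_path.exists():
            raise PeakBenchError(f"manifest references missing peak file {peak_path}")
        calls[(float(row.threshold), str(row.sample_id))] = read_peaks(
            peak_path, sample_id=str(row.sample_id)
        )
    thresholds = tuple(sorted({t for t, _ in calls}))
    return ThresholdedCallSet(
        algorithm=algorithms[0],
        thresholds=thresholds,
        calls=calls,
        default_threshold=default_thresholds[0] if default_thresholds else None,
    )


def write_call_manifest(call_set: ThresholdedCallSet, path) -> None:
    path = Path(path)
    rows = []
    for (threshold, sid), calls in sorted(call_set.calls.items()):
        peak_file = f"peaks/{call_set.algorithm}_t{call_set.thresholds.index(threshold)}_{sid}.bed"
        write_peaks(calls, path.parent / peak_file)
        rows.append(
            (
                call_set.algorithm,
                repr(float(threshold)),  # full precision: thresholds round-trip bit-exact
                sid,
                peak_file,
                str(int(threshold == call_set.default_threshold)),
            )
        )
    with atomic_write(path) as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# result tables


ERROR_TABLE_COLUMNS = (
    "window_id",
    "chrom",
    "start",
    "end",
    "label_type",
    "sample_groups",
    "sample_id",
    "fp",
    "fn",
    "observed_count",
    "status",
)


def write_error_table(results: Iterable[LabelResult], path, header_comment: str | None = None) -> None:
    """One row per (label, sample) result; bit-exact round trip via read_error_table."""
    with atomic_write(path) as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(ERROR_TABLE_COLUMNS) + "\n")
        for r in results:
            lab = r.label
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        lab.window_id,
                        lab.region.chrom,
                        lab.region.start,
                        lab.region.end,
                        lab.label_type,
                        ",".join(sorted(lab.sample_groups)),
                        r.sample_id,
                        r.fp,
                        r.fn,
                        r.observed_count,
                        r.status,
                    )
                )
                + "\n"
            )


def read_error_table(path) -> list[LabelResult]:
    df = pd.read_csv(
        Path(path), sep="\t", comment="#", dtype={"window_id": str, "sample_id": str},
        keep_default_na=False,
    )
    out = []
    for row in df.itertuples(index=False):
        label = Label(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            str(row.label_type),
            frozenset(g for g in str(row.sample_groups).split(",") if g),
            str(row.window_id),
        )
        out.append(
            LabelResult(label, str(row.sample_id), int(row.fp), int(row.fn), int(row.observed_count))
        )
    return out


def write_summary_table(
    rows: Iterable[tuple[Mapping[str, object], ErrorSummary]],
    path,
    header_comment: str | None = None,
) -> None:
    """One row per summary (e.g. per threshold or per fold).

    Each row is (metadata mapping, summary); metadata columns come first, in
    first-appearance order.  Percent error is printed to one decimal place; the
    exact value is recoverable from fp/fn/n_labels on read-back.
    """
    rows = list(rows)
    meta_cols: list[str] = []
    for meta, _ in rows:
        for key in meta:
            if key not in meta_cols:
                meta_cols.append(key)
    with atomic_write(path) as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "\t".join(meta_cols + ["fp", "fn", "errors", "n_labels", "percent_error"]) + "\n"
        )
        for meta, s in rows:
            cells = [str(meta.get(c, "")) for c in meta_cols]
            cells += [
                str(s.fp_total),
                str(s.fn_total),
                str(s.errors),
                str(s.n_labels),
                f"{s.percent_error:.1f}",
            ]
            fh.write("\t".join(cells) + "\n")


def read_summary_table(path) -> list[tuple[dict[str, object], ErrorSummary]]:
    df = pd.read_csv(Path(path), sep="\t", comment="#", keep_default_na=False)
    summary_cols = {"fp", "fn", "errors", "n_labels", "percent_error"}
    meta_cols = [c for c in df.columns if c not in summary_cols]
    out = []
    for _, row in df.iterrows():
        meta = {c: row[c] for c in meta_cols}
        out.append((meta, ErrorSummary(int(row["fp"]), int(row["fn"]), int(row["n_labels"]))))
    return out
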