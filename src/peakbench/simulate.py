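"""Synthetic labeled multi-sample benchmarks with known ground truth.

Emulates the structure of a visually labeled ChIP-seq benchmark: multiple
samples grouped into cell types, integer per-base coverage with planted
enrichment peaks shared within cell types, and region labels that obey the
labeling constraints (no two labels overlap on any sample; each window has a
noPeaks label and, when geometry allows, positive labels).

Coverage noise is Poisson (integer counts, variance = mean): the simplest law
producing nonnegative-integer coverage.  Real ChIP-seq noise is more complex
(overdispersion, mappability, GC structure, input contamination); the
generator is a test fixture for the supervision machinery, not a read-level
simulator, so passing tests demonstrate the correctness of the error metric,
training and evaluation code — not caller performance on real data.

Window geometry
---------------
Windows tile one synthetic chromosome.  Within each window, planted peaks are
separated by gaps wide enough that every label region is unambiguous:

* a ``peaks`` (or, for cell types lacking the peak, ``noPeaks``) label covers
  the peak interior, inset by a margin ``m = max(margin_min, margin_frac * w)``;
* ``peakStart``/``peakEnd`` labels span ``[boundary - m, boundary + m)``, so
  the true boundary is strictly inside and, by the gap construction, exactly
  one peak boundary can fall in each;
* one ``noPeaks`` label per window sits in a gap, clear of all boundary-label
  extents, and applies to every sample.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .caller import BENCHMARK_CONFIG, CallerConfig, build_call_set
from .exceptions import ValidationError
from .io import (
    write_call_manifest,
    write_coverage,
    write_groups,
    write_labels,
    write_peaks,
)
from .model import CoverageProfile, GenomicInterval, Label, PeakCalls, Window

_NOPEAKS_MIN = 10  # minimum width of the per-window noPeaks region, bases


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic benchmark.

    ``background_mean`` and ``peak_mean`` are expected counts per base (mu0
    outside and mu1 inside planted peaks, mu1 > mu0 > 0);
    ``peak_sharing_prob`` is the probability that a planted peak is carried by
    a given cell type (all samples of a carrying type have it; every peak is
    forced to have at least one carrier so each window keeps a positive
    label); ``boundary_label_prob`` is the probability that a planted peak
    also gets peakStart/peakEnd labels in addition to its peaks label.
    """

    n_samples: int = 20
    n_cell_types: int = 2
    n_windows: int = 8
    window_length: int = 10_000
    peaks_per_window: int = 2
    background_mean: float = 5.0
    peak_mean: float = 30.0
    peak_width_range: tuple[int, int] = (200, 2000)
    peak_sharing_prob: float = 0.75
    boundary_label_prob: float = 0.5
    label_margin_frac: float = 0.1
    label_margin_min: int = 5
    chrom: str = "chrSim"
    seed: int = 1

    def __post_init__(self):
        if not 0 < self.background_mean < self.peak_mean:
            raise ValidationError("require peak_mean > background_mean > 0")
        wmin, wmax = self.peak_width_range
        if not 0 < wmin <= wmax:
            raise ValidationError("peak widths must be positive and ordered")
        if wmin <= 2 * self._margin(wmin):
            raise ValidationError("minimum peak width too small for label margins")
        for p in (self.peak_sharing_prob, self.boundary_label_prob):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if min(self.n_samples, self.n_cell_types, self.n_windows, self.window_length) < 1:
            raise ValidationError("counts and lengths must be positive")
        if self.n_cell_types > self.n_samples:
            raise ValidationError("cannot have more cell types than samples")
        if self.peaks_per_window < 0:
            raise ValidationError("peaks_per_window must be >= 0")
        if self._required_length() > self.window_length:
            raise ValidationError(
                f"window geometry infeasible: {self.peaks_per_window} peaks of width up "
                f"to {wmax} need {self._required_length()} > window_length {self.window_length}"
            )

    def _margin(self, width: int) -> int:
        return max(self.label_margin_min, int(round(self.label_margin_frac * width)))

    @property
    def _min_gap(self) -> int:
        # room for two boundary-label margins plus a noPeaks candidate
        return 2 * self._margin(self.peak_width_range[1]) + _NOPEAKS_MIN + 2

    def _required_length(self) -> int:
        p = self.peaks_per_window
        return p * self.peak_width_range[1] + (p + 1) * self._min_gap

    @property
    def genome_length(self) -> int:
        return self.n_windows * self.window_length


#: histone-style presets: localized (H3K4me3-like) vs extended (H3K36me3-like)
#: enrichment patterns.
PRESETS: dict[str, SimulationConfig] = {
    "sharp": SimulationConfig(),
    "broad": SimulationConfig(
        window_length=200_000, peak_width_range=(5000, 50_000)
    ),
}


def preset(name: str, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}")
    return dataclasses.replace(PRESETS[name], **overrides)


@dataclass
class GroundTruth:
    """The planted peaks: which intervals, in which cell types' samples."""

    #: (window_id, cell_type) -> planted peak intervals carried by that type
    peaks: dict[tuple[str, str], tuple[GenomicInterval, ...]] = field(default_factory=dict)
    #: cell_type -> sample ids of that type
    samples_by_type: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class Benchmark:
    """Everything one simulation run produces."""

    config: SimulationConfig
    coverage: dict[str, CoverageProfile]
    truth: GroundTruth
    windows: list[Window]
    groups: dict[str, str]  # sample_id -> cell type


def _sample_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    types = [f"celltype{t}" for t in range(config.n_cell_types)]
    groups: dict[str, str] = {}
    for i in range(config.n_samples):
        ct = types[i % config.n_cell_types]
        groups[f"{ct}_s{i}"] = ct
    return types, groups


def _plant_window(
    config: SimulationConfig, rng: np.random.Generator, w_index: int, types: list[str]
) -> tuple[Window, dict[str, tuple[GenomicInterval, ...]]]:
    """Plant peaks and emit labels for one window; returns (window, peaks by type)."""
    chrom = config.chrom
    w0 = w_index * config.window_length
    wid = f"win{w_index}"
    n_peaks = config.peaks_per_window
    wmin, wmax = config.peak_width_range
    min_gap = config._min_gap

    widths = rng.integers(wmin, wmax + 1, size=n_peaks) if n_peaks else np.empty(0, int)
    slack = config.window_length - int(widths.sum()) - (n_peaks + 1) * min_gap
    extra = rng.multinomial(slack, np.full(n_peaks + 1, 1.0 / (n_peaks + 1)))

    peak_ivs: list[GenomicInterval] = []
    gap_bounds: list[tuple[int, int]] = []  # free space between peaks (and window edges)
    cursor = w0
    for j in range(n_peaks):
        gap_start = cursor
        cursor += min_gap + int(extra[j])
        gap_bounds.append((gap_start, cursor))
        peak_ivs.append(GenomicInterval(chrom, cursor, cursor + int(widths[j])))
        cursor += int(widths[j])
    gap_bounds.append((cursor, w0 + config.window_length))

    # which cell types carry each peak (at least one, so the window keeps a
    # positive label)
    carriers: list[list[str]] = []
    for _ in range(n_peaks):
        carried = [t for t in types if rng.random() < config.peak_sharing_prob]
        if not carried:
            carried = [types[int(rng.integers(len(types)))]]
        carriers.append(carried)

    labels: list[Label] = []
    margin_max = config._margin(wmax)

    # the per-window noPeaks label, in a random gap, clear of boundary labels
    g = int(rng.integers(n_peaks + 1))
    gs, ge = gap_bounds[g]
    lo = gs + (margin_max if g > 0 else 0)  # clear of the previous peak's peakEnd label
    hi = ge - (margin_max if g < n_peaks else 0)  # clear of the next peak's peakStart label
    labels.append(Label(GenomicInterval(chrom, lo, hi), "noPeaks", frozenset(), wid))

    for j, iv in enumerate(peak_ivs):
        m = config._margin(iv.width)
        interior = GenomicInterval(chrom, iv.start + m, iv.end - m)
        for t in types:
            kind = "peaks" if t in carriers[j] else "noPeaks"
            labels.append(Label(interior, kind, frozenset({t}), wid))
        if rng.random() < config.boundary_label_prob:
            group = frozenset(carriers[j])
            labels.append(
                Label(GenomicInterval(chrom, iv.start - m, iv.start + m), "peakStart", group, wid)
            )
            labels.append(
                Label(GenomicInterval(chrom, iv.end - m, iv.end + m), "peakEnd", group, wid)
            )

    window = Window(wid, GenomicInterval(chrom, w0, w0 + config.window_length), labels)
    peaks_by_type = {
        t: tuple(iv for j, iv in enumerate(peak_ivs) if t in carriers[j]) for t in types
    }
    return window, peaks_by_type


def simulate_benchmark(config: SimulationConfig = SimulationConfig()) -> Benchmark:
    """Generate coverage, ground truth and labels; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    types, groups = _sample_names(config)

    windows: list[Window] = []
    truth = GroundTruth(samples_by_type={
        t: tuple(s for s, g in groups.items() if g == t) for t in types
    })
    for w_index in range(config.n_windows):
        window, peaks_by_type = _plant_window(config, rng, w_index, types)
        windows.append(window)
        for t in types:
            truth.peaks[(window.id, t)] = peaks_by_type[t]

    b = config.genome_length
    coverage: dict[str, CoverageProfile] = {}
    for sid in sorted(groups):
        values = rng.poisson(config.background_mean, b)
        ct = groups[sid]
        for w in windows:
            for iv in truth.peaks[(w.id, ct)]:
                values[iv.start : iv.end] = rng.poisson(config.peak_mean, iv.width)
        coverage[sid] = CoverageProfile.from_array(sid, config.chrom, values)
    return Benchmark(config, coverage, truth, windows, groups)


def truth_calls(truth: GroundTruth) -> dict[str, PeakCalls]:
    """The planted peaks as per-sample PeakCalls.

    By construction these attain zero label error against the generated
    labels — the generator's central contract.
    """
    out: dict[str, PeakCalls] = {}
    for ct, samples in truth.samples_by_type.items():
        ivs = sorted(
            (iv for (_, t), peaks in truth.peaks.items() if t == ct for iv in peaks),
            key=lambda iv: (iv.chrom, iv.start),
        )
        for sid in samples:
            out[sid] = PeakCalls(sid, ivs)
    return out


def simulate_single_peak_profiles(
    n_profiles: int,
    seed: int,
    length: int = 2000,
    background_range: tuple[int, int] = (1, 8),
    height_range: tuple[int, int] = (15, 60),
) -> list[CoverageProfile]:
    """Deterministic single-peak trapezoid profiles for caller diagnostics.

    Each profile is a flat background with one trapezoidal bump (linear ramps,
    flat plateau) — an idealized isolated peak with no noise.  On such a
    profile the smoothed signal is unimodal, so the set of bases at or above
    any threshold is a single interval and the called peak count is a
    non-increasing step 1...1,0...0 as the threshold sweeps the grid.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_profiles):
        bg = int(rng.integers(*background_range))
        h = int(rng.integers(max(height_range[0], bg + 5), height_range[1] + 1))
        ramp = int(rng.integers(20, 80))
        plateau = int(rng.integers(100, 600))
        start = int(rng.integers(ramp + 10, length - (plateau + 2 * ramp) - 10))
        values = np.full(length, bg, dtype=np.int64)
        up = np.round(np.linspace(bg, h, ramp, endpoint=False)).astype(np.int64)
        down = np.round(np.linspace(h, bg, ramp, endpoint=False)).astype(np.int64)
        values[start : start + ramp] = up
        values[start + ramp : start + ramp + plateau] = h
        values[start + ramp + plateau : start + 2 * ramp + plateau] = down
        profiles.append(CoverageProfile.from_array(f"profile{i}", "chrSim", values))
    return profiles


def export_benchmark(
    benchmark: Benchmark,
    directory,
    caller_config: CallerConfig = BENCHMARK_CONFIG,
    n_thresholds: int = 20,
) -> Path:
    """Write a benchmark to disk in the standard formats; returns the directory.

    Layout: ``coverage/<sample>.bedGraph``, ``labels.txt`` (label dialect),
    ``truth/<sample>.bed`` (synthetic planted peaks), ``groups.tsv``, and a
    peak-call manifest ``manifest.tsv`` + ``peaks/`` produced by running the
    built-in caller over a threshold grid (default threshold = global mean
    coverage, flagged in the manifest).  Everything re-imports via
    :mod:`peakbench.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, profile in benchmark.coverage.items():
        write_coverage(profile, directory / "coverage" / f"{sid}.bedGraph")
    write_labels(benchmark.windows, directory / "labels.txt")
    write_groups(benchmark.groups, directory / "groups.tsv")
    for sid, calls in truth_calls(benchmark.truth).items():
        write_peaks(calls, directory / "truth" / f"{sid}.bed")
    call_set = build_call_set(
        benchmark.coverage, n_points=n_thresholds, config=caller_config
    )
    write_call_manifest(call_set, directory / "manifest.tsv")
    return directory
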