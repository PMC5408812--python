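"""A minimal built-in thresholding peak caller.

This provides a real single-parameter peak-calling family ``c_lambda`` so the
training and evaluation machinery can be exercised end to end without any
external peak-calling software.  It is deliberately simple: smooth the
coverage with a centered moving average, mark bases at or above the threshold
``lambda``, bridge short gaps, and drop short runs.  Low thresholds over-call
and high thresholds under-call, which is exactly the behaviour the supervised
calibration machinery is built to exploit.

The caller's "default" threshold is the global mean coverage — deliberately
naive, mimicking the tendency of default significance thresholds to over-call.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .io import ThresholdedCallSet
from .model import CoverageProfile, PeakCalls


@dataclass(frozen=True)
class CallerConfig:
    """Shape parameters of the thresholding caller.

    bandwidth
        width in bases of the centered moving average (1 = no smoothing).
    min_peak_width
        marked runs shorter than this are dropped.
    max_gap
        unmarked gaps of at most this many bases between runs are bridged.
    """

    bandwidth: int = 1
    min_peak_width: int = 1
    max_gap: int = 0

    def __post_init__(self):
        if self.bandwidth < 1:
            raise ValidationError("bandwidth must be a positive integer")
        if self.min_peak_width < 1:
            raise ValidationError("min_peak_width must be a positive integer")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be nonnegative")


#: identity-like config used where tests need analytic behaviour
DEFAULT_CONFIG = CallerConfig()

#: config used by the synthetic benchmarks (exercises smoothing)
BENCHMARK_CONFIG = CallerConfig(bandwidth=11, min_peak_width=1, max_gap=0)


def smooth(values: np.ndarray, bandwidth: int) -> np.ndarray:
    """Centered moving average of width ``bandwidth`` (zero-padded at edges)."""
    arr = np.asarray(values, dtype=np.float64)
    if bandwidth == 1:
        return arr
    return np.convolve(arr, np.full(bandwidth, 1.0 / bandwidth), mode="same")


def _mask_to_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def _postprocess_runs(
    starts: np.ndarray, ends: np.ndarray, config: CallerConfig
) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) and config.max_gap > 0:
        gap = starts[1:] - ends[:-1]
        keep = np.concatenate(([True], gap > config.max_gap))
        idx = np.flatnonzero(keep)
        starts = starts[idx]
        ends = ends[np.concatenate((idx[1:] - 1, [len(ends) - 1]))]
    if len(starts) and config.min_peak_width > 1:
        wide = (ends - starts) >= config.min_peak_width
        starts, ends = starts[wide], ends[wide]
    return starts, ends


def call_peaks(
    x: CoverageProfile,
    threshold: float,
    config: CallerConfig = DEFAULT_CONFIG,
    _smoothed: np.ndarray | None = None,
) -> PeakCalls:
    """Call peaks on one coverage profile at significance threshold ``threshold``.

    Bases whose smoothed coverage is >= threshold are marked; marked runs
    separated by <= max_gap unmarked bases are merged; runs shorter than
    min_peak_width are dropped.  ``_smoothed`` lets grid sweeps reuse one
    smoothing pass.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    smoothed = smooth(x.to_array(), config.bandwidth) if _smoothed is None else _smoothed
    starts, ends = _mask_to_runs(smoothed >= threshold)
    starts, ends = _postprocess_runs(starts, ends, config)
    return PeakCalls.from_arrays(x.sample_id, x.chrom, starts, ends)


def threshold_grid(
    x_set: Iterable[CoverageProfile],
    n_points: int,
    config: CallerConfig = DEFAULT_CONFIG,
) -> list[float]:
    """A linear grid of ``n_points`` thresholds spanning [0, max smoothed + 1].

    The extremes guarantee "everything called" (threshold 0) and "nothing
    called" (above the global smoothed maximum).
    """
    profiles = list(x_set)
    if not profiles:
        raise ValidationError("threshold_grid needs at least one coverage profile")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    top = max(float(smooth(p.to_array(), config.bandwidth).max()) for p in profiles)
    return [float(t) for t in np.linspace(0.0, top + 1.0, n_points)]


def default_threshold(x_set: Iterable[CoverageProfile]) -> float:
    """The naive default threshold: global mean coverage over all samples."""
    profiles = list(x_set)
    if not profiles:
        raise ValidationError("default_threshold needs at least one coverage profile")
    total = sum(p.total for p in profiles)
    bases = sum(p.b for p in profiles)
    return total / bases


def build_call_set(
    coverage: Mapping[str, CoverageProfile],
    n_points: int = 20,
    config: CallerConfig = BENCHMARK_CONFIG,
    algorithm: str = "threshold",
    include_default: bool = True,
) -> ThresholdedCallSet:
    """Run the caller over a threshold grid on every sample.

    When ``include_default`` is set, the naive default threshold (global mean
    coverage) is inserted as an extra grid point and flagged as the call set's
    default, so it can be evaluated exactly like any trained threshold.
    """
    profiles = [coverage[sid] for sid in sorted(coverage)]
    grid = threshold_grid(profiles, n_points, config)
    default = None
    if include_default:
        default = float(default_threshold(profiles))
        grid = sorted(set(grid) | {default})
    calls: dict[tuple[float, str], PeakCalls] = {}
    for sid in sorted(coverage):
        profile = coverage[sid]
        smoothed = smooth(profile.to_array(), config.bandwidth)
        for t in grid:
            calls[(float(t), sid)] = call_peaks(profile, t, config, _smoothed=smoothed)
    return ThresholdedCallSet(
        algorithm=algorithm,
        thresholds=tuple(grid),
        calls=calls,
        default_threshold=default,
    )
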