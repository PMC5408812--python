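# Methods

## The problem

Peak callers for ChIP-seq data are unsupervised: each assumes a noise model,
exposes a significance threshold λ and ships a default value for it. Because
the true noise process in real data is unknown, there is no statistical way to
verify those assumptions or to pick the threshold for a given dataset. What a
scientist *can* do reliably is look at coverage plots in a genome browser and
say "there is obviously a peak here" or "this is obviously background".
peakbench turns those judgments into supervision: labeled regions define an
error function for any set of peak calls, the error function defines a
training procedure (pick the threshold that minimizes it) and an evaluation
procedure (count violated labels on held-out regions).

## Label semantics and the error function

Four label types, each a genomic interval `[start, end)` (0-based, half-open,
as in BED), optionally restricted to named sample groups (e.g. cell types):

| type      | assertion                              | observed count k            | FP      | FN      |
|-----------|----------------------------------------|-----------------------------|---------|---------|
| noPeaks   | only background noise here             | peaks overlapping region    | k ≥ 1   | never   |
| peaks     | at least one peak overlaps (any size)  | peaks overlapping region    | never   | k = 0   |
| peakStart | exactly one peak start in the region   | starts in `[start, end)`    | k > 1   | k = 0   |
| peakEnd   | exactly one peak end in the region     | ends in `(start, end]`      | k > 1   | k = 0   |

The total error of a prediction y against a label set L is
`E(y, L) = FP + FN ∈ {0, …, |L|}`: each label contributes at most one error,
so FP and FN are capped at 1 per label per sample. A label applied to g
samples is scored once per sample and counts g times in |L|.

Decisions where the semantics were genuinely open:

* **Boundary inequalities.** A peak is `[p.start, p.end)`; its last covered
  base is `p.end − 1`. peakStart therefore counts starts with
  `start ≤ p.start < end` and peakEnd counts ends with `start < p.end ≤ end`,
  so a peak ending exactly at the region's end coordinate counts.
* **Spanning peaks.** A peak covering a whole peakStart/peakEnd region with
  no boundary inside counts k = 0 and is a false negative: the region demands
  a *visible* boundary, and a spanning peak shows none.
* **Overlap = one shared base.** Abutting intervals (`a.end == b.start`) do
  not overlap. Abutting predicted peaks are merged on construction — the
  binary vector y ∈ {0,1}^b cannot represent two abutting peaks, so "one
  peak" would otherwise be ill-defined for boundary counting.
* **peakStart with one in-region start plus another merely overlapping peak**
  is not a false positive: only in-region starts are counted.

Internally, peak calls are stored per chromosome as sorted start/end arrays
and all counts are computed with binary search (`searchsorted`), so scoring is
O(log n) per label. The test suite cross-checks this against an independent
base-resolution implementation that rasterizes calls to the binary vector and
counts rising/falling edges by scanning bases.

### Monotonicity under added peaks

Adding a *new* peak (disjoint from, and not abutting, the existing ones) can
never decrease FP and never increase FN: overlap counts and in-region boundary
counts only grow. The stronger statement "merging any interval into the calls
is monotone" is false, and the randomized suite demonstrates why: an interval
that merges two existing peaks into one can erase the visible boundary a
peakStart/peakEnd region demands (k: 1 → 0, a new FN) or merge two in-region
starts into one (FP 1 → 0). The property tests therefore draw disjoint added
peaks for the strong form and assert only the always-true weak form (noPeaks
FP non-decreasing, peaks FN non-increasing) for arbitrary merged additions.

## Training, evaluation, resampling

* **Training (grid search).** Every threshold on the grid is evaluated
  against the training labels; the minimizer λ̂ is returned together with the
  full error profile. Ties are broken toward the *largest* minimizing
  threshold: over-calling is the characteristic failure of default
  parameters, so among equally good thresholds the most conservative one is
  preferred.
* **Evaluation.** A threshold must be exactly on the grid — there is no
  interpolation between call sets. For this reason the naive default
  threshold λ~ is inserted as an extra grid point by `build_call_set` and by
  the exporter (and is a flagged row of the on-disk manifest), so the
  trained/default comparison uses the same code path.
* **Cross-validation resamples windows,** not labels or samples: each window
  was labeled as a unit, so labels within a window are not independent.
  Fold assignment is a seeded shuffle followed by round-robin (fold sizes
  differ by at most 1); aggregates report mean ± sample standard deviation
  (ddof = 1) of percent error over test folds.
* **ROC-like curves.** "ROC-like" has no canonical denominators here; the
  implemented reading (documented in every output header) is
  TPR = 1 − FN / #(peaks, peakStart, peakEnd labels) and
  FPR = FP / #(noPeaks, peakStart, peakEnd labels). "peaks" labels are
  excluded from the FPR denominator because they can never be false
  positives, which keeps FPR = 1 attainable.
* **Learning curves** use nested prefixes of seeded random orderings of the
  training windows, evaluated on a fixed test fold. Size 0 means "no labels
  at all" and is defined as the default threshold λ~ — the natural
  unsupervised baseline.

### Group resolution

The error function takes `calls_by_sample` plus labels that name sample
*groups*. An optional mapping `sample_id → group` resolves membership; a group
name equal to a sample id also matches directly, so single-sample datasets
need no mapping. A label with an empty group set applies to every scored
sample. A named group that matches no scored sample is an error (silently
scoring nothing would hide a misconfigured benchmark). The exporter persists
the mapping as `groups.tsv`.

## The built-in caller

A deliberately minimal thresholding family c_λ so the machinery is exercisable
without external software: smooth coverage with a centered moving average
(`bandwidth`, default 1 = no smoothing), mark bases with smoothed value ≥ λ,
bridge gaps ≤ `max_gap` (default 0), drop runs shorter than `min_peak_width`
(default 1). The benchmark configuration uses bandwidth 11 to exercise
smoothing. The threshold grid is linear on [0, global smoothed max + 1], so
its extremes call everything and nothing. The caller's default threshold is
the global mean coverage — intentionally naive, the kind of one-size-fits-all
default whose weaknesses supervised calibration is meant to expose.

**Peak-count monotonicity.** For this caller the *called base set* is nested
in λ when `max_gap = 0` (asserted on noisy profiles), but the *peak count* is
not monotone in general: at λ = 0 the whole profile is one peak, thresholds
near the background mean fragment it into many, and on noisy data thresholds
near the plateau mean fragment individual peaks. The count is exactly
non-increasing on unimodal profiles, where the super-threshold set is a single
interval for every λ. The diagnostic generator
`simulate_single_peak_profiles` produces deterministic single-peak trapezoid
profiles (flat background, linear ramps, one plateau) for precisely this
check; the count sequence over the grid is then 1…1, 0…0.

## The synthetic benchmark generator

`simulate_benchmark` emulates the structure of a visually labeled multi-sample
benchmark. Defaults (the study conditions used throughout the tests and the
acceptance script): 20 samples in 2 cell types, 8 windows of 10 kb, 2 planted
peaks per window, background mean μ0 = 5 and peak mean μ1 = 30 expected counts
per base, peak widths 200–2000 b, peak sharing probability 0.75, boundary-label
probability 0.5. Two presets mirror histone-mark shape classes: `sharp`
(widths 200–2000, H3K4me3-like) and `broad` (widths 5000–50000 in 200 kb
windows, H3K36me3-like). Preset parameters are chosen for testability — the
real benchmarks' signal-to-noise is not quantified anywhere usable — so they
are fixtures, not fidelity claims.

Design:

* **Noise is Poisson** (variance = mean), the simplest law producing
  nonnegative integer counts. Real ChIP-seq noise is overdispersed and
  structured (mappability, GC, input contamination); no claim of realism is
  made, and passing tests demonstrate correctness of the supervision
  machinery, not caller performance on real data.
* **Sharing structure.** Each planted peak is carried per cell type with the
  sharing probability (all samples of a carrying type have it; at least one
  carrier is forced so every window keeps a positive label). Labels are
  emitted per cell-type group; cell types lacking a peak get a noPeaks label
  over the same region, so the multi-group machinery is exercised.
* **Label geometry.** Peaks are separated by gaps wide enough that every
  label is unambiguous: boundary labels span `boundary ± m` with
  `m = max(5 b, 10% of peak width)`; the peaks/noPeaks label over a planted
  peak covers its interior inset by m (so it abuts, but never overlaps, the
  boundary labels); the per-window noPeaks label sits in a gap clear of all
  boundary-label extents. Infeasible geometry (too many/too wide peaks for
  the window) is rejected before any sampling.
* **Ground-truth contract.** By this construction the planted peaks attain
  label error exactly 0 for every seed — the generator's central invariant,
  tested over 20 seeds per preset.
* **Determinism.** One `numpy` Generator seeded from `config.seed` drives
  geometry first, then coverage in sorted sample order; identical configs give
  bit-identical benchmarks and exports.

## Numerical and format choices

* Coordinates are integers end to end; files round-trip bit-exact.
  Manifest thresholds are written with `repr()` and parsed with round-trip
  float precision so grid values survive export/import unchanged.
* Coverage is stored run-length encoded with adjacent equal runs merged, so
  equality is canonical; bedGraph output writes zero runs explicitly so the
  represented length b survives the round trip.
* Percent errors are printed to one decimal place in tables; exact values are
  recoverable from the integer FP/FN/|L| columns.
* Problem sizes in the test suite (e.g. 1000 random instances up to 1 kb for
  the oracle cross-check, 5 seeds of the default benchmark for recovery
  checks, 20 seeds per preset for the ground-truth contract) were chosen so
  the whole suite completes in about a minute on one core while still
  exercising every code path at the default study conditions.

## Limitations

* The built-in caller is a test vehicle, not a competitive peak detector; no
  input/control correction, fragment-model or multi-parameter search exists
  (multi-parameter grid search is combinatorially infeasible and deliberately
  out of scope).
* Only single-sample calling is supported; joint multi-sample callers would
  need a different call-set abstraction.
* Chromosome names must match exactly (no chr1/1 aliasing); strand is
  ignored (coverage is unstranded here).
* A label region may not span two windows.
* bigWig is not read; convert to bedGraph first.
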