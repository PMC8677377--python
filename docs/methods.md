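# Methods

This note records the model behind `movecompare`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions adopted where the design was genuinely open.

## Problem and model

Two univariate acceleration-magnitude series — an expert recording `v` and
a learner recording `u` of the same periodic movement, captured at the same
rate and in the same unit — are to be judged *similar* or *different*, with
the differences localized in time. The algorithm is entirely index-based:
the sampling rate is carried as metadata and checked for equality, but
never used in computation.

### Period by circular autocorrelation

For a series of length `n`, the profile `P_k = Pearson(v, rot(v, k))`,
`k = 1..n`, where `rot` is circular right-rotation, attains maxima at
rotations that realign whole cycles. Because rotation preserves mean and
variance, `P_k` equals the normalized circular autocorrelation of the
centered series, which the default implementation evaluates with one FFT
(`O(n log n)`); a literal per-shift implementation is kept and
cross-checked to 1e-10 in the tests. The profile is exactly symmetric
(`P_k = P_{n−k}`) and `P_n = 1`.

Maxima are local peaks with height ≥ 0.5 and separation ≥ 3 shifts
(`PeakParams`; both exposed). The period is taken from the **median**
spacing of consecutive maxima, so one spurious peak cannot shift it. Two
conventions coexist for the final number: the raw spacing (mathematically,
the period of the circular profile) and spacing − 1. The pipeline reports
and gates on **spacing − 1**, the convention under which a 125-shift
spacing corresponds to a reported 124-sample period; the raw spacing is
always surfaced alongside. The equality gate between two recordings is
strict integer equality — deliberately unforgiving, since a tempo
difference is a real movement error.

### Synchronization

The learner's first cycle is compared with the expert's first cycle under
all cyclic head-discards: `R_s = Pearson(v', advance(u', s))`,
`s = 0..p−1`, and the maximizing `s` (ties → smallest) is discarded from
the head of the full learner series. Indexing the profile by the
head-discard directly (rather than by a rotation amount whose complement
must then be discarded) makes "position of the maximum = samples to drop"
hold by construction. Only the learner is ever shifted. Both series are
then cut to start at the raw argmax of their first cycle (ties → earliest)
and truncated to the shorter length. A best correlation below 0.2 flags
the report `sync_low_confidence` but does not abort: a weak first-cycle
match can still yield a meaningful comparison window.

### Conditioning

Normalization is the affine map onto `[0, scale]` with `scale = 10000`;
it is what makes the verdict amplitude-invariant, and a constant series is
rejected (zero range). Smoothing is a 5-point moving average retaining
only full windows, so the output has `n − 4` samples (2989 → 2985, a
0.1338 % loss). Normalization runs **before** filtering: the pipeline
follows the executable ordering that produced the reference case-study
numbers rather than the block-diagram ordering, and the two differ only by
an affine factor anyway. User-overridden even windows get a warning
(phase asymmetry).

### Warping and verdict

The cost matrix is `C[j, i] = |u_j − v_i|` — absolute differences, since a
distance must be non-negative for a minimum search to be meaningful. The
default path extractor is the **greedy adjacent-side walker**: from
`(1, 1)` repeatedly step to the cheapest of the up-to-three forward
neighbors, ties preferring diagonal, then right, then up (determinism;
diagonal bias toward the ideal line); at the border the candidate set
shrinks, so termination at `(n, n)` is guaranteed. The classical
dynamic-programming recurrence over the same step set is provided as
`method="dp"`; it is a strict lower bound on the greedy cost (property
checked on 1000 random matrices, and against exhaustive path enumeration
up to 7×7). Greedy remains the default because it is the variant the
reference results were produced with; dp is the robust alternative.

Comparing whole recordings washes differences out — long paths regress
toward the ideal line regardless of shape — so the verdict is computed on
**one cycle window**: `k` uniform in `1..floor(L/p) − 1` (seeded; `k`
overridable), window `[k·p, k·p + p]` inclusive, i.e. `p + 1` samples,
1-based. With period 124 and `k = 3` this is samples 372–496. The path is
regressed by ordinary least squares (`j` on `i`, local window
coordinates); the verdict is *similar* iff periods are equal, `R² > 0.9`,
and `mean |(m·i + b) − i| < 10` over the path's i-coordinates. The
operational thresholds (rather than the idealized `diff = 0 ∧ R² = 1`) are
the applied rule and are both configurable.

Discrepancy localization is an extension of the same machinery: path
points whose local cost exceeds `band_fraction` (default 0.25) of the
joint value range of the two windows are projected to expert-sample
ranges and merged across gaps < 5 samples. `band_fraction` is a named,
documented knob, not a tuned constant.

## Synthetic generator

`SignalSpec` defaults emulate the recorded regime: 124 samples/cycle,
24 cycles (2976 samples), a gait-like waveform (one sharp Gaussian impact
peak at cycle phase 0.15, width 0.03; one broad hump at phase 0.55, width
0.15, half height — fixed constants chosen to exercise asymmetric cycles),
baseline 2, amplitude 1, additive Gaussian noise. Perturbations: integer
phase offset, amplitude scaling, a tempo factor rescaling the effective
cycle length, and a shape distortion replacing cycle phases 0.25–0.75 with
a blend toward their time-reverse scaled by `1 + 0.5·magnitude` —
mid-cycle divergence with intact cycle starts/ends. The 200-pair benchmark
(3 % noise) labels phase, amplitude and mild-noise pairs *similar* and
tempo/strong-distortion pairs *different*; the pipeline's agreement with
those labels (≥ 90 % required, ~97 % observed) is the package's
no-download end-to-end check.

What the generator does **not** emulate: biomechanical detail (ground
reaction transients, per-axis structure), cycle-to-cycle tempo jitter,
sensor drift or clipping, and non-Gaussian noise. Passing the synthetic
suite therefore demonstrates the algorithm's contract — invariances to
phase/amplitude, sensitivity to tempo/shape — not field performance on
arbitrary real recordings.

## Numerical conventions and edge cases

- 0-based indexing internally; all reported sample numbers are 1-based.
- Argmax/argmin ties always resolve to the smallest index.
- Constant series raise explicit degenerate-input errors at correlation,
  normalization and synchronization; fewer than two profile maxima raise
  an aperiodic-signal error.
- The correlation profile is clipped to `[−1, 1]` after the FFT route to
  absorb last-ulp excursions.
- CSV I/O: comma-separated, decimal point, one optional header row
  auto-detected by a non-numeric first row; floats written with 17
  significant digits and parsed in round-trip mode, so
  write → read → write is byte-identical.
- Unit conversion (1 g = 9.80665 m/s²) is explicit only; comparisons
  require identical declared units.

## Problem sizes

The test suite and `scripts/acceptance.py` use recordings of ~1200–3000
samples (10–24 cycles), 100-trial recovery experiments, a 200-pair
benchmark, 1000 random cost matrices, and exhaustive path enumeration up
to 7×7 — sizes at which every check is exact or tightly seeded while the
whole suite stays desk-scale.

## Known limitations

- The greedy walker is locally optimal only; on noisy windows it can hug
  an edge and depress `R²` for genuinely similar pairs (the few percent of
  benchmark disagreements are of this kind). The dp method avoids this but
  is not the default, for fidelity to the reference procedure.
- The single-cycle random window makes the verdict depend on the seed when
  a movement error is confined to some cycles; aggregate multi-window
  statistics are deliberately out of scope.
- The strict integer period gate treats a one-sample period difference as
  *different*; no tolerance is applied by design.
- Sub-sample phase alignment and resampling across different capture rates
  are not provided.
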