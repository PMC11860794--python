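# Methods

`fdmcma` implements a pipeline for single-lead ECG arrhythmia
classification built from three parts: an adaptive Fourier band
decomposition that yields a time–frequency (T-F) representation, 2DPCA
feature-image extraction from stacked data matrices, and a common-matrix
subspace classifier. This note records the model, its assumptions, the
numerical choices, and what the synthetic benchmark does and does not show.

## Signal model and normalization

Inputs are real, finite, 1-D sampled signals `s̄(n)`, `n = 0 … N−1`, with
sampling rate `fs > 0` Hz. Two geometries are supported end to end:
fixed-length beat segments (301 samples centered on an annotated R peak,
MIT-BIH-style at 360 Hz) and whole records (10 s at 500 Hz, 5000 samples,
Chapman-style). Before analysis every signal is normalized to

```
s(n) = (s̄(n) − mean(s̄)) / max_n |s̄(n)|
```

which removes offset and gain so recordings from different sources are
comparable; the denominator is the peak *magnitude* of the raw signal, so
the output is bounded by 2 in magnitude and the map is exactly scale-free
on mean-zero inputs. An identically zero signal has no defined
normalization and raises `DegenerateSignalError`.

## Fourier band decomposition

The DFT convention carries `1/N` in the forward transform,
`S(k) = (1/N) Σ_n s(n) e^{−j2πkn/N}`. The analytic signal is built from
the positive-frequency half: each bin `1 ≤ k < N/2` enters with weight 2
(standing in for its negative-frequency conjugate) and, for even `N`, the
Nyquist bin enters once with weight 1 — with that convention
`s(n) = S(0) + Re z(n)` holds to round-off for both parities, which the
test suite checks on random signals of both parities. (Published
treatments of this decomposition usually write out the odd-`N` case only;
the Nyquist-once rule is the natural even-`N` completion and is validated
by the reconstruction invariant rather than assumed.)

The positive half-spectrum is partitioned into contiguous bands by a
high-to-low scan. A candidate band `[n_prev − p, n_prev − 1]` is accepted
when its time-domain synthesis `v` has monotonically non-decreasing
instantaneous phase, tested without unwrapping via

```
ε(n) = Im( v(n+1) · conj(v(n)) ) ≥ −tol · max(1, ‖v‖∞²)
```

with circular wrap at the last sample and `tol = 1e−12`. The relative
slack absorbs exact-zero crossings from zero-coefficient bins; an all-zero
`v` passes. For each band the scan evaluates **every** width
`p = 1 … n_prev − 1` and keeps the largest passing width (a single complex
exponential always passes, so the scan cannot fail); the lower edge then
becomes the next scan's start, and the loop ends when it reaches bin 1.
Each step strictly lowers the edge, so at most `⌊N/2⌋` bands emerge. The
implementation shares the candidates' partial sums — a blocked cumulative
sum over bins with phasor rows built by accumulation — which is
algebraically identical to synthesizing each candidate by inverse FFT but
runs in `O(n_prev · N)` per scan; the tests compare it against a literal
one-inverse-DFT-per-candidate oracle.

Each band (AFIBF) `w_m` reports instantaneous amplitude `|w_m(n)|` and
instantaneous frequency `angle(w_m(n+1)·conj(w_m(n))) / 2π · fs`, clipped
to `[0, fs/2]`; where the band vanishes the phase is undefined and the IF
is reported as 0 with zero amplitude, so it cannot contaminate the T-F
map. Bands have disjoint DFT support, hence are exactly orthogonal, and
their real parts plus `S(0)` reconstruct the signal.

## Time–frequency map and data matrices

The T-F map is a 60 × N grid of 1 Hz-wide, half-open rows covering
[0, 60) Hz — ECG diagnostic content lives below 60 Hz, and the fixed row
count makes maps comparable across sampling rates. For every band and
sample with positive IA, `ia(n)` is accumulated into row `⌊ifreq(n)⌋`
(collisions sum, preserving energy additivity); IF values that are
integral up to round-off are snapped with a `1e−9` Hz guard before
flooring, so a tone at exactly 10 Hz fills row 10 rather than dithering
between rows 9 and 10. Cells no IF track visits stay exactly zero.
Finally the grid is divided by its maximum (no-op if all zero). Sampling
rates at or below 120 Hz are rejected: the map's top row would exceed
Nyquist.

The data matrix stacks, per variant:

| variant | rows | content                              |
|---------|------|--------------------------------------|
| D       | 62   | T-F map, spectrum row, signal row    |
| D1      | 60   | T-F map only                         |
| D2      | 61   | T-F map + signal row                 |
| D3      | 61   | T-F map + spectrum row               |

The spectrum row is `|S(k)| / max_k |S(k)|` over **all** N bins (both
symmetric halves — the row is defined as 1 × N); the signal row is the
normalized signal verbatim. Each block is normalized independently.

## 2DPCA feature images

Per class, the matrix-valued scatter of `R` data matrices is
`Φ = (1/R) Σ_k (D_k − D_a)ᵀ (D_k − D_a)` (divisor exactly `1/R`, not
`R−1`), an N × N symmetric PSD matrix. Its `d` leading eigenvectors form
the class's projection matrix `P`; features are `F = D·P`, a
(rows × d) image — no vectorization. `d` is a user parameter with
defaults 20 and 30; no automatic selection is attempted. Eigenvector sign
is fixed (largest-magnitude entry positive) so identical inputs give
bitwise-identical projections; degenerate eigenvalues are broken by the
eigensolver's order after a stable descending sort, which is harmless
because training and test share one consistently produced basis.

## Common-matrix classifier

For class `i` with feature images `X_1 … X_L`, the within-class
differences `Y_r = X_{r+1} − X_1` span the class's *difference subspace*.
They are orthonormalized under the trace inner product by modified
Gram–Schmidt with one re-orthogonalization pass; residuals below `1e−10`
times the largest input Frobenius norm are dropped as dependent (classical
GSO loses orthogonality at large L). Removing from any member its
projection onto this subspace leaves the class's *common matrix* — the
result is member-independent by an exact algebraic identity
(`X_j = X_1 + Y_{j−1}`, `Y_{j−1} ∈ span`), so it is computed once from
`X_1`. A class whose members are all identical is legal: empty basis,
common matrix equal to the shared image.

A test signal's data matrix is projected with **each class's own** `P^(i)`
(projections are class-specific, so the comparison must be too), reduced
to its common part against that class's subspace, and scored by
`W(i) = ‖T_com^(i) − X_com^(i)‖_F²`; the minimum wins, ties break to the
earliest class in training order. Training members score exactly zero
against their own class, so training-set classification is perfect
whenever class common matrices are pairwise distinct. `W` scores are
reported raw; they are not corrected for differing subspace dimensions
across classes.

## Metrics and cross-validation

From the confusion matrix, per-class one-vs-rest sensitivity,
specificity, positive predictive rate and F1 are reported in percent,
with overall accuracy the trace over the total. A zero denominator yields
NaN (e.g. Ppr for a never-predicted class), and NaN propagates into F1
and into macro averages — unweighted class means — rather than being
skipped. Monte-Carlo cross-validation redraws, per run, a per-class
training subset without replacement (a class smaller than its quota
contributes all of its samples), retrains, evaluates on a fixed held-out
set or on the run's remainder, and aggregates mean ± sd (population sd)
across runs; run `r` is seeded from `(master_seed, r)`.

## Synthetic data

Beats are sums of Gaussian bumps standing in for P/Q/R/S/T waves, with
per-beat ±10% amplitude jitter and additive white noise (default sd 0.02,
roughly 2% of the R amplitude — a clean-but-not-sterile recording).
The default beat library has six classes patterned on the AAMI-style
N/L/R/V/S/F grouping (widened QRS for the ventricular analogue, absent P
for the supraventricular one, and so on) at 360 Hz; the record library
has four rhythm classes differing in rate, regularity and P-wave presence
at 500 Hz. Records lay R peaks down at Normal(rr_mean, rr_sd) intervals
truncated positive, starting half an interval in. All generators are pure
functions of (spec, seed).

What this emulates: class-distinct morphology, RR variability, broadband
noise, and both pipeline geometries. What it does not: baseline wander,
powerline interference, electrode artefacts, within-patient drift, beat
class imbalance, or inter-patient distribution shift. Passing the
synthetic benchmark therefore demonstrates that the pipeline's mathematics
and code are correct and that well-separated classes are recovered almost
perfectly; it does not predict clinical-database performance.

## Benchmark scale and known limitations

The shipped benchmark uses four well-separated beat classes, 50 training
and 200 test beats per class (1000 beats total), `d = 20`, and 10 MCCV
runs — sized so the full suite runs comfortably on one CPU while still
exercising every stage at realistic dimensions (62 × 301 matrices,
301-point scans). Observed results: single-split overall accuracy
≥ 99.8%, MCCV mean OA ≈ 99.5–99.7% with sd ≈ 0.3–0.5%.

Known limitations:

- Decomposition cost grows roughly with the square of the record length;
  a 5000-sample record takes seconds, versus ~13 ms per 301-sample beat.
  Noisy signals decompose into more bands and scan slower.
- The classifier needs enough members per class for the difference
  subspace to span within-class variability. Whole-record rhythm classes
  with strong RR jitter are hard in the few-shot regime (a handful of
  records per class misclassifies noticeably); beat classes separate with
  tens of samples.
- R-peak detection and de-noising are out of scope: annotations are
  required inputs, and records are consumed as provided.
- WFDB input is available only when the optional `wfdb` package is
  installed; CSV is the first-class interchange format here.
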