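# Methods

## Estimators

Both estimators embed a length-N segment x(1..N) into template vectors
`X_i^m = (x(i), …, x(i+m−1))`, i = 1..N−m, and use the Chebyshev (maximum
coordinate) distance `d^m_ij`. The (m+1)-dimensional matrix shares the same
index range, so `d^{m+1}_ij = max(d^m_ij, |x(i+m) − x(j+m)|) ≥ d^m_ij`
entrywise. Self-matches (i = j) are excluded throughout.

**SampEn(m, r).** Φ^m is the mean over templates of the fraction of other
templates within `r·SD(x)` (population SD, divisor N — the convention in the
sample-entropy literature); the estimate is `ln(Φ^m / Φ^{m+1})`. When either
probability is zero the estimate is undefined; the package returns an
explicit marker (NaN value, `defined=False`, reason string) rather than
raising, so batch sweeps record NaN.

**NPSampEn(m).** The `scope` vector collects every unique value in the
pooled off-diagonal entries of both distance matrices (exact floating-point
uniqueness), sorted ascending; its length is `nbin`. The profiles
`Φ^m(q), Φ^{m+1}(q)` are the mean over templates of the row-wise empirical
CDF evaluated at `scope(q)`. Because every row contains the same number of
off-diagonal entries (N−m−1), that mean equals the pooled ECDF of all
off-diagonal entries, which is how the package computes it (sort +
`searchsorted`, O(N² log N) per segment); the test suite checks equality with
a literal per-row implementation at 1e−12. The estimate is the mean of
`ln(Φ^m(q)/Φ^{m+1}(q))` over scope bins.

*Zero-denominator bins.* The smallest pooled distance always lives in the
m-matrix (since d^{m+1} ≥ d^m), so the first scope bins can have
Φ^{m+1}(q) = 0. Such bins are excluded from both the sum and the divisor and
counted in `diagnostics["skipped_bins"]` — the minimal change that keeps the
estimator finite. At least one bin always survives (the largest scope value
has Φ^{m+1} = 1), so NPSampEn is defined for every admissible series.

*Properties.* Φ^m(q) ≥ Φ^{m+1}(q) pointwise implies NPSampEn ≥ 0. Scope and
distances co-scale under x → a·x + b, so NPSampEn is affine-invariant;
SampEn shares the invariance because r is SD-relative. Constant and strictly
periodic series (period ≤ m) give exactly 0 for both.

*Defaults.* m = 2 (field convention for RR series; configurable). SampEn
r = 0.2·SD for pipeline use and 0.25·SD in the simulation tolerance sweeps,
matching the usual 0.1–0.25·SD range.

## MIX(p) benchmark

`MIX(p)_j = (1−Z_j)·X_j + Z_j·Y_j`, j = 1..N, with X_j = 2·sin(2πj/12),
Z_j ~ Bernoulli(p) i.i.d., and Y_j i.i.d. uniform on [−3, 3] (the simplest
reading of "random variables within [−3, 3]", and the standard choice for
this process). Complexity rises with p. Sweeps draw a fresh realization per
(p, grid point, replicate) from a single seeded stream, default length grid
50..200 step 2 and tolerance grid 0.1..1.0 step 0.02 at N = 100; curves are
summarized by replicate means ± SE (replicate means are also what the
package's ordering checks use — single realizations are available by
`reps=1`).

A caution discovered while validating: SampEn of the *deterministic* MIX(0)
sine is a step function of r that is not monotone — it is exactly 0 at small
r (in a periodic signal every close m-match extends to a close (m+1)-match)
and steps up and down as r·SD crosses the few distinct template distances.
The monotone "larger r, smaller SampEn" behaviour is a property of noisy
signals; the package's tests assert it for the stochastic MIX curves
(replicate means, 2 SE slack) and assert the tolerance *inconsistency* —
realizations where SampEn orders MIX(0.3) above MIX(0.5) — on individual
realizations, where it actually occurs (roughly 40% of replicates at N = 100).

## Preprocessing

QRS detection follows the Pan-Tompkins stages: 5–15 Hz zero-phase band-pass,
derivative, squaring, 150 ms moving-window integration, adaptive signal/noise
thresholds (running-mean updates 0.125/0.875) with a 1.66·RR search-back at
half threshold, a 200 ms refractory period, and refinement of each detection
to the local band-passed extremum (±100 ms). Requires fs ≥ 100 Hz and ≥ 10 s
of signal; flat signals raise a detection error.

RR correction replaces any interval deviating from its centered 5-beat local
median by more than 20% of that median (both parameters configurable; the
method the source pipeline cites is external, and these are common
artifact-rejection defaults). Beat times are rebuilt by cumulative sum from
the first beat, so a replaced interval shifts subsequent beat times — the
interval sequence, not absolute time, is the analysis object.

Segmentation stamps each interval with its end-beat time and assigns minute k
the half-open window [60k, 60(k+1)) over the first six hours; minutes with
fewer than 30 intervals (well below the physiologic 60–100, hence likely
detector failure) are marked invalid and excluded downstream. Each valid
minute's tachogram (interval value vs. end time) is cubic-spline interpolated
onto the 0.5 s grid covering the minute — exactly 120 samples at 2 Hz — with
edge values held constant outside the first/last beat. A linear-interpolation
switch exists for sensitivity checks.

By default both entropies are computed on the same 120-sample resampled
segment the spectral stage uses (the framework resamples before both
analyses); `entropy_on_raw=True` computes them on the minute's raw beat
intervals instead, since either reading of the upstream pipeline is
defensible. Results should be reported per mode.

## Spectral indices

Sixty-second segments are too short for stable periodograms, so the PSD is
parametric: mean removal (optional linear detrend), AR(6) coefficients by
Burg's recursion (via `statsmodels`), PSD = σ²/(fs·|A(f)|²) evaluated on a
1024-point grid over [0, 1] Hz. LF = trapezoidal band power over
0.04–0.15 Hz, HF over 0.15–0.4 Hz. With RR in seconds, band powers are in s²;
LF/HF is unitless so the PSD normalization cancels, and absolute band-power
magnitudes are not a comparison surface.

## Screening and statistics

Per-recording features are means over valid minutes. AHI grades: normal < 5,
mild-moderate 5–30 (left-closed), severe ≥ 30; screening is normal vs.
apneic. Fisher's linear discriminant uses the pooled within-class covariance
and thresholds at the midpoint of the projected class means (equal priors —
balanced-cost screening; no priors are given for the original analysis), fit
and evaluated by resubstitution, which is how single-index discriminant
screening is conventionally reported; a NuSVC under stratified 2-fold CV with
pooled fold predictions is the alternative. ROC scores are sign-oriented from
training-set class means so the apneic class scores higher (entropy falls,
LF/HF rises with severity); AUC uses the trapezoidal/Mann–Whitney form with
ties counting ½. Group comparison: one-way ANOVA, then Fisher's LSD pairwise
t-tests on the pooled within-group MSE and df (the least conservative
post-hoc, by construction no more conservative than Bonferroni-adjusted
pairwise t). Association with severity: Pearson r with a two-sided t-test on
n−2 df.

## Synthetic cohort

The generator emulates the contrast the method exploits, not cardiac
physiology. Beats are produced iteratively; the interval ending at time t is

```
RR(t) = base + A_resp·sin(2π·0.25·t) + A_lf·sin(2π·0.10·t) + cycle(t) + ε
```

with per-subject base ~ N(0.9 s, 0.06 s), phases random, ε white with
group-specific SD, and `cycle(t)` a slow swing (period uniform 40–60 s per
subject) gated on/off in 2-minute epochs. The epoch activation probability is
tied to the recording's AHI, `min(0.03·AHI, 0.95)`, so mild-moderate
recordings spread between near-normal and near-severe regularity the way real
cohorts do. Frozen group parameters (seconds):

| group | resp amp | LF amp | noise SD | cycle amp | AHI range |
|-------|----------|--------|----------|-----------|-----------|
| N     | 0.040    | 0.020  | 0.045    | 0.040     | 0.5–4.5   |
| MOSA  | 0.025    | 0.025  | 0.020    | 0.085     | 6–28      |
| SOSA  | 0.015    | 0.030  | 0.015    | 0.100     | 32–80     |

Because NPSampEn is affine-invariant, what drives the entropy contrast is the
deterministic-to-noise amplitude ratio and the cycle prevalence, not the raw
noise level. The default cohort is 20/14/26 recordings of 6 h, mirroring the
normal / mild-moderate / severe composition of the public apnea ECG cohort
the pipeline targets. Effect sizes were calibrated once so the
group-ordering, ANOVA/LSD and >80%-accuracy screening checks pass with margin
across seeds, then frozen.

What the generator does **not** emulate: real QRS morphology and detector
failure modes, ectopy, sleep-stage structure, respiratory-rate drift,
non-stationary noise, and the entropy magnitudes of real RR series (synthetic
NPSampEn means run ≈ 0.39/0.31/0.21 by group — the ordering and separation,
not the absolute level, are the test surface). Passing the cohort tests shows
the pipeline recovers a known regularity contrast end to end; it does not
certify performance on clinical recordings.

## Problem sizes and numerics

The simulation checks use 20 replicates (length grid {50, 76, …, 200} for the
ordering sweep; tolerance grid 0.1–1.0 step 0.02 at N = 100), and the cohort
checks use the full default 60-recording, 6-hour cohort — sizes at which the
stochastic properties hold with comfortable margin and the whole suite runs
in a few minutes. Scope uniqueness is exact float equality; distance matrices
are materialized (segments are ≤ ~200 points, so O(N²) memory is trivial);
profile termination at exactly 1 is exact by construction (counts divided by
their own total). RR CSV files are written with 17-significant-digit floats
and read with round-trip parsing, so emitted fixtures reload bit-exactly.

## Known limitations

- NPSampEn costs O(N² log N) per segment with an O(N²) scope; fine at N ≤ 240,
  not intended for long segments.
- The Pan-Tompkins implementation targets clean single-lead recordings;
  heavily artifacted signals will need upstream cleaning the package does not
  provide.
- The screening layer assumes one feature table per cohort in memory;
  nothing is streamed.
- Real-data results depend on an external database and are intentionally
  outside the test surface; the pipeline supports them via the optional
  waveform-database reader.
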