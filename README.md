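# npsampen

Short-term heart-rate-variability (HRV) analysis with **nonparametric sample
entropy**, built for obstructive sleep apnea (OSA) screening from single-lead
overnight ECG.

## The problem

Minute-by-minute apnea annotation means HRV indices must work on ~1-minute RR
segments (60–100 beats). Classical sample entropy

```
SampEn(m, r) = ln( Φ^m / Φ^{m+1} )
```

counts template vectors of length *m* whose Chebyshev distance is within a
tolerance *r*·SD and asks how often those matches survive extension to length
*m*+1. On such short segments SampEn is fragile: a poor *r* leaves zero
matches (the estimate is undefined) or inverts the complexity ordering of
signals.

**NPSampEn** removes the tolerance. Let `scope` be the ascending vector of
all unique template distances pooled from the *m*- and (*m*+1)-dimensional
distance matrices (`nbin` values, self-matches excluded). Evaluating the two
cumulative match-probability profiles on that grid and averaging gives

```
NPSampEn = (1 / nbin) · Σ_q  ln( Φ^m(q) / Φ^{m+1}(q) )
```

The tolerance set adapts to each individual's signal, so the estimator is
always defined, affine-invariant, and far less length-sensitive — which is
what a per-minute, per-patient screening index needs.

The package also provides everything around the estimator:

- `npsampen.mix` — the MIX(p) benchmark process (a 12-sample sine with each
  point replaced by uniform(−3, 3) noise with probability p) plus length and
  tolerance sweeps;
- `npsampen.preprocess` — Pan-Tompkins QRS detection, local-median RR
  correction, nonoverlapping 1-min segmentation over the first six hours,
  cubic-spline resampling to 2 Hz (120 samples per segment);
- `npsampen.spectral` — order-6 Burg autoregressive PSD with LF (0.04–0.15 Hz),
  HF (0.15–0.4 Hz) and LF/HF indices;
- `npsampen.screening` — AHI severity grading (<5 normal, 5–30 mild-moderate,
  ≥30 severe), Fisher's linear discriminant and 2-fold-CV SVM screening,
  ROC/AUC, Pearson correlation with AHI, one-way ANOVA with LSD post-hoc;
- `npsampen.cohort` — a seeded synthetic ECG/RR cohort generator so the whole
  pipeline is testable without any data download.

## Worked example

```python
import numpy as np
from npsampen import MIXParams, generate_mix, npsampen, sampen

sig = generate_mix(MIXParams(p=0.3, n=100, seed=7))   # 30% noise, 70% sine
np_res = npsampen(sig.values, m=2)
se_res = sampen(sig.values, m=2, r=0.2)
print("NPSampEn :", round(np_res.value, 4), np_res.diagnostics)
print("SampEn   :", round(se_res.value, 4))
```

prints

```
NPSampEn : 0.4925 {'nbin': 1859, 'skipped_bins': 1}
SampEn   : 1.0162
```

NPSampEn averaged the log-ratio of the two match profiles over 1859
data-derived tolerances (one bin skipped because no (m+1)-template pair was
that close); SampEn used the single tolerance 0.2·SD. For MIX(p) signals the
NPSampEn values increase monotonically in p at every length 50–200 with no
curve crossings, while SampEn curves for MIX(0.3) and MIX(0.5) cross at small
N and at some tolerances invert their ordering — the failure mode the
nonparametric estimator removes.

The same analysis from the shell:

```
npsampen simulate --p 0.3 --n 100 --seed 7 --out sig.csv
npsampen entropy --method npsampen --input sig.csv
npsampen sweep --mode length --p 0,0.3,0.5 --reps 20 --out sweep.csv
npsampen fixtures --out-dir cohort/            # synthetic 20/14/26 cohort
npsampen pipeline --rr cohort/x000.csv --out features.csv
npsampen screen --features features.csv --labels cohort/ahi.csv --out report.json
```

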