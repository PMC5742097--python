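# Methods

This document records the analysis model, the parameter defaults (all in
`cinemetrics.Config` / `cinemetrics.SimConfig`), and the numerical and design
choices behind them.

## EEG preprocessing (`eeg_preprocess`)

Continuous recordings (matrix CSV with a JSON sidecar, EDF, or BDF via mne)
are conditioned in this order:

1. **Resample to 256 Hz** with polyphase FIR resampling
   (`scipy.signal.resample_poly`), which includes the anti-alias low-pass.
   Upsampling is refused: an input below the target rate has no content above
   its own Nyquist and resampling it up would only interpolate.
2. **High-pass** 1.5 Hz, 4th-order Butterworth, applied zero-phase
   (`sosfiltfilt`) so that power latencies are not shifted.
3. **Notch** filters at 50 and 100 Hz (`iirnotch`, Q = 30), zero-phase.
4. **Average reference** (subtract the channel mean per sample; needs ≥ 2
   channels).

Zero-phase IIR filtering needs explicit edge padding: the defaults (a few
samples) are far shorter than the ~0.3 s settling time of a 1.5 Hz high-pass
or a Q = 30 notch, so the padding is set to about three filter time constants.
Even so the pipeline is only approximately idempotent — an IIR notch passband
is not perfectly flat (|H| deviates from 1 by ~6·10⁻⁵ at 10 Hz), which bounds
how closely a second pass can reproduce the first.

Epochs are cut per trailer from event markers (`start:<id>` / `end:<id>`) with
±2000 ms padding; the mean of the [−2000, 0) ms baseline is subtracted per
channel.

## Spectrotemporal decomposition (`spectrotemporal`)

Power is computed with complex Morlet wavelets (`mne.time_frequency.
tfr_array_morlet`, 7 cycles) on a 1–80 Hz grid in 0.5 Hz steps (159 bins),
then averaged over non-overlapping 125 ms bins, i.e. an 8 Hz power series.
Epochs shorter than the support of the slowest wavelet are rejected. Band
power averages all grid frequencies inside the closed interval
`[f_lo, f_hi]`. The analysis bands are beta sub-bands {14–16, 16–18, 18–20 Hz}
and gamma sub-bands {40–48, 52–60, 60–70, 52–70 Hz}; 48–52 Hz is excluded
around the 50 Hz mains notch. `band_power_epoch` is a fast path that places
wavelets only on the in-band frequencies; it is verified equal to slicing the
full grid.

## Cognitive-congruency (`cognitive_congruency`)

For each subject s and viewing v, let X_sv be the row-centered D×T band-power
matrix. With

    R11 = (1/(S·T)) Σ_s X_s1 X_s1ᵀ      (and R22 analogously)
    R12 = (1/(S·T)) Σ_s ½(X_s1 X_s2ᵀ + X_s2 X_s1ᵀ)

the metric is the largest generalized eigenvalue λ of

    R12 w = λ (R11 + R22 + γI) w ,

with shrinkage γ = 10⁻⁶ · trace(R11 + R22)/D by default (γ = 0 is allowed
when the denominator is positive definite). By Cauchy–Schwarz, |λ| ≤ 0.5,
and λ = 0.5 exactly when both viewings are identical. The forward model
(scalp pattern) is a = R̄w / (wᵀR̄w) with R̄ = (R11 + R22)/2, returned
unit-normalized because only its direction is identifiable.

Note that band **power** is quadratic in channel amplitudes: if a source with
mixing vector m drives the channels, the congruent pattern in power space is
proportional to m², not m. Topography-recovery checks therefore compare
against the squared mixing vector, ignoring sign.

## Attentional-asynchrony (`gaze_asynchrony`)

Gaze traces (60 Hz, screen 1024×768 px) for one trailer are cut into 250 ms
windows (15 samples) hopped by 50 ms (3 samples; 80% overlap); a 600-sample
trace yields ⌊(600−15)/3⌋+1 = 196 windows. A trace enters a window if at
least 50% of its samples are valid; a window needs ≥ 2 usable traces, else it
is *unclassifiable*. The observed statistic is the pooled set of pairwise
Euclidean distances between time-matched valid samples (C(P,2)·15 distances
for a full window of P traces).

The null distribution shuffles the **window order within each trace**
(preserving within-window structure and each viewer's position marginal),
pools all pairwise distances over `n_draws` = 1000 draws (subsampled to at
most 2·10⁶ values), and takes the 5th/95th percentiles. A window is labelled
*divergent* when at least 30% of its observed distances fall **inside**
[q05, q95] — under strong synchrony the observed distances collapse far below
the null interval, so falling inside the null band is the signature of
uncoordinated (divergent) gaze. The complementary "outside" reading is
available via `Config(divergence_rule="outside")`. A degenerate null
(q05 = q95) forces *non-divergent*. The score is
divergent / classifiable windows; limits: i.i.d.-uniform gaze → ~1, perfectly
synchronized gaze → ~0.

## Behavior, KPI and outlier rule (`behavioral_kpi`)

LM is the mean liking (0–10) per trailer; WTW and WTR are the yes-fractions
of the willingness-to-watch and willingness-to-refer questions, pooled over
participants and both viewings. The KPI is weekend revenue divided by
production budget. The packaged study table (15 movies × premiere + 8
weekends) ships as CSV. A movie is excluded as an outlier when its premiere
KPI lies ≥ 4 leave-one-out standard deviations **above** the mean of the
remaining movies (one-sided; sample sd, ddof = 1). On the packaged table this
flags exactly the first movie, at z = 4.383.

## Regression harness (`prediction`)

OLS with intercept (statsmodels); F, adjusted R² and the p-value are derived
from the R² identities

    F = (R²/k) / ((1−R²)/(n−k−1)),   adjR² = 1 − (1−R²)(n−1)/(n−k−1).

A perfect fit (R² = 1) reports F = ∞, p = 0. The standard error of R² is a
case-resampling bootstrap (B = 2000 by default; degenerate resamples with a
constant column are redrawn and logged). Within each model row, p-values are
Benjamini–Hochberg adjusted across the nine outcomes (premiere + 8 weekends).
The default sweep has seven models: two asynchrony versions, four gamma-band
congruency models, and a bivariate asynchrony + congruency model. Rows
flagged by the outlier rule are excluded throughout.

## Synthetic data (`synthetic_data`)

All generators are seeded; randomness flows from one mandatory seed through
named substreams (`SeedSequence` keyed by a CRC32 of the stream name), so the
EEG, gaze and KPI generators are independently reproducible.

* **EEG**: each trailer has *one* band-limited source time course (a slow
  ~0.4 Hz positive envelope times a 52–70 Hz band-limited carrier), identical
  in both viewings of every subject, mixed through a fixed unit-norm random
  topography and scaled by a per-trailer SNR; channel noise is band-limited
  and independent per viewing. λ therefore grows with SNR, and holding the
  seed fixed across an SNR grid (common random numbers — SNR enters only as a
  scale factor) makes λ(SNR) monotone per seed.
* **Gaze**: each trailer has a smooth attractor path; a trace is
  ρ·attractor + (1−ρ)·independent smooth wander + 5 px jitter, clipped to the
  screen, with a 2% invalid-sample rate. The default ρ grid spans 0.5–1.0:
  the divergence rule reacts in the strong-synchrony regime, so this range
  produces variation in the score across trailers.
* **Behavior/KPI**: premiere = 0.4 + 0.5·metric + N(0, 0.05), clipped at 0;
  weekends decay geometrically (factor 0.45) with multiplicative log-normal
  noise; liking is drawn around a per-trailer base level (correlated across
  participants) and yes/no answers follow a logistic link on liking.

The generators emulate the *statistical structure* the metrics assume, not
biophysics: no realistic EEG forward model, no saccade dynamics, no market
model for revenues. Default sizes (8 subjects, 6 trailers, 30 s, 8 channels)
are the package's own desk-scale choice so the full pipeline runs in seconds
on one CPU.

## Numerical choices

* Generalized eigenproblem via `scipy.linalg.eigh(R12, R11+R22+γI)` after a
  Cholesky positive-definiteness check (failure suggests adding shrinkage).
* Window segmentation via `sliding_window_view`; the permutation null and the
  bootstrap slope CI are fully vectorized.
* Percentiles use NumPy's default linear interpolation.
* Deterministic tests: all stochastic tests fix seeds; hypothesis runs
  derandomized with 25 examples.
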