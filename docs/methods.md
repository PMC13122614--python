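# Methods

## Signal model and simulator

A continuous-wave radar observing an insect at close range yields, after
I/Q demodulation, a complex baseband series modeled as additive noise +
body-motion Doppler + wingbeat micro-Doppler.  The simulator realizes each
term explicitly:

* **Wingbeat** — a sum of `N` complex harmonics of the fundamental `f_w`
  with per-harmonic amplitude `A_n` and phase `φ_n`.  Optional slow
  frequency jitter (default relative SD 0.003) is applied as a
  piecewise-constant instantaneous fundamental over 0.25 s frames with a
  continuous phase, which broadens the harmonic lines as real wingbeats
  do.  Generation refuses configurations whose top harmonic (with a
  3-sigma jitter allowance) reaches Nyquist.
* **Body motion** — low-pass filtered circularly symmetric Gaussian noise
  (4th-order Butterworth, forward-backward) scaled to a target RMS.  Only
  its spectral confinement below the 50 Hz high-pass cutoff matters
  downstream, so no attempt is made to model specific flight kinematics.
* **Noise** — circularly symmetric white Gaussian, with power set by the
  wingbeat-to-noise ratio `snr_db` relative to `Σ A_n²`.  Real captures
  additionally contain multipath clutter and gain drift; see
  "Limitations".

Recordings are 60 s at 1 kHz with inclusive endpoints (60,001 samples).
Wingbeat and body motion are present only inside scheduled flight bouts.
Each subject draws `f_w` once from the species distribution (clipped at
2.5 SD so the aliasing invariant stays satisfiable) and a multiplicative
perturbation of the harmonic envelope (SD 0.08), so subject identity is a
real nuisance factor for the grouped split to control.

### Default species profiles

| species | f_w mean (Hz) | SD | envelope | SNR (dB) |
|---|---|---|---|---|
| *Bombus terrestris* | 120 | 4 | 1.0, 0.55, 0.28 | 15 |
| *Bombus lapidarius* | 160 | 4 | 1.0, 0.40 | 15 |
| *Bombus muscorum* | 200 | 4 | 1.0, 0.65 | 15 |
| *Apis mellifera* | 240 | 4 | 1.0 | 15 |
| *Vespula vulgaris* | 300 | 4 | 1.0 | 15 |

Fundamentals are well separated and every species keeps `N·f_w` below the
500 Hz Nyquist limit, which is why higher-fundamental species carry fewer
harmonics.  Body motion defaults: RMS 1.0, bandwidth 12 Hz.  Bout
schedules are drawn per recording (3–5 bouts of 3–6 s) unless specified.

## Preprocessing

Per-recording normalization (complex mean removal, unit RMS) precedes a
second-order Chebyshev type-I high-pass at 50 Hz (1 dB passband ripple).
The filter is applied forward-backward by default: zero phase preserves
the harmonic phase relations used by cepstral features, at the cost of
squaring the magnitude response (the ripple band doubles in dB); a
forward-only mode is available.  The same real-coefficient filter acts on
the I and Q channels independently.  Frames are 2 s Hann windows with 1 s
overlap (periodic Hann, so 50%-overlapped frames satisfy constant
overlap-add).

## Detection

The harmonic ratio of a real frame is
`η_HR = clamp(max_{k∈[K0,K]} Ψ(k), 0, 1)` with
`Ψ(k) = Σ x[n]x[n+k] / sqrt(Σ x[n]² · Σ x[n+k]²)` (per-lag energy
normalization, sums over the overlapping part), `K = round(0.04·Fs)` and
`K0` the first lag with `Ψ(k−1)Ψ(k) ≤ 0` (fallback lag 1 when no crossing
occurs — the frame is kept rather than discarded).  The statistic is
computed on the real part of the filtered signal by default (imaginary
part and magnitude are selectable); it is scale-free by construction.
Frames with `η_HR > 0.4` become micro-Doppler segments; the stored
segment samples are the un-tapered frame so feature spectra are not
colored by the detection window.  Under the synthetic null (white noise,
2 s frames) the 95th percentile of `η_HR` is below 0.3, so the 0.4
threshold is conservative.

Re-segmentation at shorter windows (1 down to 0.1 s, 50% overlap) has two
modes.  `independent` scans every duration over the whole recording and
is how per-duration segment inventories are counted.  `exclusive` scans
longest-first and lets each region of signal contribute only at the
longest duration for which it qualifies; on bout-structured recordings
this assigns nearly all flight to the longest window, so the duration
sweep uses independent scanning (with an even-subsampling cap per
recording, default 40–50 segments, purely to bound problem size).

## Features (70 per segment)

* **MFCC block (42)** — 15 half-overlapped sub-frames of length L/8,
  Hann-tapered, power spectra on a ≥256-point FFT, 26 triangular mel
  bands over 0–500 Hz, log, orthonormal DCT-II, first 14 coefficients.
  Deltas are least-squares slopes over ±2 sub-frames (edge-padded);
  delta-deltas are deltas of deltas; each is aggregated by the mean over
  sub-frames.  The relative sub-frame length keeps the delta features
  defined from 2 s down to 0.1 s segments.
* **Fundamental frequency (3)** — search band 50–400 Hz.
  `PEF_F0`: a comb filter bank on a zero-padded periodogram; candidates
  scored by the *mean* power at their harmonics (mean, not sum, so low
  candidates gain nothing from extra noise bins), validated by requiring
  ≥15% of total power within ±2 Hz of the harmonics.
  `WT_F0`: Morlet CWT over 80 log-spaced scales; ridge = scale of maximal
  mean squared coefficient, parabolic interpolation in log-frequency;
  valid when the ridge exceeds 3× the median scale power.  The
  transform's built-in scale weighting leaves unit-tone ridge heights
  flat across the band (verified on pure tones), so no further
  normalization is applied.
  `NCF_F0`: first convincing autocorrelation peak seeds the period, then
  the peak at progressively doubled period multiples (parabolic
  interpolation each step) refines it — at 1 kHz a 300 Hz wingbeat spans
  only ~3.3 samples, and locking onto the m-th multiple divides the lag
  quantization error by m.  Estimators returning no valid value (noise
  segments) are imputed with the NCF estimate, then with the 50 Hz search
  floor.  On clean 2 s segments all three agree within 5 Hz and recover
  `f_w` with sub-Hz median error.
* **HarmonicRatio (1)** — copied from the detection statistic.
* **Band powers (9)** — periodogram power fractions in 50 Hz bins over
  50–500 Hz; amplitude-invariant, sum ≤ 1.
* **Spectral/temporal descriptors (15)** — centroid, spread, skewness,
  kurtosis, flatness, entropy, crest, 95% rolloff, slope, decrease, flux,
  peak frequency, RMS energy, zero-crossing rate, temporal crest factor.
  Moments use the Welch PSD (sub-frame averaging keeps white-noise
  flatness near 1, which a raw periodogram would not).

The registry is configuration-driven; its validator enforces the expected
total (70 by default) and unique names, so a re-specified feature table
fails loudly if it changes dimensionality silently.

## Classification

Stages are trained on true labels: stage 1 (family) on all rows, stage 2
(genus) on Apidae rows, stage 3 (species) on *Bombus* rows.  Stages 1–2
are gradient-boosted tree ensembles (300 trees, depth 6, learning rate
0.1); stage 3 is an extremely-randomized-trees ensemble (300 trees) —
randomized splits average away variance where class separability is
subtle.  Class weights `total/(n_classes·count)` (sample-weighted mean
exactly 1) are applied as sample weights; over/undersampling is available
behind a flag but off by default.  All estimators are seeded; ties in
stage probabilities resolve by the library's fixed class order
(alphabetical, i.e. taxonomy order).

The subject-grouped split assigns whole subjects per species to the test
side greedily while the realized sample fraction approaches the 20%
target (exact 80/20 is generally unattainable under grouping); a species
with a single subject goes to train with a warning.  Evaluation reports
per-class precision/recall/F1, cumulative confusion matrices at species,
genus and family granularity (labels finalized early are carried forward
by mapping up the taxonomy), and accuracy = trace/total, which equals
micro-averaged F1 in this single-label setting.

The duration sweep detects, extracts, splits (one subject partition,
computed at the longest duration and reused so accuracies are paired),
fits and evaluates per duration.  On the default cohort (5 species ×
4 subjects, 60 s recordings) species accuracy is 1.00 at 2 s and ~0.96 at
0.1 s — shorter segments lose frequency resolution, reproducing the
expected degradation direction.

## Attribution

Attributions use the interventional value function: a coalition's value
is the mean model output with in-coalition features from the explained
row and the rest from background rows.  `exact_shapley` enumerates all
coalitions (≤ 12 features — 4096 coalitions — as a combinatorial guard)
and is the oracle.  `tree_attributions` computes the same quantity in
closed form: restricted to one leaf and one background row, the tree's
value function is an indicator requiring features satisfied only by the
instance to be in the coalition (set `A`) and features satisfied only by
the background to be out (set `B`); the Shapley value of such an
indicator game is `±v·a!·(m−a)!/m!`-type closed-form weights
(`a = |A|`, `m = |A|+|B|`), summed over leaves, trees and background
rows.  No sampling is involved; agreement with the oracle is exact to
float round-off.  Gradient-boosted stages are explained on the raw margin
(log-odds); forest stages on class probabilities.  The cascade is not a
single model, so a row's species-level attribution is taken from the
stage that finalized its label, with a seeded background of at most 100
training rows.

## Problem sizes

The test suite and acceptance script use: a 20-recording cohort (60 s
each), a 200-segment F0-recovery cohort, 1000-draw detection null, 100
random frames for the autocorrelation oracle and 20 instances for the
Shapley oracle, and a two-point duration sweep (2 s, 0.1 s) capped at 40
segments per recording per duration.  These sizes give stable statistics
while keeping a full run around a minute.

## Limitations

* The simulator's noise is white and Gaussian; real captures contain
  multipath clutter, gain drift and container-wall reflections.  Passing
  tests demonstrate the pipeline's correctness and its behaviour under
  the stated model, not field-level accuracy: the synthetic species are
  deliberately well separated, so end-to-end accuracies here are upper
  bounds on what overlapping real wingbeat distributions allow.
* The published 70-feature inventory is not fully enumerated in public
  text; the default registry reconstructs every named feature and pads
  with standard descriptors to the documented total, and is re-specifiable.
* The NCF refinement degrades near the top of the search band
  (> ~350 Hz) where the fundamental period approaches 2–3 samples.
* Only binary gradient-boosting stages are supported by the closed-form
  tree attributions (the cascade needs no more).
* The harmonic-ratio threshold (0.4) and the complex-to-real reduction
  (real part) are exposed as configuration; alternative choices shift
  detection counts but not the pipeline's structure.
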