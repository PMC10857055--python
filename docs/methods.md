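# Methods

This note documents the models, numerical choices and limitations behind
`triad`. It is written for someone validating a chest-worn multimodal
infant wearable (ECG + IMU + audio) against gold-standard equipment and
wanting to know exactly what each pipeline computes and what the synthetic
experiments do and do not show.

## Recording model and codec

A device session is a set of timestamped chunks per modality: ECG at
2426 Hz and IMU at a nominal 70 Hz in 30 s chunks, audio at 22 050 Hz in
10 s chunks. Chunk start/end stamps come from a battery-backed real-time
clock in UTC milliseconds; all cross-modal alignment uses these stamps and
never sample arithmetic, because the modalities are written asynchronously
at different rates.

The binary dialect (magic `LBK1`) is a declared convention, not a
reverse-engineering claim: per chunk, a modality tag, two uint64 UTC
stamps, a uint32 sample count, an integer payload (uint16 ADC counts for
ECG; int16 × 9 for IMU with per-LSB scales 0.01 m/s², 0.1 deg/s,
0.001 a.u.; int32 holding 24-bit audio), and a run-length-encoded
missing-sample mask. Padding is stored as literal zeros *plus* the mask so
a padded zero remains distinguishable from a true zero downstream.
Round-trips are bit-exact for values on the payload grids; `codec.quantize`
puts arbitrary floats on-grid.

Missing data are modelled where they arise physically: slow SD-card writes
drop samples in bursts at chunk tails. `missing_fraction` is defined
against the expectation implied by the UTC span × nominal rate, so a chunk
that simply contains fewer samples (firmware loss) and a chunk padded with
masked zeros (post-sync) give the same answer.

Real-time-clock drift (1–3 s per 11–12 h) is deliberately **not**
corrected during synchronization: the three modalities share the same
clock, so the drift does not affect their mutual alignment. It is only
emulated by the generator so downstream code can be shown insensitive to
it.

## Interbeat intervals

R peaks are found with a Pan–Tompkins-style chain: 5–20 Hz band-pass
(2nd-order Butterworth, zero-phase), derivative, squaring, 150 ms moving
integration, adaptive threshold with a 200 ms refractory period. The
threshold anchors at the median of the strongest coarse peaks (assuming at
least one beat per 2 s); anchoring at the median of *all* integrator peaks
is unstable because most of them are noise. Fiducials are refined to the
band-passed maximum within ±100 ms and quantized to a 4 ms grid — the
250 Hz tick of the IBI files consumed by downstream HRV software; the
"250 Hz" is a quantization of beat times, not a resampling of the ECG.

Artifact editing uses the standard HRV moves with two implementation
decisions that matter:

1. **Edits never move clean beats.** Divide inserts equally spaced beats
   inside a long interval; combine removes the intermediate beat;
   interpolation replaces a value in place. Rebuilding the time base from
   a cumulative sum of edited values would shift every later beat and
   corrupt session alignment.
2. **Gap repair uses a smooth heart-period estimate.** Intervals
   overlapping zero-padded stretches (plus a 0.3 s guard, because beats
   detected right at a padding edge are unreliable) are refilled from a
   cubic spline through the clean intervals. A flat local average would
   miss the respiratory modulation across the gap; the spline tracks it.

Outliers are intervals outside physiological bounds (adult 300–2000 ms,
infant 250–1000 ms, configurable) or deviating more than 25 % from the
local median. The local median uses 5 neighbours *per side*: a 5-beat
total window spans roughly one respiratory cycle at typical rates, which
anti-correlates the reference with genuine modulation peaks and causes
false edits; the wider window averages the modulation out. Divide/combine
matching tolerance is 12.5 %. A series needing edits on more than 20 % of
intervals is marked unusable (the threshold is configurable; studies
typically exclude recordings above a few percent). Editing is idempotent.

## Respiratory sinus arrhythmia

RSA follows the Porges–Bohrer recipe: step-interpolate heart period onto a
uniform grid (0.5 s adult / 0.25 s infant, keeping each band's upper edge
below Nyquist); subtract a centered 21-point moving cubic least-squares
smoother (implemented as a Savitzky–Golay filter with polynomial edge
handling — mathematically the same local-polynomial smoother); band-pass
with a 127-tap Hamming FIR applied forward–backward (zero phase); then
ln(variance) per non-overlapping 30 s epoch, averaged to the task mean.
Trailing partial epochs are dropped; an epoch with numerically zero
variance (constant heart period) has no defined log and is excluded with a
warning.

The closed-form anchor: a sinusoidal modulation of amplitude A ms inside
the band has variance A²/2, so RSA = ln(A²/2) (8.52 for A = 100). The
implementation lands within ~0.08 ln-units; the residue is harmonic
distortion of the step interpolation and finite filter pass-band ripple,
both of which raise the variance slightly.

`rsa_contrast` runs one-tailed paired t tests on subject-level task-mean
differences in a hypothesized direction (e.g. RSA withdrawal from baseline
into a challenge task, recovery afterwards).

## Activity recognition

Gravity is removed by subtracting 9.8 m/s² (sign-matched) from the axis
with the largest 0.25 Hz low-pass mean — valid while orientation is
quasi-static per window. The IMU's dynamic rate (70 ± 5 Hz) is corrected
per non-overlapping 30 s interval onto exactly 2100 samples. The sample
count decides the direction (up/down), but the mapping itself is linear
interpolation at the recorded timestamps: a purely index-based mapping
accumulates the timing jitter into a growing phase error and cannot keep
a 1 Hz signal within 1 % RMS, which timestamp interpolation achieves
easily.

Windows are 5 s (350 samples × 3 axes); windows spanning an activity
transition are excluded. Features are the raw flattened window samples,
z-normalized with statistics fitted on the training portion only (the
leakage-safe choice). The classifier is a 100-tree random forest with
entropy splits. Evaluation uses ten repeated stratified 80/20 splits with
the test folds pooled into one confusion matrix — the reading that
reconciles an "80/20 split" with "10-fold" pooling of ten test sets. F1
is reported class-frequency weighted. Chair rotation is detected from the
gyroscope alone: a window whose single-axis cumulative integral reaches
300° (below the nominal 360° to tolerate integration leakage) is a
rotation.

## Audio

Downsampling 22.05 → 16 kHz is polyphase (`scipy.signal.resample_poly`).
Declipping treats a *flat plateau* at or above 70 % of full scale as
clipped — flatness is the signature of hard clipping — and restores each
run with a cubic spline through 4 flanking unclipped samples per side,
spread over a span comparable to the run so the spline sees local
curvature rather than just the clip edge. Restored peaks may exceed the
clip level; the plateau criterion makes the operation exactly idempotent
and the identity on unclipped signals. The threshold is relative to full
scale (samples in [−1, 1]); pass `full_scale=` for signals known to clip
lower. On pure tones (≤ ~400 Hz at 16 kHz) restoration error is below 5 %
of the true amplitude; on harmonic-rich voice-like signals the clipped
peak contains high-frequency structure no local interpolant can recover,
and errors of ~10–15 % of peak are typical. That is a genuine limitation
of interpolation-based declipping, not of this implementation.

The speech-emotion pipeline computes, per 25 ms frame (10 ms hop):
log-energy, an autocorrelation f0 estimate (60–400 Hz), spectral centroid,
85 % rolloff and 13 cepstral coefficients (DCT of the log power spectrum);
per utterance, the mean, SD, 20th/80th percentiles and least-squares slope
of each descriptor (85 features). Constant columns are dropped with a
warning. Classification is a linear discriminant under stratified 3-fold
cross-validation, stratified by emotion rather than by speaker — the
corpus shape (141 utterances, 28/37/38/38) is too small for
speaker-independent folds, a documented limitation. The per-utterance
correctness vector is returned in corpus order for matched-pairs testing
between devices.

## Agreement statistics

All statistics are computed from first principles so they can be driven by
plain CSV/tables: MAPE normalizes by the reference device's value; limits
of agreement are bias ± 1.96 SD of paired differences; kappa uses marginal
products for chance agreement. McNemar defaults to the *uncorrected*
chi-square (b−c)²/(b+c) — the form consistent with both published worked
examples this package reproduces (χ² = 7.41 from 95/61 discordant pairs;
p = 0.26 from 16/23) — with the continuity-corrected and exact-binomial
forms available as options. WER tokenization lower-cases, strips
punctuation and splits on whitespace; alignment is unit-cost Levenshtein
with substitutions preferred on ties.

## Synthetic data

The generators define the study conditions and return ground truth
alongside every signal:

- **ECG**: beats are placed by integrating the prescribed instantaneous
  heart period (base + A·sin(2πft), defaults 800 ms, 100 ms, 0.25 Hz —
  adult-range values with modulation inside the adult band); each beat is
  a three-Gaussian QRS-like template (widths 10/12/10 ms, amplitudes
  −0.15/1.0/−0.25 of an 800-count R wave on a 2048-count baseline) with
  Gaussian noise (default SD 10 counts). No PQRST morphology realism is
  claimed — the template is peak-detectable and documented.
- **Sample loss**: binomial per-chunk counts around the target rate
  (defaults 0.087 and 0.023, the two firmware-era levels), dropped as one
  burst at each chunk tail where slow writes actually lose data. Clock
  drift is linear (default study range 1–3 s per 12 h).
- **Activity**: upright = gravity + noise; walk = 2 Hz vertical
  oscillation; glide = 1 Hz lateral; squat = 0.5 Hz vertical
  high-amplitude; rotation = sustained ~60 deg/s single-axis gyro rate;
  sampling jittered uniformly within 70 ± 5 Hz. Default corpus counts
  follow the reference design (812/150/176/116 five-second windows).
- **Speech**: harmonic source with emotion-dependent f0 contour, energy
  and spectral tilt plus noise, 28/37/38/38 utterances; a `separation`
  dial collapses the class profiles to chance for negative controls.

What passing these experiments shows — and does not. The synthetic classes
are separable by construction, so classifier accuracies near 1.0 verify
the *pipeline* (windowing, normalization, split hygiene, metric
arithmetic), not real-world recognizability of activities or emotions;
the published device-vs-device numbers (per-task MAPE tables, absolute
word error rates, cross-device RSA t statistics) depend on the original
recordings and trained ASR models and are out of reach of desk-scale
synthesis. What the experiments do establish: the detector recovers
prescribed rhythms to one 4 ms tick on clean signal; 2 % burst loss is
repaired to < 1 % interval MAPE; RSA matches its closed form and orders
task conditions correctly across a cohort; and every statistic agrees
with independent oracles.

## Problem sizes and determinism

Test and acceptance runs use 2–5 min sessions, ten-subject cohorts, the
reference corpus sizes (1254 activity windows, 141 utterances) and
exhaustive word-error enumeration up to length 6 over a 3-word
vocabulary — sizes chosen so the full suite completes in a couple of
minutes while exercising every code path at the study's own scales. All
randomness flows through explicit integer seeds; generators and
cross-validation are bit-reproducible given the same seed.
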