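"""Audio preprocessing and speech emotion recognition (SER).

The device records 24-bit audio at 22.05 kHz; most speech models expect
16 kHz, so :func:`downsample` resamples polyphase.  The microphone's limited
headroom clips loud utterances; :func:`declip` restores maximal clipped runs
(relative threshold, default 70% of the observed peak) by cubic
interpolation through flanking unclipped samples, letting restored peaks
exceed the clip level.

SER is a four-class problem (neutral / happy / sad / angry).  Utterance
features are statistical functionals (mean, SD, 20th/80th percentiles,
linear slope) of frame-level descriptors — log-energy, a fundamental
frequency estimate, spectral centroid and rolloff, and 13 cepstral
coefficients over 25 ms frames with a 10 ms hop — fed to a linear
discriminant classifier under stratified 3-fold cross-validation.  The
per-utterance correctness vector is returned for matched-pairs testing
between recording devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft
from scipy.interpolate import CubicSpline
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from triad.agreement import ConfusionMatrix

DEVICE_RATE = 22050
MODEL_RATE = 16000
EMOTIONS = ["neutral", "happy", "sad", "angry"]

FRAME_S = 0.025
HOP_S = 0.010
N_CEPSTRA = 13
F0_RANGE_HZ = (60.0, 400.0)


@dataclass
class Utterance:
    """One labelled emotional-speech sample at the model rate (16 kHz)."""

    waveform: np.ndarray
    emotion: str
    speaker: str = ""
    device: str = "A"


def downsample(waveform: np.ndarray, orig_rate: int = DEVICE_RATE,
               target_rate: int = MODEL_RATE) -> np.ndarray:
    """Polyphase resampling; output length = round(n * target/orig)."""
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    g = np.gcd(orig_rate, target_rate)
    return signal.resample_poly(x, target_rate // g, orig_rate // g)


def declip(waveform: np.ndarray, threshold_frac: float = 0.70,
           n_flank: int = 4, full_scale: float = 1.0) -> np.ndarray:
    """Restore clipped runs by cubic interpolation through flanking samples.

    A sample is clipped when |x| >= threshold_frac * full_scale (samples are
    expected in [-1, 1]; pass ``full_scale=np.max(np.abs(x))`` for signals
    known to clip below full scale).  Each maximal clipped run is replaced
    by a cubic spline through ``n_flank`` unclipped samples on each side,
    spread over a span comparable to the run so local curvature is captured;
    unclipped samples are untouched and restored peaks may exceed the clip
    level.  Only plateau runs — where the samples sit flat at one level, the
    signature of hard clipping — are touched, so the operation is idempotent
    (a restored peak is curved, not flat) and is the identity on signals
    with no clipped samples.
    """
    x = np.asarray(waveform, dtype=float).copy()
    if x.size == 0:
        raise ValueError("empty input")
    flat_tol = 1e-3 * full_scale
    clipped = np.abs(x) >= threshold_frac * full_scale
    if not clipped.any():
        return x
    if clipped.all():
        raise ValueError("signal is fully clipped; nothing to interpolate from")

    idx = np.flatnonzero(clipped)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        if np.ptp(x[s:e + 1]) > flat_tol:
            continue  # curved excursion above threshold, not a clip plateau
        # spread the flanking support over a span comparable to the run so
        # the spline sees the local curvature, not just the clip edge
        stride = max(1, (e - s + 1) // n_flank)
        left = s - 1 - stride * np.arange(n_flank)[::-1]
        right = e + 1 + stride * np.arange(n_flank)
        left = left[(left >= 0) & ~clipped[np.clip(left, 0, len(x) - 1)]]
        right = right[(right < len(x)) & ~clipped[np.clip(right, 0, len(x) - 1)]]
        support = np.concatenate([left, right])
        if support.size < 2:
            continue  # run at the very edge with no usable flank
        if left.size and right.size and support.size >= 4:
            spline = CubicSpline(support.astype(float), x[support])
            x[s:e + 1] = spline(np.arange(s, e + 1, dtype=float))
        else:
            order = min(3, support.size - 1)
            coeff = np.polyfit(support.astype(float), x[support], order)
            x[s:e + 1] = np.polyval(coeff, np.arange(s, e + 1, dtype=float))
    return x


def _frame(x: np.ndarray, rate: int) -> np.ndarray:
    flen = int(round(FRAME_S * rate))
    hop = int(round(HOP_S * rate))
    n = 1 + max(0, (len(x) - flen) // hop)
    return np.stack([x[i * hop:i * hop + flen] for i in range(n)])


def _frame_descriptors(x: np.ndarray, rate: int) -> np.ndarray:
    """Per-frame descriptors: log-energy, f0, centroid, rolloff, 13 cepstra."""
    frames = _frame(x, rate) * np.hamming(int(round(FRAME_S * rate)))
    eps = 1e-10
    energy = np.log(np.sum(frames**2, axis=1) + eps)

    spec = np.abs(rfft(frames, axis=1))
    power = spec**2
    freqs = np.fft.rfftfreq(frames.shape[1], d=1.0 / rate)
    psum = power.sum(axis=1) + eps
    centroid = (power * freqs).sum(axis=1) / psum
    cum = np.cumsum(power, axis=1)
    roll_idx = np.argmax(cum >= 0.85 * cum[:, -1:], axis=1)
    rolloff = freqs[roll_idx]

    ceps = dct(np.log(power + eps), axis=1, norm="ortho")[:, :N_CEPSTRA]

    # f0 by autocorrelation peak within the voice range
    lag_lo = int(rate / F0_RANGE_HZ[1])
    lag_hi = int(rate / F0_RANGE_HZ[0])
    f0 = np.zeros(len(frames))
    for i, fr in enumerate(frames):
        ac = signal.correlate(fr, fr, mode="full")[len(fr) - 1:]
        if ac[0] <= 0:
            continue
        seg = ac[lag_lo:lag_hi]
        if seg.size:
            lag = lag_lo + int(np.argmax(seg))
            if ac[lag] > 0.2 * ac[0]:
                f0[i] = rate / lag
    return np.column_stack([energy, f0, centroid, rolloff, ceps])


def utterance_features(u: Utterance, rate: int = MODEL_RATE) -> np.ndarray:
    """Utterance-level functionals of the frame descriptors.

    mean, SD, 20th/80th percentile, and least-squares slope over time for
    each of the 17 frame descriptors -> an 85-dimensional vector.
    """
    d = _frame_descriptors(u.waveform, rate)
    t = np.arange(len(d))
    tc = t - t.mean()
    denom = np.sum(tc**2) or 1.0
    slope = (tc @ d) / denom
    return np.concatenate([
        d.mean(axis=0), d.std(axis=0),
        np.percentile(d, 20, axis=0), np.percentile(d, 80, axis=0),
        slope,
    ])


def ser_crossval(
    utterances: list[Utterance],
    folds: int = 3,
    seed: int = 0,
) -> tuple[ConfusionMatrix, list[dict[str, float]], np.ndarray]:
    """Stratified k-fold linear-discriminant SER evaluation.

    Returns the pooled confusion matrix (rows = ground truth, in corpus
    label order), per-fold metrics, and the per-utterance correctness vector
    in corpus order (deterministic given the utterances and seed) for
    matched-pairs comparison across devices.  Degenerate constant feature
    columns are dropped.
    """
    from triad.agreement import classifier_metrics

    labels = [l for l in EMOTIONS if any(u.emotion == l for u in utterances)]
    extra = sorted({u.emotion for u in utterances} - set(labels))
    labels += extra
    idx = {l: i for i, l in enumerate(labels)}

    X = np.stack([utterance_features(u) for u in utterances])
    y = np.array([u.emotion for u in utterances])
    keep = X.std(axis=0) > 1e-12
    if not keep.all():
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d constant feature columns", int((~keep).sum()))
    X = X[:, keep]

    k = len(labels)
    pooled = np.zeros((k, k))
    correct = np.zeros(len(utterances), dtype=bool)
    per_fold = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        clf = LinearDiscriminantAnalysis()
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        cm = np.zeros((k, k))
        for t, p in zip(y[test_idx], pred):
            cm[idx[t], idx[p]] += 1
        pooled += cm
        per_fold.append(classifier_metrics(ConfusionMatrix(labels, cm)))
        correct[test_idx] = pred == y[test_idx]
    return ConfusionMatrix(labels, pooled), per_fold, correct
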