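"""Synthetic fixture generators for the full pipeline.

These generators emulate the study conditions the analysis pipelines are
exercised under, with ground truth returned alongside every signal:

* :func:`gen_ecg` — ECG with beats placed by a prescribed instantaneous
  heart period (base + sinusoidal respiratory modulation), each beat a
  three-Gaussian QRS-like template on a noisy baseline, chunked at 30 s;
* :func:`gen_activity` — 9-axis IMU traces with per-activity accelerometer
  signatures and jittered 70 ± 5 Hz sampling, plus a direct labelled-window
  corpus builder for classifier experiments;
* :func:`degrade` — firmware-dependent sample loss (bursts at chunk tails,
  where slow SD-card writes drop data; ~8.7% for v1-era recordings vs
  ~2.3% for v2) and linear real-time-clock drift (1-3 s per 11-12 h);
* :func:`gen_speech_corpus` — parametric vocal surrogates with
  emotion-dependent fundamental-frequency contour, energy and spectral
  tilt, in the reference corpus shape (28/37/38/38 utterances).

All generators are deterministic given their seed.  No physiological ECG
morphology or infant-cry realism is claimed: the fixtures are built to be
detectable/separable by the documented pipelines, with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from triad.activity import ActivityWindow, GRAVITY, TARGET_RATE, WINDOW_SAMPLES
from triad.audio import DEVICE_RATE, Utterance
from triad.codec import NOMINAL_RATES, Recording, SensorChunk, quantize

ECG_RATE = NOMINAL_RATES["ecg"]
ECG_CHUNK_S = 30.0
ADC_BASELINE = 2048.0
ADC_R_AMPLITUDE = 800.0

# QRS-like template: (time offset s, width s, amplitude relative to R)
QRS_GAUSSIANS = [(-0.030, 0.010, -0.15), (0.0, 0.012, 1.0), (0.030, 0.010, -0.25)]

V1_MISSING_RATE = 0.087
V2_MISSING_RATE = 0.023

CORPUS_COUNTS = {"neutral": 28, "happy": 37, "sad": 38, "angry": 38}


@dataclass
class SessionSpec:
    """Prescribed heart-period dynamics for one task session."""

    label: str
    duration_s: float
    base_ms: float = 800.0
    modulation_amp_ms: float = 100.0
    modulation_hz: float = 0.25


@dataclass
class EcgGroundTruth:
    """What :func:`gen_ecg` actually generated."""

    beat_times: np.ndarray  # s from recording start (continuous, unquantized)
    ibi_ms: np.ndarray
    sessions: list[tuple[str, float, float]]  # (label, start_s, end_s)


def prescribed_beat_times(schedule: list[SessionSpec]) -> EcgGroundTruth:
    """Integrate the instantaneous heart period into beat times.

    Each next beat falls one current-period later:
    t_{k+1} = t_k + (base + A sin(2 pi f t_k)) / 1000, with session-local
    parameters switching at session boundaries.
    """
    beats = [0.0]
    sessions = []
    t_sess = 0.0
    for spec in schedule:
        if spec.modulation_amp_ms >= spec.base_ms:
            raise ValueError("modulation amplitude must be below the base period")
        end = t_sess + spec.duration_s
        sessions.append((spec.label, t_sess, end))
        t = beats[-1]
        while True:
            period_s = (spec.base_ms + spec.modulation_amp_ms
                        * np.sin(2 * np.pi * spec.modulation_hz * (t - t_sess))) / 1000.0
            if t + period_s > end:
                break
            t += period_s
            beats.append(t)
        t_sess = end
    bt = np.asarray(beats)
    return EcgGroundTruth(beat_times=bt, ibi_ms=np.diff(bt) * 1000.0, sessions=sessions)


def gen_ecg(
    schedule: list[SessionSpec],
    seed: int = 0,
    noise_sd: float = 10.0,
    start_utc_ms: int = 0,
) -> tuple[Recording, EcgGroundTruth]:
    """Synthesize a chunked ECG recording with prescribed interbeat intervals.

    Beats are stamped with the QRS-like Gaussian template on a constant ADC
    baseline with Gaussian noise of ``noise_sd`` counts.  Returns the 30 s
    chunked recording and the prescribed ground truth.
    """
    rng = np.random.default_rng(seed)
    truth = prescribed_beat_times(schedule)
    total_s = sum(s.duration_s for s in schedule)
    n = int(round(total_s * ECG_RATE))
    t = np.arange(n) / ECG_RATE

    x = np.full(n, ADC_BASELINE)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    for tb in truth.beat_times:
        for off, width, amp in QRS_GAUSSIANS:
            lo = max(0, int((tb + off - 4 * width) * ECG_RATE))
            hi = min(n, int((tb + off + 4 * width) * ECG_RATE) + 1)
            if lo >= hi:
                continue
            seg = t[lo:hi]
            x[lo:hi] += ADC_R_AMPLITUDE * amp * np.exp(-0.5 * ((seg - tb - off) / width) ** 2)
    x = np.clip(x, 0, 0xFFFF)

    chunks = []
    per = int(round(ECG_CHUNK_S * ECG_RATE))
    for s in range(0, n, per):
        e = min(n, s + per)
        chunk = SensorChunk(
            "ecg",
            start_utc_ms + int(round(s / ECG_RATE * 1000)),
            start_utc_ms + int(round(e / ECG_RATE * 1000)),
            x[s:e].copy(),
        )
        chunks.append(quantize(chunk))
    return Recording(chunks=chunks, firmware_version="v2", device_id="synthetic"), truth


ACTIVITY_SIGNATURES = {
    # axis index, frequency Hz, amplitude m/s^2 of the dominant oscillation
    "upright": (2, 0.0, 0.0),
    "walk": (2, 2.0, 3.0),
    "glide": (0, 1.0, 2.0),
    "squat": (2, 0.5, 5.0),
}


def _activity_accel(label: str, n: int, rate: float, rng: np.random.Generator,
                    noise_sd: float = 0.3) -> np.ndarray:
    axis, freq, amp = ACTIVITY_SIGNATURES[label]
    t = np.arange(n) / rate
    out = rng.normal(0.0, noise_sd, (n, 3)) if noise_sd > 0 else np.zeros((n, 3))
    out[:, 2] += GRAVITY  # device worn upright: gravity on the vertical axis
    if amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        a = amp * rng.uniform(0.8, 1.2)
        out[:, axis] += a * np.sin(2 * np.pi * freq * t + phase)
        # secondary harmonic gives each activity a distinctive waveform shape
        out[:, (axis + 1) % 3] += 0.3 * a * np.sin(4 * np.pi * freq * t + phase)
    return out


def gen_activity(
    plan: list[tuple[str, float]],
    seed: int = 0,
    rotation_rate_dps: float = 60.0,
    noise_sd: float = 0.3,
    start_utc_ms: int = 0,
) -> tuple[Recording, np.ndarray, np.ndarray]:
    """Synthesize a 9-axis IMU recording following an activity plan.

    ``plan`` is an ordered (activity, duration_s) list; activities are the
    four accelerometer classes plus ``"rotate"`` (sustained single-axis gyro
    rate).  Sampling times are jittered within 70 ± 5 Hz.  Returns the
    chunked recording, per-sample activity labels, and per-sample times (s);
    samples spanning an activity change are the transition windows callers
    should exclude.
    """
    rng = np.random.default_rng(seed)
    times, accel, gyro, labels = [], [], [], []
    t = 0.0
    for label, dur in plan:
        end = t + dur
        seg_t = []
        while t < end:
            seg_t.append(t)
            t += 1.0 / (TARGET_RATE + rng.uniform(-5.0, 5.0))
        n = len(seg_t)
        if label == "rotate":
            a = _activity_accel("upright", n, TARGET_RATE, rng, noise_sd)
            g = rng.normal(0.0, 2.0, (n, 3))
            g[:, 2] += rotation_rate_dps
        else:
            a = _activity_accel(label, n, TARGET_RATE, rng, noise_sd)
            g = rng.normal(0.0, 2.0, (n, 3))
        times.extend(seg_t)
        accel.append(a)
        gyro.append(g)
        labels.extend([label] * n)

    times = np.asarray(times)
    samples = np.hstack([
        np.vstack(accel),
        np.vstack(gyro),
        rng.normal(0.0, 0.05, (len(times), 3)),  # magnetometer: idle
    ])
    chunks = []
    per = 30.0
    for s0 in np.arange(0.0, times[-1], per):
        sel = (times >= s0) & (times < s0 + per)
        if not sel.any():
            continue
        chunk = SensorChunk(
            "imu",
            start_utc_ms + int(round(s0 * 1000)),
            start_utc_ms + int(round(min(s0 + per, times[-1] + 1.0 / TARGET_RATE) * 1000)),
            samples[sel],
        )
        chunks.append(quantize(chunk))
    rec = Recording(chunks=chunks, firmware_version="v1", device_id="synthetic")
    return rec, np.asarray(labels, dtype=object), times


def activity_corpus(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    noise_sd: float = 0.3,
) -> list[ActivityWindow]:
    """Build a labelled 5 s window corpus directly (no chunking/resampling).

    Default class counts follow the reference study design: 812 upright,
    150 walk, 176 glide, 116 squat.  Gravity is already removed.
    """
    counts = counts or {"upright": 812, "walk": 150, "glide": 176, "squat": 116}
    rng = np.random.default_rng(seed)
    windows = []
    for label, cnt in counts.items():
        for _ in range(cnt):
            a = _activity_accel(label, WINDOW_SAMPLES, TARGET_RATE, rng, noise_sd)
            a[:, 2] -= GRAVITY
            windows.append(ActivityWindow(features=a, label=label))
    return windows


def degrade(
    recording: Recording,
    missing_rate: float = V1_MISSING_RATE,
    drift_s_per_12h: float = 0.0,
    seed: int = 0,
) -> tuple[Recording, dict[int, int]]:
    """Emulate firmware-dependent sample loss and real-time-clock drift.

    Samples are dropped in a single burst at each chunk's tail (slow-write
    loss accumulates at the end of a write window); per-chunk drop counts
    are binomially distributed around ``missing_rate``.  Chunk UTC stamps
    keep their nominal span, so the loss is visible to
    :func:`triad.codec.missing_fraction`.  Timestamps then drift linearly by
    ``drift_s_per_12h`` seconds per 12 h.  Returns the degraded recording
    and per-chunk dropped-sample counts (bookkeeping oracle); surviving
    samples are preserved bit-exactly.
    """
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    t0 = min((c.start_utc for c in recording.chunks), default=0)
    drift = drift_s_per_12h / (12 * 3600.0)

    chunks = []
    dropped: dict[int, int] = {}
    for i, c in enumerate(recording.chunks):
        n = c.n_samples
        k = int(rng.binomial(n, missing_rate)) if missing_rate > 0 else 0
        k = min(k, n - 1)
        dropped[i] = k
        keep = slice(0, n - k)
        start = c.start_utc + int(round((c.start_utc - t0) * drift))
        end = c.end_utc + int(round((c.end_utc - t0) * drift))
        chunks.append(SensorChunk(c.modality, start, end,
                                  c.samples[keep].copy(), c.missing_mask[keep].copy()))
    return Recording(chunks=chunks, firmware_version=recording.firmware_version,
                     device_id=recording.device_id), dropped


EMOTION_PROFILES = {
    # f0 start Hz, f0 slope Hz/s, amplitude, spectral tilt (per-harmonic decay)
    "neutral": (120.0, 0.0, 0.3, 0.7),
    "happy": (220.0, 40.0, 0.5, 0.8),
    "sad": (100.0, -20.0, 0.2, 0.5),
    "angry": (180.0, 0.0, 0.8, 0.95),
}


def gen_utterance(
    emotion: str,
    rng: np.random.Generator,
    rate: int = DEVICE_RATE,
    duration_s: float | None = None,
    separation: float = 1.0,
) -> np.ndarray:
    """One parametric vocal surrogate: harmonic source + noise.

    ``separation`` scales the inter-class parameter differences; 0 collapses
    every emotion onto the neutral profile (chance-level corpus).
    """
    f0_0, slope, amp, tilt = EMOTION_PROFILES[emotion]
    neu = EMOTION_PROFILES["neutral"]
    f0_0 = neu[0] + separation * (f0_0 - neu[0])
    slope = neu[1] + separation * (slope - neu[1])
    amp = neu[2] + separation * (amp - neu[2])
    tilt = neu[3] + separation * (tilt - neu[3])

    dur = duration_s if duration_s is not None else rng.uniform(1.2, 2.5)
    n = int(dur * rate)
    t = np.arange(n) / rate
    f0 = (f0_0 + rng.normal(0, 5)) + slope * t
    phase = 2 * np.pi * np.cumsum(f0) / rate
    x = np.zeros(n)
    for h in range(1, 9):
        x += (tilt ** (h - 1)) * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    x *= amp * rng.uniform(0.9, 1.1)
    # syllable-like amplitude envelope
    env = 0.55 + 0.45 * np.sin(2 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi))
    x *= env
    x += rng.normal(0, 0.01, n)
    peak = np.max(np.abs(x))
    return x / peak * amp if peak > 0 else x


def gen_speech_corpus(
    seed: int = 0,
    counts: dict[str, int] | None = None,
    rate: int = DEVICE_RATE,
    clip_level: float | None = None,
    separation: float = 1.0,
) -> list[Utterance]:
    """Generate the surrogate emotional-speech corpus (default 28/37/38/38).

    Waveforms are at the device rate (22.05 kHz) so the full preprocessing
    chain (downsample, declip) can run; ``clip_level`` hard-clips each
    waveform at that fraction of its peak first.
    """
    counts = counts or dict(CORPUS_COUNTS)
    rng = np.random.default_rng(seed)
    corpus = []
    for emotion, cnt in counts.items():
        for i in range(cnt):
            x = gen_utterance(emotion, rng, rate=rate, separation=separation)
            if clip_level is not None:
                lim = clip_level * np.max(np.abs(x))
                x = np.clip(x, -lim, lim)
            corpus.append(Utterance(waveform=x, emotion=emotion,
                                    speaker=f"s{i % 8}", device="A"))
    return corpus
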