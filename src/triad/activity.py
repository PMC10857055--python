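"""Accelerometer activity recognition and the gyroscope rotation rule.

A chest-worn accelerometer cannot separate sitting from standing, so those
collapse into a single "upright" class, leaving a four-way problem: upright
vs walk vs glide (side-stepping) vs squat.  Preprocessing removes gravity
from the dominant axis, corrects the device's dynamic sampling rate
(70 ± 5 Hz) onto a fixed 70 Hz grid per 30 s interval, and cuts
non-overlapping 5 s windows (350 samples x 3 axes).  The raw z-normalized
window samples are the classifier features — a 100-tree random forest with
entropy splits, evaluated over 10 repeated stratified 80/20 train/test
splits with the test folds pooled into one confusion matrix.

Chair rotation is detected separately from the gyroscope with a rule: a
window whose cumulative single-axis rotation reaches 300 degrees (tolerance
below the nominal 360) is labelled rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from triad.agreement import ConfusionMatrix, classifier_metrics

TARGET_RATE = 70.0
WINDOW_S = 5.0
WINDOW_SAMPLES = int(WINDOW_S * TARGET_RATE)  # 350
INTERVAL_S = 30.0
GRAVITY = 9.8  # m/s^2

ACTIVITY_LABELS = ["upright", "walk", "glide", "squat"]

ROTATION_THRESHOLD_DEG = 300.0


@dataclass
class ActivityWindow:
    """One 5 s window of 3-axis accelerometer data with its label."""

    features: np.ndarray  # (350, 3), gravity-removed, resampled
    label: str
    subject: str = ""


def remove_gravity(accel: np.ndarray, rate: float = TARGET_RATE) -> np.ndarray:
    """Subtract 9.8 m/s^2 from the gravity-bearing axis, sign-matched.

    The affected axis is the one whose low-pass (0.25 Hz) mean magnitude is
    largest — valid while device orientation is quasi-static at window
    scale.  Input shape (n, 3); returns a corrected copy.
    """
    accel = np.asarray(accel, dtype=float)
    sos = signal.butter(2, 0.25, btype="lowpass", fs=rate, output="sos")
    padlen = min(accel.shape[0] - 1, 50)
    low = signal.sosfiltfilt(sos, accel, axis=0, padlen=padlen)
    means = low.mean(axis=0)
    axis = int(np.argmax(np.abs(means)))
    out = accel.copy()
    out[:, axis] -= GRAVITY * np.sign(means[axis])
    return out


def resample_dynamic(
    times_s: np.ndarray,
    values: np.ndarray,
    target_rate: float = TARGET_RATE,
    interval_s: float = INTERVAL_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Correct a dynamic sampling rate onto a fixed grid per 30 s interval.

    A sliding window counts the samples in each non-overlapping interval to
    decide the direction of correction (up- vs downsampling); the mapping
    itself uses the recorded timestamps: each interval emits exactly
    ``target_rate * interval_s`` samples on a uniform time grid, with values
    linearly interpolated between the bracketing recorded samples.  (A
    purely index-based mapping would ignore the accumulated timing jitter
    of the dynamic rate and misplace samples by a growing phase error.)
    Returns (uniform values, per-interval low-coverage flags); an interval
    with under half the expected samples is flagged.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != times_s.size:
        values = values.T
    per = int(round(target_rate * interval_s))
    t0 = times_s[0]
    n_int = int(np.ceil((times_s[-1] - t0) / interval_s))
    n_int = max(n_int, 1)

    out = np.empty((n_int * per, values.shape[1]))
    flagged = np.zeros(n_int, dtype=bool)
    for k in range(n_int):
        lo = t0 + k * interval_s
        sel = (times_s >= lo) & (times_s < lo + interval_s)
        n = int(sel.sum())
        if n < per // 2:
            flagged[k] = True
        if n == 0:
            out[k * per:(k + 1) * per] = 0.0
            continue
        seg_t = times_s[sel]
        seg = values[sel]
        grid = lo + np.arange(per) / target_rate
        for c in range(values.shape[1]):
            out[k * per:(k + 1) * per, c] = np.interp(grid, seg_t, seg[:, c])
    return out, flagged


def make_windows(
    accel: np.ndarray,
    labels_per_sample: np.ndarray,
    subject: str = "",
) -> list[ActivityWindow]:
    """Cut uniform 70 Hz accelerometer data into labelled 5 s windows.

    Windows containing more than one label (activity transitions) are
    excluded, as are windows labelled with an empty string.
    """
    accel = np.asarray(accel, dtype=float)
    n = (len(accel) // WINDOW_SAMPLES) * WINDOW_SAMPLES
    out = []
    for s in range(0, n, WINDOW_SAMPLES):
        seg_labels = set(labels_per_sample[s:s + WINDOW_SAMPLES])
        if len(seg_labels) != 1:
            continue
        label = seg_labels.pop()
        if not label:
            continue
        out.append(ActivityWindow(features=accel[s:s + WINDOW_SAMPLES], label=str(label),
                                  subject=subject))
    return out


def classify_activities(
    windows: list[ActivityWindow],
    n_splits: int = 10,
    test_size: float = 0.2,
    seed: int = 0,
    n_trees: int = 100,
) -> tuple[ConfusionMatrix, list[dict[str, float]], np.ndarray]:
    """Four-way random-forest classification over repeated 80/20 splits.

    Features are the flattened raw window samples, z-normalized with
    statistics fitted on the training portion of each split only.  Test
    predictions from all splits are pooled into one confusion matrix.
    Returns (pooled matrix, per-split metrics, per-test-sample correctness
    vector pooled in split order) — the correctness vector feeds McNemar
    comparisons against another device.
    """
    labels = sorted({w.label for w in windows})
    if len(labels) < 2:
        raise ValueError("classification requires at least two classes")
    order = [l for l in ACTIVITY_LABELS if l in labels] + [l for l in labels if l not in ACTIVITY_LABELS]
    X = np.stack([w.features.reshape(-1) for w in windows])
    y = np.array([w.label for w in windows])

    k = len(order)
    idx = {l: i for i, l in enumerate(order)}
    pooled = np.zeros((k, k))
    per_split = []
    correct_all = []
    rng = np.random.default_rng(seed)
    for s in range(n_splits):
        split_seed = int(rng.integers(0, 2**31 - 1))
        for _ in range(100):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, random_state=split_seed, stratify=y)
            if set(y_tr) == set(order) and set(y_te) == set(order):
                break
            split_seed = int(rng.integers(0, 2**31 - 1))
        else:
            raise ValueError("could not build a split containing all classes")
        scaler = StandardScaler().fit(X_tr)
        clf = RandomForestClassifier(n_estimators=n_trees, criterion="entropy",
                                     random_state=split_seed)
        clf.fit(scaler.transform(X_tr), y_tr)
        pred = clf.predict(scaler.transform(X_te))
        cm = np.zeros((k, k))
        for t, p in zip(y_te, pred):
            cm[idx[t], idx[p]] += 1
        pooled += cm
        per_split.append(classifier_metrics(ConfusionMatrix(order, cm)))
        correct_all.append(pred == y_te)
    return (ConfusionMatrix(order, pooled), per_split, np.concatenate(correct_all))


def detect_rotation(
    gyro: np.ndarray,
    rate: float = TARGET_RATE,
    window_s: float = WINDOW_S,
    threshold_deg: float = ROTATION_THRESHOLD_DEG,
) -> np.ndarray:
    """Rule-based rotation detection from 3-axis gyroscope data (deg/s).

    A window is a rotation when the absolute cumulative integral of any
    single axis reaches ``threshold_deg`` within the window.  The threshold
    sits below the nominal 360 degrees of a full chair turn to tolerate
    integration leakage.  Returns one boolean per non-overlapping window.
    """
    gyro = np.asarray(gyro, dtype=float)
    per = int(round(window_s * rate))
    n_win = len(gyro) // per
    out = np.zeros(n_win, dtype=bool)
    dt = 1.0 / rate
    for w in range(n_win):
        seg = gyro[w * per:(w + 1) * per]
        total = np.abs(np.sum(seg, axis=0) * dt)
        out[w] = bool(np.max(total) >= threshold_deg)
    return out
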