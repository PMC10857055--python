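"""Respiratory sinus arrhythmia (RSA) by the Porges–Bohrer method.

RSA indexes cardiac vagal tone as the natural log of heart-period variance
restricted to the respiration band.  The procedure, applied per task
session:

1. step-interpolate heart period (ms) from the beat series onto a uniform
   grid (0.5 s for adults, 0.25 s for infants, keeping the band's upper
   edge below Nyquist);
2. detrend by subtracting a centered 21-point moving cubic-polynomial fit
   (local least-squares smoother), which removes slow aperiodic shifts;
3. zero-phase FIR band-pass within the respiration band — 0.12-0.40 Hz for
   adults, 0.30-1.30 Hz for infants;
4. per non-overlapping 30 s epoch, take ln(variance) of the filtered series;
5. average epoch values into the task-level mean (ln ms^2).

A pure sinusoidal modulation of amplitude A ms inside the band yields
variance A^2/2, giving a closed-form check: ln(A^2/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from triad.ibi import IBISeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandConfig:
    """Respiration-band configuration for one subject class."""

    subject_class: str
    band_hz: tuple[float, float]
    resample_step_s: float
    epoch_s: float = 30.0
    detrend_window: int = 21
    detrend_order: int = 3
    fir_taps: int = 127

    def __post_init__(self) -> None:
        nyq = 1.0 / (2.0 * self.resample_step_s)
        if self.band_hz[1] >= nyq:
            raise ValueError(
                f"band upper edge {self.band_hz[1]} Hz >= Nyquist {nyq} Hz of the resampled grid"
            )


ADULT = BandConfig("adult", (0.12, 0.40), 0.5)
INFANT = BandConfig("infant", (0.30, 1.30), 0.25)

BAND_CONFIGS = {"adult": ADULT, "infant": INFANT}


@dataclass
class RSAResult:
    """Per-epoch RSA values (ln ms^2) and their task-level mean."""

    epoch_values: np.ndarray
    task_mean: float
    n_epochs: int
    n_undefined: int = 0


def _heart_period_grid(ibi: IBISeries, step: float) -> np.ndarray:
    """Step-interpolated heart period (ms) on a uniform grid."""
    bt = ibi.beat_times
    grid = np.arange(bt[0], bt[-1], step)
    idx = np.clip(np.searchsorted(bt[:-1], grid, side="right") - 1, 0, len(ibi.ibi_ms) - 1)
    return ibi.ibi_ms[idx]


def _detrend(x: np.ndarray, window: int, order: int) -> np.ndarray:
    """Residual of a centered moving polynomial least-squares smoother."""
    if len(x) <= window:
        window = len(x) - 1 if (len(x) - 1) % 2 else len(x) - 2
        if window <= order:
            return x - np.mean(x)
    smooth = signal.savgol_filter(x, window_length=window, polyorder=order, mode="interp")
    return x - smooth


def _bandpass(x: np.ndarray, cfg: BandConfig) -> np.ndarray:
    fs = 1.0 / cfg.resample_step_s
    taps = signal.firwin(cfg.fir_taps, cfg.band_hz, pass_zero=False, fs=fs, window="hamming")
    padlen = min(len(x) - 1, 3 * cfg.fir_taps)
    return signal.filtfilt(taps, [1.0], x, padlen=padlen)


def compute_rsa(ibi: IBISeries, cfg: BandConfig) -> RSAResult:
    """Compute per-epoch and task-mean RSA (ln ms^2) for one session.

    Epochs are non-overlapping, anchored at session start; a trailing
    partial epoch is dropped.  A zero-variance (constant heart period)
    epoch has no defined log-variance and is excluded with a warning.
    """
    if ibi.n_intervals < 2:
        raise ValueError("compute_rsa requires at least two intervals")
    duration = ibi.beat_times[-1] - ibi.beat_times[0]
    if duration < cfg.epoch_s:
        raise ValueError(
            f"session spans {duration:.1f} s; at least one {cfg.epoch_s:.0f} s epoch required"
        )

    hp = _heart_period_grid(ibi, cfg.resample_step_s)
    detrended = _detrend(hp, cfg.detrend_window, cfg.detrend_order)
    filtered = _bandpass(detrended, cfg)

    per_epoch = int(round(cfg.epoch_s / cfg.resample_step_s))
    n_epochs = len(filtered) // per_epoch
    values = []
    n_undef = 0
    for e in range(n_epochs):
        seg = filtered[e * per_epoch:(e + 1) * per_epoch]
        var = float(np.var(seg))
        # numerically-zero variance (constant heart period) has no defined
        # log; 1e-12 ms^2 is far below any physiological band power
        if var <= 1e-12:
            n_undef += 1
            logger.warning("epoch %d has zero band-limited variance; excluded", e)
            continue
        values.append(np.log(var))
    if not values:
        logger.warning("all %d epochs undefined (constant heart period?)", n_epochs)
        return RSAResult(epoch_values=np.array([]), task_mean=float("nan"),
                         n_epochs=0, n_undefined=n_undef)
    arr = np.asarray(values)
    return RSAResult(epoch_values=arr, task_mean=float(np.mean(arr)),
                     n_epochs=len(arr), n_undefined=n_undef)


@dataclass
class ContrastResult:
    """Adjacent-task RSA differences with a one-tailed paired test."""

    transitions: list[tuple[str, str]]
    mean_diffs: list[float]  # first task mean minus second, averaged over subjects
    t_stats: list[float]
    p_values: list[float]  # one-tailed in the direction of expected_pattern
    sign_agreement: list[bool]


def rsa_contrast(
    per_subject: list[list[tuple[str, RSAResult]]],
    expected_pattern: list[int],
) -> ContrastResult:
    """Test hypothesized RSA changes across adjacent tasks over subjects.

    ``per_subject`` holds, for each subject, the ordered (task, result)
    list; task sets must match across subjects.  ``expected_pattern`` gives
    the hypothesized sign of (task_i − task_{i+1}) per transition: +1 when
    RSA should fall into the next task (e.g. baseline → challenge), −1 when
    it should rise.  Returns one-tailed paired-t p values in the expected
    direction and whether the observed mean difference agrees in sign.
    """
    from triad.agreement import paired_t

    tasks = [t for t, _ in per_subject[0]]
    for subj in per_subject:
        if [t for t, _ in subj] != tasks:
            raise ValueError("task sets differ across subjects")
    if len(tasks) < 2:
        raise ValueError("need at least two tasks")
    if len(expected_pattern) != len(tasks) - 1:
        raise ValueError("expected_pattern must have one sign per transition")

    transitions, mean_diffs, t_stats, p_values, agree = [], [], [], [], []
    for i, sign in enumerate(expected_pattern):
        diffs = np.array([subj[i][1].task_mean - subj[i + 1][1].task_mean
                          for subj in per_subject])
        transitions.append((tasks[i], tasks[i + 1]))
        mean_diffs.append(float(np.mean(diffs)))
        if len(diffs) >= 2 and np.std(diffs, ddof=1) > 0:
            t, _, p = paired_t(sign * diffs, tail="one")
            t_stats.append(float(sign * t))
        else:
            t, p = float("nan"), float("nan")
            if np.allclose(diffs, 0):
                t, p = 0.0, 0.5
            t_stats.append(t)
        p_values.append(float(p))
        agree.append(bool(np.sign(np.mean(diffs)) == sign) if np.mean(diffs) != 0 else False)
    return ContrastResult(transitions, mean_diffs, t_stats, p_values, agree)
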