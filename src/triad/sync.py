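"""UTC-based synchronization of chunked multi-rate sensor streams.

Chunks from the three modalities are written asynchronously and at different
rates, so cross-modal alignment always goes through the shared UTC
timestamps, never through sample arithmetic.  Streams are split into frames
on a common UTC grid; where the device dropped samples (slow SD writes), the
deficit is restored as zero padding with the missing mask set, so downstream
consumers can account for padding-induced artifacts.

The real-time clock drifts by roughly 1-3 s per 11-12 h.  That drift is left
uncorrected here — the shared clock keeps the modalities mutually consistent,
which is what synchronization needs — and is only emulated by the synthetic
generators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from triad.codec import NOMINAL_RATES, Recording, SensorChunk, ValidationError

DEFAULT_FRAME_PERIOD_S = {"ecg": 30.0, "imu": 30.0, "audio": 10.0}

#: relative improvement of the alignment objective over zero lag below which
#: the estimate is flagged low-confidence
LOW_CONFIDENCE_IMPROVEMENT = 0.05


@dataclass
class AlignedFrame:
    """One fixed-period frame of one modality on the shared UTC grid."""

    modality: str
    frame_start_utc: int  # ms
    frame_period: float  # s
    samples: np.ndarray
    missing_mask: np.ndarray

    @property
    def n_padded(self) -> int:
        return int(np.sum(self.missing_mask))


@dataclass
class AlignmentResult:
    """Lag estimate between two irregularly sampled series."""

    lag_s: float
    objective: float  # mean |a - shifted b| at the chosen lag
    objective_zero: float
    low_confidence: bool
    aligned: tuple[np.ndarray, np.ndarray]  # step-interpolated overlap


def frame_streams(
    recording: Recording,
    frame_period: float | dict[str, float] | None = None,
) -> dict[str, list[AlignedFrame]]:
    """Split each modality into UTC-aligned, zero-padded fixed-length frames.

    The frame grid is anchored at the earliest chunk start across all
    modalities, so frames from different modalities share start stamps
    (modalities with different periods share every common multiple).  Each
    chunk's samples are placed by their nominal UTC stamp; missing tail
    samples become zero padding with the mask set.
    """
    recording.validate()
    if not recording.chunks:
        return {}
    if frame_period is None:
        periods = dict(DEFAULT_FRAME_PERIOD_S)
    elif isinstance(frame_period, dict):
        periods = {**DEFAULT_FRAME_PERIOD_S, **frame_period}
    else:
        periods = {m: float(frame_period) for m in NOMINAL_RATES}

    anchor = min(c.start_utc for c in recording.chunks)
    out: dict[str, list[AlignedFrame]] = {}
    for modality in recording.modalities:
        chunks = recording.by_modality(modality)
        period = periods[modality]
        rate = NOMINAL_RATES[modality]
        frame_len = int(round(period * rate))
        period_ms = period * 1000.0

        last_end = max(c.end_utc for c in chunks)
        n_frames = int(np.ceil((last_end - anchor) / period_ms))
        n_frames = max(n_frames, 1)

        width = (frame_len,) if chunks[0].samples.ndim == 1 else (frame_len, 9)
        frames = [
            AlignedFrame(
                modality=modality,
                frame_start_utc=int(round(anchor + i * period_ms)),
                frame_period=period,
                samples=np.zeros(width),
                missing_mask=np.ones(frame_len, dtype=bool),
            )
            for i in range(n_frames)
        ]
        for chunk in chunks:
            times = chunk.sample_times_ms()
            # global sample index on the modality's uniform grid
            gidx = np.round((times - anchor) * rate / 1000.0).astype(np.int64)
            fidx = np.minimum(gidx // frame_len, n_frames - 1)
            sidx = gidx - fidx * frame_len
            for f in np.unique(fidx):
                sel = fidx == f
                frames[f].samples[sidx[sel]] = chunk.samples[sel]
                frames[f].missing_mask[sidx[sel]] = chunk.missing_mask[sel]
        out[modality] = frames
    return out


def _step_interp(t: np.ndarray, v: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Previous-value (zero-order-hold) interpolation onto ``grid``."""
    idx = np.searchsorted(t, grid, side="right") - 1
    idx = np.clip(idx, 0, len(v) - 1)
    return v[idx]


def align_series(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    max_lag: float = 30.0,
    step: float = 0.1,
) -> AlignmentResult:
    """Estimate the lag of series ``b`` relative to ``a``.

    Both series are (time_s, value) pairs, e.g. beat times vs interbeat
    interval from two devices.  The lag minimizing the mean absolute
    difference between step-interpolated series over a 0.1 s lag grid is
    returned; a positive lag means ``b`` is late.  Ties break toward the
    smallest absolute lag.  When the best objective improves on the zero-lag
    objective by less than 5%, the result is flagged low-confidence.
    """
    ta, va = (np.asarray(x, dtype=float) for x in a)
    tb, vb = (np.asarray(x, dtype=float) for x in b)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("align_series requires non-empty series")
    span_a = ta[-1] - ta[0]
    span_b = tb[-1] - tb[0]
    if min(span_a, span_b) < 2 * max_lag:
        raise ValidationError("series must span at least twice max_lag")

    lags = np.arange(-max_lag, max_lag + step / 2, step)
    # order candidate lags by |lag| so argmin picks the smallest |lag| on ties
    lags = lags[np.argsort(np.abs(lags), kind="stable")]
    objectives = np.empty(len(lags))
    for i, lag in enumerate(lags):
        # shifted-b(t) = b(t + lag): positive lag means b is late
        lo = max(ta[0], tb[0] - lag)
        hi = min(ta[-1], tb[-1] - lag)
        grid = np.arange(lo, hi, step)
        if grid.size < 2:
            objectives[i] = np.inf
            continue
        objectives[i] = np.mean(np.abs(_step_interp(ta, va, grid) - _step_interp(tb - lag, vb, grid)))

    best = int(np.argmin(objectives))
    lag = float(lags[best])
    obj0 = float(objectives[np.flatnonzero(np.abs(lags) < step / 2)[0]])
    obj = float(objectives[best])
    low_conf = obj0 <= 0 or (obj0 - obj) / obj0 < LOW_CONFIDENCE_IMPROVEMENT

    lo = max(ta[0], tb[0] - lag)
    hi = min(ta[-1], tb[-1] - lag)
    grid = np.arange(lo, hi, step)
    aligned = (_step_interp(ta, va, grid), _step_interp(tb - lag, vb, grid))
    return AlignmentResult(lag_s=round(lag, 6), objective=obj, objective_zero=obj0,
                           low_confidence=bool(low_conf), aligned=aligned)


def padding_intervals(frames: list[AlignedFrame]) -> list[tuple[float, float]]:
    """Merge frame missing-masks into (start_s, end_s) padded intervals.

    Times are seconds relative to the first frame start — the time base used
    by the interbeat-interval pipeline.
    """
    if not frames:
        return []
    t0 = frames[0].frame_start_utc
    intervals: list[tuple[float, float]] = []
    for f in frames:
        rate = NOMINAL_RATES[f.modality]
        idx = np.flatnonzero(f.missing_mask)
        if not idx.size:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        base = (f.frame_start_utc - t0) / 1000.0
        for s, e in zip(starts, ends):
            intervals.append((base + s / rate, base + (e + 1) / rate))
    # merge touching intervals across frame boundaries
    merged: list[tuple[float, float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1e-9:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
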