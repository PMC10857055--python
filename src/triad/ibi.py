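"""R-peak detection and interbeat-interval (IBI) processing.

The pipeline mirrors standard heart-rate-variability practice: a
Pan–Tompkins-style detector finds R peaks in the raw ECG, beat times are
quantized to a 4 ms grid (250 Hz tick, the resolution of the IBI files
consumed downstream), and the resulting interval series is screened for
artifacts.  Dropped ECG samples (restored as zero padding during
synchronization) corrupt the intervals that overlap them; those intervals
are flagged and repaired with the conventional editing moves:

* divide — one spuriously long interval that is close to an integer
  multiple of the local median (a missed beat) is split into equal parts;
* combine — adjacent spuriously short intervals summing to roughly the
  local median (a false extra beat) are merged;
* interpolate — anything else is replaced by linear interpolation between
  its neighbours.

Sessions (tasks) are attached from an external label table by beat midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

TICK_MS = 4.0  # 250 Hz beat-time grid

#: default physiological interval bounds (ms) by subject class
IBI_BOUNDS_MS = {"adult": (300.0, 2000.0), "infant": (250.0, 1000.0)}

FLAG_OK = "ok"
FLAG_DIVIDE = "edited_divide"
FLAG_COMBINE = "edited_combine"
FLAG_INTERP = "edited_interpolate"
FLAG_MISSING = "missing_overlap"


class NoPeaksError(ValueError):
    """Raised when the ECG carries no detectable heartbeats."""


@dataclass
class IBISeries:
    """Beat times (s from recording start) and the intervals between them.

    ``ibi_ms[i]`` spans ``beat_times[i]`` to ``beat_times[i+1]``; flags and
    session labels are per interval.
    """

    beat_times: np.ndarray
    ibi_ms: np.ndarray
    flags: list[str] = field(default_factory=list)
    session: list[str] = field(default_factory=list)
    usable: bool = True
    edited_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        n = len(self.ibi_ms)
        if not self.flags:
            self.flags = [FLAG_OK] * n
        if not self.session:
            self.session = [""] * n

    @classmethod
    def from_beat_times(cls, beat_times: np.ndarray) -> "IBISeries":
        bt = np.asarray(beat_times, dtype=float)
        return cls(beat_times=bt, ibi_ms=np.diff(bt) * 1000.0)

    @property
    def n_intervals(self) -> int:
        return len(self.ibi_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beat_time_s": self.beat_times[:-1] if len(self.beat_times) else [],
            "ibi_ms": self.ibi_ms,
            "flag": self.flags,
            "session": self.session,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IBISeries":
        df = pd.read_csv(path, keep_default_na=False)
        bt = df["beat_time_s"].to_numpy(dtype=float)
        ibi = df["ibi_ms"].to_numpy(dtype=float)
        beat_times = np.append(bt, bt[-1] + ibi[-1] / 1000.0) if len(bt) else bt
        return cls(beat_times=beat_times, ibi_ms=ibi,
                   flags=list(df["flag"]), session=[str(s) for s in df["session"]])


def quantize_beat_times(beat_times: np.ndarray) -> np.ndarray:
    """Snap beat times onto the 4 ms (250 Hz) grid."""
    tick = TICK_MS / 1000.0
    return np.round(np.asarray(beat_times, dtype=float) / tick) * tick


def detect_r_peaks(
    ecg: np.ndarray,
    rate: float,
    refractory_s: float = 0.2,
    integrate_s: float = 0.150,
) -> np.ndarray:
    """Detect R-peak times (seconds, 4 ms grid) in a raw ECG trace.

    Pan–Tompkins-style pipeline: band-limit to 5-20 Hz, differentiate,
    square, integrate over a 150 ms moving window, threshold adaptively with
    a 200 ms refractory period, then refine each fiducial to the band-passed
    maximum nearby.
    """
    x = np.asarray(ecg, dtype=float)
    if len(x) < 10 * rate:
        raise ValueError("detect_r_peaks needs at least 10 s of signal")
    if np.ptp(x) == 0:
        raise NoPeaksError("flat signal")

    sos = signal.butter(2, [5.0, 20.0], btype="bandpass", fs=rate, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(1, int(round(integrate_s * rate)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    # adaptive threshold: anchored on the height of genuine QRS complexes,
    # estimated as the median of the strongest coarse peaks (at least one
    # beat every 2 s is assumed, i.e. >= 30 bpm)
    coarse, _ = signal.find_peaks(integ, distance=max(1, int(refractory_s * rate)))
    if coarse.size == 0:
        raise NoPeaksError("no candidate peaks")
    k = max(1, int(len(x) / rate / 2.0))
    top = np.sort(integ[coarse])[-k:]
    level = np.median(top)
    peaks, _ = signal.find_peaks(
        integ, height=0.3 * level, distance=max(1, int(refractory_s * rate))
    )
    if peaks.size < 2:
        raise NoPeaksError("fewer than two beats detected")

    # refine to the local band-passed maximum (R apex) within +-100 ms
    half = int(round(0.1 * rate))
    refined = np.empty(peaks.size, dtype=np.int64)
    for i, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined[i] = lo + int(np.argmax(bp[lo:hi]))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if (p - keep[-1]) / rate >= refractory_s:
            keep.append(int(p))
    return quantize_beat_times(np.asarray(keep) / rate)


def _local_median(values: np.ndarray, i: int, k: int = 5) -> float:
    """Median of the k nearest neighbours on each side of index i.

    The window spans up to 2k intervals (shorter at the edges), wide enough
    that genuine respiratory modulation of the heart period — roughly one
    cycle per 4-5 beats — averages out instead of biasing the reference.
    """
    n = len(values)
    neigh = [values[j] for j in range(max(0, i - k), min(n, i + k + 1)) if j != i]
    return float(np.median(neigh)) if neigh else float(values[i])


def correct_missing_artifacts(
    ibi: IBISeries,
    padding_intervals: list[tuple[float, float]] | None = None,
    bounds_ms: tuple[float, float] = IBI_BOUNDS_MS["adult"],
    neighbour_k: int = 5,
    outlier_frac: float = 0.25,
    match_frac: float = 0.125,
    unusable_frac: float = 0.20,
    pad_guard_s: float = 0.3,
) -> IBISeries:
    """Flag and repair artifactual intervals; returns an edited copy.

    Intervals overlapping zero-padded signal stretches are suspect, as are
    intervals outside the physiological ``bounds_ms`` or deviating more than
    ``outlier_frac`` from the median of the ``neighbour_k`` nearest
    neighbours.  Suspect intervals are divided, combined, or interpolated
    (see module docstring); edits land back on the 4 ms grid.  If more than
    ``unusable_frac`` of intervals needed editing the series is marked
    unusable.  The operation is idempotent.
    """
    padding_intervals = padding_intervals or []
    times = ibi.beat_times.copy()
    values = list(ibi.ibi_ms.astype(float))
    n = len(values)
    if n == 0:
        return replace(ibi, usable=True, edited_fraction=0.0)

    # beats detected right at a padded-gap edge are unreliable (the zero
    # padding distorts the band-passed signal there), so the overlap test
    # widens each padding interval by a small guard margin
    suspect = np.zeros(n, dtype=bool)
    flags = [FLAG_OK] * n
    for i in range(n):
        t0, t1 = times[i], times[i + 1]
        for ps, pe in padding_intervals:
            if t0 < pe + pad_guard_s and t1 > ps - pad_guard_s:
                suspect[i] = True
                flags[i] = FLAG_MISSING
                break

    med = np.array([_local_median(np.asarray(values), i, neighbour_k) for i in range(n)])
    out_of_bounds = (np.asarray(values) < bounds_ms[0]) | (np.asarray(values) > bounds_ms[1])
    deviant = np.abs(np.asarray(values) - med) > outlier_frac * med
    suspect |= out_of_bounds | deviant

    # smooth heart-period estimate from the clean intervals, used to fill
    # padding gaps: a cubic spline tracks the respiratory modulation that a
    # flat local average would miss
    clean_idx = np.flatnonzero(~suspect)
    mids_all = (times[:-1] + times[1:]) / 2.0
    if clean_idx.size >= 4:
        from scipy.interpolate import CubicSpline
        _est = CubicSpline(mids_all[clean_idx], np.asarray(values)[clean_idx])
        estimate = lambda t: float(_est(np.clip(t, mids_all[clean_idx][0], mids_all[clean_idx][-1])))
    elif clean_idx.size >= 2:
        estimate = lambda t: float(np.interp(t, mids_all[clean_idx], np.asarray(values)[clean_idx]))
    else:
        estimate = lambda t, _m=float(np.median(values)): _m

    # Edits keep the measured beat times of clean beats anchored: divide
    # inserts equally spaced beats inside the long interval, combine removes
    # the intermediate beat, and interpolation replaces the value in place.
    new_times: list[float] = [times[0]]
    new_values: list[float] = []
    new_flags: list[str] = []
    n_edited = 0
    i = 0
    while i < n:
        v = values[i]
        t1 = times[i + 1]
        if not suspect[i]:
            new_times.append(t1)
            new_values.append(v)
            new_flags.append(flags[i])
            i += 1
            continue
        m = med[i]
        n_edited += 1
        if flags[i] == FLAG_MISSING:
            # padding gap: subdivide the spanning interval into the implied
            # number of beats and take values from the smooth heart-period
            # estimate, which tracks respiratory modulation across the gap
            k = max(1, int(round(v / m)))
            inner = np.linspace(times[i], t1, k + 1)[1:]
            inner = np.round(inner / (TICK_MS / 1000.0)) * (TICK_MS / 1000.0)
            inner[-1] = t1
            prev_t = times[i]
            flag = FLAG_DIVIDE if k >= 2 else FLAG_INTERP
            for tt in inner:
                new_times.append(tt)
                new_values.append(_snap(estimate((prev_t + tt) / 2.0)))
                new_flags.append(flag)
                prev_t = tt
            i += 1
            continue
        # divide: long interval ~= integer multiple of the local median
        k = int(round(v / m))
        if k >= 2 and abs(v - k * m) <= match_frac * (k * m):
            inner = np.linspace(times[i], t1, k + 1)[1:]
            inner = np.round(inner / (TICK_MS / 1000.0)) * (TICK_MS / 1000.0)
            inner[-1] = t1
            prev_t = times[i]
            for tt in inner:
                new_times.append(tt)
                new_values.append((tt - prev_t) * 1000.0)
                new_flags.append(FLAG_DIVIDE)
                prev_t = tt
            i += 1
            continue
        # combine: adjacent short pair summing to ~= the local median
        if i + 1 < n and suspect[i + 1]:
            s = v + values[i + 1]
            if abs(s - m) <= match_frac * m:
                new_times.append(times[i + 2])
                new_values.append(s)
                new_flags.append(FLAG_COMBINE)
                n_edited += 1
                i += 2
                continue
        # fallback: value replaced by the smooth estimate at the interval
        # midpoint; the surrounding beat times stay as measured
        new_times.append(t1)
        new_values.append(_snap(estimate((times[i] + t1) / 2.0)))
        new_flags.append(FLAG_INTERP)
        i += 1

    edited_fraction = n_edited / n
    usable = edited_fraction <= unusable_frac
    if not usable:
        logger.warning("%.1f%% of intervals required editing; series marked unusable",
                       100 * edited_fraction)

    out = IBISeries(beat_times=np.asarray(new_times), ibi_ms=np.asarray(new_values),
                    flags=new_flags, session=[""] * len(new_values),
                    usable=usable, edited_fraction=edited_fraction)
    return out


def _snap(v_ms: float) -> float:
    return float(np.round(v_ms / TICK_MS) * TICK_MS)


def segment_sessions(
    ibi: IBISeries,
    session_table: list[tuple[str, float, float]],
) -> dict[str, IBISeries]:
    """Split an interval series into per-session series by beat midpoint.

    ``session_table`` rows are (label, start_s, end_s) and must not overlap.
    A session window containing no intervals yields an empty series with a
    warning.
    """
    rows = sorted(session_table, key=lambda r: r[1])
    for (l1, s1, e1), (l2, s2, e2) in zip(rows, rows[1:]):
        if s2 < e1:
            raise ValueError(f"sessions {l1!r} and {l2!r} overlap")

    mids = (ibi.beat_times[:-1] + ibi.beat_times[1:]) / 2.0
    out: dict[str, IBISeries] = {}
    for label, start, end in rows:
        sel = (mids >= start) & (mids < end)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            logger.warning("session %r (%.1f-%.1f s) contains no intervals", label, start, end)
            out[label] = IBISeries(beat_times=np.array([]), ibi_ms=np.array([]),
                                   flags=[], session=[])
            continue
        bt = np.append(ibi.beat_times[idx], ibi.beat_times[idx[-1] + 1])
        out[label] = IBISeries(
            beat_times=bt,
            ibi_ms=ibi.ibi_ms[idx],
            flags=[ibi.flags[i] for i in idx],
            session=[label] * idx.size,
            usable=ibi.usable,
        )
    return out


def read_session_table(path) -> list[tuple[str, float, float]]:
    """Read a session table CSV with columns label,start_s,end_s."""
    df = pd.read_csv(path)
    return [(str(r.label), float(r.start_s), float(r.end_s)) for r in df.itertuples()]
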