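"""Shared fixtures: synthetic recordings and pipeline helpers."""

import numpy as np
import pytest

from triad import ibi as ibim
from triad import sync
from triad import synth


def run_ecg_pipeline(schedule, seed, missing_rate=0.0, noise_sd=10.0,
                     bounds_key="adult"):
    """Generate, degrade, frame, detect and edit; returns (edited, truth)."""
    rec, truth = synth.gen_ecg(schedule, seed=seed, noise_sd=noise_sd)
    if missing_rate > 0:
        rec, _ = synth.degrade(rec, missing_rate=missing_rate, seed=(seed + 7919) % (2**31 - 1))
    frames = sync.frame_streams(rec)["ecg"]
    x = np.concatenate([f.samples for f in frames])
    pads = sync.padding_intervals(frames)
    series = ibim.IBISeries.from_beat_times(ibim.detect_r_peaks(x, 2426.0))
    edited = ibim.correct_missing_artifacts(
        series, pads, bounds_ms=ibim.IBI_BOUNDS_MS[bounds_key])
    return edited, truth


def mape_vs_truth(series, truth):
    """MAPE (%) of an interval series against the prescribed ground truth.

    Each interval is compared with the prescribed interval active at its
    midpoint (step lookup on the true beat grid), so the metric is robust to
    inserted or removed beats.
    """
    mids = (series.beat_times[:-1] + series.beat_times[1:]) / 2.0
    idx = np.clip(np.searchsorted(truth.beat_times[:-1], mids, side="right") - 1,
                  0, len(truth.ibi_ms) - 1)
    ref = truth.ibi_ms[idx]
    return float(np.mean(np.abs(ref - series.ibi_ms) / ref) * 100.0)


@pytest.fixture(scope="session")
def clean_ecg_5min():
    """5 min noiseless ECG with 0.25 Hz, 100 ms modulation around 800 ms."""
    schedule = [synth.SessionSpec("baseline", 300.0)]
    rec, truth = synth.gen_ecg(schedule, seed=11, noise_sd=0.0)
    return rec, truth


@pytest.fixture(scope="session")
def detected_ibi_5min(clean_ecg_5min):
    rec, truth = clean_ecg_5min
    x = np.concatenate([c.samples for c in rec.by_modality("ecg")])
    beats = ibim.detect_r_peaks(x, 2426.0)
    return ibim.IBISeries.from_beat_times(beats), truth
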