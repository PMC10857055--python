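"""Chunked little-endian binary recording format.

The wearable writes each sensor modality to flash in timestamped chunks
(10 s for audio, 30 s for ECG and IMU), with UTC millisecond stamps at chunk
start and end taken from a battery-backed real-time clock.  Slow SD-card
writes can drop samples at the tail of a chunk; dropped samples are restored
downstream as zero padding, so the on-disk dialect keeps an explicit
run-length-encoded missing-sample mask per chunk to keep padding auditable
(a padded zero is distinguishable from a true zero sample).

File layout (all integers little-endian)::

    header:  magic "LBK1" | firmware version uint8 (1|2) |
             device-id length uint16 + UTF-8 bytes
    chunk:   modality tag uint8 (1=ecg, 2=imu, 3=audio) |
             start_utc uint64 ms | end_utc uint64 ms | n_samples uint32 |
             payload | n_runs uint32 | runs of (start uint32, length uint32)

Payload encodings: ECG uint16 ADC counts; IMU int16 x 9 channels scaled by
(accel 0.01 m/s^2, gyro 0.1 deg/s, magnetometer 0.001 a.u. per LSB); audio
int32 holding 24-bit samples, held in memory as floats in [-1, 1] (value =
int / 2**23).  Round-trips are bit-exact for values on these grids; use
:func:`quantize` to put arbitrary floats on-grid before writing.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

MAGIC = b"LBK1"

NOMINAL_RATES = {"ecg": 2426.0, "imu": 70.0, "audio": 22050.0}
CHUNK_PERIOD_S = {"ecg": 30.0, "imu": 30.0, "audio": 10.0}

_MODALITY_TAG = {"ecg": 1, "imu": 2, "audio": 3}
_TAG_MODALITY = {v: k for k, v in _MODALITY_TAG.items()}

# IMU per-LSB scale factors: accel m/s^2, gyro deg/s, magnetometer a.u.
IMU_SCALES = np.array([0.01] * 3 + [0.1] * 3 + [0.001] * 3)

AUDIO_FULL_SCALE = float(1 << 23)  # 24-bit signed


class FormatError(ValueError):
    """Raised when a file does not follow the documented binary dialect."""


class ValidationError(ValueError):
    """Raised when an in-memory recording violates its invariants."""


@dataclass
class SensorChunk:
    """One timestamped block of samples for one modality.

    ``samples`` is 1-D for ecg/audio and (n, 9) for imu.  ``missing_mask``
    marks zero-padded (dropped-then-restored) samples.
    """

    modality: str
    start_utc: int  # UTC milliseconds
    end_utc: int
    samples: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.modality not in NOMINAL_RATES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.samples = np.asarray(self.samples)
        if self.modality == "imu":
            if self.samples.ndim != 2 or self.samples.shape[1] != 9:
                raise ValidationError("imu samples must have shape (n, 9)")
        elif self.samples.ndim != 1:
            raise ValidationError(f"{self.modality} samples must be 1-D")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(len(self.samples), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(self.missing_mask) != len(self.samples):
            raise ValidationError("missing_mask length must match samples")
        if self.end_utc <= self.start_utc:
            raise ValidationError("end_utc must exceed start_utc")

    @property
    def nominal_rate(self) -> float:
        return NOMINAL_RATES[self.modality]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return (self.end_utc - self.start_utc) / 1000.0

    def expected_samples(self) -> int:
        """Sample count implied by the UTC span and the nominal rate."""
        return int(round(self.duration_s * self.nominal_rate))

    def sample_times_ms(self) -> np.ndarray:
        """Nominal per-sample UTC stamps (uniform from chunk start)."""
        step = 1000.0 / self.nominal_rate
        return self.start_utc + step * np.arange(self.n_samples)

    def validate(self) -> None:
        if np.any(self.samples[self.missing_mask] != 0):
            raise ValidationError("padded samples must be exactly zero")


@dataclass
class Recording:
    """Chunks for up to three modalities from one device session."""

    chunks: list[SensorChunk] = field(default_factory=list)
    firmware_version: str = "v2"
    device_id: str = ""

    def by_modality(self, modality: str) -> list[SensorChunk]:
        out = [c for c in self.chunks if c.modality == modality]
        return sorted(out, key=lambda c: c.start_utc)

    @property
    def modalities(self) -> list[str]:
        return sorted({c.modality for c in self.chunks})

    def validate(self) -> None:
        if self.firmware_version not in ("v1", "v2"):
            raise ValidationError(f"bad firmware version {self.firmware_version!r}")
        for modality in self.modalities:
            prev_end = None
            for c in self.by_modality(modality):
                c.validate()
                if prev_end is not None and c.start_utc < prev_end:
                    raise ValidationError(f"overlapping {modality} chunks")
                prev_end = c.end_utc


def quantize(chunk: SensorChunk) -> SensorChunk:
    """Snap sample values onto the on-disk integer grids (in place)."""
    if chunk.modality == "ecg":
        chunk.samples = np.clip(np.round(chunk.samples), 0, 0xFFFF).astype(np.float64)
    elif chunk.modality == "imu":
        q = np.clip(np.round(chunk.samples / IMU_SCALES), -32768, 32767)
        chunk.samples = q * IMU_SCALES
    else:
        q = np.clip(np.round(chunk.samples * AUDIO_FULL_SCALE), -AUDIO_FULL_SCALE, AUDIO_FULL_SCALE - 1)
        chunk.samples = q / AUDIO_FULL_SCALE
    chunk.samples[chunk.missing_mask] = 0.0  # boolean row mask also zeroes imu rows
    return chunk


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        runs = [(int(s), int(e - s + 1)) for s, e in zip(starts, ends)]
    return runs


def _encode_payload(chunk: SensorChunk) -> bytes:
    if chunk.modality == "ecg":
        return np.round(chunk.samples).astype("<u2").tobytes()
    if chunk.modality == "imu":
        return np.round(chunk.samples / IMU_SCALES).astype("<i2").tobytes()
    return np.round(chunk.samples * AUDIO_FULL_SCALE).astype("<i4").tobytes()


def _decode_payload(modality: str, n: int, raw: bytes) -> np.ndarray:
    if modality == "ecg":
        return np.frombuffer(raw, dtype="<u2", count=n).astype(np.float64)
    if modality == "imu":
        flat = np.frombuffer(raw, dtype="<i2", count=9 * n).astype(np.float64)
        return flat.reshape(n, 9) * IMU_SCALES
    return np.frombuffer(raw, dtype="<i4", count=n).astype(np.float64) / AUDIO_FULL_SCALE


def _payload_nbytes(modality: str, n: int) -> int:
    return {"ecg": 2 * n, "imu": 18 * n, "audio": 4 * n}[modality]


def write_recording(recording: Recording, path: str | Path) -> int:
    """Serialize a recording; returns the number of bytes written.

    Sample values must sit on the on-disk grids (see :func:`quantize`) for
    the round trip to be bit-exact; padded samples are written as zeros.
    """
    recording.validate()
    parts = [MAGIC]
    parts.append(struct.pack("<B", 1 if recording.firmware_version == "v1" else 2))
    dev = recording.device_id.encode("utf-8")
    parts.append(struct.pack("<H", len(dev)))
    parts.append(dev)
    for chunk in recording.chunks:
        parts.append(struct.pack("<BQQI", _MODALITY_TAG[chunk.modality],
                                 chunk.start_utc, chunk.end_utc, chunk.n_samples))
        parts.append(_encode_payload(chunk))
        runs = _mask_runs(chunk.missing_mask)
        parts.append(struct.pack("<I", len(runs)))
        for start, length in runs:
            parts.append(struct.pack("<II", start, length))
    blob = b"".join(parts)
    Path(path).write_bytes(blob)
    return len(blob)


def read_recording(path: str | Path) -> Recording:
    """Parse a recording file; a malformed trailing chunk is dropped with a warning."""
    blob = Path(path).read_bytes()
    if blob[:4] != MAGIC:
        raise FormatError(f"bad magic {blob[:4]!r}")
    off = 4
    (fw,) = struct.unpack_from("<B", blob, off)
    off += 1
    if fw not in (1, 2):
        raise FormatError(f"unknown format/firmware version {fw}")
    (ndev,) = struct.unpack_from("<H", blob, off)
    off += 2
    device_id = blob[off:off + ndev].decode("utf-8")
    off += ndev

    chunks: list[SensorChunk] = []
    while off < len(blob):
        try:
            tag, start, end, n = struct.unpack_from("<BQQI", blob, off)
            off2 = off + struct.calcsize("<BQQI")
            modality = _TAG_MODALITY[tag]
            nbytes = _payload_nbytes(modality, n)
            if off2 + nbytes + 4 > len(blob):
                raise struct.error("truncated payload")
            samples = _decode_payload(modality, n, blob[off2:off2 + nbytes])
            off2 += nbytes
            (n_runs,) = struct.unpack_from("<I", blob, off2)
            off2 += 4
            if off2 + 8 * n_runs > len(blob):
                raise struct.error("truncated mask")
            mask = np.zeros(n, dtype=bool)
            for _ in range(n_runs):
                rs, rl = struct.unpack_from("<II", blob, off2)
                off2 += 8
                mask[rs:rs + rl] = True
        except (struct.error, KeyError):
            logger.warning("truncated or malformed trailing chunk at byte %d; dropped", off)
            break
        chunks.append(SensorChunk(modality, start, end, samples, mask))
        off = off2
    return Recording(chunks=chunks, firmware_version="v1" if fw == 1 else "v2",
                     device_id=device_id)


def export(recording: Recording, out_dir: str | Path) -> dict[str, Path]:
    """Export to human-readable files: CSV for ECG/IMU, 16-bit PCM WAV for audio.

    Returns a mapping modality -> written path; empty modalities emit no file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    ecg_chunks = recording.by_modality("ecg")
    if ecg_chunks:
        frames = [
            pd.DataFrame({
                "utc_ms": c.sample_times_ms(),
                "adc": c.samples.astype(int),
                "padded": c.missing_mask.astype(int),
            })
            for c in ecg_chunks
        ]
        path = out_dir / "ecg.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written["ecg"] = path

    imu_chunks = recording.by_modality("imu")
    if imu_chunks:
        cols = ["ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]
        frames = []
        for c in imu_chunks:
            df = pd.DataFrame(c.samples, columns=cols)
            df.insert(0, "utc_ms", c.sample_times_ms())
            df["padded"] = c.missing_mask.astype(int)
            frames.append(df)
        path = out_dir / "imu.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written["imu"] = path

    audio_chunks = recording.by_modality("audio")
    if audio_chunks:
        wave = np.concatenate([c.samples for c in audio_chunks])
        pcm = np.clip(np.round(wave * 32767.0), -32768, 32767).astype(np.int16)
        path = out_dir / "audio.wav"
        wavfile.write(path, int(NOMINAL_RATES["audio"]), pcm)
        written["audio"] = path
    return written


def missing_fraction(chunks: list[SensorChunk]) -> float:
    """Proportion of expected samples that are absent or padded.

    Expected counts come from each chunk's UTC span times the nominal rate;
    observed counts exclude padded samples.  Invariant under chunk order.
    """
    if not chunks:
        raise ValueError("missing_fraction requires at least one chunk")
    expected = sum(c.expected_samples() for c in chunks)
    if expected <= 0:
        raise ValueError("zero expected samples")
    observed = sum(int(np.sum(~c.missing_mask)) for c in chunks)
    return 1.0 - observed / expected
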