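"""Binary codec: round trips, export shapes, missing-sample accounting."""

import numpy as np
import pytest
from scipy.io import wavfile

from triad import codec
from triad.codec import Recording, SensorChunk, quantize


def _random_recording(seed: int, n_chunks: int = 3) -> Recording:
    rng = np.random.default_rng(seed)
    chunks = []
    t = 1_700_000_000_000  # some UTC ms epoch
    for _ in range(n_chunks):
        modality = rng.choice(["ecg", "imu", "audio"])
        period = codec.CHUNK_PERIOD_S[modality]
        n = int(period * codec.NOMINAL_RATES[modality])
        n_obs = n - int(rng.integers(0, n // 10))
        if modality == "ecg":
            samples = rng.integers(0, 4096, n_obs).astype(float)
        elif modality == "imu":
            samples = rng.normal(0, 5, (n_obs, 9))
        else:
            samples = rng.uniform(-1, 1, n_obs)
        mask = rng.random(n_obs) < 0.02
        chunk = SensorChunk(modality, t, t + int(period * 1000), samples, mask)
        chunks.append(quantize(chunk))
        t += int(period * 1000)
    return Recording(chunks=chunks, firmware_version="v1", device_id="dev-042")


def _recordings_equal(a: Recording, b: Recording) -> bool:
    if (a.firmware_version, a.device_id, len(a.chunks)) != (
            b.firmware_version, b.device_id, len(b.chunks)):
        return False
    return all(
        ca.modality == cb.modality
        and ca.start_utc == cb.start_utc and ca.end_utc == cb.end_utc
        and np.array_equal(ca.samples, cb.samples)
        and np.array_equal(ca.missing_mask, cb.missing_mask)
        for ca, cb in zip(a.chunks, b.chunks)
    )


class TestRoundTrip:
    def test_empty_recording(self, tmp_path):
        rec = Recording(firmware_version="v2", device_id="empty")
        path = tmp_path / "empty.lbk"
        n = codec.write_recording(rec, path)
        assert n > 0
        back = codec.read_recording(path)
        assert _recordings_equal(rec, back)

    def test_single_ecg_chunk_expected_length(self, tmp_path):
        # 30 s at 2426 Hz is 72 780 samples
        n = int(30 * 2426)
        assert n == 72_780
        samples = np.arange(n, dtype=float) % 4096
        rec = Recording(chunks=[SensorChunk("ecg", 0, 30_000, samples)],
                        firmware_version="v1")
        codec.write_recording(rec, tmp_path / "one.lbk")
        back = codec.read_recording(tmp_path / "one.lbk")
        assert np.array_equal(back.chunks[0].samples, samples)

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_identity(self, tmp_path, seed):
        rec = _random_recording(seed)
        path = tmp_path / f"r{seed}.lbk"
        codec.write_recording(rec, path)
        assert _recordings_equal(rec, codec.read_recording(path))

    @pytest.mark.parametrize("fw", ["v1", "v2"])
    def test_firmware_flag_preserved(self, tmp_path, fw):
        rec = Recording(firmware_version=fw, device_id="x")
        codec.write_recording(rec, tmp_path / "fw.lbk")
        assert codec.read_recording(tmp_path / "fw.lbk").firmware_version == fw

    def test_truncated_file_drops_last_chunk(self, tmp_path, caplog):
        rec = _random_recording(1, n_chunks=3)
        path = tmp_path / "t.lbk"
        codec.write_recording(rec, path)
        blob = path.read_bytes()
        path.write_bytes(blob[:-1000])
        with caplog.at_level("WARNING"):
            back = codec.read_recording(path)
        assert len(back.chunks) == 2
        assert _recordings_equal(
            Recording(rec.chunks[:2], rec.firmware_version, rec.device_id), back)
        assert any("truncated" in r.message for r in caplog.records)

    def test_bad_magic_raises(self, tmp_path):
        path = tmp_path / "bad.lbk"
        path.write_bytes(b"NOPE" + b"\x00" * 64)
        with pytest.raises(codec.FormatError):
            codec.read_recording(path)

    def test_padded_nonzero_sample_rejected(self, tmp_path):
        samples = np.ones(100)
        mask = np.zeros(100, dtype=bool)
        mask[10] = True
        chunk = SensorChunk("ecg", 0, 30_000, samples, mask)
        rec = Recording(chunks=[chunk])
        with pytest.raises(codec.ValidationError):
            codec.write_recording(rec, tmp_path / "x.lbk")


class TestExport:
    def test_ecg_csv_row_count_and_columns(self, tmp_path):
        import pandas as pd
        n = 500
        chunk = SensorChunk("ecg", 0, 30_000, np.arange(n, dtype=float))
        rec = Recording(chunks=[chunk])
        written = codec.export(rec, tmp_path)
        df = pd.read_csv(written["ecg"])
        assert list(df.columns) == ["utc_ms", "adc", "padded"]
        assert len(df) == n

    def test_audio_wav_frame_count(self, tmp_path):
        n = 10 * 22_050
        chunk = SensorChunk("audio", 0, 10_000, np.zeros(n))
        written = codec.export(Recording(chunks=[chunk]), tmp_path)
        sr, wave = wavfile.read(written["audio"])
        assert sr == 22_050
        assert len(wave) == 220_500

    def test_empty_modality_emits_no_file(self, tmp_path):
        chunk = SensorChunk("ecg", 0, 30_000, np.zeros(10))
        written = codec.export(Recording(chunks=[chunk]), tmp_path)
        assert set(written) == {"ecg"}
        assert not (tmp_path / "audio.wav").exists()


class TestMissingFraction:
    def test_no_padding_is_zero(self):
        n = 72_780
        chunk = SensorChunk("ecg", 0, 30_000, np.zeros(n))
        assert codec.missing_fraction([chunk]) == pytest.approx(0.0)

    @pytest.mark.parametrize("observed,expected_frac", [(913, 0.087), (977, 0.023)])
    def test_arithmetic(self, observed, expected_frac):
        # expected 1000 samples from the UTC span; some were never written
        rate = codec.NOMINAL_RATES["ecg"]
        span_ms = int(round(1000 / rate * 1000))
        chunk = SensorChunk("ecg", 0, span_ms, np.zeros(observed))
        assert codec.missing_fraction([chunk]) == pytest.approx(expected_frac, abs=1e-9)

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        chunks = []
        for i in range(4):
            n_obs = int(rng.integers(500, 1000))
            span_ms = int(round(1000 / codec.NOMINAL_RATES["ecg"] * 1000))
            chunks.append(SensorChunk("ecg", i * 40_000, i * 40_000 + span_ms,
                                      np.zeros(n_obs)))
        f1 = codec.missing_fraction(chunks)
        f2 = codec.missing_fraction(chunks[::-1])
        assert f1 == pytest.approx(f2)

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError):
            codec.missing_fraction([])
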