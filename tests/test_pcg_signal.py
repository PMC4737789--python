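import numpy as np
import pytest
from scipy.io import wavfile
from scipy.signal import sosfreqz

from cadscore.errors import (
    FormatError,
    InsufficientDataError,
    ParameterError,
    UnsupportedRateError,
)
from cadscore.pcg_signal import (
    PCGRecording,
    assess_quality,
    bandlimit,
    bandpass_sos,
    read_recording,
)
from cadscore.segmentation import detect_cycles
from cadscore.simulator import SubjectParams, add_noise_bursts, simulate_pcg


def _write_wav(path, data, rate=8000):
    wavfile.write(str(path), rate, data)


class TestReadRecording:
    def test_zeros_roundtrip(self, tmp_path):
        p = tmp_path / "z.wav"
        _write_wav(p, np.zeros(80000, dtype=np.int16))
        rec = read_recording(p)
        assert rec.duration == pytest.approx(10.0)
        assert rec.samples.size == 80000

    def test_full_scale_int16_sine_normalises_to_unit_peak(self, tmp_path):
        t = np.arange(8000) / 8000
        data = (32767 * np.sin(2 * np.pi * 100 * t[:8000])).astype(np.int16)
        data[100] = 32767  # guarantee an exact full-scale sample
        p = tmp_path / "s.wav"
        _write_wav(p, data)
        rec = read_recording(p)
        assert np.max(np.abs(rec.samples)) == pytest.approx(1.0)

    def test_stereo_keeps_first_channel(self, tmp_path):
        left = (1000 * np.ones(16000)).astype(np.int16)
        right = np.zeros(16000, dtype=np.int16)
        p = tmp_path / "st.wav"
        _write_wav(p, np.column_stack([left, right]))
        rec = read_recording(p)
        assert np.all(rec.samples > 0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_recording(tmp_path / "nope.wav")

    def test_unsupported_rate(self, tmp_path):
        p = tmp_path / "lo.wav"
        _write_wav(p, np.zeros(4000, dtype=np.int16), rate=1000)
        with pytest.raises(UnsupportedRateError):
            read_recording(p)

    def test_sidecar_metadata(self, tmp_path):
        p = tmp_path / "m.wav"
        _write_wav(p, np.zeros(80000, dtype=np.int16))
        p.with_suffix(".yaml").write_text(
            "subject_id: abc\nbreath_hold_intervals: [[1.0, 3.0], [5.0, 7.0]]\n"
        )
        rec = read_recording(p)
        assert rec.subject_id == "abc"
        assert rec.breath_hold_intervals == [(1.0, 3.0), (5.0, 7.0)]


class TestBandlimit:
    @staticmethod
    def _tone(freq, fs=8000, dur=5.0):
        t = np.arange(int(fs * dur)) / fs
        return PCGRecording(samples=np.sin(2 * np.pi * freq * t), sample_rate=fs)

    def test_stopband_tone_attenuated(self):
        rec = self._tone(10.0)
        out = bandlimit(rec, 20.0, 1000.0)
        assert np.sqrt(np.mean(out.samples**2)) < 0.01 * np.sqrt(np.mean(rec.samples**2))

    def test_passband_tone_preserved(self):
        rec = self._tone(100.0)
        out = bandlimit(rec, 20.0, 1000.0)
        ratio = np.sqrt(np.mean(out.samples**2)) / np.sqrt(np.mean(rec.samples**2))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_white_noise_power_matches_fft_mask_oracle(self, rng):
        # forward-backward filtering applies |H|^2 in amplitude, so white
        # noise keeps the fraction mean(|H|^4) of its power
        fs = 8000
        rec = PCGRecording(samples=rng.standard_normal(fs * 8), sample_rate=fs)
        out = bandlimit(rec, 20.0, 1000.0)
        sos = bandpass_sos(20.0, 1000.0, fs)
        _, h = sosfreqz(sos, worN=4096, fs=fs)
        expected = float(np.mean(np.abs(h) ** 4))
        measured = float(np.var(out.samples) / np.var(rec.samples))
        assert measured == pytest.approx(expected, rel=0.10)

    def test_idempotent_on_heart_sound_content(self, clean_60bpm):
        # in-band content passes a second application almost unchanged
        rec, _ = clean_60bpm
        once = bandlimit(rec, 20.0, 1000.0)
        twice = bandlimit(once, 20.0, 1000.0)
        r1 = np.sqrt(np.mean(once.samples**2))
        r2 = np.sqrt(np.mean(twice.samples**2))
        assert abs(r2 - r1) / r1 < 0.01

    def test_band_outside_nyquist(self):
        rec = self._tone(100.0)
        with pytest.raises(ParameterError):
            bandlimit(rec, 20.0, 5000.0)


class TestQualityGates:
    def test_clean_recording_ok(self, clean_60bpm):
        rec, _ = clean_60bpm
        cycles = detect_cycles(rec)
        q = assess_quality(rec, cycles)
        assert q.status == "ok"
        assert q.heart_rate_bpm == pytest.approx(60.0, abs=1.0)

    def test_tachycardia_gate(self):
        rec, _ = simulate_pcg(SubjectParams(heart_rate_bpm=95.0, seed=3),
                              duration_s=20.0, breath_holds=None)
        q = assess_quality(rec, detect_cycles(rec))
        assert q.status == "arrhythmia"

    def test_rr_variability_gate(self):
        rec, truth = simulate_pcg(
            SubjectParams(heart_rate_bpm=60.0, rr_jitter_frac=0.20, seed=4),
            duration_s=30.0, breath_holds=None,
        )
        q = assess_quality(rec, truth)
        assert q.rr_cv > 0.12
        assert q.status == "arrhythmia"

    def test_excess_noise_gate(self, clean_60bpm):
        rec, truth = clean_60bpm
        from cadscore.segmentation import extract_windows

        windows = extract_windows(rec, truth)
        n_noisy = int(round(0.6 * len(windows)))
        noisy = add_noise_bursts(
            rec, [(w.start, w.end) for w in windows[:n_noisy]], amplitude=0.3, seed=0
        )
        q = assess_quality(noisy, detect_cycles(noisy))
        assert q.noisy_window_fraction > 0.5
        assert q.status == "excess_noise"

    def test_weak_signal_gate(self):
        rec, truth = simulate_pcg(
            SubjectParams(
                heart_rate_bpm=60.0, s1_amp=0.004, s2_amp=0.003,
                s3_amp=0.0, s4_amp=0.0,
                murmur_low_gain_db=-np.inf, murmur_high_gain_db=-np.inf,
                noise_floor_db=-40.0, seed=5,
            ),
            duration_s=20.0, breath_holds=None,
        )
        q = assess_quality(rec, truth)
        assert q.s1_snr_db < 6.0
        assert q.status == "weak_signal"

    def test_too_few_cycles(self, clean_60bpm):
        rec, truth = clean_60bpm
        with pytest.raises(InsufficientDataError):
            assess_quality(rec, truth[:5])

    @pytest.mark.parametrize("bpm", [45.0, 75.0, 100.0])
    def test_heart_rate_recovered_within_1_bpm(self, bpm):
        rec, truth = simulate_pcg(SubjectParams(heart_rate_bpm=bpm, seed=6),
                                  duration_s=25.0, breath_holds=None)
        q = assess_quality(rec, detect_cycles(rec))
        true_rate = 60.0 / np.mean([c.rr_interval for c in truth])
        assert q.heart_rate_bpm == pytest.approx(true_rate, abs=1.0)
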