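"""Phonocardiogram I/O, band-limiting and recording-level quality gating.

A recording is a single acoustic channel captured at the 4th left
intercostal space.  Recordings that cannot be scored reliably are excluded
before feature extraction, mirroring the three clinical exclusion labels:
arrhythmia/tachycardia, excess noise, and a heart signal too weak relative
to the background floor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

from .config import DEFAULT_CONFIG, AlgorithmConfig
from .errors import (
    FormatError,
    InsufficientDataError,
    ParameterError,
    UnsupportedRateError,
)

log = logging.getLogger(__name__)

MIN_SAMPLE_RATE_HZ = 2000.0


@dataclass
class PCGRecording:
    """A mono phonocardiogram with acquisition metadata.

    ``samples`` are linear amplitudes normalised to [-1, 1];
    ``breath_hold_intervals`` are (start_s, end_s) pairs delimiting the
    breath-hold portions of the protocol.  When present, only cardiac
    cycles fully inside a breath-hold are analysed.
    """

    samples: np.ndarray
    sample_rate: float
    subject_id: str = ""
    breath_hold_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if self.sample_rate < MIN_SAMPLE_RATE_HZ:
            raise UnsupportedRateError(
                f"sample rate {self.sample_rate} Hz < {MIN_SAMPLE_RATE_HZ} Hz "
                "(cannot resolve 1000 Hz content)"
            )
        if self.samples.size == 0:
            raise FormatError("recording contains no samples")
        ivals = sorted(self.breath_hold_intervals)
        for (a, b) in ivals:
            if not (0.0 <= a < b <= self.duration + 1e-9):
                raise ParameterError(f"breath-hold interval ({a}, {b}) outside recording")
        for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ParameterError("breath-hold intervals overlap")
        self.breath_hold_intervals = [tuple(map(float, iv)) for iv in ivals]

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class QualityReport:
    """Recording-level quality gate result.

    ``status`` is ``ok`` only when the heart rate is at most the tachycardia
    limit and all gates pass; otherwise it names the first failed gate.
    """

    status: str  # ok | arrhythmia | excess_noise | weak_signal
    heart_rate_bpm: float
    rr_cv: float
    noisy_window_fraction: float
    s1_snr_db: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


_INT_FULL_SCALE = {
    np.dtype(np.int16): 32767.0,
    np.dtype(np.int32): 2147483647.0,
}


def read_recording(path: str | Path, subject_id: Optional[str] = None) -> PCGRecording:
    """Read a PCM or float WAV file into a normalised :class:`PCGRecording`.

    Integer encodings are scaled by their positive full-scale value so a
    full-scale sine maps to peak 1.0.  Stereo files keep the first channel
    (with a warning).  A metadata sidecar ``<path>.yaml`` / ``.json``
    (subject_id, breath_hold_intervals) is honoured when present.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - map any read failure
        raise FormatError(f"unreadable WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"empty WAV file: {path}")
    if data.ndim == 2:
        log.warning("%s: %d channels; keeping the first", path.name, data.shape[1])
        data = data[:, 0]
    if rate < MIN_SAMPLE_RATE_HZ:
        raise UnsupportedRateError(f"{path}: sample rate {rate} Hz unsupported")

    if data.dtype in _INT_FULL_SCALE:
        samples = data.astype(np.float64) / _INT_FULL_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned with midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64)

    meta = _read_sidecar(path)
    return PCGRecording(
        samples=samples,
        sample_rate=float(rate),
        subject_id=subject_id or meta.get("subject_id", path.stem),
        breath_hold_intervals=[tuple(iv) for iv in meta.get("breath_hold_intervals", [])],
    )


def _read_sidecar(path: Path) -> dict:
    for suffix, loader in ((".yaml", yaml.safe_load), (".yml", yaml.safe_load), (".json", json.load)):
        side = path.with_suffix(suffix)
        if side.exists():
            with open(side) as fh:
                return loader(fh) or {}
    return {}


def bandpass_sos(low_hz: float, high_hz: float, sample_rate: float, order: int = 4):
    if not (0.0 < low_hz < high_hz < sample_rate / 2.0):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={sample_rate} Hz"
        )
    return butter(order, [low_hz, high_hz], btype="bandpass", fs=sample_rate, output="sos")


def bandlimit_samples(
    samples: np.ndarray,
    sample_rate: float,
    low_hz: float,
    high_hz: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a raw sample array."""
    sos = bandpass_sos(low_hz, high_hz, sample_rate, order)
    return sosfiltfilt(sos, samples)


def bandlimit(
    rec: PCGRecording,
    low_hz: float,
    high_hz: float,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> PCGRecording:
    """Zero-phase band-pass of a recording (forward-backward Butterworth).

    The forward-backward pass squares the magnitude response, giving
    >= 40 dB attenuation one octave outside the band at order 4 while
    preserving envelope timing exactly (zero phase).
    """
    out = bandlimit_samples(rec.samples, rec.sample_rate, low_hz, high_hz, config.filter_order)
    return PCGRecording(
        samples=out,
        sample_rate=rec.sample_rate,
        subject_id=rec.subject_id,
        breath_hold_intervals=list(rec.breath_hold_intervals),
    )


def resample(rec: PCGRecording, target_rate_hz: int) -> PCGRecording:
    """Polyphase resampling to the internal analysis rate."""
    if int(rec.sample_rate) == int(target_rate_hz):
        return rec
    frac = Fraction(int(target_rate_hz), int(rec.sample_rate)).limit_denominator(1000)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator)
    return PCGRecording(
        samples=out,
        sample_rate=float(target_rate_hz),
        subject_id=rec.subject_id,
        breath_hold_intervals=list(rec.breath_hold_intervals),
    )


def smoothed_envelope(
    samples: np.ndarray, sample_rate: float, smooth_s: float = 0.020
) -> np.ndarray:
    """Hilbert magnitude envelope smoothed with a Hann-weighted moving average."""
    env = np.abs(hilbert(samples))
    n = max(3, int(round(smooth_s * sample_rate)))
    win = np.hanning(n)
    win /= win.sum()
    return np.convolve(env, win, mode="same")


def assess_quality(
    rec: PCGRecording,
    cycles: Sequence,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> QualityReport:
    """Gate a recording on rhythm regularity, noise burden and S1 strength.

    Gates (first failure wins): arrhythmia when the RR coefficient of
    variation exceeds ``rr_cv_max`` or the heart rate exceeds the
    tachycardia limit; excess noise when more than ``noisy_fraction_max``
    of candidate diastasis windows carry more than
    ``noisy_window_power_ratio`` times the median broadband envelope power;
    weak signal when the median S1 envelope peak sits less than
    ``s1_snr_min_db`` above the background floor.
    """
    from .segmentation import locate_diastasis  # local import; segmentation uses our types
    from .errors import DegenerateWindowError

    if len(cycles) < config.min_cycles_for_quality:
        raise InsufficientDataError(
            f"{len(cycles)} cycles < {config.min_cycles_for_quality} required for quality gating"
        )

    rr = np.array([c.rr_interval for c in cycles], dtype=float)
    heart_rate = 60.0 / float(np.mean(rr))
    rr_cv = float(np.std(rr) / np.mean(rr))

    broadband = bandlimit_samples(
        rec.samples, rec.sample_rate, config.band_low_hz,
        min(config.band_high_hz, rec.sample_rate / 2 * 0.95), config.filter_order,
    )
    env = smoothed_envelope(broadband, rec.sample_rate, config.envelope_smooth_s)
    fs = rec.sample_rate

    window_powers = []
    for c in cycles:
        try:
            w = locate_diastasis(c, rec, config)
        except DegenerateWindowError:
            continue
        i0, i1 = int(w.start * fs), int(w.end * fs)
        if i1 > i0:
            window_powers.append(float(np.mean(env[i0:i1] ** 2)))
    if window_powers:
        # lower-quartile reference: stays clean even when most windows are
        # contaminated (a median reference saturates above 50 % noisy)
        ref = float(np.percentile(window_powers, config.noisy_reference_percentile))
        noisy = sum(p > config.noisy_window_power_ratio * ref for p in window_powers)
        noisy_fraction = noisy / len(window_powers)
        floor = float(np.sqrt(ref))
    else:
        noisy_fraction = 0.0
        floor = float(np.median(env))

    s1_peaks = []
    for c in cycles:
        i0 = max(0, int(c.s1_onset * fs))
        i1 = min(env.size, int((c.s1_onset + 0.12) * fs))
        if i1 > i0:
            s1_peaks.append(float(np.max(env[i0:i1])))
    s1_peak = float(np.median(s1_peaks)) if s1_peaks else 0.0
    s1_snr_db = (
        20.0 * np.log10(s1_peak / floor) if s1_peak > 0 and floor > 0 else -np.inf
    )

    if heart_rate > config.max_heart_rate_bpm or rr_cv > config.rr_cv_max:
        status = "arrhythmia"
    elif noisy_fraction > config.noisy_fraction_max:
        status = "excess_noise"
    elif s1_snr_db < config.s1_snr_min_db:
        status = "weak_signal"
    else:
        status = "ok"

    return QualityReport(
        status=status,
        heart_rate_bpm=float(heart_rate),
        rr_cv=rr_cv,
        noisy_window_fraction=float(noisy_fraction),
        s1_snr_db=float(s1_snr_db),
    )


def write_recording(path: str | Path, rec: PCGRecording) -> None:
    """Write a recording as 16-bit PCM WAV plus a YAML metadata sidecar."""
    path = Path(path)
    peak = float(np.max(np.abs(rec.samples))) or 1.0
    scaled = np.clip(rec.samples / max(peak, 1.0), -1.0, 1.0)
    wavfile.write(str(path), int(rec.sample_rate), (scaled * 32767).astype(np.int16))
    meta = {
        "subject_id": rec.subject_id,
        "breath_hold_intervals": [list(iv) for iv in rec.breath_hold_intervals],
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
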