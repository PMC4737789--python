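"""Heart-cycle detection and mid-diastolic (diastasis) window extraction.

The analysis window is the quiescent diastasis period between the third and
fourth heart sounds.  When no S4 is identified the window is ended 50 ms
before the next S1; windows shorter than 128 ms are flagged short and only
contribute to the reduced (AMI + S4) feature path.

Cycle detection is ECG-free: a smoothed Hilbert envelope of the 20-200 Hz
band, an autocorrelation estimate of the beat period, peak picking, and
systole/diastole disambiguation by interval ordering (the S1->S2 interval
is the shorter intra-beat interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .config import DEFAULT_CONFIG, AlgorithmConfig
from .errors import DegenerateWindowError, ParameterError, SegmentationError
from .pcg_signal import PCGRecording, bandlimit_samples, smoothed_envelope

log = logging.getLogger(__name__)


@dataclass
class CardiacCycle:
    """Per-beat landmarks, all in seconds from the start of the recording."""

    s1_onset: float
    s2_onset: float
    next_s1_onset: float
    s3_onset: Optional[float] = None
    s4_onset: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.s1_onset < self.s2_onset < self.next_s1_onset):
            raise ParameterError("require s1 < s2 < next_s1")
        if self.s3_onset is not None and not (self.s2_onset < self.s3_onset < self.next_s1_onset):
            raise ParameterError("s3 outside (s2, next_s1)")
        if self.s4_onset is not None:
            lo = self.s3_onset if self.s3_onset is not None else self.s2_onset
            if not (lo < self.s4_onset < self.next_s1_onset):
                raise ParameterError("s4 outside (s3, next_s1)")

    @property
    def rr_interval(self) -> float:
        return self.next_s1_onset - self.s1_onset


@dataclass
class DiastasisWindow:
    """The extracted mid-diastolic analysis segment, half-open [start, end)."""

    start: float
    end: float
    samples: np.ndarray
    short_diastasis: bool
    cycle_index: int

    @property
    def length_s(self) -> float:
        return self.end - self.start


def _estimate_period(env: np.ndarray, fs: float, config: AlgorithmConfig) -> float:
    """Beat period via the autocorrelation peak in the [min_bpm, max_bpm] range."""
    x = env - env.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        raise SegmentationError("flat envelope; no periodicity")
    ac = ac / ac[0]
    lo = int(fs * 60.0 / config.max_bpm)
    hi = min(int(fs * 60.0 / config.min_bpm), n - 1)
    if hi <= lo:
        raise SegmentationError("recording too short for rate estimation")
    k = lo + int(np.argmax(ac[lo:hi]))
    if ac[k] < config.min_autocorr:
        raise SegmentationError(
            f"no cardiac periodicity in [{config.min_bpm}, {config.max_bpm}] bpm "
            f"(autocorrelation {ac[k]:.2f})"
        )
    return k / fs


def detect_cycles(
    rec: PCGRecording, config: AlgorithmConfig = DEFAULT_CONFIG
) -> list[CardiacCycle]:
    """Detect cardiac cycles (S1, S2, and S3/S4 when present).

    S3/S4 are marked present only when the 20-60 Hz envelope peak in their
    physiological search region exceeds ``s34_detect_ratio`` times the
    median envelope level of those regions across the recording.
    """
    if rec.duration < 10.0:
        raise SegmentationError(f"recording of {rec.duration:.1f} s < 10 s minimum")
    fs = rec.sample_rate

    beat = bandlimit_samples(
        rec.samples, fs, config.beat_band_low_hz, config.beat_band_high_hz, config.filter_order
    )
    env = smoothed_envelope(beat, fs, config.envelope_smooth_s)
    period = _estimate_period(env, fs, config)

    # Peak threshold relative to the typical per-beat maximum, so detection
    # is invariant to overall recording gain.
    nblk = max(1, int(period * fs))
    nfull = (env.size // nblk) * nblk
    block_max = env[:nfull].reshape(-1, nblk).max(axis=1)
    thr = config.peak_height_frac * float(np.percentile(block_max, 95))
    peaks, _ = find_peaks(env, height=thr, distance=max(1, int(0.12 * fs)))
    if peaks.size < 4:
        raise SegmentationError("too few envelope peaks above threshold")
    ptimes = peaks / fs

    # S1 starts the shorter (systolic) intra-beat interval.
    s1_times, s2_for_s1 = [], {}
    d = np.diff(ptimes)
    for i in range(ptimes.size - 1):
        if d[i] < 0.5 * period:
            prev_short = i > 0 and d[i - 1] < 0.5 * period
            if not prev_short:
                s1_times.append(ptimes[i])
                s2_for_s1[ptimes[i]] = ptimes[i + 1]

    env34 = smoothed_envelope(
        bandlimit_samples(rec.samples, fs, config.s34_band_low_hz,
                          config.s34_band_high_hz, config.filter_order),
        fs, config.envelope_smooth_s,
    )

    raw: list[dict] = []
    s3_region_levels: list[np.ndarray] = []
    s4_region_levels: list[np.ndarray] = []
    for t1, t1n in zip(s1_times, s1_times[1:]):
        gap = t1n - t1
        if not (0.65 * period <= gap <= 1.35 * period):
            continue
        t2 = s2_for_s1.get(t1)
        if t2 is None or not (t1 < t2 < t1n):
            continue
        s1_onset = t1 - config.s1_half_duration_s
        s2_onset = t2 - config.s2_half_duration_s
        next_s1 = t1n - config.s1_half_duration_s
        # S3 search: early-to-mid diastole; S4 search: 200-50 ms before next S1
        s3_lo = s2_onset + 0.06
        s3_hi = s2_onset + 0.6 * (next_s1 - s2_onset)
        s4_lo = next_s1 - config.s4_search_before_s1_s
        s4_hi = next_s1 - config.s4_search_end_before_s1_s
        seg3 = env34[int(s3_lo * fs): int(s3_hi * fs)]
        seg4 = env34[int(s4_lo * fs): int(s4_hi * fs)]
        if seg3.size == 0 or seg4.size == 0:
            continue
        s3_region_levels.append(seg3)
        s4_region_levels.append(seg4)
        raw.append(dict(s1=s1_onset, s2=s2_onset, n1=next_s1,
                        s3_lo=s3_lo, s4_lo=s4_lo, seg3=seg3, seg4=seg4))
    if not raw:
        raise SegmentationError("no consistent beat sequence found")

    med3 = float(np.median(np.concatenate(s3_region_levels)))
    med4 = float(np.median(np.concatenate(s4_region_levels)))
    # absolute floor: a real S3/S4 must carry a minimum fraction of the S1
    # low-frequency envelope, so near-silent diastoles yield no detections
    s1_peaks = []
    for r in raw:
        i0 = max(0, int(r["s1"] * fs))
        i1 = min(env34.size, int((r["s1"] + 0.12) * fs))
        if i1 > i0:
            s1_peaks.append(float(np.max(env34[i0:i1])))
    abs_floor = config.s34_min_rel_s1 * (float(np.median(s1_peaks)) if s1_peaks else 0.0)

    cycles: list[CardiacCycle] = []
    for r in raw:
        s3_onset = s4_onset = None
        thr3 = max(config.s34_detect_ratio * med3, abs_floor)
        thr4 = max(config.s34_detect_ratio * med4, abs_floor)
        if med3 > 0 and float(r["seg3"].max()) > thr3:
            s3_onset = r["s3_lo"] + int(np.argmax(r["seg3"])) / fs - config.s34_half_duration_s
        if med4 > 0 and float(r["seg4"].max()) > thr4:
            s4_onset = r["s4_lo"] + int(np.argmax(r["seg4"])) / fs - config.s34_half_duration_s
        if s3_onset is not None and not (r["s2"] < s3_onset < r["n1"]):
            s3_onset = None
        if s4_onset is not None:
            lo = s3_onset if s3_onset is not None else r["s2"]
            if not (lo < s4_onset < r["n1"]):
                s4_onset = None
        cycles.append(CardiacCycle(
            s1_onset=float(r["s1"]), s2_onset=float(r["s2"]),
            next_s1_onset=float(r["n1"]),
            s3_onset=None if s3_onset is None else float(s3_onset),
            s4_onset=None if s4_onset is None else float(s4_onset),
        ))
    return cycles


def locate_diastasis(
    cycle: CardiacCycle,
    rec: PCGRecording,
    config: AlgorithmConfig = DEFAULT_CONFIG,
    cycle_index: int = 0,
) -> DiastasisWindow:
    """Extract the diastasis window of one cycle.

    Start: end of S3 (onset + nominal S3 duration) when S3 was detected,
    otherwise ``s2_onset + diastole_start_frac * RR``.  End: S4 onset when
    detected, otherwise 50 ms before the next S1.  Windows shorter than
    128 ms are flagged ``short_diastasis``.
    """
    if cycle.s3_onset is not None:
        start = cycle.s3_onset + config.s3_duration_s
    else:
        start = cycle.s2_onset + config.diastole_start_frac * cycle.rr_interval
    if cycle.s4_onset is not None:
        end = cycle.s4_onset
    else:
        end = cycle.next_s1_onset - config.pre_s1_guard_s
    if end <= start:
        raise DegenerateWindowError(
            f"cycle {cycle_index}: window [{start:.3f}, {end:.3f}) non-positive"
        )
    fs = rec.sample_rate
    i0 = max(0, int(round(start * fs)))
    i1 = min(rec.samples.size, i0 + int(round((end - start) * fs)))
    return DiastasisWindow(
        start=float(start),
        end=float(end),
        samples=rec.samples[i0:i1].copy(),
        short_diastasis=(end - start) < config.short_diastasis_s,
        cycle_index=cycle_index,
    )


def extract_windows(
    rec: PCGRecording,
    cycles: Sequence[CardiacCycle],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> list[DiastasisWindow]:
    """Diastasis windows for all cycles, skipping degenerate ones with a log entry."""
    windows = []
    for i, c in enumerate(cycles):
        try:
            windows.append(locate_diastasis(c, rec, config, cycle_index=i))
        except DegenerateWindowError as exc:
            log.info("skipping cycle: %s", exc)
    return windows


def filter_cycles_to_breath_holds(
    cycles: Sequence[CardiacCycle], intervals: Sequence[tuple[float, float]]
) -> list[CardiacCycle]:
    """Keep cycles fully inside a breath-hold interval; all cycles if none given."""
    if not intervals:
        return list(cycles)
    out = []
    for c in cycles:
        if any(a <= c.s1_onset and c.next_s1_onset <= b for a, b in intervals):
            out.append(c)
    return out


def export_labels(path: str, cycles: Sequence[CardiacCycle],
                  windows: Sequence[DiastasisWindow]) -> None:
    """Write landmarks/windows as a tab-separated (start, end, label) file."""
    with open(path, "w") as fh:
        for c in cycles:
            fh.write(f"{c.s1_onset:.4f}\t{c.s1_onset:.4f}\tS1\n")
            fh.write(f"{c.s2_onset:.4f}\t{c.s2_onset:.4f}\tS2\n")
            if c.s3_onset is not None:
                fh.write(f"{c.s3_onset:.4f}\t{c.s3_onset:.4f}\tS3\n")
            if c.s4_onset is not None:
                fh.write(f"{c.s4_onset:.4f}\t{c.s4_onset:.4f}\tS4\n")
        for w in windows:
            label = "diastasis_short" if w.short_diastasis else "diastasis"
            fh.write(f"{w.start:.4f}\t{w.end:.4f}\t{label}\n")
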