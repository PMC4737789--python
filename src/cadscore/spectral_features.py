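"""The four acoustic measures computed from diastasis windows.

* FPR    - frequency power ratio: log10 of low-band (20-150 Hz) over
           high-band (150-1000 Hz) diastolic power.
* PCASpec - projection of the 20-1000 Hz diastolic power spectrum (dB) onto
           the first principal component of a training corpus of spectra.
* AMI    - auto-mutual information, a complexity measure: histogram mutual
           information between the signal and its lagged copy, averaged
           over lags of 0.5-12.5 ms at 2 kHz, in bits.
* S4Amp  - peak of the 20-60 Hz envelope in the S4 region, normalised by
           the median S1 envelope peak.

FPR and PCASpec require windows of at least 128 ms; subjects in whom most
windows are shorter ("short diastasis") are scored from AMI and S4Amp only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy.signal import resample_poly, welch

from .config import DEFAULT_CONFIG, AlgorithmConfig
from .errors import (
    DegenerateModelError,
    NormalizationError,
    ParameterError,
    ShortDiastasisError,
)
from .pcg_signal import PCGRecording, bandlimit_samples, resample, smoothed_envelope
from .segmentation import (
    CardiacCycle,
    DiastasisWindow,
    detect_cycles,
    extract_windows,
    filter_cycles_to_breath_holds,
)

log = logging.getLogger(__name__)


@dataclass
class PowerSpectrum:
    """Mean diastolic power spectrum on the 20-1000 Hz grid, in dB."""

    freqs: np.ndarray
    power_db: np.ndarray
    n_windows: int


@dataclass
class FeatureVector:
    """The four acoustic measures for one recording.

    ``fpr`` and ``pcaspec`` are ``None`` when the subject has short
    diastasis (most windows < 128 ms).
    """

    fpr: Optional[float]
    pcaspec: Optional[float]
    ami: float
    s4amp: float
    short_diastasis: bool

    def as_full_array(self) -> np.ndarray:
        return np.array([self.fpr, self.pcaspec, self.ami, self.s4amp], dtype=float)

    def as_reduced_array(self) -> np.ndarray:
        return np.array([self.ami, self.s4amp], dtype=float)


@dataclass
class PCAModel:
    """First principal axis of mean-centred dB spectra on a fixed grid."""

    freqs: np.ndarray
    mean_spectrum: np.ndarray
    loading: np.ndarray          # unit Euclidean norm
    explained_variance_fraction: float

    def to_dict(self) -> dict:
        return {
            "freqs": self.freqs.tolist(),
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loading": self.loading.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            freqs=np.asarray(d["freqs"], dtype=float),
            mean_spectrum=np.asarray(d["mean_spectrum"], dtype=float),
            loading=np.asarray(d["loading"], dtype=float),
            explained_variance_fraction=float(d["explained_variance_fraction"]),
        )


def mean_spectrum(
    windows: Sequence[DiastasisWindow],
    sample_rate: float,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> PowerSpectrum:
    """Welch spectrum per window (128 ms Hann segments, 50 % overlap),
    averaged on the linear power scale across windows, expressed in dB and
    restricted to the 20-1000 Hz band.  Only windows >= 128 ms contribute."""
    nperseg = int(round(config.welch_segment_s * sample_rate))
    eligible = [w for w in windows if w.samples.size >= nperseg]
    if not eligible:
        raise ShortDiastasisError("no diastasis window reaches 128 ms")
    acc = None
    for w in eligible:
        f, p = welch(
            w.samples, fs=sample_rate, window="hann",
            nperseg=nperseg, noverlap=nperseg // 2, detrend=False,
        )
        acc = p if acc is None else acc + p
    mean_p = acc / len(eligible)
    lo, hi = config.band_low_hz, config.band_high_hz
    mask = (f >= lo) & (f <= hi)
    floor = 10.0 ** (config.spectrum_floor_db / 10.0)
    power_db = 10.0 * np.log10(np.maximum(mean_p[mask], floor))
    return PowerSpectrum(freqs=f[mask], power_db=power_db, n_windows=len(eligible))


def feature_fpr(spec: PowerSpectrum, config: AlgorithmConfig = DEFAULT_CONFIG) -> float:
    """log10( power(20-150 Hz) / power(150-1000 Hz) ) on the linear scale."""
    linear = 10.0 ** (spec.power_db / 10.0)
    split = config.fpr_split_hz
    low = float(np.sum(linear[spec.freqs < split]))
    high = float(np.sum(linear[spec.freqs >= split]))
    floor = 10.0 ** (config.spectrum_floor_db / 10.0)
    n_high = int(np.sum(spec.freqs >= split))
    if high <= floor * max(n_high, 1) * 1.01:
        log.warning("FPR denominator at spectral floor; substituting floor power")
        high = floor * max(n_high, 1)
    return float(np.log10(max(low, floor) / high))


def fit_pca_spec(
    spectra: Sequence[PowerSpectrum], config: AlgorithmConfig = DEFAULT_CONFIG
) -> PCAModel:
    """First principal axis of the training spectra (dB scale).

    Sign convention: the loading's mean over bins below the FPR split
    frequency is positive, so more low-frequency diastolic power projects
    to larger values (the disease direction).
    """
    if len(spectra) < 10:
        raise ParameterError(f"need >= 10 spectra to fit the spectral PCA, got {len(spectra)}")
    grid = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != grid.shape or not np.allclose(s.freqs, grid):
            raise ParameterError("spectra are not on a common frequency grid")
    X = np.stack([s.power_db for s in spectra])
    mean = X.mean(axis=0)
    Xc = X - mean
    if float(np.max(np.abs(Xc))) < 1e-12:
        raise DegenerateModelError("all training spectra identical; PCA undefined")
    _, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    evf = float(sv[0] ** 2 / np.sum(sv**2))
    if float(np.mean(loading[grid < config.fpr_split_hz])) < 0:
        loading = -loading
    return PCAModel(
        freqs=grid.copy(), mean_spectrum=mean, loading=loading,
        explained_variance_fraction=evf,
    )


def feature_pcaspec(spec: PowerSpectrum, model: PCAModel) -> float:
    """Projection of a spectrum onto the trained first principal axis."""
    if spec.freqs.shape != model.freqs.shape or not np.allclose(spec.freqs, model.freqs):
        raise ParameterError("spectrum grid does not match the PCA model grid")
    return float(np.dot(model.loading, spec.power_db - model.mean_spectrum))


def _equiprobable_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=np.int64)
    ranks[order] = np.arange(x.size)
    return (ranks * n_bins) // x.size


def feature_ami(
    samples: np.ndarray,
    sample_rate: float,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> float:
    """Auto-mutual information of one diastasis window, in bits.

    The signal is decimated to 2 kHz, amplitudes are mapped to 16
    equiprobable bins, and the joint-histogram mutual information
    I(x_t; x_{t+tau}) is averaged over lags tau = 1..25 samples.
    Constant windows return 0 by convention.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < int(config.ami_min_window_s * sample_rate):
        raise ParameterError("window shorter than the AMI minimum (64 ms)")
    if int(sample_rate) != config.ami_rate_hz:
        frac = Fraction(config.ami_rate_hz, int(sample_rate)).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    if np.ptp(x) < 1e-15:
        log.warning("constant window; AMI defined as 0")
        return 0.0
    b = _equiprobable_bins(x, config.ami_bins)
    total = 0.0
    n_lags = 0
    for tau in range(1, config.ami_max_lag + 1):
        if b.size - tau < 2:
            break
        total += _histogram_mi_bits(b[:-tau], b[tau:], config.ami_bins)
        n_lags += 1
    return total / n_lags if n_lags else 0.0


def _histogram_mi_bits(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    joint = np.zeros((n_bins, n_bins), dtype=np.float64)
    np.add.at(joint, (a, b), 1.0)
    joint /= a.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def feature_s4amp(
    cycle: CardiacCycle,
    rec: PCGRecording,
    config: AlgorithmConfig = DEFAULT_CONFIG,
    env34: Optional[np.ndarray] = None,
    s1_reference: Optional[float] = None,
) -> float:
    """Normalised S4 amplitude for one cycle.

    Peak of the 20-60 Hz envelope in the S4 search region
    [next_s1 - 200 ms, next_s1 - 50 ms], divided by the median S1 envelope
    peak across the recording.  Returns 0 when the region sits below the
    noise floor (peak < ``s4_floor_ratio`` x median envelope).

    ``env34`` and ``s1_reference`` can be precomputed once per recording.
    """
    fs = rec.sample_rate
    if env34 is None:
        env34 = s4_envelope(rec, config)
    if s1_reference is None:
        i0 = max(0, int(cycle.s1_onset * fs))
        i1 = min(env34.size, int((cycle.s1_onset + 0.12) * fs))
        s1_reference = float(np.max(env34[i0:i1])) if i1 > i0 else 0.0
    if not np.isfinite(s1_reference) or s1_reference <= 0:
        raise NormalizationError("no S1 reference amplitude available")
    lo = cycle.next_s1_onset - config.s4_search_before_s1_s
    hi = cycle.next_s1_onset - config.s4_search_end_before_s1_s
    i0, i1 = max(0, int(lo * fs)), min(env34.size, int(hi * fs))
    if i1 <= i0:
        return 0.0
    peak = float(np.max(env34[i0:i1]))
    if peak < config.s4_floor_ratio * float(np.median(env34)):
        return 0.0
    return peak / s1_reference


def s4_envelope(rec: PCGRecording, config: AlgorithmConfig = DEFAULT_CONFIG) -> np.ndarray:
    return smoothed_envelope(
        bandlimit_samples(rec.samples, rec.sample_rate, config.s34_band_low_hz,
                          config.s34_band_high_hz, config.filter_order),
        rec.sample_rate, config.s4_envelope_smooth_s,
    )


def _s1_reference(rec: PCGRecording, cycles: Sequence[CardiacCycle],
                  env34: np.ndarray, config: AlgorithmConfig) -> float:
    fs = rec.sample_rate
    peaks = []
    for c in cycles:
        i0 = max(0, int(c.s1_onset * fs))
        i1 = min(env34.size, int((c.s1_onset + 0.12) * fs))
        if i1 > i0:
            peaks.append(float(np.max(env34[i0:i1])))
    if not peaks:
        raise NormalizationError("no S1 peaks found for amplitude normalisation")
    return float(np.median(peaks))


def recording_spectrum(
    rec: PCGRecording,
    config: AlgorithmConfig = DEFAULT_CONFIG,
    cycles: Optional[Sequence[CardiacCycle]] = None,
) -> PowerSpectrum:
    """Mean diastolic spectrum of one recording (segments + averages windows)."""
    rec, cycles, windows = _prepare(rec, config, cycles)
    return mean_spectrum(windows, rec.sample_rate, config)


def _prepare(rec, config, cycles=None):
    rec = resample(rec, config.internal_rate_hz)
    band = PCGRecording(
        samples=bandlimit_samples(rec.samples, rec.sample_rate, config.band_low_hz,
                                  config.band_high_hz, config.filter_order),
        sample_rate=rec.sample_rate, subject_id=rec.subject_id,
        breath_hold_intervals=list(rec.breath_hold_intervals),
    )
    if cycles is None:
        cycles = detect_cycles(rec, config)
    cycles = filter_cycles_to_breath_holds(cycles, rec.breath_hold_intervals)
    windows = extract_windows(band, cycles, config)
    return band, cycles, windows


def extract_features(
    rec: PCGRecording,
    pca_model: Optional[PCAModel] = None,
    config: AlgorithmConfig = DEFAULT_CONFIG,
    cycles: Optional[Sequence[CardiacCycle]] = None,
) -> FeatureVector:
    """Full feature extraction for one recording.

    Orchestrates segmentation, window acceptance and per-window features.
    The recording-level short-diastasis flag is set when more than half of
    the accepted windows are shorter than 128 ms; FPR/PCASpec are then
    omitted.  PCASpec additionally requires a trained :class:`PCAModel`.
    """
    band, cycles, windows = _prepare(rec, config, cycles)
    return _features_from_prepared(band, cycles, windows, pca_model, config)


def _features_from_prepared(
    band: PCGRecording,
    cycles: Sequence[CardiacCycle],
    windows: Sequence[DiastasisWindow],
    pca_model: Optional[PCAModel],
    config: AlgorithmConfig,
) -> FeatureVector:
    if not windows:
        raise ShortDiastasisError("no usable diastasis windows in recording")
    fs = band.sample_rate

    short_frac = float(np.mean([w.short_diastasis for w in windows]))
    short = short_frac > config.short_recording_frac

    min_ami = int(config.ami_min_window_s * fs)
    ami_vals = [feature_ami(w.samples, fs, config) for w in windows
                if w.samples.size >= min_ami]
    ami = float(np.mean(ami_vals)) if ami_vals else 0.0

    env34 = s4_envelope(band, config)
    s1_ref = _s1_reference(band, cycles, env34, config)
    s4_vals = [feature_s4amp(c, band, config, env34=env34, s1_reference=s1_ref)
               for c in cycles]
    s4amp = float(np.mean(s4_vals)) if s4_vals else 0.0

    fpr = pcaspec = None
    if not short:
        spec = mean_spectrum(windows, fs, config)
        fpr = feature_fpr(spec, config)
        if pca_model is not None:
            pcaspec = feature_pcaspec(spec, pca_model)
    return FeatureVector(fpr=fpr, pcaspec=pcaspec, ami=ami, s4amp=s4amp,
                         short_diastasis=short)


def extract_cohort_features(
    recordings: Sequence[PCGRecording],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> tuple[list[FeatureVector], PCAModel]:
    """One-pass cohort extraction: fits the spectral PCA on the cohort's
    diastolic spectra, then returns the completed feature vectors."""
    prepared = [_prepare(rec, config) for rec in recordings]
    spectra: list[Optional[PowerSpectrum]] = []
    for band, _, windows in prepared:
        try:
            spectra.append(mean_spectrum(windows, band.sample_rate, config))
        except ShortDiastasisError:
            spectra.append(None)
    usable = [s for s in spectra if s is not None]
    pca = fit_pca_spec(usable, config)
    features = [
        _features_from_prepared(band, cycles, windows, pca, config)
        for band, cycles, windows in prepared
    ]
    return features, pca


def export_spectrum(path: str, spec: PowerSpectrum) -> None:
    """Two-column (Hz, dB) text export of a spectrum for plotting."""
    np.savetxt(path, np.column_stack([spec.freqs, spec.power_db]),
               fmt="%.4f", header="freq_hz\tpower_db", delimiter="\t")
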