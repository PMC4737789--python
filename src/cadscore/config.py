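"""Algorithm configuration.

Every threshold the pipeline uses is collected here so that quality gates,
band edges, detector settings and score calibration are explicit and
overridable (from Python or from a YAML file).  Defaults are the package's
documented operating point; see docs/methods.md for the rationale behind
each value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ParameterError

#: Default coefficient table for the updated pre-test-probability model
#: (logistic in age, male sex and chest-pain type).  Shipped as data, not
#: code: replace it wholesale via ``AlgorithmConfig.df_coefficients`` to use
#: a different published table.
DEFAULT_DF_COEFFICIENTS: dict[str, float] = {
    "intercept": -7.539,
    "age": 0.062,
    "male": 1.332,
    "non_anginal": 0.0,
    "atypical": 0.633,
    "typical": 2.244,
}


@dataclass
class AlgorithmConfig:
    # --- band limiting / resampling ---
    band_low_hz: float = 20.0
    band_high_hz: float = 1000.0
    filter_order: int = 4              # Butterworth, applied forward-backward
    internal_rate_hz: int = 8000       # single FFT grid for spectra <= 1 kHz

    # --- quality gates ---
    max_heart_rate_bpm: float = 85.0   # tachycardia exclusion
    rr_cv_max: float = 0.12            # RR coefficient of variation gate
    noisy_window_power_ratio: float = 4.0   # window power vs reference => noisy
    noisy_reference_percentile: float = 25.0  # clean-power reference quantile
    noisy_fraction_max: float = 0.50        # fraction of noisy windows gate
    s1_snr_min_db: float = 6.0              # weak-signal gate
    min_cycles_for_quality: int = 10

    # --- cycle detection ---
    beat_band_low_hz: float = 20.0
    beat_band_high_hz: float = 200.0
    envelope_smooth_s: float = 0.020
    min_bpm: float = 40.0
    max_bpm: float = 120.0
    peak_height_frac: float = 0.4      # of the typical per-beat envelope max
    min_autocorr: float = 0.15         # periodicity acceptance
    s1_half_duration_s: float = 0.035
    s2_half_duration_s: float = 0.030
    s34_half_duration_s: float = 0.025

    # --- S3/S4 detection & diastasis window ---
    s34_band_low_hz: float = 20.0
    s34_band_high_hz: float = 60.0
    s34_detect_ratio: float = 3.5      # envelope peak vs region median
    s34_min_rel_s1: float = 0.05       # and vs the S1 low-band envelope
    s3_duration_s: float = 0.060       # nominal S3 duration (window start)
    diastole_start_frac: float = 0.15  # fallback start: s2 + frac * RR
    pre_s1_guard_s: float = 0.050      # window end when no S4: S1 - 50 ms
    short_diastasis_s: float = 0.128   # spectral minimum window length
    short_recording_frac: float = 0.5  # >50 % short windows => short subject

    # --- spectrum / FPR ---
    welch_segment_s: float = 0.128     # Hann segments, 50 % overlap
    spectrum_floor_db: float = -120.0
    fpr_split_hz: float = 150.0        # low band [20, split), high [split, 1000]

    # --- AMI ---
    ami_rate_hz: int = 2000
    ami_bins: int = 16                 # equiprobable amplitude bins
    ami_max_lag: int = 25              # lags 1..25 samples (0.5-12.5 ms)
    ami_min_window_s: float = 0.064

    # --- S4 amplitude ---
    s4_search_before_s1_s: float = 0.20
    s4_search_end_before_s1_s: float = 0.05
    s4_floor_ratio: float = 2.0        # below this x median envelope => 0
    s4_envelope_smooth_s: float = 0.008  # light smoothing preserves peak ratios

    # --- scoring ---
    score_mean: float = 25.0           # calibration target of training scores
    score_sd: float = 12.0
    lda_ridge: float = 1e-6
    score_low_max: float = 20.0        # value <= 20  -> low
    score_intermediate_max: float = 30.0   # 20 < value <= 30 -> intermediate
    cutpoint_method: str = "liu"       # or "youden"

    # --- risk models ---
    risk_thresholds: tuple[float, float, float] = (10.0, 30.0, 60.0)
    cacs_high_threshold: float = 400.0
    df_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DF_COEFFICIENTS)
    )

    def replace(self, **kwargs: Any) -> "AlgorithmConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "AlgorithmConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "risk_thresholds" in raw:
            raw["risk_thresholds"] = tuple(raw["risk_thresholds"])
        return cls(**raw)


DEFAULT_CONFIG = AlgorithmConfig()
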