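import math
from collections import Counter

import numpy as np
import pytest

from cadscore.errors import DegenerateModelError, ParameterError
from cadscore.segmentation import DiastasisWindow
from cadscore.simulator import SubjectParams, simulate_pcg
from cadscore.spectral_features import (
    PCAModel,
    PowerSpectrum,
    extract_features,
    feature_ami,
    feature_fpr,
    feature_pcaspec,
    feature_s4amp,
    fit_pca_spec,
    mean_spectrum,
    s4_envelope,
)

FS = 8000.0


def _windows_from(signal_fn, n_windows, length_s=0.3, seed=0):
    rng = np.random.default_rng(seed)
    n = int(length_s * FS)
    out = []
    for i in range(n_windows):
        out.append(DiastasisWindow(
            start=0.0, end=length_s, samples=signal_fn(rng, n),
            short_diastasis=False, cycle_index=i,
        ))
    return out


class TestMeanSpectrum:
    def test_pure_tone_peak_location(self):
        t = np.arange(int(0.3 * FS)) / FS
        windows = _windows_from(lambda rng, n: np.sin(2 * np.pi * 100 * t), 5)
        spec = mean_spectrum(windows, FS)
        peak_freq = spec.freqs[np.argmax(spec.power_db)]
        bin_width = spec.freqs[1] - spec.freqs[0]
        assert abs(peak_freq - 100.0) <= bin_width

    def test_white_noise_flat_within_6db(self):
        windows = _windows_from(lambda rng, n: rng.standard_normal(n), 50)
        spec = mean_spectrum(windows, FS)
        assert spec.power_db.max() - spec.power_db.min() <= 6.0

    def test_silence_at_floor(self):
        windows = _windows_from(lambda rng, n: np.zeros(n), 3)
        spec = mean_spectrum(windows, FS)
        assert np.all(spec.power_db == -120.0)

    def test_short_windows_excluded(self):
        long = _windows_from(lambda rng, n: rng.standard_normal(n), 2)
        short = _windows_from(lambda rng, n: rng.standard_normal(n), 3, length_s=0.1)
        spec = mean_spectrum(long + short, FS)
        assert spec.n_windows == 2


class TestFPR:
    @staticmethod
    def _flat_spectrum():
        freqs = np.arange(3, 129) * 7.8125  # the 8 kHz / 1024-point Welch grid
        return PowerSpectrum(freqs=freqs, power_db=np.zeros(freqs.size), n_windows=1)

    def test_flat_spectrum_bandwidth_ratio(self):
        fpr = feature_fpr(self._flat_spectrum())
        assert fpr == pytest.approx(math.log10(130 / 850), abs=0.05)

    def test_tone_concentration_floored_denominator(self):
        t = np.arange(int(0.3 * FS)) / FS
        windows = _windows_from(lambda rng, n: np.sin(2 * np.pi * 100 * t), 3)
        spec = mean_spectrum(windows, FS)
        assert feature_fpr(spec) >= 2.0

    def test_murmur_low_gain_shifts_fpr_by_one(self, murmur_pair):
        from cadscore.spectral_features import recording_spectrum

        fprs = {}
        for gain, (rec, truth) in murmur_pair.items():
            spec = recording_spectrum(rec, cycles=truth)
            fprs[gain] = feature_fpr(spec)
        assert fprs[10.0] - fprs[0.0] == pytest.approx(1.0, abs=0.1)


class TestPCASpec:
    @staticmethod
    def _grid():
        return np.arange(3, 129) * 7.8125

    def _spectra(self, X):
        return [PowerSpectrum(freqs=self._grid(), power_db=row, n_windows=1) for row in X]

    def test_single_factor_recovered(self, rng):
        grid = self._grid()
        v = np.exp(-((grid - 80) ** 2) / (2 * 40.0**2))  # low-frequency shape
        vhat = v / np.linalg.norm(v)
        coeffs = rng.normal(0, 2.0, size=30)
        base = np.full(grid.size, -60.0)
        spectra = self._spectra([base + c * v for c in coeffs])
        model = fit_pca_spec(spectra)
        assert np.allclose(np.abs(model.loading @ vhat), 1.0, atol=1e-6)
        scores = [feature_pcaspec(s, model) for s in spectra]
        centred = (coeffs - coeffs.mean()) * np.linalg.norm(v)
        assert np.allclose(scores, centred, atol=1e-6)

    def test_two_mode_variance_fraction(self, rng):
        grid = self._grid()
        v1 = np.zeros(grid.size); v1[:40] = 1.0; v1 /= np.linalg.norm(v1)
        v2 = np.zeros(grid.size); v2[40:80] = 1.0; v2 /= np.linalg.norm(v2)
        n = 2000
        X = (np.full((n, grid.size), -50.0)
             + np.outer(rng.normal(0, 3.0, n), v1)
             + np.outer(rng.normal(0, 1.0, n), v2))
        model = fit_pca_spec(self._spectra(X))
        assert model.explained_variance_fraction == pytest.approx(0.9, abs=0.02)

    def test_identical_spectra_degenerate(self):
        spectra = self._spectra(np.tile(np.full(self._grid().size, -50.0), (10, 1)))
        with pytest.raises(DegenerateModelError):
            fit_pca_spec(spectra)

    def test_projection_identities(self, rng):
        grid = self._grid()
        X = np.full((12, grid.size), -50.0) + rng.normal(0, 1, (12, grid.size))
        model = fit_pca_spec(self._spectra(X))
        at_mean = PowerSpectrum(grid, model.mean_spectrum.copy(), 1)
        assert feature_pcaspec(at_mean, model) == pytest.approx(0.0, abs=1e-9)
        shifted = PowerSpectrum(grid, model.mean_spectrum + 2.0 * model.loading, 1)
        assert feature_pcaspec(shifted, model) == pytest.approx(2.0, abs=1e-9)

    def test_grid_mismatch(self, rng):
        grid = self._grid()
        model = fit_pca_spec(self._spectra(
            np.full((10, grid.size), -50.0) + rng.normal(0, 1, (10, grid.size))))
        other = PowerSpectrum(grid[:-1], np.zeros(grid.size - 1), 1)
        with pytest.raises(ParameterError):
            feature_pcaspec(other, model)

    def test_disease_direction_positive(self, murmur_pair):
        # sign convention: more low-frequency diastolic power projects higher
        from cadscore.spectral_features import recording_spectrum

        specs = {g: recording_spectrum(rec, cycles=truth)
                 for g, (rec, truth) in murmur_pair.items()}
        extra = []
        for seed in range(10, 18):
            rec, truth = simulate_pcg(
                SubjectParams(seed=seed, murmur_low_gain_db=5.0 * (seed % 2)),
                duration_s=20.0, breath_holds=None)
            extra.append(recording_spectrum(rec, cycles=truth))
        model = fit_pca_spec(list(specs.values()) + extra)
        assert feature_pcaspec(specs[10.0], model) > feature_pcaspec(specs[0.0], model)


def _ami_oracle(x, n_bins=16, max_lag=25):
    """Independent brute-force AMI: rank binning + Counter-based joint MI."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    b = [0] * len(x)
    for rank, idx in enumerate(order):
        b[idx] = (rank * n_bins) // len(x)
    total = 0.0
    for tau in range(1, max_lag + 1):
        pairs = list(zip(b[:-tau], b[tau:]))
        n = len(pairs)
        joint, pa, pb = Counter(pairs), Counter(b[:-tau]), Counter(b[tau:])
        mi = 0.0
        for (i, j), c in joint.items():
            pij = c / n
            mi += pij * math.log2(pij / ((pa[i] / n) * (pb[j] / n)))
        total += mi
    return total / max_lag


class TestAMI:
    def test_constant_window_zero(self):
        assert feature_ami(np.ones(2000), 2000.0) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(1500)
        assert feature_ami(x, 2000.0) == pytest.approx(_ami_oracle(x), abs=1e-9)

    def test_sine_more_predictable_than_noise(self, rng):
        t = np.arange(2000) / 2000.0
        sine = np.sin(2 * np.pi * 40 * t)
        noise = rng.standard_normal(2000)
        assert feature_ami(sine, 2000.0) > feature_ami(noise, 2000.0)

    def test_iid_noise_small_positive_bias(self, rng):
        x = rng.standard_normal(4096)
        ami = feature_ami(x, 2000.0)
        assert 0.0 < ami < 0.2


class TestS4Amp:
    def test_amplitude_ratio_recovered(self):
        # S4 with the same burst shape as S1 so the peak ratio equals a/b
        rec, truth = simulate_pcg(
            SubjectParams(s4_amp=0.2, seed=20, murmur_low_gain_db=-np.inf,
                          murmur_high_gain_db=-np.inf,
                          sound_shapes={"s4": (45.0, 0.070)}),
            duration_s=20.0, breath_holds=None)
        env = s4_envelope(rec)
        vals = [feature_s4amp(c, rec, env34=env) for c in truth]
        assert np.median(vals) == pytest.approx(0.2, rel=0.10)

    def test_no_s4_near_zero(self):
        rec, truth = simulate_pcg(
            SubjectParams(s4_amp=0.0, seed=21, murmur_low_gain_db=-np.inf,
                          murmur_high_gain_db=-np.inf),
            duration_s=20.0, breath_holds=None)
        env = s4_envelope(rec)
        vals = [feature_s4amp(c, rec, env34=env) for c in truth]
        assert np.median(vals) < 0.05

    def test_doubling_amplitude_doubles_feature(self):
        meds = []
        for amp in (0.15, 0.30):
            rec, truth = simulate_pcg(
                SubjectParams(s4_amp=amp, seed=22, murmur_low_gain_db=-np.inf,
                              murmur_high_gain_db=-np.inf),
                duration_s=20.0, breath_holds=None)
            env = s4_envelope(rec)
            meds.append(np.median([feature_s4amp(c, rec, env34=env) for c in truth]))
        assert meds[1] / meds[0] == pytest.approx(2.0, rel=0.10)


class TestExtractFeatures:
    def test_healthy_60bpm_all_features_present(self, clean_60bpm):
        rec, _ = clean_60bpm
        fv = extract_features(rec)
        assert not fv.short_diastasis
        assert fv.fpr is not None
        assert fv.ami > 0 and fv.s4amp > 0

    def test_115bpm_reduced_features_only(self):
        rec, _ = simulate_pcg(SubjectParams(heart_rate_bpm=115.0, seed=23),
                              duration_s=25.0, breath_holds=None)
        fv = extract_features(rec)
        assert fv.short_diastasis
        assert fv.fpr is None and fv.pcaspec is None
        assert np.isfinite(fv.ami) and np.isfinite(fv.s4amp)

    def test_deterministic(self, clean_60bpm):
        rec, _ = clean_60bpm
        a = extract_features(rec)
        b = extract_features(rec)
        assert (a.fpr, a.pcaspec, a.ami, a.s4amp, a.short_diastasis) == \
               (b.fpr, b.pcaspec, b.ami, b.s4amp, b.short_diastasis)
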