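"""Smoothing, baseline, noise estimation, and centroid peak detection."""

import numpy as np
import pytest

import archaeotype as at
from archaeotype.preprocess import _grid_step


def gaussians(mz, centers, amps, sigma=2.5):
    y = np.zeros_like(mz)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return y


GRID = np.arange(2000.0, 20001.0)


class TestSmooth:
    def test_constant_signal_unchanged(self):
        spec = at.RawSpectrum(mz=GRID, intensity=np.full_like(GRID, 7.0))
        out = at.smooth(spec)
        np.testing.assert_allclose(out.intensity, 7.0)

    def test_quadratic_reproduced_exactly(self):
        y = (GRID - 2000.0) ** 2
        out = at.smooth(at.RawSpectrum(mz=GRID, intensity=y))
        np.testing.assert_allclose(out.intensity, y, rtol=1e-8, atol=1e-6)

    def test_window_too_small_is_config_error(self):
        cfg = at.PreprocessConfig(sg_width_mz=1.0, sg_polyorder=2)
        spec = at.RawSpectrum(mz=GRID, intensity=np.zeros_like(GRID))
        with pytest.raises(at.ConfigError):
            at.smooth(spec, cfg)

    def test_non_uniform_grid_rejected(self):
        mz = np.concatenate([np.arange(2000.0, 3000.0), np.arange(3000.0, 5000.0, 2.0)])
        with pytest.raises(at.InputError, match="uniform"):
            at.smooth(at.RawSpectrum(mz=mz, intensity=np.zeros_like(mz)))


class TestSubtractBaseline:
    def test_flat_zero_stays_zero(self, flat_spectrum):
        out = at.subtract_baseline(flat_spectrum)
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_constant_offset_removed_height_kept(self):
        y = gaussians(GRID, [9000.0], [500.0]) + 80.0
        out = at.subtract_baseline(at.RawSpectrum(mz=GRID, intensity=y))
        peak_height = out.intensity[GRID == 9000.0][0]
        assert abs(peak_height - 500.0) / 500.0 < 0.01
        far = out.intensity[GRID == 15000.0][0]
        assert abs(far) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_anti_extensive_output_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        y = np.abs(rng.normal(50, 20, GRID.size)) + gaussians(
            GRID, rng.uniform(3000, 19000, 10), rng.uniform(100, 5000, 10)
        )
        out = at.subtract_baseline(at.RawSpectrum(mz=GRID, intensity=y))
        assert np.all(out.intensity >= 0)

    def test_element_wider_than_spectrum_rejected(self):
        mz = np.arange(2000.0, 2050.0)
        spec = at.RawSpectrum(mz=mz, intensity=np.zeros_like(mz))
        with pytest.raises(at.InputError):
            at.subtract_baseline(spec, at.PreprocessConfig(tophat_width_mz=500.0))


class TestEstimateNoise:
    def test_white_noise_scale_recovered(self):
        rng = np.random.default_rng(42)
        sigma = 13.0
        mz = np.arange(2000.0, 12000.0)
        spec = at.RawSpectrum(mz=mz, intensity=rng.normal(0, sigma, mz.size))
        assert abs(at.estimate_noise(spec) - sigma) / sigma < 0.10

    def test_constant_signal_gives_zero(self):
        mz = np.arange(2000.0, 2100.0)
        assert at.estimate_noise(at.RawSpectrum(mz=mz, intensity=np.full(mz.size, 5.0))) == 0

    def test_robust_to_sparse_tall_peaks(self):
        rng = np.random.default_rng(7)
        sigma = 10.0
        noise = rng.normal(0, sigma, GRID.size)
        plain = at.estimate_noise(at.RawSpectrum(mz=GRID, intensity=noise))
        spiked = noise + gaussians(
            GRID, [3000, 6000, 9000, 12000, 15000], [5000] * 5
        )
        with_peaks = at.estimate_noise(at.RawSpectrum(mz=GRID, intensity=spiked))
        assert abs(with_peaks - plain) / plain < 0.05

    def test_short_spectrum_rejected(self):
        mz = np.arange(2000.0, 2010.0)
        with pytest.raises(at.InputError):
            at.estimate_noise(at.RawSpectrum(mz=mz, intensity=np.zeros(mz.size)))


class TestDetectPeaks:
    def test_flat_zero_gives_empty_list(self, flat_spectrum):
        assert len(at.detect_peaks(flat_spectrum, noise=1.0)) == 0

    def test_five_gaussians_recovered(self):
        rng = np.random.default_rng(1)
        centers = [3000.0, 6000.0, 9000.0, 12000.0, 15000.0]
        sigma_noise = 10.0
        y = gaussians(GRID, centers, [200.0] * 5) + rng.normal(0, sigma_noise, GRID.size)
        spec = at.RawSpectrum(mz=GRID, intensity=y)
        peaks = at.detect_peaks(at.subtract_baseline(at.smooth(spec)),
                                noise=sigma_noise)
        assert len(peaks) == 5
        for c in centers:
            assert np.min(np.abs(peaks.mz - c)) <= 0.5

    def test_cap_keeps_most_intense(self):
        centers = np.arange(2500.0, 2500.0 + 150 * 100, 100.0)
        amps = np.linspace(100.0, 1000.0, 150)
        y = gaussians(GRID, centers, amps)
        peaks = at.detect_peaks(at.RawSpectrum(mz=GRID, intensity=y), noise=1.0)
        assert len(peaks) == 100
        # the 100 tallest planted peaks are the last 100 by amplitude
        expected = set(np.round(centers[50:]).astype(int))
        got = {int(round(p.mz)) for p in peaks}
        assert got == expected

    def test_deterministic_bit_identical(self, strain_model):
        spec, _ = at.simulate_replicate(strain_model, at.SimulationConfig(seed=9))
        a = at.preprocess(spec)
        b = at.preprocess(spec)
        assert a == b

    def test_snr_and_count_invariants(self, strain_model):
        cfg = at.PreprocessConfig()
        for seed in range(5):
            spec, _ = at.simulate_replicate(strain_model, at.SimulationConfig(seed=seed))
            peaks = at.preprocess(spec, cfg)
            assert len(peaks) <= cfg.max_peaks
            assert all(p.snr >= cfg.snr_threshold for p in peaks)

    def test_centroid_bias_small_on_symmetric_peaks(self, strain_model):
        errors = []
        for seed in range(50):
            cfg = at.SimulationConfig(seed=200 + seed)
            spec, truth = at.simulate_replicate(strain_model, cfg)
            peaks = at.preprocess(spec)
            for mz_true, amp in truth.planted:
                if amp / cfg.noise_sd >= 10 and len(peaks):
                    d = peaks.mz - mz_true
                    k = np.argmin(np.abs(d))
                    if abs(d[k]) <= 2.0:
                        errors.append(d[k])
        assert abs(np.mean(errors)) <= 0.2


class TestNormalizeIntensities:
    def test_max_mode_single_peak(self):
        pl = at.PeakList(peaks=(at.Peak(mz=5000.0, intensity=37.0, snr=5.0),))
        out = at.normalize_intensities(pl, mode="max")
        assert out.peaks[0].intensity == 100.0

    def test_base_peak_at_100_with_others_relative(self):
        pl = at.PeakList(peaks=(
            at.Peak(mz=3000.0, intensity=50.0, snr=5.0),
            at.Peak(mz=6148.52, intensity=200.0, snr=5.0),
        ))
        out = at.normalize_intensities(pl, mode="max")
        assert out.peaks[1].intensity == 100.0
        assert out.peaks[0].intensity == 25.0

    def test_tic_mode_sums_to_100(self):
        rng = np.random.default_rng(3)
        pl = at.PeakList(peaks=tuple(
            at.Peak(mz=2000.0 + 10 * k, intensity=float(v), snr=5.0)
            for k, v in enumerate(rng.uniform(1, 100, 20))
        ))
        out = at.normalize_intensities(pl, mode="tic")
        assert abs(sum(p.intensity for p in out) - 100.0) < 1e-9

    def test_empty_list_rejected(self):
        with pytest.raises(at.InputError):
            at.normalize_intensities(at.PeakList(peaks=()))


def test_grid_step_estimates_median_spacing():
    mz = np.arange(2000.0, 3000.0, 0.5)
    assert _grid_step(at.RawSpectrum(mz=mz, intensity=np.zeros(mz.size))) == 0.5
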