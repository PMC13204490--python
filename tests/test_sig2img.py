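"""Signal-to-image transforms: identities, oracles, localization."""

import numpy as np
import pytest

from s2cfl.errors import ConfigurationError, InvalidArgumentError
from s2cfl.sig2img import (
    constant_window_law,
    emd,
    mhht_image,
    mr_stft,
    normalize_image,
    wpt_decompose,
    wpt_image,
)


def naive_gaussian_stft(x, rate, L, freqs, centers):
    """Direct per-(f, t) windowed-DFT loop: the independent MR-STFT oracle."""
    n = x.shape[0]
    half = L // 2
    offs = np.arange(-half, L - half)
    w = np.exp(-0.5 * (offs / (L / 6.0)) ** 2)
    grid = np.zeros((len(freqs), len(centers)))
    for fi, f in enumerate(freqs):
        for ti, c in enumerate(centers):
            acc = 0.0 + 0.0j
            for k, off in enumerate(offs):
                idx = c + off
                if 0 <= idx < n:
                    acc += x[idx] * w[k] * np.exp(-2j * np.pi * f * off / rate)
            grid[fi, ti] = abs(acc) ** 2
    return grid


class TestMRSTFT:
    def test_constant_window_matches_naive_dft(self, rng):
        x = rng.normal(size=256)
        rate, L, F, T = 8.0, 32, 6, 10
        img = mr_stft(x, rate, window_law=constant_window_law(L), F=F, T=T, freq_spacing="linear")
        centers = np.round(img.time_axis * rate).astype(int)
        oracle = naive_gaussian_stft(x, rate, L, img.freq_axis, centers)
        assert np.allclose(img.grid, oracle, rtol=1e-6, atol=1e-10)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        rate, f0 = 10.0, 1.2
        t = np.arange(4000) / rate
        x = np.sin(2 * np.pi * f0 * t)
        img = mr_stft(x, rate, F=48, T=16)
        expect = np.argmin(np.abs(img.freq_axis - f0))
        for col in range(img.grid.shape[1]):
            assert abs(int(np.argmax(img.grid[:, col])) - expect) <= 1

    def test_zero_signal_gives_zero_grid(self):
        img = mr_stft(np.zeros(512), 4.0, F=8, T=8)
        assert np.all(img.grid == 0.0)

    def test_time_translation_shifts_profile(self, rng):
        rate = 4.0
        burst = np.exp(-0.5 * ((np.arange(2048) - 600) / 20.0) ** 2) * np.sin(
            2 * np.pi * 0.8 * np.arange(2048) / rate
        )
        shifted = np.roll(burst, 256)  # 64 s shift
        a = mr_stft(burst, rate, F=16, T=32)
        b = mr_stft(shifted, rate, F=16, T=32)
        prof_a = a.grid.sum(axis=0)
        prof_b = b.grid.sum(axis=0)
        bin_shift = 256 / rate / (a.time_axis[1] - a.time_axis[0])
        assert abs((np.argmax(prof_b) - np.argmax(prof_a)) - bin_shift) <= 1.0


class TestWPT:
    def test_levels_zero_is_identity(self, rng):
        x = rng.normal(size=64)
        tree = wpt_decompose(x, "db4", 0)
        assert len(tree.leaves) == 1
        assert np.allclose(tree.leaves[0], x)

    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=256)
        tree = wpt_decompose(x, "db4", 5)
        assert np.allclose(tree.reconstruct(), x, atol=1e-8)

    def test_parseval_energy_conservation(self, rng):
        x = rng.normal(size=512)
        tree = wpt_decompose(x, "db4", 5)
        coeff_energy = sum(float((leaf**2).sum()) for leaf in tree.leaves)
        assert np.isclose(coeff_energy, float((x**2).sum()), rtol=1e-6)

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ConfigurationError):
            wpt_decompose(np.ones(64), "not-a-wavelet", 2)

    def test_image_shape_and_zero_signal(self):
        img = wpt_image(np.zeros(128), "db4", 4, T=20)
        assert img.grid.shape == (16, 20)
        assert np.all(img.grid == 0.0)

    def test_lowpass_noise_energy_in_bottom_rows(self, rng):
        from scipy.signal import butter, filtfilt

        rate = 16.0
        white = rng.normal(size=4096)
        b, a = butter(6, (rate / 2) / 16 / (rate / 2))  # lowest octave of [0, nyquist]
        x = filtfilt(b, a, white)
        levels = 4
        tree = wpt_decompose(x, "db4", levels)
        leaf_energy = np.array([(leaf**2).sum() for leaf in tree.leaves])
        oracle_ratio = leaf_energy[: 2 ** (levels - 1)].sum() / leaf_energy.sum()
        img = wpt_image(x, "db4", levels, T=32, rate=rate)
        bottom = img.grid[: 2 ** (levels - 1)].sum() / img.grid.sum()
        assert oracle_ratio >= 0.9
        assert bottom == pytest.approx(oracle_ratio, abs=0.05)
        assert bottom >= 0.9


class TestEMD:
    def test_monotone_ramp_yields_no_imfs(self):
        x = np.linspace(0.0, 5.0, 100)
        result = emd(x)
        assert result.imfs == []
        assert np.allclose(result.residue, x)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_identity(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        result = emd(x)
        assert np.allclose(result.reconstruct(), x, atol=1e-8)

    def test_first_imf_captures_fast_component(self):
        rate = 100.0
        t = np.arange(1000) / rate
        x = np.sin(2 * np.pi * 2.0 * t) + 0.8 * np.sin(2 * np.pi * 20.0 * t)
        result = emd(x, max_imfs=6)
        imf1 = result.imfs[0]
        spec = np.abs(np.fft.rfft(imf1))
        fdom = np.fft.rfftfreq(imf1.shape[0], 1.0 / rate)[np.argmax(spec)]
        assert abs(fdom - 20.0) / 20.0 < 0.2

    def test_imf_extrema_zero_crossing_admissibility(self):
        rate = 100.0
        t = np.arange(1000) / rate
        x = np.sin(2 * np.pi * 2.0 * t) + 0.8 * np.sin(2 * np.pi * 20.0 * t)
        imf1 = emd(x, max_imfs=4).imfs[0]
        n_zc = int(np.sum(np.diff(np.sign(imf1)) != 0))
        d = np.diff(imf1)
        n_ext = int(np.sum((d[:-1] > 0) & (d[1:] < 0)) + np.sum((d[:-1] < 0) & (d[1:] > 0)))
        assert abs(n_zc - n_ext) <= 2  # interior-extrema counting tolerance

    def test_rejects_tiny_or_nonfinite_input(self):
        with pytest.raises(InvalidArgumentError):
            emd(np.ones(4))
        with pytest.raises(InvalidArgumentError):
            emd(np.array([1.0, np.nan] * 10))


class TestMHHT:
    def test_sinusoid_energy_centered_at_frequency(self):
        rate, f0 = 20.0, 2.0
        t = np.arange(2000) / rate
        x = np.sin(2 * np.pi * f0 * t)
        img = mhht_image(x, rate, n_scales=2, F=40, T=20)
        total = img.grid.sum()
        mean_f = float((img.grid.sum(axis=1) * img.freq_axis).sum() / total)
        assert abs(mean_f - f0) / f0 < 0.15

    def test_single_scale_equals_plain_hht(self, rng):
        x = rng.normal(size=512)
        a = mhht_image(x, 8.0, n_scales=1, F=16, T=16)
        # independent plain-HHT path: EMD + Hilbert + histogram, no pyramid
        from scipy.signal import hilbert

        from s2cfl.sig2img import emd as _emd

        res = _emd(x, max_imfs=6)
        f_edges = np.linspace(0, 4.0, 17)
        t_edges = np.linspace(0, 64.0, 17)
        grid = np.zeros((16, 16))
        ts = np.arange(512) / 8.0
        for imf in res.imfs:
            an = hilbert(imf)
            freq = np.clip(np.gradient(np.unwrap(np.angle(an))) * 8.0 / (2 * np.pi), 0, 4.0)
            h, _, _ = np.histogram2d(freq, ts, bins=[f_edges, t_edges], weights=np.abs(an) ** 2)
            grid += h
        assert np.allclose(a.grid, grid, rtol=1e-10, atol=1e-10)

    def test_zero_signal_and_scale_limit(self):
        img = mhht_image(np.zeros(256), 4.0, n_scales=2, F=8, T=8)
        assert np.all(img.grid == 0.0)
        with pytest.raises(ConfigurationError):
            mhht_image(np.zeros(64), 4.0, n_scales=5)


class TestNormalize:
    def test_zero_grid_passes_through(self):
        img = mr_stft(np.zeros(256), 4.0, F=8, T=8)
        out = normalize_image(img)
        assert np.all(out.grid == 0.0)

    def test_range_and_argmax_preserved(self, rng):
        x = rng.normal(size=512)
        img = mr_stft(x, 4.0, F=16, T=16)
        out = normalize_image(img)
        assert out.grid.min() >= 0.0 and out.grid.max() <= 1.0
        assert np.unravel_index(np.argmax(out.grid), out.grid.shape) == np.unravel_index(
            np.argmax(img.grid), img.grid.shape
        )
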