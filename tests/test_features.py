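import numpy as np
import pytest

from breathsound.features import (
    FeatureParams,
    band_energy_fraction,
    compute_mfcc,
    compute_spectrogram,
    line_persistence,
    mfcc_feature_vector,
    modulation_peak,
    spectrogram_image,
)

from .oracles import fft_band_energy_fraction, mfcc_bruteforce

SR = 44100


def sine(freq, dur=1.0, sr=SR):
    return np.sin(2 * np.pi * freq * np.arange(int(dur * sr)) / sr)


class TestSpectrogram:
    def test_single_tone_argmax(self):
        spec = compute_spectrogram((sine(1000), SR))
        bin_width = spec.freqs[1] - spec.freqs[0]
        peak_freqs = spec.freqs[np.argmax(spec.power, axis=1)]
        assert np.all(np.abs(peak_freqs - 1000) <= bin_width)

    def test_zero_signal_zero_power(self):
        spec = compute_spectrogram((np.zeros(SR), SR))
        assert np.all(spec.power == 0)

    def test_parseval_oracle(self):
        # spectrogram energy equals windowed time-domain energy per frame
        rng = np.random.default_rng(0)
        x = rng.standard_normal(SR)
        params = FeatureParams()
        spec = compute_spectrogram((x, SR), params)
        frame_len = int(round(params.window_s * SR))
        hop = int(round(params.hop_s * SR))
        from scipy.signal import get_window

        win = get_window("hann", frame_len, fftbins=True)
        time_energy = 0.0
        for i in range(spec.n_frames):
            frame = x[i * hop : i * hop + frame_len] * win
            time_energy += np.sum(frame**2)
        # one-sided FFT: double everything but DC (and Nyquist for even N)
        weights = np.full(spec.power.shape[1], 2.0)
        weights[0] = 1.0
        if frame_len % 2 == 0:
            weights[-1] = 1.0
        spec_energy = np.sum(spec.power * weights) / frame_len
        assert spec_energy == pytest.approx(time_energy, rel=0.01)

    def test_axes(self):
        spec = compute_spectrogram((sine(500, 0.5), SR))
        assert spec.freqs[0] == 0.0
        assert spec.freqs[-1] == pytest.approx(SR / 2)
        assert np.all(np.diff(spec.freqs) > 0)
        assert np.all(np.diff(spec.times) > 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="window"):
            compute_spectrogram((np.zeros(100), SR))

    def test_window_doubling_halves_bin_width(self):
        s1 = compute_spectrogram((sine(1000), SR), FeatureParams(window_s=0.025))
        s2 = compute_spectrogram((sine(1000), SR), FeatureParams(window_s=0.050))
        w1 = s1.freqs[1] - s1.freqs[0]
        w2 = s2.freqs[1] - s2.freqs[0]
        # window lengths round to whole samples, hence the loose tolerance
        assert w2 == pytest.approx(w1 / 2, rel=1e-3)

    def test_image_shape_and_range(self):
        img = spectrogram_image(compute_spectrogram((sine(1000), SR)))
        assert img.shape == (128, 128)
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestMFCC:
    def test_shapes(self):
        x = np.random.default_rng(0).standard_normal(SR // 2)
        for n in (20, 40):
            m = compute_mfcc((x, SR), n)
            assert m.coeffs.shape[0] == n
            assert np.all(np.isfinite(m.coeffs))

    def test_invalid_n_coeffs_rejected(self):
        x = np.random.default_rng(0).standard_normal(SR // 2)
        with pytest.raises(ValueError, match="20 or 40"):
            compute_mfcc((x, SR), 25)
        m = compute_mfcc((x, SR), 25, allow_any_n=True)
        assert m.coeffs.shape[0] == 25

    def test_scaling_shifts_only_c0(self):
        x = np.random.default_rng(1).standard_normal(SR // 2)
        a = compute_mfcc((x, SR), 20).coeffs
        b = compute_mfcc((10 * x, SR), 20).coeffs
        np.testing.assert_allclose(b[1:], a[1:], atol=1e-6)
        shift = b[0] - a[0]
        np.testing.assert_allclose(shift, shift[0], atol=1e-6)
        assert shift[0] > 0

    @pytest.mark.parametrize("n_coeffs", [20, 40])
    def test_bruteforce_oracle(self, n_coeffs):
        # 50 random frames, loop-based mel + explicit DCT oracle
        rng = np.random.default_rng(2)
        params = FeatureParams()
        frame_len = int(round(params.window_s * SR))
        hop = int(round(params.hop_s * SR))
        n_frames = 50
        x = rng.standard_normal(frame_len + hop * (n_frames - 1))
        m = compute_mfcc((x, SR), n_coeffs, params)
        from scipy.signal import get_window

        win = get_window("hann", frame_len, fftbins=True)
        frames_power = np.array(
            [
                np.abs(np.fft.rfft(x[i * hop : i * hop + frame_len] * win)) ** 2
                for i in range(m.coeffs.shape[1])
            ]
        )
        expected = mfcc_bruteforce(
            frames_power, SR, frame_len, params.n_mels, n_coeffs,
            params.mel_fmin, params.mel_fmax,
        )
        np.testing.assert_allclose(m.coeffs, expected, atol=1e-8)

    def test_feature_vector_length(self):
        x = np.random.default_rng(0).standard_normal(SR // 2)
        v = mfcc_feature_vector(compute_mfcc((x, SR), 20))
        assert v.shape == (40,)


class TestBandEnergyFraction:
    def test_tone_in_band(self):
        spec = compute_spectrogram((sine(1000), SR))
        assert band_energy_fraction(spec, (900, 1100)) >= 0.95

    def test_tone_out_of_band(self):
        spec = compute_spectrogram((sine(1000), SR))
        assert band_energy_fraction(spec, (4000, 8000)) <= 0.02

    def test_ss_cycle_matches_fft_oracle(self):
        from breathsound.synth import generate_breath_cycle

        seg = generate_breath_cycle("SS", 3.0, seed=7)
        spec = compute_spectrogram((seg.samples, SR))
        ours = band_energy_fraction(spec, (2000, 12000))
        oracle = fft_band_energy_fraction(seg.samples, SR, 2000, 12000)
        assert ours == pytest.approx(oracle, abs=0.05)

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(3)
        spec = compute_spectrogram((rng.standard_normal(SR // 2), SR))
        edges = [0, 500, 1500, 2000, 8000, SR / 2]
        total = sum(
            band_energy_fraction(spec, (lo, hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_empty_band_rejected(self):
        spec = compute_spectrogram((sine(1000, 0.2), SR))
        with pytest.raises(ValueError, match="band"):
            band_energy_fraction(spec, (2000, 2000))


class TestModulationPeak:
    def test_forced_am(self):
        rng = np.random.default_rng(4)
        t = np.arange(2 * SR) / SR
        carrier = rng.standard_normal(2 * SR)
        x = carrier * (0.5 * (1 - np.cos(2 * np.pi * 100 * t)))
        peak = modulation_peak((x, SR))
        assert peak is not None
        hz, prominence = peak
        assert 95 <= hz <= 105
        assert prominence >= 6

    def test_stationary_tone_absent(self):
        assert modulation_peak((sine(5000, 2.0), SR)) is None

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            modulation_peak((np.zeros(SR // 4), SR))


class TestLinePersistence:
    def test_stable_tone(self):
        spec = compute_spectrogram((sine(5000, 2.0), SR))
        assert line_persistence(spec) >= 0.95

    def test_white_noise_null(self):
        # empirical null over seeded noise cycles
        vals = []
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(SR)
            vals.append(line_persistence(compute_spectrogram((x, SR))))
        assert max(vals) <= 0.2

    def test_ss_cycles_high(self, descriptors100):
        ss = [d.line_persistence for lab, d in descriptors100 if lab == "SS"]
        assert np.mean(np.array(ss) >= 0.8) >= 0.95

    def test_too_few_frames_rejected(self):
        spec = compute_spectrogram((sine(5000, 0.03), SR))
        with pytest.raises(ValueError, match="frames"):
            line_persistence(spec)
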