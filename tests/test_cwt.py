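import hashlib

import numpy as np
import pytest
from scipy.integrate import quad

from wavetap import WaveletConfig, cwt, matrix_to_images, morlet, render_scalogram
from wavetap.tappy_io import FeatureMatrix


def naive_cwt(x, scales):
    """Direct double-loop Riemann-sum evaluation, no truncation."""
    n = len(x)
    out = np.zeros((len(scales), n))
    for i, lam in enumerate(scales):
        for t in range(n):
            tau = np.arange(n, dtype=float)
            out[i, t] = np.sum(x * morlet((tau - t) / lam)) / np.sqrt(lam)
    return out


class TestMorlet:
    def test_value_at_zero(self):
        assert morlet(0.0) == 1.0

    def test_even_symmetry(self):
        t = np.linspace(-6, 6, 301)
        np.testing.assert_array_equal(morlet(t), morlet(-t))

    def test_integral_matches_quadrature(self):
        # closed form: integral of exp(-t^2/2)cos(5t) = sqrt(2*pi)*exp(-25/2)
        expected = np.sqrt(2 * np.pi) * np.exp(-12.5)
        numeric, err = quad(morlet, -8, 8, limit=200)
        assert numeric == pytest.approx(expected, rel=1e-6)

    def test_decays_below_truncation_threshold(self):
        assert abs(morlet(8.0)) < 1e-13


class TestWaveletConfig:
    def test_default_scale_grid(self):
        cfg = WaveletConfig()
        np.testing.assert_array_equal(cfg.scales, np.arange(1.0, 21.0))

    @pytest.mark.parametrize("bad", [[0.0, 1.0], [2.0, 1.0], [-1.0], []])
    def test_invalid_scales_rejected(self, bad):
        with pytest.raises(ValueError):
            WaveletConfig(scales=bad)


class TestCwt:
    def test_zero_signal_zero_scalogram(self):
        s = cwt(np.zeros(30))
        assert np.all(s.coefficients == 0.0)

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        a = cwt(3.5 * x).coefficients
        b = 3.5 * cwt(x).coefficients
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        cfg = WaveletConfig(scales=np.arange(1.0, 11.0))
        for n in (2, 7, 50):
            x = rng.normal(size=n)
            got = cwt(x, cfg).coefficients
            ref = naive_cwt(x, cfg.scales)
            assert np.abs(got - ref).max() <= 1e-9 * max(1.0, np.abs(ref).max())

    def test_reversed_signal_reverses_scalogram(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=35)
        fwd = cwt(x).coefficients
        rev = cwt(x[::-1]).coefficients
        np.testing.assert_allclose(rev, fwd[:, ::-1], rtol=1e-9, atol=1e-12)

    def test_cosine_peak_scale_tracks_center_frequency(self):
        """For cos(w*t), |W| peaks near scale 5/w, monotone across w."""
        t = np.arange(400, dtype=float)
        cfg = WaveletConfig(scales=np.arange(1.0, 21.0))
        peaks = []
        for w in (0.3, 0.5, 1.0):
            s = cwt(np.cos(w * t), cfg)
            energy = np.abs(s.coefficients[:, 100:300]).mean(axis=1)
            peak_scale = cfg.scales[int(np.argmax(energy))]
            assert peak_scale == pytest.approx(5.0 / w, abs=1.5)
            peaks.append(peak_scale)
        assert peaks == sorted(peaks, reverse=True)

    def test_agrees_with_pywavelets_on_peak_location(self):
        """Independent cross-check: pywt's 'morl' is the same mother wavelet;
        its different discretization still localizes the same peak scale."""
        pywt = pytest.importorskip("pywt")
        t = np.arange(400, dtype=float)
        x = np.cos(0.5 * t)
        scales = np.arange(1, 21, dtype=float)
        ours = np.abs(cwt(x, WaveletConfig(scales=scales)).coefficients[:, 100:300]).mean(axis=1)
        theirs, _ = pywt.cwt(x, scales, "morl")
        theirs = np.abs(theirs[:, 100:300]).mean(axis=1)
        assert abs(int(np.argmax(ours)) - int(np.argmax(theirs))) <= 1

    @pytest.mark.parametrize("bad", [np.array([1.0]), np.array([1.0, np.nan])])
    def test_invalid_signals_rejected(self, bad):
        with pytest.raises(ValueError):
            cwt(bad)


class TestRendering:
    def test_default_output_shape(self):
        s = cwt(np.random.default_rng(0).random(50))
        img = render_scalogram(s)
        assert img.shape == (240, 240, 3) and img.dtype == np.uint8

    def test_zero_scalogram_uniform_image(self):
        s = cwt(np.zeros(20))
        img = render_scalogram(s, (32, 32))
        assert len({tuple(px) for px in img.reshape(-1, 3)}) == 1

    def test_rendering_deterministic(self):
        s = cwt(np.random.default_rng(5).random(60))
        h1 = hashlib.sha256(render_scalogram(s, (64, 64)).tobytes()).hexdigest()
        h2 = hashlib.sha256(render_scalogram(s, (64, 64)).tobytes()).hexdigest()
        assert h1 == h2


class TestMatrixToImages:
    def _matrix(self, n=4):
        rng = np.random.default_rng(9)
        return FeatureMatrix(
            rng.random((n, 30)), [f"f{i}" for i in range(30)],
            np.array(["healthy", "parkinson"] * (n // 2), dtype=object),
            np.array([f"s{i}" for i in range(n)], dtype=object),
        )

    def test_one_png_per_row_and_manifest(self, tmp_path):
        m = self._matrix()
        manifest = matrix_to_images(m, outdir=tmp_path, size=(32, 32))
        assert len(manifest) == m.n_subjects
        assert sorted(manifest["label"]) == sorted(m.labels)
        for _, row in manifest.iterrows():
            assert (tmp_path / row["file"]).exists()
        assert (tmp_path / "manifest.csv").exists()

    def test_class_directories(self, tmp_path):
        matrix_to_images(self._matrix(), outdir=tmp_path, size=(16, 16))
        assert (tmp_path / "healthy").is_dir() and (tmp_path / "parkinson").is_dir()

    def test_regeneration_bitwise_identical(self, tmp_path):
        m = self._matrix()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        man = matrix_to_images(m, outdir=d1, size=(32, 32))
        matrix_to_images(m, outdir=d2, size=(32, 32))
        for f in man["file"]:
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_in_memory_dataset(self):
        ds = matrix_to_images(self._matrix(), outdir=None, size=(32, 32))
        assert ds.images.shape == (4, 32, 32, 3)
        assert list(ds.labels) == ["healthy", "parkinson", "healthy", "parkinson"]
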