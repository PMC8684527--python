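import numpy as np
import pytest

from focusfuse.imio import RasterImage
from focusfuse.sharpen import (
    LAPLACIAN_KERNELS,
    SharpenConfig,
    SpectralImage,
    dft2,
    idft2,
    laplacian_response,
    radial_emphasis_window,
    sharpen_laplacian,
    sharpen_lf_dft,
    sharpen_unsharp,
)

ALL_SHARPENERS = [sharpen_laplacian, sharpen_unsharp, sharpen_lf_dft]


def brute_force_dft2(x):
    """O(N^4) double-sum forward DFT, the independent oracle."""
    m, n = x.shape
    out = np.zeros((m, n), dtype=complex)
    for u in range(m):
        for v in range(n):
            acc = 0.0j
            for a in range(m):
                for b in range(n):
                    acc += x[a, b] * np.exp(-2j * np.pi * (u * a / m + v * b / n))
            out[u, v] = acc
    return out


def brute_force_idft2(coef):
    m, n = coef.shape
    out = np.zeros((m, n), dtype=complex)
    for a in range(m):
        for b in range(n):
            acc = 0.0j
            for u in range(m):
                for v in range(n):
                    acc += coef[u, v] * np.exp(2j * np.pi * (u * a / m + v * b / n))
            out[a, b] = acc / (m * n)
    return out


class TestLaplacianResponse:
    @pytest.mark.parametrize("variant", ["four_neighbor", "eight_neighbor"])
    def test_zero_on_constant(self, variant):
        cfg = SharpenConfig(method="laplacian", kernel_variant=variant)
        img = RasterImage(np.full((16, 16), 100.0))
        assert np.allclose(laplacian_response(img, cfg).pixels, 0.0)

    def test_zero_on_linear_ramp_interior(self):
        cfg = SharpenConfig(method="laplacian", boundary="circular")
        ramp = np.tile(np.arange(16, dtype=float), (16, 1))
        resp = laplacian_response(RasterImage(ramp), cfg).pixels
        # circular wrap distorts the first/last columns only
        assert np.allclose(resp[:, 2:-2], 0.0)

    def test_impulse_reproduces_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        # convolution of a symmetric kernel with a centered impulse = kernel
        for variant, kernel in LAPLACIAN_KERNELS.items():
            cfg = SharpenConfig(method="laplacian", kernel_variant=variant)
            resp = laplacian_response(RasterImage(img), cfg).pixels
            np.testing.assert_allclose(resp[3:6, 3:6], kernel)
            assert np.all(resp[np.abs(resp) > 0].size <= kernel.size)


class TestSharpeners:
    @pytest.mark.parametrize("fn", ALL_SHARPENERS)
    def test_identity_on_constant(self, fn, const_img):
        cfg = SharpenConfig(method="laplacian")
        out = fn(const_img, cfg)
        np.testing.assert_allclose(out.pixels, const_img.pixels, atol=1e-10)

    @pytest.mark.parametrize("fn", ALL_SHARPENERS)
    def test_output_in_range(self, fn, random_image):
        out = fn(random_image, SharpenConfig(method="laplacian", gain=2.0))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 255.0

    def test_step_edge_overshoots_before_clip(self):
        step = np.zeros((16, 16))
        step[:, 8:] = 255.0
        cfg = SharpenConfig(method="laplacian", gain=1.0)
        raw = step - cfg.gain * laplacian_response(RasterImage(step), cfg).pixels
        assert raw.min() < 0.0 and raw.max() > 255.0

    def test_small_gain_approaches_identity(self, random_image):
        cfg = SharpenConfig(method="laplacian", gain=1e-9)
        for fn in ALL_SHARPENERS:
            out = fn(random_image, cfg)
            np.testing.assert_allclose(out.pixels, random_image.pixels, atol=1e-5)

    @pytest.mark.parametrize("fn", ALL_SHARPENERS)
    def test_edge_contrast_nondecreasing_in_gain(self, fn):
        step = np.full((16, 16), 100.0)
        step[:, 8:] = 160.0
        img = RasterImage(step)
        contrasts = []
        for gain in (0.25, 0.5, 1.0, 2.0):
            cfg = SharpenConfig(method="laplacian", gain=gain)
            out = fn(img, cfg).pixels
            contrasts.append(out.max() - out.min())
        assert all(b >= a - 1e-12 for a, b in zip(contrasts, contrasts[1:]))

    def test_unsharp_preserves_column_structure(self, rng):
        # an image varying only by column stays column-only (separability)
        profile = rng.uniform(0, 255, size=16)
        img = RasterImage(np.tile(profile, (16, 1)))
        out = sharpen_unsharp(img, SharpenConfig(method="unsharp", sigma=2.0))
        assert np.allclose(out.pixels, out.pixels[0:1, :], atol=1e-9)

    def test_unsharp_shape_unchanged(self, random_image):
        out = sharpen_unsharp(random_image, SharpenConfig(method="unsharp"))
        assert out.shape == random_image.shape


class TestDFT:
    def test_constant_image_is_dc_only(self):
        spec = dft2(RasterImage(np.full((8, 12), 7.0))).coefficients
        assert spec[0, 0] == pytest.approx(7.0 * 8 * 12)
        spec[0, 0] = 0.0
        assert np.allclose(spec, 0.0, atol=1e-9)

    def test_hermitian_symmetry_of_real_input(self, rng):
        x = rng.uniform(0, 255, size=(8, 8))
        f = dft2(x).coefficients
        m, n = x.shape
        for u in range(m):
            for v in range(n):
                assert f[u, v] == pytest.approx(np.conj(f[-u % m, -v % n]), rel=1e-9)

    def test_checkerboard_concentrates_at_nyquist(self):
        y, x = np.mgrid[0:4, 0:4]
        board = 255.0 * ((x + y) % 2)
        f = dft2(board).coefficients.copy()
        # energy at DC (mean) and the Nyquist bin (2,2) only
        f[0, 0] = 0.0
        nyq = f[2, 2]
        f[2, 2] = 0.0
        assert abs(nyq) > 0.0
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_matches_brute_force_double_sum(self, rng):
        x = rng.uniform(0, 255, size=(8, 8))
        np.testing.assert_allclose(
            dft2(x).coefficients, brute_force_dft2(x), atol=1e-8 * 255 * 64
        )

    def test_idft_matches_brute_force(self, rng):
        x = rng.uniform(0, 255, size=(8, 8))
        coef = dft2(x).coefficients
        np.testing.assert_allclose(
            idft2(SpectralImage(coef)).pixels,
            np.real(brute_force_idft2(coef)),
            atol=1e-8,
        )

    def test_round_trip(self, rng):
        x = rng.uniform(0, 255, size=(16, 24))
        back = idft2(dft2(x)).pixels
        assert np.max(np.abs(back - x)) / np.max(np.abs(x)) < 1e-9

    def test_parseval(self, rng):
        x = rng.uniform(0, 255, size=(16, 16))
        f = dft2(x).coefficients
        lhs = np.sum(np.abs(x) ** 2)
        rhs = np.sum(np.abs(f) ** 2) / x.size
        assert abs(lhs - rhs) / lhs < 1e-9

    def test_rejects_rgb(self):
        with pytest.raises(ValueError):
            dft2(RasterImage(np.zeros((16, 16, 3))))


class TestHybridSharpener:
    def test_matches_spatial_laplacian_without_emphasis(self, rng):
        cfg = SharpenConfig(method="lf_dft", boundary="circular", emphasis=False)
        for _ in range(100):
            img = RasterImage(rng.uniform(0, 255, size=(32, 32)))
            a = sharpen_laplacian(img, cfg).pixels
            b = sharpen_lf_dft(img, cfg).pixels
            assert np.max(np.abs(a - b)) < 1e-6

    def test_emphasis_window_limits(self):
        w = radial_emphasis_window((16, 16))
        assert w[0, 0] == 0.0
        assert w[8, 8] == pytest.approx(1.0)
        assert np.all((w >= 0) & (w <= 1.0))

    def test_emphasis_boosts_high_over_low_frequency(self):
        # at equal gain the Nyquist-pattern correction must exceed the
        # first-harmonic correction when the emphasis window is active
        m = 16
        y, x = np.mgrid[0:m, 0:m]
        nyquist = 127.5 + 100.0 * np.cos(np.pi * x) * np.cos(np.pi * y)
        harmonic = 127.5 + 100.0 * np.cos(2 * np.pi * x / m)
        cfg_on = SharpenConfig(method="lf_dft", gain=1e-3, emphasis=True)

        def correction_magnitude(img, cfg):
            out = sharpen_lf_dft(RasterImage(img), cfg).pixels
            return np.max(np.abs(out - img))

        assert correction_magnitude(nyquist, cfg_on) > correction_magnitude(
            harmonic, cfg_on
        )

    def test_emphasis_attenuates_low_frequency_correction(self):
        m = 16
        x = np.mgrid[0:m, 0:m][1]
        harmonic = 127.5 + 100.0 * np.cos(2 * np.pi * x / m)
        kw = dict(method="lf_dft", gain=1e-3, boundary="circular")
        on = sharpen_lf_dft(RasterImage(harmonic), SharpenConfig(emphasis=True, **kw))
        off = sharpen_lf_dft(RasterImage(harmonic), SharpenConfig(emphasis=False, **kw))
        mag_on = np.max(np.abs(on.pixels - harmonic))
        mag_off = np.max(np.abs(off.pixels - harmonic))
        assert mag_on < mag_off

    def test_constant_unchanged_any_emphasis(self, const_img):
        for emphasis in (True, False):
            out = sharpen_lf_dft(
                const_img, SharpenConfig(method="lf_dft", emphasis=emphasis)
            )
            np.testing.assert_allclose(out.pixels, const_img.pixels, atol=1e-9)


class TestConfigValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SharpenConfig(method="laplacian", gain=-1.0)
        with pytest.raises(ValueError):
            SharpenConfig(sigma=0.0)
        with pytest.raises(ValueError):
            SharpenConfig(kernel_variant="five_neighbor")
        with pytest.raises(ValueError):
            SharpenConfig(boundary="mirror")
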