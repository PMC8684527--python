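"""Sharpening preprocessors applied to multifocus sources before fusion.

Three sharpeners are provided:

* ``laplacian`` — subtract a gain-scaled discrete Laplacian response
  (the 3x3 second-derivative mask; the kernel's center is negative, so
  subtracting the response adds edge contrast).
* ``unsharp`` — unsharp masking: add back a gain-scaled high-pass
  residual, the image minus its Gaussian blur.
* ``lf_dft`` — the hybrid cross-domain sharpener: the Laplacian is
  applied as a transfer function in the 2-D DFT domain, optionally
  reweighted by a radial high-frequency emphasis window before
  inverting.  With the emphasis off and circular boundary handling this
  path is mathematically identical to ``laplacian`` (convolution
  theorem), which is how it is cross-checked.

All sharpeners are identity on constant images and clip their output to
[0, 255].  RGB images are processed per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .imio import PEAK, RasterImage

__all__ = [
    "SharpenConfig",
    "SpectralImage",
    "LAPLACIAN_KERNELS",
    "laplacian_response",
    "sharpen_laplacian",
    "sharpen_unsharp",
    "dft2",
    "idft2",
    "sharpen_lf_dft",
    "apply_sharpener",
]

#: Discrete 3x3 Laplacian masks.  four_neighbor approximates
#: d2/dx2 + d2/dy2 on the axes only; eight_neighbor adds the diagonals.
LAPLACIAN_KERNELS = {
    "four_neighbor": np.array(
        [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
    ),
    "eight_neighbor": np.array(
        [[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]]
    ),
}

_BOUNDARY_TO_NDIMAGE = {"reflect": "reflect", "circular": "wrap"}


@dataclass
class SharpenConfig:
    """Parameters of the sharpening stage.

    gain is the positive scaling factor of the high-pass correction
    (lambda of unsharp masking); sigma the Gaussian radius of the
    unsharp low-pass, in pixels.  emphasis only affects ``lf_dft``.
    """

    method: Literal["laplacian", "unsharp", "lf_dft", "none"] = "none"
    gain: float = 1.0
    sigma: float = 1.0
    kernel_variant: Literal["four_neighbor", "eight_neighbor"] = "four_neighbor"
    boundary: Literal["reflect", "circular"] = "reflect"
    emphasis: bool = True

    def __post_init__(self) -> None:
        if self.gain <= 0 and self.method != "none":
            raise ValueError(f"gain must be positive, got {self.gain}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.kernel_variant not in LAPLACIAN_KERNELS:
            raise ValueError(f"unknown kernel variant {self.kernel_variant!r}")
        if self.boundary not in _BOUNDARY_TO_NDIMAGE:
            raise ValueError(f"unknown boundary mode {self.boundary!r}")


@dataclass
class SpectralImage:
    """Unnormalized 2-D DFT coefficients of a single-channel image.

    The DC coefficient (the pixel sum) sits at index (0, 0).
    """

    coefficients: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.coefficients.shape


def laplacian_response(img: RasterImage, cfg: SharpenConfig) -> RasterImage:
    """Raw (unclipped, possibly negative) Laplacian of the image."""
    kernel = LAPLACIAN_KERNELS[cfg.kernel_variant]
    mode = _BOUNDARY_TO_NDIMAGE[cfg.boundary]
    return img.map_channels(lambda ch: ndimage.convolve(ch, kernel, mode=mode))


def sharpen_laplacian(img: RasterImage, cfg: SharpenConfig) -> RasterImage:
    """Edge sharpening: clip(img - gain * laplacian_response)."""
    resp = laplacian_response(img, cfg)
    out = RasterImage(img.pixels - cfg.gain * resp.pixels, meta=dict(img.meta))
    return out.clip_to_range()


def sharpen_unsharp(img: RasterImage, cfg: SharpenConfig) -> RasterImage:
    """Unsharp masking: clip(img + gain * (img - gaussian_blur(img)))."""
    mode = _BOUNDARY_TO_NDIMAGE[cfg.boundary]

    def one(ch: np.ndarray) -> np.ndarray:
        blurred = ndimage.gaussian_filter(ch, cfg.sigma, mode=mode)
        return ch + cfg.gain * (ch - blurred)

    return img.map_channels(one).clip_to_range()


def dft2(img: RasterImage | np.ndarray) -> SpectralImage:
    """Unnormalized forward 2-D DFT (negative exponent) of one channel.

    F(0,0) equals the pixel sum; real input yields a Hermitian-symmetric
    spectrum.
    """
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, float)
    if px.ndim != 2:
        raise ValueError("dft2 takes a single channel; split RGB first")
    return SpectralImage(np.fft.fft2(px))


def idft2(spec: SpectralImage) -> RasterImage:
    """Normalized (1/MN) inverse DFT, returning the real part."""
    return RasterImage(np.real(np.fft.ifft2(spec.coefficients)))


def _laplacian_transfer(shape: tuple[int, int], variant: str) -> np.ndarray:
    """DFT of the 3x3 Laplacian kernel zero-padded and centered at the origin.

    Multiplying a spectrum by this array realizes circular convolution
    with the kernel (convolution theorem).
    """
    m, n = shape
    padded = np.zeros(shape)
    padded[:3, :3] = LAPLACIAN_KERNELS[variant]
    padded = np.roll(padded, (-1, -1), axis=(0, 1))
    return np.fft.fft2(padded)


def radial_emphasis_window(shape: tuple[int, int]) -> np.ndarray:
    """W(u,v) = r(u,v)/r_max: 0 at DC, 1 at the Nyquist corner.

    r is the centered radial frequency distance in index units.
    """
    m, n = shape
    fu = np.fft.fftfreq(m) * m
    fv = np.fft.fftfreq(n) * n
    r = np.hypot(fu[:, None], fv[None, :])
    r_max = np.hypot(m / 2.0, n / 2.0)
    return r / r_max


def sharpen_lf_dft(img: RasterImage, cfg: SharpenConfig) -> RasterImage:
    """Hybrid Laplacian + DFT sharpener.

    Per channel: take the spectrum, multiply by the Laplacian transfer
    function (and, if ``cfg.emphasis``, by the radial emphasis window),
    invert, and subtract gain times the resulting correction from the
    image.  Emphasis off reduces exactly to circular-boundary Laplacian
    sharpening.
    """

    def one(ch: np.ndarray) -> np.ndarray:
        spec = np.fft.fft2(ch)
        corr_spec = spec * _laplacian_transfer(ch.shape, cfg.kernel_variant)
        if cfg.emphasis:
            corr_spec = corr_spec * radial_emphasis_window(ch.shape)
        correction = np.real(np.fft.ifft2(corr_spec))
        return ch - cfg.gain * correction

    return img.map_channels(one).clip_to_range()


_SHARPENERS = {
    "laplacian": sharpen_laplacian,
    "unsharp": sharpen_unsharp,
    "lf_dft": sharpen_lf_dft,
}


def apply_sharpener(img: RasterImage, cfg: SharpenConfig) -> RasterImage:
    """Dispatch on ``cfg.method``; ``none`` returns the input unchanged."""
    if cfg.method == "none":
        return img
    return _SHARPENERS[cfg.method](img, cfg)
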