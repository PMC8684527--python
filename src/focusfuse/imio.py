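"""Image I/O and the numeric conventions shared by the whole pipeline.

Every stage operates on floating-point intensities on the nominal 8-bit
scale [0, 255], held in a :class:`RasterImage`.  Grayscale images are
2-D ``(rows, cols)`` arrays; RGB images are ``(rows, cols, 3)``.  The
coordinate convention is (row, col), 0-based, row 0 at top.  Grayscale
and RGB are never silently coerced into each other: pairing a 1-channel
with a 3-channel image is an error the caller must resolve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GREY_LEVELS",
    "PEAK",
    "RasterImage",
    "ImagePair",
    "PairingError",
    "FormatError",
    "load_image",
    "save_image",
    "validate_pair",
]

logger = logging.getLogger(__name__)

#: Number of grey levels of an 8-bit image (G).
GREY_LEVELS = 256
#: Peak signal amplitude, G - 1.
PEAK = 255.0

#: Minimum extent in either direction; wavelet stages need nontrivial support.
MIN_EXTENT = 8

# ITU-R BT.601 luma weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Unsupported image format or bit depth."""


class PairingError(ValueError):
    """Two images cannot form a multifocus pair."""


@dataclass
class RasterImage:
    """A registered intensity grid on the [0, 255] float scale.

    Parameters
    ----------
    pixels
        ``(M, N)`` or ``(M, N, 3)`` array of finite floats.
    meta
        Free-form provenance record (sharpener, fusion method, ...).
    """

    pixels: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3):
            raise FormatError(f"expected 2-D or 3-D pixel array, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise FormatError(f"3-D images must have 3 channels, got {px.shape[2]}")
        if px.shape[0] < MIN_EXTENT or px.shape[1] < MIN_EXTENT:
            raise FormatError(
                f"image extent {px.shape[:2]} below minimum {MIN_EXTENT}x{MIN_EXTENT}"
            )
        if not np.all(np.isfinite(px)):
            raise FormatError("image contains non-finite values")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    def clip_to_range(self) -> "RasterImage":
        """Return a copy with values clipped to [0, 255]."""
        return RasterImage(np.clip(self.pixels, 0.0, PEAK), meta=dict(self.meta))

    def iter_channels(self):
        """Yield each channel as a 2-D array (one yield for grayscale)."""
        if self.channels == 1:
            yield self.pixels
        else:
            for c in range(3):
                yield self.pixels[:, :, c]

    def map_channels(self, fn) -> "RasterImage":
        """Apply ``fn`` (2-D array -> 2-D array) independently per channel."""
        if self.channels == 1:
            return RasterImage(fn(self.pixels), meta=dict(self.meta))
        out = np.stack([fn(self.pixels[:, :, c]) for c in range(3)], axis=-1)
        return RasterImage(out, meta=dict(self.meta))


@dataclass
class ImagePair:
    """Two same-shape images of one scene with complementary focus."""

    source_a: RasterImage
    source_b: RasterImage

    def __post_init__(self) -> None:
        a, b = self.source_a, self.source_b
        if a.shape[:2] != b.shape[:2]:
            raise PairingError(f"shape mismatch: {a.shape[:2]} vs {b.shape[:2]}")
        if a.channels != b.channels:
            raise PairingError(
                f"channel mismatch: {a.channels} vs {b.channels} channels"
            )


def as_array(img: "RasterImage | np.ndarray") -> np.ndarray:
    """Coerce a RasterImage or bare array to a float64 ndarray."""
    if isinstance(img, RasterImage):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def to_gray(img: RasterImage) -> RasterImage:
    """Collapse RGB to luma with BT.601 weights; identity on grayscale."""
    if img.channels == 1:
        return img
    return RasterImage(img.pixels @ _LUMA, meta=dict(img.meta))


_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def load_image(path: str | Path, force_gray: bool = False) -> RasterImage:
    """Read a PNG/TIFF/JPEG image as a float RasterImage on [0, 255].

    16-bit inputs are rescaled to [0, 255]; an RGBA alpha channel is
    dropped with a logged warning.  With ``force_gray``, RGB input is
    converted by the BT.601 luma weights (0.299, 0.587, 0.114).
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format: {path}")
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if raw.dtype == np.uint8:
        px = raw.astype(np.float64)
    elif raw.dtype == np.uint16:
        px = raw.astype(np.float64) * (PEAK / 65535.0)
    else:
        raise FormatError(f"unsupported bit depth {raw.dtype} in {path}")

    if px.ndim == 3 and px.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        px = px[:, :, :3]
    img = RasterImage(px)
    if force_gray and img.channels == 3:
        img = to_gray(img)
    return img


def save_image(img: RasterImage, path: str | Path) -> Path:
    """Write an 8-bit PNG/TIFF, clipping to [0, 255] and rounding half-to-even.

    ``load_image(save_image(x))`` equals ``clip(rint(x))`` bitwise.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported output format: {path}")
    data = np.rint(np.clip(img.pixels, 0.0, PEAK)).astype(np.uint8)
    try:
        iio.imwrite(path, data)
    except OSError as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc
    return path


def validate_pair(a: RasterImage, b: RasterImage) -> ImagePair:
    """Pair two images, raising :class:`PairingError` on any mismatch."""
    return ImagePair(a, b)
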