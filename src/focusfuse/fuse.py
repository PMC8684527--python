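"""Fusion back-ends: pixel average, pixel minimum, DWT and SWT fusion.

The wavelet paths decompose both sources into an approximation band plus
per-level {horizontal, vertical, diagonal} detail bands, combine
corresponding coefficients (mean for the approximation, maximum-absolute
selection for details, by default), and invert the transform.

The discrete wavelet transform (DWT) decimates and is therefore not
shift-invariant; the stationary wavelet transform (SWT) up-samples the
filters instead of down-sampling the data, keeps every subband at full
image extent, and — under periodic extension — commutes with circular
shifts.  Both properties are exercised directly by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pywt

from .imio import ImagePair, RasterImage
from .sharpen import SharpenConfig, apply_sharpener

__all__ = [
    "FuseConfig",
    "WaveletPyramid",
    "DecompositionError",
    "FusionError",
    "fuse_average",
    "fuse_minimum",
    "decompose",
    "fuse_coefficients",
    "reconstruct",
    "fuse",
]


class DecompositionError(ValueError):
    """Image cannot be decomposed at the requested depth."""


class FusionError(ValueError):
    """Pyramids are structurally incompatible."""


@dataclass
class FuseConfig:
    """Fusion method and wavelet parameters.

    db2 at 2 levels is the default: a short filter with perfect
    reconstruction, at a depth typical for 512x512 inputs.  Approximation
    coefficients are averaged; detail coefficients are selected by
    maximum absolute value (ties go to source A).
    """

    method: Literal["average", "minimum", "dwt", "swt"] = "swt"
    wavelet_name: str = "db2"
    levels: int = 2
    approx_rule: Literal["mean", "max_abs"] = "mean"
    detail_rule: Literal["max_abs", "mean"] = "max_abs"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {self.wavelet_name!r}")


@dataclass
class WaveletPyramid:
    """Multilevel subband decomposition of one 2-D channel.

    ``details`` runs coarsest-first; each entry is the (horizontal,
    vertical, diagonal) triple of that level.  For SWT every subband has
    the (padded) full image extent; for DWT level-l subbands have extent
    ceil(M / 2**l).  ``orig_shape`` is the pre-padding extent so
    :func:`reconstruct` can crop back.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    transform: Literal["dwt", "swt"]
    wavelet_name: str
    extension_mode: Literal["periodic", "symmetric"]
    orig_shape: tuple[int, int]

    @property
    def levels(self) -> int:
        return len(self.details)

    def structure(self) -> tuple:
        return (
            self.transform,
            self.wavelet_name,
            self.levels,
            self.approximation.shape,
            tuple(d[0].shape for d in self.details),
        )

    def __add__(self, other: "WaveletPyramid") -> "WaveletPyramid":
        if self.structure() != other.structure():
            raise FusionError("cannot add structurally different pyramids")
        return WaveletPyramid(
            self.approximation + other.approximation,
            [
                tuple(a + b for a, b in zip(da, db))
                for da, db in zip(self.details, other.details)
            ],
            self.transform,
            self.wavelet_name,
            self.extension_mode,
            self.orig_shape,
        )


def fuse_average(pair: ImagePair) -> RasterImage:
    """Pixelwise arithmetic mean of the two sources."""
    return RasterImage(
        (pair.source_a.pixels + pair.source_b.pixels) / 2.0,
        meta={"fusion": "average"},
    )


def fuse_minimum(pair: ImagePair) -> RasterImage:
    """Pixelwise minimum of the two sources."""
    return RasterImage(
        np.minimum(pair.source_a.pixels, pair.source_b.pixels),
        meta={"fusion": "minimum"},
    )


def _swt_pad(shape: tuple[int, int], levels: int) -> tuple[int, int]:
    """Row/col padding that makes each extent divisible by 2**levels."""
    step = 2**levels
    return tuple((-s) % step for s in shape)  # type: ignore[return-value]


def decompose(img: RasterImage | np.ndarray, cfg: FuseConfig) -> WaveletPyramid:
    """Wavelet-decompose a single channel per ``cfg``.

    DWT uses symmetric extension; SWT uses the transform's inherent
    periodic extension, with symmetric padding up to the next multiple
    of 2**levels (cropped again on reconstruction).
    """
    arr = img.pixels if isinstance(img, RasterImage) else np.asarray(img, float)
    if arr.ndim != 2:
        raise DecompositionError("decompose takes a single channel; split RGB first")
    orig_shape = arr.shape

    if cfg.method == "dwt":
        max_lev = pywt.dwtn_max_level(arr.shape, cfg.wavelet_name)
        if cfg.levels > max_lev:
            raise DecompositionError(
                f"image {arr.shape} supports at most {max_lev} DWT levels "
                f"with {cfg.wavelet_name}, requested {cfg.levels}"
            )
        coeffs = pywt.wavedec2(arr, cfg.wavelet_name, mode="symmetric", level=cfg.levels)
        ext = "symmetric"
    elif cfg.method == "swt":
        if min(arr.shape) < 2**cfg.levels:
            raise DecompositionError(
                f"image {arr.shape} too small for {cfg.levels} SWT levels"
            )
        pr, pc = _swt_pad(arr.shape, cfg.levels)
        if pr or pc:
            arr = np.pad(arr, ((0, pr), (0, pc)), mode="symmetric")
        coeffs = pywt.swt2(
            arr, cfg.wavelet_name, level=cfg.levels, trim_approx=True, norm=True
        )
        ext = "periodic"
    else:
        raise DecompositionError(f"method {cfg.method!r} has no wavelet decomposition")

    return WaveletPyramid(
        approximation=coeffs[0],
        details=[tuple(level) for level in coeffs[1:]],
        transform=cfg.method,  # type: ignore[arg-type]
        wavelet_name=cfg.wavelet_name,
        extension_mode=ext,  # type: ignore[arg-type]
        orig_shape=orig_shape,
    )


def _combine(a: np.ndarray, b: np.ndarray, rule: str) -> np.ndarray:
    if rule == "mean":
        return (a + b) / 2.0
    if rule == "max_abs":
        # ties (|a| == |b|) keep the source-A coefficient
        return np.where(np.abs(a) >= np.abs(b), a, b)
    raise FusionError(f"unknown coefficient rule {rule!r}")


def fuse_coefficients(
    pyr_a: WaveletPyramid, pyr_b: WaveletPyramid, cfg: FuseConfig
) -> WaveletPyramid:
    """Combine two pyramids subband by subband per the configured rules."""
    if pyr_a.structure() != pyr_b.structure():
        raise FusionError(
            f"pyramid structure mismatch: {pyr_a.structure()} vs {pyr_b.structure()}"
        )
    fused_approx = _combine(pyr_a.approximation, pyr_b.approximation, cfg.approx_rule)
    fused_details = [
        tuple(_combine(da, db, cfg.detail_rule) for da, db in zip(lev_a, lev_b))
        for lev_a, lev_b in zip(pyr_a.details, pyr_b.details)
    ]
    return WaveletPyramid(
        fused_approx,
        fused_details,
        pyr_a.transform,
        pyr_a.wavelet_name,
        pyr_a.extension_mode,
        pyr_a.orig_shape,
    )


def reconstruct(pyr: WaveletPyramid) -> RasterImage:
    """Invert the decomposition, cropping away any SWT padding."""
    coeffs = [pyr.approximation] + [list(level) for level in pyr.details]
    if pyr.transform == "dwt":
        arr = pywt.waverec2(coeffs, pyr.wavelet_name, mode="symmetric")
    else:
        arr = pywt.iswt2(coeffs, pyr.wavelet_name, norm=True)
    m, n = pyr.orig_shape
    return RasterImage(arr[:m, :n])


def _fuse_wavelet_channel(a: np.ndarray, b: np.ndarray, cfg: FuseConfig) -> np.ndarray:
    pyr = fuse_coefficients(decompose(a, cfg), decompose(b, cfg), cfg)
    return reconstruct(pyr).pixels


def fuse(
    pair: ImagePair,
    fuse_cfg: FuseConfig | None = None,
    sharpen_cfg: SharpenConfig | None = None,
) -> RasterImage:
    """Sharpen both sources, then fuse them by the configured method.

    RGB pairs are fused per channel.  The sharpener and fusion method
    are recorded in the result's ``meta`` for reporting.
    """
    fuse_cfg = fuse_cfg or FuseConfig()
    sharpen_cfg = sharpen_cfg or SharpenConfig(method="none")

    a = apply_sharpener(pair.source_a, sharpen_cfg)
    b = apply_sharpener(pair.source_b, sharpen_cfg)

    if fuse_cfg.method == "average":
        fused = fuse_average(ImagePair(a, b))
    elif fuse_cfg.method == "minimum":
        fused = fuse_minimum(ImagePair(a, b))
    elif fuse_cfg.method in ("dwt", "swt"):
        if a.channels == 1:
            out = _fuse_wavelet_channel(a.pixels, b.pixels, fuse_cfg)
        else:
            out = np.stack(
                [
                    _fuse_wavelet_channel(
                        a.pixels[:, :, c], b.pixels[:, :, c], fuse_cfg
                    )
                    for c in range(3)
                ],
                axis=-1,
            )
        fused = RasterImage(out)
    else:
        raise FusionError(f"unknown fusion method {fuse_cfg.method!r}")

    fused = fused.clip_to_range()
    fused.meta.update(
        {
            "fusion": fuse_cfg.method,
            "sharpener": sharpen_cfg.method,
            "wavelet": fuse_cfg.wavelet_name,
            "levels": fuse_cfg.levels,
            "approx_rule": fuse_cfg.approx_rule,
            "detail_rule": fuse_cfg.detail_rule,
        }
    )
    return fused
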