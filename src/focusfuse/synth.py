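"""Seeded synthetic multifocus pairs with a known all-in-focus ground truth.

Real multifocus benchmarks pair two photographs of one scene taken at
different focus settings; an all-in-focus reference rarely exists.  The
generator here builds the reference first — a deterministic scene of
random rectangles, ellipses and line gratings over a textured background,
with high-frequency content on both sides of the focus split — and then
simulates the two limited-depth-of-field exposures by blending the sharp
scene with a Gaussian-blurred copy through a complementary focus mask:

    source_a = mask * gt + (1 - mask) * blur(gt)
    source_b = (1 - mask) * gt + mask * blur(gt)

so that ``source_a + source_b == gt + blur(gt)`` holds exactly, which
the tests exploit.  Defocus is modelled as a fixed-sigma Gaussian rather
than a physical thin-lens point-spread function: that is the standard
simulation practice for multifocus fusion benchmarks and keeps the
algebra exact.

Presets mirror the two common benchmark geometries: ``gray512``
(512x512 grayscale) and ``rgb520`` (520x520 RGB), plus a fast ``tiny64``
for unit tests.  Every operation is a pure function of (preset, seed,
parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imio import ImagePair, PEAK, RasterImage, save_image

__all__ = [
    "PRESETS",
    "SynthScene",
    "generate_ground_truth",
    "make_focus_mask",
    "defocus_pair",
    "make_fixture",
]

#: preset -> (rows, cols, channels)
PRESETS = {
    "gray512": (512, 512, 1),
    "rgb520": (520, 520, 3),
    "tiny64": (64, 64, 1),
}

#: Default defocus blur radius in pixels.
DEFAULT_BLUR_SIGMA = 3.0


@dataclass
class SynthScene:
    """Provenance record of one generated fixture."""

    ground_truth: RasterImage
    focus_mask: np.ndarray
    source_pair: ImagePair
    blur_sigma: float
    transition_width: float
    seed: int
    preset: str
    geometry: str

    def save(self, directory: str | Path) -> Path:
        """Write source_a/source_b/ground_truth PNGs plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_image(self.source_pair.source_a, directory / "source_a.png")
        save_image(self.source_pair.source_b, directory / "source_b.png")
        save_image(self.ground_truth, directory / "ground_truth.png")
        sidecar = {
            "preset": self.preset,
            "seed": self.seed,
            "blur_sigma": self.blur_sigma,
            "transition_width": self.transition_width,
            "geometry": self.geometry,
        }
        (directory / "scene.json").write_text(json.dumps(sidecar, indent=2))
        return directory


def _rng_for(preset: str, seed: int) -> np.random.Generator:
    # fold the preset name into the stream so presets differ at equal seed
    return np.random.default_rng([seed, *preset.encode()])


def generate_ground_truth(preset: str = "gray512", seed: int = 42) -> RasterImage:
    """Deterministic all-in-focus scene with detail everywhere.

    Random rectangles, ellipses and line gratings at distinct grey
    levels are painted over a smoothly varying background, then a
    low-amplitude texture noise field is added so every region carries
    high-frequency content for the sharpness-selective fusion rules to
    latch onto.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    m, n, ch = PRESETS[preset]
    rng = _rng_for(preset, seed)

    rows, cols = np.mgrid[0:m, 0:n].astype(float)
    n_shapes = max(6, (m * n) // 16384)

    def one_channel() -> np.ndarray:
        # smooth illumination gradient background
        gx, gy = rng.uniform(-40, 40, size=2)
        canvas = 110.0 + gx * (rows / m - 0.5) + gy * (cols / n - 0.5)
        for _ in range(n_shapes):
            level = rng.uniform(20, 235)
            kind = rng.choice(["rect", "ellipse", "grating"])
            cy, cx = rng.uniform(0.1, 0.9) * m, rng.uniform(0.1, 0.9) * n
            hy, hx = rng.uniform(0.04, 0.18) * m, rng.uniform(0.04, 0.18) * n
            if kind == "rect":
                sel = (np.abs(rows - cy) < hy) & (np.abs(cols - cx) < hx)
                canvas[sel] = level
            elif kind == "ellipse":
                sel = ((rows - cy) / hy) ** 2 + ((cols - cx) / hx) ** 2 < 1.0
                canvas[sel] = level
            else:
                period = rng.uniform(4, 12)
                phase = rng.uniform(0, 2 * np.pi)
                angle = rng.uniform(0, np.pi)
                sel = (np.abs(rows - cy) < hy) & (np.abs(cols - cx) < hx)
                wave = np.sin(
                    2 * np.pi * (rows * np.cos(angle) + cols * np.sin(angle)) / period
                    + phase
                )
                canvas[sel] = level + 40.0 * wave[sel]
        canvas += rng.normal(0.0, 6.0, size=(m, n))
        return np.clip(canvas, 0.0, PEAK)

    if ch == 1:
        return RasterImage(one_channel())
    return RasterImage(np.stack([one_channel() for _ in range(3)], axis=-1))


def make_focus_mask(
    shape: tuple[int, int],
    geometry: str = "half_vertical",
    transition_width: float = 0.0,
) -> np.ndarray:
    """Focus mask in [0, 1]; 1 marks the region in focus in source A.

    ``half_vertical`` puts the left half in focus, ``half_horizontal``
    the top half, ``disc`` a central disc of radius min(M, N)/4.  With
    ``transition_width`` 0 the partition is hard; otherwise the 1->0
    edge is a linear ramp of that width, centred on the split.
    """
    if transition_width < 0:
        raise ValueError("transition_width must be >= 0")
    m, n = shape
    rows, cols = np.mgrid[0:m, 0:n].astype(float)

    if geometry == "half_vertical":
        signed_dist = (n - 1) / 2.0 - cols
    elif geometry == "half_horizontal":
        signed_dist = (m - 1) / 2.0 - rows
    elif geometry == "disc":
        r = min(m, n) / 4.0
        signed_dist = r - np.hypot(rows - (m - 1) / 2.0, cols - (n - 1) / 2.0)
    else:
        raise ValueError(f"unknown mask geometry {geometry!r}")

    if transition_width == 0:
        return (signed_dist > 0).astype(float)
    return np.clip(0.5 + signed_dist / transition_width, 0.0, 1.0)


def defocus_pair(
    gt: RasterImage, mask: np.ndarray, blur_sigma: float = DEFAULT_BLUR_SIGMA
) -> ImagePair:
    """Simulate two limited-depth-of-field exposures of the scene."""
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    blurred = gt.map_channels(
        lambda ch: ndimage.gaussian_filter(ch, blur_sigma, mode="reflect")
    )
    w = mask if gt.channels == 1 else mask[:, :, None]
    a = w * gt.pixels + (1.0 - w) * blurred.pixels
    b = (1.0 - w) * gt.pixels + w * blurred.pixels
    return ImagePair(RasterImage(a), RasterImage(b))


def make_fixture(
    preset: str = "gray512",
    seed: int = 42,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    geometry: str = "half_vertical",
    transition_width: float = 0.0,
) -> SynthScene:
    """Compose ground truth, focus mask, and defocused pair into a scene."""
    gt = generate_ground_truth(preset, seed)
    mask = make_focus_mask(gt.shape[:2], geometry, transition_width)
    pair = defocus_pair(gt, mask, blur_sigma)
    return SynthScene(
        ground_truth=gt,
        focus_mask=mask,
        source_pair=pair,
        blur_sigma=blur_sigma,
        transition_width=transition_width,
        seed=seed,
        preset=preset,
        geometry=geometry,
    )
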