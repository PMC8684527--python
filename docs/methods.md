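# Methods

## Problem and pipeline

Two registered images of one scene, each with a different region in
focus, are merged into a single all-in-focus image. The pipeline is
sharpen-then-fuse: both sources pass through an optional sharpening
operator, then a fusion back-end combines them. Quality is judged by
eight full-reference metrics against a ground-truth image, which the
synthetic generator supplies.

All images are floating point on the nominal 8-bit scale [0, 255]
(G = 256 grey levels, peak 255). RGB images are processed per channel
in every stage; no colour transform is applied. Coordinates are
(row, col), 0-based, row 0 at top.

## Sharpening operators

**Laplacian.** `clip(I − gain · L∗I)` where `L` is the 3×3
four-neighbour (centre −4) or eight-neighbour (centre −8) Laplacian
mask. The mask's centre is negative, so *subtracting* the response adds
edge contrast. Boundary handling is reflective by default; circular is
available and is what makes the frequency-domain identity below exact.

**Unsharp masking.** `clip(I + gain · (I − G_σ∗I))` with a Gaussian
low-pass of radius `sigma` (pixels). The output shape equals the input
shape.

**Hybrid Laplacian + DFT.** Per channel: take the 2-D DFT, multiply by
the transfer function of the Laplacian mask (the DFT of the zero-padded,
origin-centred kernel — circular convolution by the convolution
theorem), optionally multiply by a radial emphasis window, invert, and
subtract `gain` times the real part from the image. The emphasis window
is `W(u,v) = r(u,v)/r_max`, with `r` the centred radial frequency
distance: weight 0 at DC, 1 at the Nyquist corner. It progressively
amplifies the correction toward high frequencies, the band where
defocus destroys information.

How the frequency-domain Laplacian should be recombined with the image,
and whether any spectral weighting applies, is genuinely open design
space: applied literally with no weighting the construction reduces to
plain Laplacian sharpening. We therefore expose the window as a flag,
default ON for the hybrid method. The OFF path is retained because it
admits an exact oracle: with circular boundaries it must equal spatial
Laplacian sharpening to floating-point accuracy, and the test suite
checks this on 100 seeded random images at 1e−6.

Defaults: `gain = 1.0`, `sigma = 1.0`, four-neighbour kernel, reflective
boundary. No authoritative values exist for these; they are the
conventional unit-strength settings and are exposed on every interface.

All sharpeners are identity on constant images, clip to [0, 255], and
have edge contrast nondecreasing in gain (tested on a step fixture).

## Fusion back-ends

*average* and *minimum* are pixelwise. The wavelet paths decompose each
source, combine coefficients subband-by-subband, and invert:

- approximation band: arithmetic mean (keeps overall luminance
  unbiased);
- detail bands: maximum-absolute selection, ties to source A — the
  coefficient with larger magnitude is the one carrying the in-focus
  edge energy at that location.

Both rules are configurable (`mean`/`max_abs` each way). Wavelet `db2`,
2 decomposition levels by default: a short perfect-reconstruction
filter at a depth that separates defocus-scale detail from scene
structure for 512² images.

DWT uses symmetric extension. SWT — the undecimated ("à trous")
transform — keeps every subband at full image extent and uses its
inherent periodic extension; input extents are symmetric-padded up to
the next multiple of 2^levels and cropped after reconstruction.
Periodic extension makes SWT fusion commute with circular shifts
*exactly*, which the tests assert at 1e−6, and the same test shows DWT
fusion failing on a shifted step edge — the decimated transform's
well-known shift sensitivity. Transforms are backed by PyWavelets;
perfect reconstruction is asserted at 1e−8 for levels 1–3.

## Quality metrics

For reference I_z, fused I_p, sources I_a/I_b, M×N pixels:

- RMSE = √(1/MN Σ(I_z − I_p)²)
- PFE = (‖I_z−I_p‖/‖I_z‖ + ‖I_z−I_p‖/‖I_p‖)·100 (Frobenius). This
  two-term form is the package default; the conventional single-term
  ‖I_z−I_p‖/‖I_z‖·100 sits behind `variant="conventional"`.
- MAE = mean|I_a−I_p| + mean|I_b−I_p| — deviation of the fused image
  from *both* sources; zero only when it equals both.
- Entropy = −Σ S_k log₂ S_k over the 256-bin histogram of rounded grey
  levels (luma channel for RGB); in [0, 8] bits.
- SNR = 10·log₁₀(ΣI_z² / Σ(I_z−I_p)²) dB.
- PSNR = 10·log₁₀(255²/MSE) dB by default. A literal
  20·log₁₀(G²/MSE) variant is kept behind a flag; the conventional form
  is the default because typical fusion results (26–44 dB) live on that
  scale and it satisfies the identity
  PSNR = 10·log₁₀(255²) − 20·log₁₀(RMSE), which the suite asserts.
- CC = 2·ΣI_zI_p/(ΣI_z² + ΣI_p²) — an energy-normalized (cosine-like)
  similarity, *not* Pearson correlation: 1 iff identical, in [0, 1] for
  nonnegative images, with the closed form CC(I, αI) = 2α/(1+α²).
- ERGAS = 100·(dh/dl)·√(1/n Σᵢ RMSEᵢ²/meanᵢ²) over the n bands; the
  resolution ratio dh/dl defaults to 1 for same-resolution multifocus
  fusion.

Every variant used is recorded in the report's `variant_flags`. Error
metrics are zero exactly on equality; SNR/PSNR report +inf then.
Metrics needing a true image take it as an explicit argument — for real
pairs with no all-in-focus reference these metrics are simply not
computable, which the interface surfaces rather than hides.

## Synthetic fixtures

`make_fixture(preset, seed, blur_sigma, geometry)` builds a
deterministic scene — random rectangles, ellipses and line gratings at
distinct grey levels over an illumination gradient, plus σ = 6 Gaussian
texture noise so both focus regions carry high-frequency content — then
simulates the two exposures:

    source_a = m·gt + (1−m)·G_σ∗gt,   source_b = (1−m)·gt + m·G_σ∗gt

with focus mask m (hard vertical half-split by default; horizontal and
disc geometries, and a linear transition ramp, are available) and
defocus σ = 3 px. The identity `source_a + source_b = gt + G_σ∗gt`
holds exactly pre-quantization and is tested. Presets: `gray512`
(512×512 grayscale), `rgb520` (520×520 RGB) — the two standard
benchmark geometries — and `tiny64` for fast unit tests. Everything is
a pure function of (preset, seed, parameters).

Defocus is modelled as fixed-σ Gaussian blur blended through the mask,
not a thin-lens point-spread function: the standard simulation practice
for multifocus benchmarks, and the choice that keeps the algebra exact.
What the generator does **not** emulate: spatially varying blur radius,
misregistration, sensor noise, saturation, demosaicing. Passing tests
show the pipeline recovers a scene under ideal two-region defocus; they
do not certify performance on real camera pairs.

## What the synthetic benchmark shows about sharpening

On these fixtures, sharpen-then-fuse rows score *worse* on the
reference-error metrics (RMSE/PFE/SNR/PSNR/CC/ERGAS) than plain DWT/SWT
fusion, while scoring higher entropy. That is structural: the ground
truth here is the unsharpened scene, so any sharpening gain ≥ ~1 adds
overshoot that counts as error, even though it increases apparent edge
contrast. Claims that sharpening preprocessing improves reference-based
scores depend on the reference used and do not transfer to this
benchmark; the package reports the grid and lets the numbers speak.

## Numerical choices

- Detail-rule ties (|a| = |b|) keep source A's coefficient —
  deterministic and order-stable.
- Saving rounds half-to-even and clips; save∘load is the identity on
  integral images, asserted bitwise.
- DFT primitives are numpy-fft-backed; the test suite holds them to the
  O(N⁴) brute-force double sums at 1e−8 and to Parseval at 1e−9.
- 16-bit input scales by 255/65535; RGBA drops alpha with a warning.
- The demo grid and acceptance script run at 512² (the native preset
  size); unit tests use 64² and smaller for speed.

## Known limitations

- Exactly two source images; no registration or alignment.
- The hybrid sharpener's emphasis window is one reasonable realization
  of a cross-domain sharpener, not a canonical definition.
- The energy-normalized CC saturates near 1 for any two bright images
  of similar energy; it is far less discriminative than Pearson
  correlation.
- The printed two-term PFE double-counts the error norm relative to
  common usage; comparisons with other toolchains should use the
  conventional variants of PFE and PSNR.
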