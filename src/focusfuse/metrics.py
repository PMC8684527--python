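"""Full-reference quality metrics for fused images.

Eight metrics are computed against a known all-in-focus reference
("true") image I_z: RMSE, percentage fit error (PFE), a two-source mean
absolute error (MAE), Shannon entropy of the fused image, SNR, PSNR,
an energy-normalized correlation (CC), and ERGAS.

Two of the formulas here deviate from common practice and both variants
are kept, selected by flags and recorded in the report:

* PFE — the default is the two-term form
  ``(||d||/||I_z|| + ||d||/||I_f||) * 100`` (Frobenius norms); the
  conventional single-term form ``||d||/||I_z|| * 100`` is available as
  ``variant="conventional"``.
* PSNR — the default is the conventional
  ``10 log10((G-1)^2 / MSE)`` dB with G-1 = 255, the scale on which
  typical fusion results (26-44 dB) live; a literal
  ``20 log10(G^2 / MSE)`` form is available as ``variant="printed"``.

The CC metric is an energy-normalized similarity
``2 * sum(z*p) / (sum z^2 + sum p^2)`` — a cosine-like measure, not the
Pearson coefficient; it is 1 exactly when the images are identical and
lies in [0, 1] for nonnegative images.

MAE here measures the fused image against *both* sources:
``mean|I_z - I_p| + mean|I_x - I_p|``; it is zero only when the fused
image equals both sources.

RGB reduction: rmse/pfe/mae/snr/psnr/cc pool over all elements; ERGAS
aggregates per band by construction; entropy is taken on the luma
channel.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imio import GREY_LEVELS, PEAK, RasterImage, as_array, to_gray

__all__ = [
    "QualityReport",
    "MetricError",
    "rmse",
    "pfe",
    "mae_fusion",
    "entropy",
    "snr",
    "psnr",
    "cc",
    "ergas",
    "evaluate_all",
    "METRIC_NAMES",
]

METRIC_NAMES = ("rmse", "pfe", "mae", "entropy", "snr", "psnr", "cc", "ergas")

#: Names of metrics where smaller is better (the rest prefer larger).
LOWER_IS_BETTER = frozenset({"rmse", "pfe", "mae", "ergas"})


class MetricError(ValueError):
    """Metric undefined for the given inputs."""


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch: {a.shape} vs {b.shape}")


def rmse(reference: RasterImage | np.ndarray, test: RasterImage | np.ndarray) -> float:
    """Root mean square error over all elements."""
    z, f = as_array(reference), as_array(test)
    _check_same_shape(z, f)
    return float(np.sqrt(np.mean((z - f) ** 2)))


def pfe(
    reference: RasterImage | np.ndarray,
    test: RasterImage | np.ndarray,
    variant: str = "printed",
) -> float:
    """Percentage fit error (Frobenius norms), see module docstring."""
    z, f = as_array(reference), as_array(test)
    _check_same_shape(z, f)
    nz, nf = np.linalg.norm(z.ravel()), np.linalg.norm(f.ravel())
    if nz == 0.0 or (variant == "printed" and nf == 0.0):
        raise MetricError("PFE undefined for an all-zero image norm")
    nd = np.linalg.norm((z - f).ravel())
    if variant == "printed":
        return float((nd / nz + nd / nf) * 100.0)
    if variant == "conventional":
        return float(nd / nz * 100.0)
    raise ValueError(f"unknown PFE variant {variant!r}")


def mae_fusion(
    source_a: RasterImage | np.ndarray,
    source_b: RasterImage | np.ndarray,
    fused: RasterImage | np.ndarray,
) -> float:
    """Sum of mean absolute deviations of the fused image from both sources."""
    a, b, p = as_array(source_a), as_array(source_b), as_array(fused)
    _check_same_shape(a, p)
    _check_same_shape(b, p)
    return float(np.mean(np.abs(a - p)) + np.mean(np.abs(b - p)))


def entropy(img: RasterImage | np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin grey-level histogram.

    Values are rounded to integer grey levels first; RGB images are
    collapsed to luma.  Result lies in [0, 8] bits.
    """
    if isinstance(img, RasterImage) and img.channels == 3:
        img = to_gray(img)
    x = as_array(img)
    levels = np.clip(np.rint(x), 0, GREY_LEVELS - 1).astype(np.intp)
    counts = np.bincount(levels.ravel(), minlength=GREY_LEVELS)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def snr(reference: RasterImage | np.ndarray, test: RasterImage | np.ndarray) -> float:
    """10 log10 of signal energy over error energy; +inf on equality."""
    z, p = as_array(reference), as_array(test)
    _check_same_shape(z, p)
    sig = float(np.sum(z**2))
    if sig == 0.0:
        raise MetricError("SNR undefined for an all-zero reference")
    err = float(np.sum((z - p) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(sig / err)


def psnr(
    reference: RasterImage | np.ndarray,
    test: RasterImage | np.ndarray,
    variant: str = "conventional",
) -> float:
    """Peak signal-to-noise ratio in dB; +inf on equality."""
    z, p = as_array(reference), as_array(test)
    _check_same_shape(z, p)
    mse = float(np.mean((z - p) ** 2))
    if mse == 0.0:
        return math.inf
    if variant == "conventional":
        return 10.0 * math.log10(PEAK**2 / mse)
    if variant == "printed":
        return 20.0 * math.log10(GREY_LEVELS**2 / mse)
    raise ValueError(f"unknown PSNR variant {variant!r}")


def cc(reference: RasterImage | np.ndarray, test: RasterImage | np.ndarray) -> float:
    """Energy-normalized correlation 2*C_zp / (C_z + C_p)."""
    z, p = as_array(reference), as_array(test)
    _check_same_shape(z, p)
    cz, cp = float(np.sum(z**2)), float(np.sum(p**2))
    if cz + cp == 0.0:
        raise MetricError("CC undefined when both images are all-zero")
    czp = float(np.sum(z * p))
    return 2.0 * czp / (cz + cp)


def _bands(x: np.ndarray) -> list[np.ndarray]:
    return [x] if x.ndim == 2 else [x[:, :, c] for c in range(x.shape[2])]


def ergas(
    reference: RasterImage | np.ndarray,
    test: RasterImage | np.ndarray,
    scale_ratio: float = 1.0,
) -> float:
    """Relative dimensionless global error of synthesis.

    ``100 * scale_ratio * sqrt(mean_i(RMSE_i^2 / mean_i^2))`` over the
    n bands.  ``scale_ratio`` is the high/low resolution ratio (dh/dl);
    1 for same-resolution multifocus fusion.
    """
    z, p = as_array(reference), as_array(test)
    _check_same_shape(z, p)
    terms = []
    for zb, pb in zip(_bands(z), _bands(p)):
        mu = float(np.mean(zb))
        if mu == 0.0:
            raise MetricError("ERGAS undefined for a zero-mean reference band")
        terms.append(float(np.mean((zb - pb) ** 2)) / mu**2)
    return float(100.0 * scale_ratio * math.sqrt(sum(terms) / len(terms)))


@dataclass
class QualityReport:
    """The eight metric values for one fused result, plus variant flags."""

    rmse: float
    pfe: float
    mae: float
    entropy: float
    snr: float
    psnr: float
    cc: float
    ergas: float
    variant_flags: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def to_json(self) -> str:
        d: dict = self.to_dict()
        d["variant_flags"] = self.variant_flags
        return json.dumps(d, indent=2)

    @staticmethod
    def write_csv(
        path: str | Path, rows: list[tuple[str, "QualityReport"]]
    ) -> Path:
        """Write labelled reports as CSV, one row per (label, report)."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(("method",) + tuple(METRIC_NAMES))
            for label, report in rows:
                writer.writerow(
                    [label] + [f"{getattr(report, m):.6g}" for m in METRIC_NAMES]
                )
        return path


def evaluate_all(
    source_a: RasterImage | np.ndarray,
    source_b: RasterImage | np.ndarray,
    fused: RasterImage | np.ndarray,
    reference: RasterImage | np.ndarray,
    psnr_variant: str = "conventional",
    pfe_variant: str = "printed",
    ergas_scale_ratio: float = 1.0,
) -> QualityReport:
    """Compute the full eight-metric report for one fused image."""
    return QualityReport(
        rmse=rmse(reference, fused),
        pfe=pfe(reference, fused, variant=pfe_variant),
        mae=mae_fusion(source_a, source_b, fused),
        entropy=entropy(fused if isinstance(fused, RasterImage) else np.asarray(fused)),
        snr=snr(reference, fused),
        psnr=psnr(reference, fused, variant=psnr_variant),
        cc=cc(reference, fused),
        ergas=ergas(reference, fused, scale_ratio=ergas_scale_ratio),
        variant_flags={
            "psnr": psnr_variant,
            "pfe": pfe_variant,
            "ergas_scale_ratio": str(ergas_scale_ratio),
        },
    )
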