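"""Objective fusion-quality metrics: SD, mean gradient, spatial frequency, entropy.

All four are no-reference statistics of the fused image on the 8-bit gray
scale.  Unit-range images are rescaled by 255 before measuring; color
images are scored on their IHS intensity plane (that is the plane the
fusion actually modifies).

* ``std_dev``: population standard deviation — gray-level contrast.
* ``mean_gradient``: average magnitude of the local intensity gradient
  (forward differences on the (M-1)x(N-1) interior grid) — fine-detail
  sharpness, in gray levels/pixel.
* ``spatial_frequency``: RMS of row and column first differences
  (RF, CF; SF = sqrt(RF^2 + CF^2)) — overall activity.
* ``entropy``: Shannon entropy of the L-level gray histogram, in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import EIGHT_BIT, ColorImage, RasterImage


@dataclass(frozen=True)
class MetricsReport:
    """The four quality scores of one fused image."""

    sd: float
    mean_gradient: float
    rf: float
    cf: float
    spatial_frequency: float
    entropy: float

    def to_dict(self) -> dict[str, float]:
        return {
            "sd": self.sd,
            "mean_gradient": self.mean_gradient,
            "rf": self.rf,
            "cf": self.cf,
            "spatial_frequency": self.spatial_frequency,
            "entropy": self.entropy,
        }


def _gray(img: RasterImage | np.ndarray) -> np.ndarray:
    """Pixel array on the 8-bit scale."""
    if isinstance(img, RasterImage):
        return img.to_eight_bit().pixels
    return np.asarray(img, dtype=float)


def std_dev(img: RasterImage | np.ndarray) -> float:
    """Population standard deviation (divisor M*N) of the gray values."""
    z = _gray(img)
    return float(np.sqrt(np.mean((z - z.mean()) ** 2)))


def mean_gradient(img: RasterImage | np.ndarray) -> float:
    """Mean magnitude sqrt((dx^2 + dy^2)/2) of forward differences."""
    z = _gray(img)
    dr = z[1:, :-1] - z[:-1, :-1]   # down a row
    dc = z[:-1, 1:] - z[:-1, :-1]   # across a column
    return float(np.mean(np.sqrt((dr**2 + dc**2) / 2.0)))


def spatial_frequency(img: RasterImage | np.ndarray) -> tuple[float, float, float]:
    """(SF, RF, CF): RMS first differences along rows and columns.

    Both use the 1/(M*N) normalizer even though only (N-1) or (M-1)
    differences exist per line.
    """
    z = _gray(img)
    m, n = z.shape
    rf = float(np.sqrt(np.sum((z[:, 1:] - z[:, :-1]) ** 2) / (m * n)))
    cf = float(np.sqrt(np.sum((z[1:, :] - z[:-1, :]) ** 2) / (m * n)))
    return float(np.hypot(rf, cf)), rf, cf


def quantize_gray(img: RasterImage | np.ndarray, levels: int = 256) -> np.ndarray:
    """Integer gray levels 0..levels-1 for histogramming.

    8-bit images are clipped and rounded in place on their own scale (so an
    in-range constant shift permutes bins without merging them); unit-range
    images are scaled by ``levels - 1``; raw float arrays are min-max
    remapped onto the full scale.
    """
    if isinstance(img, RasterImage):
        if img.value_range == EIGHT_BIT:
            z = img.pixels * (levels - 1) / 255.0
        else:
            z = img.pixels * (levels - 1)
        return np.clip(np.rint(z), 0, levels - 1).astype(np.int64)
    z = np.asarray(img, dtype=float)
    lo, hi = z.min(), z.max()
    if hi == lo:
        return np.zeros(z.shape, dtype=np.int64)
    return np.clip(
        np.rint((z - lo) / (hi - lo) * (levels - 1)), 0, levels - 1
    ).astype(np.int64)


def entropy(img: RasterImage | np.ndarray, levels: int = 256) -> float:
    """Shannon entropy (bits) of the gray-level histogram; 0*log0 := 0."""
    q = quantize_gray(img, levels)
    counts = np.bincount(q.ravel(), minlength=levels)
    p = counts[counts > 0] / q.size
    return float(-np.sum(p * np.log2(p)))


def evaluate_all(
    img: RasterImage | ColorImage | np.ndarray, levels: int = 256
) -> MetricsReport:
    """Bundle all four metrics; color images are scored on IHS intensity."""
    if isinstance(img, ColorImage):
        from .ihs import rgb_to_ihs

        img = rgb_to_ihs(img).i
    sf, rf, cf = spatial_frequency(img)
    return MetricsReport(
        sd=std_dev(img),
        mean_gradient=mean_gradient(img),
        rf=rf,
        cf=cf,
        spatial_frequency=sf,
        entropy=entropy(img, levels),
    )
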