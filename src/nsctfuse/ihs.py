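"""Linear triangular IHS (intensity-hue-saturation) transform.

Fusion replaces the intensity of the pseudo-colored functional image and
inverts, preserving its hue/saturation.  The linear triangular model is
used because it has an exact linear inverse:

    I  = (R + G + B) / 3
    v1 = (-R - G + 2B) / sqrt(18)
    v2 = (R - G) / sqrt(2)

with hue H = atan2(v2, v1) and saturation S = hypot(v1, v2).  H is defined
as 0 on the gray axis (S = 0) so the inverse stays exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import UNIT, ColorImage, RasterImage

logger = logging.getLogger(__name__)

#: Forward matrix mapping (R, G, B) -> (I, v1, v2).  The v1 row is built
#: from one rounded constant so that R = G = B cancels *exactly* in
#: floating point (2*c is an exact doubling), keeping S = 0 on the gray axis.
_C1 = 1.0 / np.sqrt(18.0)
_C2 = 1.0 / np.sqrt(2.0)
FORWARD_MATRIX = np.array(
    [
        [1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
        [-_C1, -_C1, 2.0 * _C1],
        [_C2, -_C2, 0.0],
    ]
)
INVERSE_MATRIX = np.linalg.inv(FORWARD_MATRIX)


@dataclass(frozen=True)
class IHSTriple:
    """Intensity plane plus hue angles (radians) and saturation magnitudes."""

    i: RasterImage
    h: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        if not (self.i.shape == self.h.shape == self.s.shape):
            raise ValidationError("I, H, S must share one shape")
        if np.any(self.s < 0):
            raise ValidationError("saturation must be non-negative")


def rgb_to_ihs(img: ColorImage) -> IHSTriple:
    """Forward IHS transform; input is rescaled to [0, 1] internally."""
    unit = img.to_unit()
    r, g, b = unit.r.pixels, unit.g.pixels, unit.b.pixels
    # elementwise (not matrix-dot) so that R=G=B cancels exactly in floating
    # point and the gray axis gets S = 0, not rounding dust
    i = (r + g + b) / 3.0
    v1 = (2.0 * b - r - g) * _C1
    v2 = (r - g) * _C2
    s = np.hypot(v1, v2)
    h = np.arctan2(v2, v1)
    h[s == 0] = 0.0  # hue undefined on the gray axis; fixed at 0
    # lowpass-free average of in-range channels stays in range; guard fp dust
    return IHSTriple(RasterImage(np.clip(i, 0.0, 1.0), UNIT), h, s)


def ihs_to_rgb_with_count(
    i: RasterImage | np.ndarray, h: np.ndarray, s: np.ndarray
) -> tuple[ColorImage, int]:
    """Exact algebraic inverse of :func:`rgb_to_ihs`.

    Fused intensity can leave the RGB gamut; outputs are clipped to [0, 1]
    and the number of clipped samples (over all three channels) returned.
    Accepts a raw intensity array so out-of-range I' can be inverted before
    clipping.
    """
    ival = i.to_unit().pixels if isinstance(i, RasterImage) else np.asarray(i)
    v1 = s * np.cos(h)
    v2 = s * np.sin(h)
    ivv = np.stack([ival, v1, v2], axis=-1)
    rgb = np.tensordot(ivv, INVERSE_MATRIX, axes=([2], [1]))
    n_clipped = int(np.count_nonzero((rgb < 0.0) | (rgb > 1.0)))
    if n_clipped:
        logger.info("inverse IHS clipped %d samples to [0,1]", n_clipped)
    return ColorImage.from_array(np.clip(rgb, 0.0, 1.0), UNIT), n_clipped


def ihs_to_rgb(t: IHSTriple) -> ColorImage:
    """Inverse IHS transform of a full triple (clipping logged)."""
    img, _ = ihs_to_rgb_with_count(t.i, t.h, t.s)
    return img
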