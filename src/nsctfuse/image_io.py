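"""Image containers, PNG/TIFF I/O and intensity conditioning.

The whole pipeline operates on two container types: :class:`RasterImage`
(a single 2-D intensity plane with an explicitly recorded value range) and
:class:`ColorImage` (three such planes, R/G/B).  Pixel coordinates are
0-based ``(row, column)`` with row 0 at the top, everywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np

from .errors import ImageFormatError, RegistrationError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical value ranges.  8-bit is the on-disk range, unit is the
#: working range for the transforms.
EIGHT_BIT: tuple[float, float] = (0.0, 255.0)
UNIT: tuple[float, float] = (0.0, 1.0)

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class RasterImage:
    """A single-channel 2-D intensity image.

    Parameters
    ----------
    pixels
        ``(M, N)`` array of finite real intensities, ``M, N >= 2``.
    value_range
        Declared range, either ``EIGHT_BIT`` (``[0, 255]``) or ``UNIT``
        (``[0, 1]``).  All pixel values must lie within it.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = EIGHT_BIT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValidationError(
                f"RasterImage needs a 2-D array with M,N >= 2, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValidationError("RasterImage contains non-finite values")
        lo, hi = self.value_range
        if px.min() < lo - 1e-9 or px.max() > hi + 1e-9:
            raise ValidationError(
                f"pixel values [{px.min():g}, {px.max():g}] outside the declared "
                f"range [{lo:g}, {hi:g}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_unit(self) -> "RasterImage":
        """Rescale the declared range to [0, 1] (no-op if already unit)."""
        if self.value_range == UNIT:
            return self
        lo, hi = self.value_range
        return RasterImage((self.pixels - lo) / (hi - lo), UNIT)

    def to_eight_bit(self) -> "RasterImage":
        """Rescale the declared range to [0, 255] (no-op if already 8-bit)."""
        if self.value_range == EIGHT_BIT:
            return self
        lo, hi = self.value_range
        return RasterImage((self.pixels - lo) / (hi - lo) * 255.0, EIGHT_BIT)


@dataclass(frozen=True)
class ColorImage:
    """Three co-registered R, G, B planes sharing shape and value range."""

    r: RasterImage
    g: RasterImage
    b: RasterImage

    def __post_init__(self) -> None:
        shapes = {self.r.shape, self.g.shape, self.b.shape}
        ranges = {self.r.value_range, self.g.value_range, self.b.value_range}
        if len(shapes) != 1:
            raise ValidationError(f"R/G/B planes have differing shapes: {shapes}")
        if len(ranges) != 1:
            raise ValidationError(f"R/G/B planes have differing ranges: {ranges}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    @property
    def value_range(self) -> tuple[float, float]:
        return self.r.value_range

    def to_array(self) -> np.ndarray:
        """Stack into an ``(M, N, 3)`` float array."""
        return np.stack([self.r.pixels, self.g.pixels, self.b.pixels], axis=-1)

    @classmethod
    def from_array(
        cls, arr: np.ndarray, value_range: tuple[float, float] = EIGHT_BIT
    ) -> "ColorImage":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ValidationError(f"expected (M, N, 3) array, got shape {arr.shape}")
        return cls(
            RasterImage(arr[..., 0], value_range),
            RasterImage(arr[..., 1], value_range),
            RasterImage(arr[..., 2], value_range),
        )

    def to_unit(self) -> "ColorImage":
        return ColorImage(self.r.to_unit(), self.g.to_unit(), self.b.to_unit())

    def to_eight_bit(self) -> "ColorImage":
        return ColorImage(
            self.r.to_eight_bit(), self.g.to_eight_bit(), self.b.to_eight_bit()
        )


class NormalizedImage(NamedTuple):
    """Result of :func:`normalize_intensity`: unit image plus the affine map."""

    image: RasterImage
    original_min: float
    original_max: float


def load_image(path: str | Path) -> RasterImage | ColorImage:
    """Read a PNG or TIFF file.

    Single-channel files load as :class:`RasterImage`, 3-channel as
    :class:`ColorImage`, both in the 8-bit range.  RGBA/LA inputs are
    accepted only when the alpha channel is fully opaque (it is dropped);
    16-bit inputs are linearly rescaled to [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ImageFormatError(
            f"unsupported file type {path.suffix!r}; only PNG and TIFF are supported"
        )
    arr = np.asarray(iio.imread(path))
    if arr.dtype == np.uint16:
        logger.info("16-bit input %s rescaled to [0,255] (scale 255/65535)", path)
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    else:
        arr = arr.astype(np.float64)

    if arr.ndim == 3 and arr.shape[-1] in (2, 4):  # LA / RGBA
        alpha = arr[..., -1]
        if not np.all(alpha == alpha.max()) or alpha.max() <= 0:
            raise ImageFormatError(
                f"unsupported channel count {arr.shape[-1]} "
                "(alpha channel is not fully opaque)"
            )
        arr = arr[..., :-1]
        if arr.shape[-1] == 1:
            arr = arr[..., 0]
    if arr.ndim == 2:
        return RasterImage(arr, EIGHT_BIT)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return ColorImage.from_array(arr, EIGHT_BIT)
    n_chan = arr.shape[-1] if arr.ndim == 3 else arr.ndim
    raise ImageFormatError(f"unsupported channel count {n_chan} in {path}")


def save_image(img: RasterImage | ColorImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG or TIFF (values rounded to uint8)."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ImageFormatError(
            f"unsupported file type {path.suffix!r}; only PNG and TIFF are supported"
        )
    if isinstance(img, ColorImage):
        arr = img.to_eight_bit().to_array()
    else:
        arr = img.to_eight_bit().pixels
    iio.imwrite(path, np.clip(np.rint(arr), 0, 255).astype(np.uint8))


def normalize_intensity(img: RasterImage) -> NormalizedImage:
    """Affinely map an image onto [0, 1]: ``x -> (x - min) / (max - min)``.

    A constant image maps to all zeros (the stated convention).  The
    original min/max are returned so the map can be inverted.
    """
    px = img.pixels
    lo = float(px.min())
    hi = float(px.max())
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return NormalizedImage(RasterImage(out, UNIT), lo, hi)


def check_registered_pair(
    a: ColorImage, b: RasterImage
) -> tuple[ColorImage, RasterImage]:
    """Validate that a functional/anatomical pair is pixel-registered.

    Registration itself is out of scope; only an exact shape match is
    accepted.  Returns the pair unchanged.
    """
    if a.shape != b.shape:
        raise RegistrationError(
            f"images are not registered: shapes {a.shape} vs {b.shape}"
        )
    return a, b
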