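"""Deterministic CT-like / SPECT-like phantom pairs on a shared head mask.

The generator stands in for real registered brain images so that every
stage of the pipeline is testable offline.  The CT phantom is a bright
bone annulus (the skull) around a mid-gray, weakly textured interior on a
dark background — sharp edges, high gradient.  The SPECT phantom is a
handful of smooth Gaussian activity blobs inside the skull, rendered
through a fixed hot-iron pseudo-colormap — low spatial resolution, strong
hue structure, black outside the head.  Both are drawn on the same mask,
so the pair is registered by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import EIGHT_BIT, ColorImage, RasterImage

BONE_LEVEL = 230.0
TISSUE_LEVEL = 90.0
BACKGROUND_LEVEL = 5.0
TEXTURE_AMPLITUDE = 8.0  # gray levels, smoothed interior texture


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activity and noise settings of one phantom pair."""

    size: tuple[int, int] = (128, 128)
    skull_radius_frac: float = 0.42
    skull_thickness_frac: float = 0.06
    n_blobs: int = 3
    blob_sigma_frac: float = 0.08
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.skull_radius_frac < 0.5:
            raise ValidationError("skull_radius_frac must be in (0, 0.5)")
        if self.n_blobs < 1:
            raise ValidationError("n_blobs must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def _geometry(spec: PhantomSpec):
    m, n = spec.size
    rows, cols = np.mgrid[0:m, 0:n]
    cy, cx = (m - 1) / 2.0, (n - 1) / 2.0
    dist = np.hypot(rows - cy, cols - cx)
    r = spec.skull_radius_frac * min(m, n)
    half_t = spec.skull_thickness_frac * min(m, n) / 2.0
    ring = (dist >= r - half_t) & (dist <= r + half_t)
    interior = dist < r - half_t
    background = dist > r + half_t
    return dist, ring, interior, background, r, half_t, (cy, cx)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_ct_phantom(spec: PhantomSpec = PhantomSpec()) -> RasterImage:
    """Anatomical phantom: bone ring, textured interior, dark background."""
    rng = _streams(spec.seed, 2)[0]
    _, ring, interior, background, *_ = _geometry(spec)
    img = np.full(spec.size, BACKGROUND_LEVEL)
    texture = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, spec.size), 3.0, mode="mirror"
    )
    texture *= TEXTURE_AMPLITUDE / max(texture.std(), 1e-12)
    img[interior] = TISSUE_LEVEL + texture[interior]
    img[ring] = BONE_LEVEL
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, spec.size)
    return RasterImage(np.clip(np.rint(img), 0, 255), EIGHT_BIT)


def hot_iron(activity: np.ndarray) -> np.ndarray:
    """Fixed hot-iron pseudo-colormap: black -> red -> yellow -> white.

    ``activity`` in [0, 1]; returns an (M, N, 3) array in [0, 1].
    """
    a = np.clip(activity, 0.0, 1.0)
    r = np.clip(3.0 * a, 0.0, 1.0)
    g = np.clip(3.0 * a - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * a - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def make_spect_phantom(spec: PhantomSpec = PhantomSpec()) -> ColorImage:
    """Functional phantom: smooth colored activity blobs inside the head mask."""
    rng = _streams(spec.seed, 2)[1]
    m, n = spec.size
    dist, _, interior, _, r, half_t, (cy, cx) = _geometry(spec)
    rows, cols = np.mgrid[0:m, 0:n]
    sigma = spec.blob_sigma_frac * min(m, n)
    activity = np.zeros(spec.size)
    for _ in range(spec.n_blobs):
        # blob centers uniform in a disk well inside the skull
        rho = 0.6 * r * np.sqrt(rng.random())
        ang = rng.random() * 2.0 * np.pi
        by, bx = cy + rho * np.sin(ang), cx + rho * np.cos(ang)
        amp = 0.5 + 0.5 * rng.random()
        activity += amp * np.exp(
            -((rows - by) ** 2 + (cols - bx) ** 2) / (2.0 * sigma**2)
        )
    activity /= activity.max()
    if spec.noise_sd > 0:
        noise = ndimage.gaussian_filter(
            rng.normal(0.0, spec.noise_sd / 255.0, spec.size), 1.0, mode="mirror"
        )
        activity = np.clip(activity + noise, 0.0, 1.0)
    activity = activity * interior  # zero outside the head mask
    rgb = hot_iron(activity) * 255.0
    return ColorImage.from_array(np.rint(rgb), EIGHT_BIT)


def make_pair(spec: PhantomSpec = PhantomSpec()) -> tuple[ColorImage, RasterImage]:
    """A registered (SPECT-like, CT-like) pair on the same head mask."""
    return make_spect_phantom(spec), make_ct_phantom(spec)
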