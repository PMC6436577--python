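"""Simplified pulse-coupled neural network (PCNN).

One neuron per pixel.  The gray value is the external stimulus; a neuron
fires when its modulated internal activity exceeds its dynamic threshold,
the threshold jumps by ``V_theta`` on firing and decays exponentially at
rate ``alpha_theta`` otherwise, and firing neurons excite their neighbours
through the linking kernel ``W``.  The simplified model (no feeding leak,
unit feeding gain, single linking compartment) exposes exactly the three
parameters tuned by the optimizer — alpha_theta, beta, V_theta — plus the
structural choices W and T:

    F[n] = S
    L[n] = W (*) Y[n-1]
    U[n] = F[n] * (1 + beta * L[n])
    Y[n] = 1  where  U[n] > exp(-alpha_theta) * theta[n-1]   (strict)
    theta[n] = exp(-alpha_theta) * theta[n-1] + V_theta * Y[n]

with Y[0] = 0 and theta[0] = 0, so every neuron with S > 0 fires at n = 1.
The threshold decays *before* the comparison of step n.  The firing
statistic is the cumulative count over T iterations — the standard PCNN
activity measure for coefficient selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import RasterImage


def default_linking_kernel() -> np.ndarray:
    """3x3 inverse-Euclidean-distance kernel, zero center."""
    s = 1.0 / np.sqrt(2.0)
    return np.array([[s, 1.0, s], [1.0, 0.0, 1.0], [s, 1.0, s]])


@dataclass(frozen=True)
class PCNNParams:
    """Neuron parameters: the three tuned scalars plus W and T."""

    alpha_theta: float
    beta: float
    v_theta: float
    iterations: int = 100
    linking_kernel: np.ndarray = field(default_factory=default_linking_kernel)

    def __post_init__(self) -> None:
        if not (self.alpha_theta > 0 and self.v_theta > 0):
            raise ValidationError("alpha_theta and V_theta must be positive")
        if self.beta < 0:
            raise ValidationError("beta must be non-negative")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        w = np.asarray(self.linking_kernel, dtype=float)
        object.__setattr__(self, "linking_kernel", w)
        if w[w.shape[0] // 2, w.shape[1] // 2] != 0 or w.min() < 0 or w.max() <= 0:
            raise ValidationError(
                "linking kernel needs a zero center and a positive off-center weight"
            )


@dataclass(frozen=True)
class FiringMap:
    """Per-neuron cumulative firing counts over the T iterations."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.min() < 0:
            raise ValidationError("firing counts must be non-negative")


def run_pcnn(stimulus: RasterImage | np.ndarray, params: PCNNParams) -> FiringMap:
    """Iterate the network on a [0, 1] stimulus and return firing counts.

    The linking convolution uses symmetric boundary extension.  The run is
    fully deterministic.
    """
    s = (
        stimulus.to_unit().pixels
        if isinstance(stimulus, RasterImage)
        else np.asarray(stimulus, dtype=float)
    )
    if s.min() < 0.0 or s.max() > 1.0:
        raise ValidationError(
            f"stimulus range [{s.min():g}, {s.max():g}] outside [0, 1]"
        )
    decay = float(np.exp(-params.alpha_theta))
    w = params.linking_kernel
    beta = params.beta
    y = np.zeros_like(s)
    theta = np.zeros_like(s)
    counts = np.zeros(s.shape, dtype=np.int64)
    for _ in range(params.iterations):
        if beta == 0.0:
            u = s
        else:
            link = ndimage.convolve(y, w, mode="mirror")
            u = s * (1.0 + beta * link)
        theta *= decay
        y = (u > theta).astype(np.float64)
        theta += params.v_theta * y
        counts += y.astype(np.int64)
    return FiringMap(counts=counts)
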