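"""Model V1 front end.

``discount_illuminant`` converts luminance into illuminant-discounted on/off
feature-contour activity via a shunting center-surround network; these signals
later serve as sources for surface filling-in.  ``simple_cells`` applies an
odd (antisymmetric) oriented filter bank, splitting responses into the two
contrast-polarity channels; ``complex_cells`` pools the two polarities, which
makes everything downstream of it invariant to contrast sign.
``end_stopped_cells`` converts oriented activity at line terminations into
perpendicular "end cut" activity.

Orientation index k means a contour *tangent* angle of k*pi/K (y-down
coordinates); k = 0 is a horizontal contour, k = K/2 a vertical one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from fgseg._convolve import KernelBank, gaussian_kernel
from fgseg.config import EarlyVisionParams
from fgseg.stimuli import BACKGROUND, LuminanceImage


@dataclass(frozen=True)
class FeatureContourField:
    """Half-wave rectified on/off center-surround activity (dimensionless)."""

    on_activity: np.ndarray
    off_activity: np.ndarray

    @property
    def signed(self) -> np.ndarray:
        return self.on_activity - self.off_activity

    @property
    def magnitude(self) -> np.ndarray:
        return self.on_activity + self.off_activity


@dataclass(frozen=True)
class OrientedActivityField:
    """Non-negative activity indexed by (orientation, y, x).

    ``polarity`` is True for simple-cell fields, whose ``activity`` carries a
    leading polarity axis of size 2 (index 0: dark-to-light along the filter
    normal; index 1: light-to-dark).
    """

    activity: np.ndarray
    polarity: bool = False

    def __post_init__(self):
        a = np.asarray(self.activity, dtype=float)
        want = 4 if self.polarity else 3
        if a.ndim != want:
            raise ValueError(f"expected {want}D activity, got {a.ndim}D")
        object.__setattr__(self, "activity", a)

    @property
    def n_orientations(self) -> int:
        return self.activity.shape[1 if self.polarity else 0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.activity.shape[-2:]


def orientation_angles(n_orientations: int) -> np.ndarray:
    """Tangent angle of each orientation channel, k*pi/K."""
    return np.arange(n_orientations) * np.pi / n_orientations


@lru_cache(maxsize=8)
def _dog_bank(params: EarlyVisionParams) -> KernelBank:
    return KernelBank([gaussian_kernel(params.center_sigma),
                       gaussian_kernel(params.surround_sigma)])


def _odd_gabor(theta: float, wavelength: float, sigma: float) -> np.ndarray:
    """Odd Gabor with carrier along the normal of a contour with tangent theta.

    Antisymmetric under point reflection, hence exactly zero-mean: polarity
    flips of the input negate the response.
    """
    r = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    # tangent t = (cos, sin), normal n = (-sin, cos) in y-down coordinates
    b = -x * np.sin(theta) + y * np.cos(theta)   # along the normal
    env = np.exp(-(x * x + y * y) / (2 * sigma * sigma))
    k = env * np.sin(2 * np.pi * b / wavelength)
    k -= k.mean()  # enforce zero DC against rounding
    return k / np.abs(k).sum()


@lru_cache(maxsize=8)
def _gabor_bank(params: EarlyVisionParams) -> KernelBank:
    return KernelBank([_odd_gabor(t, params.gabor_wavelength, params.gabor_sigma)
                       for t in orientation_angles(params.n_orientations)])


def _axis_gaussian(theta: float, sigma_axial: float,
                   sigma_lateral: float = 1.0) -> np.ndarray:
    """Gaussian elongated along the tangent direction, sum 1."""
    r = int(np.ceil(3.0 * max(sigma_axial, sigma_lateral)))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    a = x * np.cos(theta) + y * np.sin(theta)
    b = -x * np.sin(theta) + y * np.cos(theta)
    k = np.exp(-a * a / (2 * sigma_axial ** 2) - b * b / (2 * sigma_lateral ** 2))
    return k / k.sum()


@lru_cache(maxsize=8)
def _endstop_banks(params: EarlyVisionParams):
    """Per-orientation (short, long) along-axis smoothing kernel pairs."""
    angles = orientation_angles(params.n_orientations)
    return [(KernelBank([_axis_gaussian(t, params.endstop_short_sigma)]),
             KernelBank([_axis_gaussian(t, params.endstop_long_sigma)]))
            for t in angles]


def _validate_image(image: LuminanceImage) -> np.ndarray:
    v = image.values
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("image must be finite and non-negative")
    return v


def discount_illuminant(image: LuminanceImage,
                        params: EarlyVisionParams | None = None
                        ) -> FeatureContourField:
    """Shunting center-surround response split into on and off channels.

    X = (C - S) / (A + C + S) with Gaussian center C and surround S (each
    normalized to unit mass), so a uniform field gives zero and doubling the
    luminance compresses the response (divisive gain control).
    """
    params = params or EarlyVisionParams()
    v = _validate_image(image)
    center, surround = _dog_bank(params).convolve(v)
    x = (center - surround) / (params.shunting_offset + center + surround)
    return FeatureContourField(on_activity=np.maximum(x, 0.0),
                               off_activity=np.maximum(-x, 0.0))


def simple_cells(image: LuminanceImage,
                 params: EarlyVisionParams | None = None
                 ) -> OrientedActivityField:
    """Polarity-specific oriented responses (odd filters, half-wave rectified).

    The filters are linear in luminance and exactly antisymmetric, so the
    luminance reflection L -> 2*L_bg - L swaps the two polarity channels.
    """
    params = params or EarlyVisionParams()
    v = _validate_image(image)
    responses = np.stack(_gabor_bank(params).convolve(v))
    act = np.stack([np.maximum(responses, 0.0), np.maximum(-responses, 0.0)])
    return OrientedActivityField(act, polarity=True)


def complex_cells(simple: OrientedActivityField) -> OrientedActivityField:
    """Pool the two polarity channels at each (position, orientation)."""
    if not simple.polarity:
        raise ValueError("complex_cells expects a polarity-specific field")
    return OrientedActivityField(simple.activity[0] + simple.activity[1])


def end_stopped_cells(complex_field: OrientedActivityField,
                      params: EarlyVisionParams | None = None
                      ) -> OrientedActivityField:
    """End cuts: perpendicular activity concentrated at line terminations.

    For each orientation, activity smoothed over a short along-axis window is
    compared against a long window; the rectified difference peaks where the
    line ends (the long window then reaches into empty space), and is emitted
    on the perpendicular orientation channel.
    """
    params = params or EarlyVisionParams()
    if complex_field.polarity:
        raise ValueError("end_stopped_cells expects a pooled field")
    act = complex_field.activity
    K = act.shape[0]
    banks = _endstop_banks(params)
    out = np.zeros_like(act)
    for k in range(K):
        short = banks[k][0].convolve(act[k])[0]
        long = banks[k][1].convolve(act[k])[0]
        e = np.maximum(short - long, 0.0)
        out[(k + K // 2) % K] += e
    return OrientedActivityField(out)


@lru_cache(maxsize=8)
def edge_response_scale(params: EarlyVisionParams) -> float:
    """Peak complex-cell response to a canonical full-contrast luminance step.

    Used to normalize driving input to the grouping stage so that boundary
    activity is expressed relative to a strong physical edge (dark|light step
    of the default display luminances).
    """
    v = np.full((64, 64), BACKGROUND)
    v[:, 32:] = 99.5
    v[:, :32] = 1.5
    c = complex_cells(simple_cells(LuminanceImage(v), params))
    return float(c.activity.max())
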