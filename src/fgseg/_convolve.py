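"""FFT convolution with cached kernel transforms.

The grouping loop convolves the same oriented kernel bank with an evolving
field many times per run; caching the kernel FFTs per (kernel bank, padded
shape) makes the fixed-point iteration cheap.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class KernelBank:
    """A list of 2D kernels convolved with images of a fixed shape.

    Convolution semantics (kernel flipped), 'same' output, reflective padding
    at the image border.
    """

    def __init__(self, kernels: list[np.ndarray], pad_mode: str = "reflect"):
        self.kernels = [np.asarray(k, dtype=float) for k in kernels]
        self.pad = max(max(k.shape) for k in self.kernels) // 2
        self.pad_mode = pad_mode
        self._cache: dict[tuple[int, int], list[np.ndarray]] = {}

    def _kernel_ffts(self, fshape: tuple[int, int]) -> list[np.ndarray]:
        if fshape not in self._cache:
            self._cache[fshape] = [sfft.rfft2(k, fshape) for k in self.kernels]
        return self._cache[fshape]

    def convolve(self, image: np.ndarray) -> list[np.ndarray]:
        """Convolve one image with every kernel; returns list of 2D arrays."""
        if self.pad_mode == "constant":
            img = np.pad(image, self.pad, mode="constant")
        else:
            img = np.pad(image, self.pad, mode=self.pad_mode)
        H, W = img.shape
        kh = max(k.shape[0] for k in self.kernels)
        kw = max(k.shape[1] for k in self.kernels)
        fshape = (sfft.next_fast_len(H + kh - 1), sfft.next_fast_len(W + kw - 1))
        img_fft = sfft.rfft2(img, fshape)
        out = []
        for k, kf in zip(self.kernels, self._kernel_ffts(fshape)):
            full = sfft.irfft2(img_fft * kf, fshape)
            oy, ox = (k.shape[0] - 1) // 2, (k.shape[1] - 1) // 2
            same = full[oy:oy + H, ox:ox + W]
            out.append(same[self.pad:H - self.pad, self.pad:W - self.pad].copy())
        return out


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Normalized 2D Gaussian (sum 1)."""
    r = max(1, int(np.ceil(truncate * sigma)))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    k = np.exp(-(x * x + y * y) / (2 * sigma * sigma))
    return k / k.sum()


def disc_kernel(radius: float) -> np.ndarray:
    """Flat disc, normalized to sum 1."""
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    k = (x * x + y * y <= radius * radius).astype(float)
    return k / k.sum()
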