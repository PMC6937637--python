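"""DCT-IV low-frequency truncation of FCGR images.

The type-IV discrete cosine transform with orthonormal scaling,

    X_j = sqrt(2/N) * sum_i x_i * cos(pi * (i + 1/2) * (j + 1/2) / N),

is its own inverse, which makes truncation/reconstruction round trips
trivial to reason about. An FCGR image is first centred by subtracting its
global mean (removing the DC component), transformed separably along rows
and columns, and only the top-left f x f block of low-frequency
coefficients is kept. With the default k=7 image (128 x 128) and f=30 this
compresses each image by a factor of 128^2 / 30^2 ≈ 18.2 before the SVD
stage ever sees it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft


@dataclass(frozen=True)
class SpectralParams:
    """Number of retained frequencies per dimension (default 30)."""

    f: int = 30

    def __post_init__(self) -> None:
        if self.f < 1:
            raise ValueError("f must be >= 1")


def dct_iv(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Orthonormally scaled DCT-IV; an involution (applying it twice is
    the identity to machine precision)."""
    x = np.asarray(x, dtype=float)
    if x.shape[axis] == 0:
        raise ValueError("dct_iv of an empty vector")
    return scipy.fft.dct(x, type=4, norm="ortho", axis=axis)


def reduce_image(image: np.ndarray, params: SpectralParams = SpectralParams()) -> np.ndarray:
    """Centre an image, apply the separable 2-D DCT-IV, keep the low-frequency
    f x f corner.

    Subtracting the global mean first removes the DC component; the
    transform is then applied to every row and every column (order
    immaterial), and indices 0..f-1 along both axes — the lowest
    frequencies — are returned.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    f = params.f
    if f > min(image.shape):
        raise ValueError(f"f={f} exceeds image dimension {min(image.shape)}")
    centered = image - image.mean()
    spectrum = dct_iv(dct_iv(centered, axis=0), axis=1)
    return spectrum[:f, :f]


def flatten_center(block: np.ndarray) -> np.ndarray:
    """Row-major flatten of an f x f coefficient block, centred by
    subtracting the vector's own mean (so every feature vector sums to 0)."""
    v = np.asarray(block, dtype=float).ravel(order="C")
    return v - v.mean()


def image_to_feature(image: np.ndarray, params: SpectralParams = SpectralParams()) -> np.ndarray:
    """Convenience composition: reduce_image then flatten_center."""
    return flatten_center(reduce_image(image, params))
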