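"""Radiograph enhancement: Gaussian smoothing and unsharp masking.

Images are plain 2-D ``numpy`` arrays of float intensities in [0, 1]
(the scikit-image convention); every operation clamps its output back to
that range and preserves dimensions.  File I/O normalises 8- and 16-bit
grayscale rasters to [0, 1] on read and restores the original bit depth
on write.

Enhancement here is cosmetic — landmark coordinates are supplied
separately, so filter parameters never influence a measurement.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

__all__ = [
    "as_gray_image",
    "gaussian_smooth",
    "unsharp_mask",
    "read_gray",
    "write_gray",
]

DEFAULT_SIGMA = 2.0
DEFAULT_AMOUNT = 1.0


def as_gray_image(pixels) -> np.ndarray:
    """Validate and coerce an array to a float64 [0, 1] grayscale image."""
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidInputError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite intensities")
    if img.min() < 0.0 or img.max() > 1.0:
        raise InvalidInputError("intensities must lie in [0, 1]")
    return img


def gaussian_smooth(img, sigma: float) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel (reflective boundaries).

    ``sigma`` is the kernel standard deviation in pixels; ``sigma = 0``
    returns the image unchanged.  A constant image maps to itself for any
    sigma because the kernel integrates to one.
    """
    img = as_gray_image(img)
    if not np.isfinite(sigma) or sigma < 0:
        raise InvalidInputError(f"sigma must be >= 0, got {sigma!r}")
    if sigma == 0:
        return img.copy()
    out = ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def unsharp_mask(img, sigma: float = DEFAULT_SIGMA,
                 amount: float = DEFAULT_AMOUNT) -> np.ndarray:
    """Sharpen by adding back scaled high-frequency detail.

    out = clamp(img + amount * (img - gaussian_smooth(img, sigma))).
    ``amount = 0`` is the identity; a constant image is unchanged for any
    amount because its detail term vanishes.
    """
    img = as_gray_image(img)
    if not np.isfinite(sigma) or sigma <= 0:
        raise InvalidInputError(f"sigma must be > 0, got {sigma!r}")
    if not np.isfinite(amount) or amount < 0:
        raise InvalidInputError(f"amount must be >= 0, got {amount!r}")
    if amount == 0:
        return img.copy()
    blurred = ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")
    out = img + amount * (img - blurred)
    return np.clip(out, 0.0, 1.0)


def read_gray(path) -> Tuple[np.ndarray, np.dtype]:
    """Read a grayscale raster, returning ([0, 1] float image, source dtype).

    Multi-channel inputs are reduced by the standard luminance weights.
    """
    raw = iio.imread(Path(path))
    dtype = raw.dtype
    if raw.ndim == 3:  # RGB(A) -> luminance
        rgb = raw[..., :3].astype(np.float64)
        raw = rgb @ np.array([0.2125, 0.7154, 0.0721])
        raw = raw.astype(np.float64)
    else:
        raw = raw.astype(np.float64)
    if np.issubdtype(dtype, np.integer):
        scale = float(np.iinfo(dtype).max)
        img = raw / scale
    else:
        img = raw
    return as_gray_image(np.clip(img, 0.0, 1.0)), dtype


def write_gray(path, img, dtype=np.uint8) -> None:
    """Write a [0, 1] float image at the given integer bit depth."""
    img = as_gray_image(img)
    dtype = np.dtype(dtype)
    if not np.issubdtype(dtype, np.integer):
        raise InvalidInputError(f"output dtype must be integer, got {dtype}")
    scale = float(np.iinfo(dtype).max)
    out = np.round(img * scale).astype(dtype)
    path = Path(path)
    if path.suffix.lower() in {".jpg", ".jpeg"} and dtype != np.uint8:
        out = np.round(img * 255.0).astype(np.uint8)  # JPEG is 8-bit only
    iio.imwrite(path, out)
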