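"""Image standardization ahead of segmentation.

Dermoscopy acquisitions suffer from isolated extreme-valued ("spot") pixels;
a small median filter removes them while preserving lesion borders far better
than linear smoothing.  Images are also resized to a common 256x256 raster
and reduced to luminance where downstream texture statistics need a single
channel.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "median_filter",
    "resize_to_standard",
    "to_grayscale",
    "load_image",
    "save_image",
]

# Rec. 709 luminance weights, as used by scikit-image
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Replace each pixel by the median of its ``window`` x ``window`` neighborhood.

    Borders are handled by edge replication so the output keeps the input
    size.  RGB images are filtered channel by channel.

    Parameters
    ----------
    image : 2-D grayscale or 3-D (H, W, 3) array.
    window : odd neighborhood side, default 3.
    """
    image = np.asarray(image)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if image.ndim not in (2, 3):
        raise ValueError("expected a 2-D grayscale or 3-D RGB image")
    if window > min(image.shape[0], image.shape[1]):
        raise ValueError("window exceeds image extent")
    if image.ndim == 2:
        return ndimage.median_filter(image, size=window, mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.median_filter(image[..., c], size=window, mode="nearest")
    return out


def resize_to_standard(image: np.ndarray, side: int = 256) -> np.ndarray:
    """Bilinear resize to ``side`` x ``side`` (channels preserved).

    Integer inputs come back rounded to the same dtype; float inputs stay
    float with the intensity range preserved.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.shape[:2] == (side, side):
        return image
    shape = (side, side) + image.shape[2:]
    out = resize(image, shape, order=1, preserve_range=True,
                 anti_aliasing=image.shape[0] > side)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted channel collapse; identity for grayscale input.

    The output lives in the same intensity range as the input (the weights
    are convex).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return image.astype(float) @ _LUMA
    raise ValueError("expected (H, W) or (H, W, 3) image")


def load_image(path: str | Path, as_float: bool = True) -> np.ndarray:
    """Read a PNG/JPEG; optionally rescale 8-bit intensities to [0, 1]."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    if as_float and np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    return img


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an image; float arrays in [0, 1] are quantized to 8 bit."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.floating):
        image = np.clip(np.rint(image * 255), 0, 255).astype(np.uint8)
    elif image.dtype == bool:
        image = image.astype(np.uint8) * 255
    iio.imwrite(Path(path), image)
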