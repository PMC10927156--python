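"""Preliminary brain segmentation: threshold the skull, strip it, fill the ring.

Head-CT intensity structure drives the whole step: bone is the brightest
tissue (near the slice maximum), while brain parenchyma and extracranial
soft tissue sit far below it.  The skull image ``e1`` keeps every pixel
within 15 gray levels of the slice maximum; the skull-removed image ``e2``
keeps the band [1, Max(E) - 20].  Filling the enclosed hole of ``e1``
yields mask 1, and multiplying ``e2`` by mask 1 discards the scalp, pillow
and any other tissue outside the bone ring.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .ct_io import as_binary_mask, as_gray_image

__all__ = [
    "SKULL_OFFSET",
    "SOFT_TISSUE_OFFSET",
    "extract_skull",
    "remove_skull",
    "fill_holes",
    "apply_mask",
    "denoise_median",
]

#: Offset below the slice maximum that still counts as skull.
SKULL_OFFSET = 15
#: Offset below the slice maximum above which pixels are discarded as bone.
SOFT_TISSUE_OFFSET = 20


def extract_skull(E: np.ndarray) -> np.ndarray:
    """Binarize the skull: 1 where ``E >= Max(E) - 15``, else 0.

    Raises
    ------
    ValueError
        If the slice is identically zero (the threshold would mark every
        pixel as bone).
    """
    E = as_gray_image(E)
    max_e = int(E.max())
    if max_e == 0:
        raise ValueError("degenerate all-zero slice: skull threshold undefined")
    return (E.astype(np.int32) >= max_e - SKULL_OFFSET).astype(np.uint8)


def remove_skull(E: np.ndarray) -> np.ndarray:
    """Suppress bone: keep ``E`` in the band [1, Max(E) - 20], zero elsewhere."""
    E = as_gray_image(E)
    max_e = int(E.max())
    keep = (E >= 1) & (E.astype(np.int32) <= max_e - SOFT_TISSUE_OFFSET)
    return np.where(keep, E, 0).astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed background regions of a binary mask.

    Background reachability uses 4-connectivity, so a closed ring that is
    only diagonally tight still encloses its interior; a ring with a gap
    that connects interior to the border is left unchanged.
    """
    mask = as_binary_mask(mask)
    # 4-connected background <=> structure of connectivity 1 (scipy default).
    filled = ndimage.binary_fill_holes(mask)
    return filled.astype(np.uint8)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Element-wise product of an image with a binary mask."""
    image = np.asarray(image)
    mask = as_binary_mask(mask)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    return (image * mask).astype(image.dtype)


def denoise_median(image: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median-filter an image with a ``kernel x kernel`` window.

    Edge handling replicates the border pixel ('nearest'); the kernel must
    be odd so the window has a center.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"median kernel must be odd and >= 3, got {kernel}")
    image = np.asarray(image)
    return ndimage.median_filter(image, size=kernel, mode="nearest")
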