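"""Reading and writing head-CT slice images.

The pipeline works on single-channel 8-bit slices (``GrayImage``: a 2-D
``uint8`` array with values in [0, 255]) and on binary masks
(``BinaryMask``: a 2-D ``uint8`` array with values in {0, 1}).  Slices
arrive as 8-bit PNGs, either grayscale or RGB; RGB input is reduced to one
channel with the ITU-R BT.601 luma weights, which is also what MATLAB's
``rgb2gray`` and Pillow's ``convert("L")`` use.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = ["load_slice", "save_image", "to_gray", "as_gray_image", "as_binary_mask"]

#: ITU-R BT.601 luma weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])

MIN_SIDE = 32


def as_gray_image(pixels: np.ndarray, min_side: int = 1) -> np.ndarray:
    """Validate and return ``pixels`` as a canonical GrayImage (2-D uint8).

    Slice-level entry points (file loading, classifier preprocessing) pass
    ``min_side=MIN_SIDE``; the pixel algebra accepts any 2-D extent.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"GrayImage must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < min_side or arr.shape[1] < min_side:
        raise ValueError(f"GrayImage sides must be >= {min_side}, got {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("GrayImage values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_binary_mask(pixels: np.ndarray) -> np.ndarray:
    """Validate and return ``pixels`` as a canonical BinaryMask (2-D uint8 in {0,1})."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"BinaryMask must be 2-D, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"BinaryMask values must be exactly {{0,1}}, got {uniq[:10]}")
    return arr.astype(np.uint8)


def to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W) or (H, W, 3) uint8 array to a single gray channel.

    3-channel input is combined with the BT.601 weights (0.299, 0.587, 0.114)
    and rounded to the nearest integer; already-gray input passes through
    unchanged, so the conversion is idempotent.
    """
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        gray = np.rint(rgb @ _LUMA)
        return np.clip(gray, 0, 255).astype(np.uint8)
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {arr.shape}")


def load_slice(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit PNG slice and return it as a GrayImage."""
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB", "RGBA", "P", "1"):
                raise ValueError(
                    f"{path}: unsupported image mode {im.mode!r}; expected 8-bit gray or RGB"
                )
            if im.mode in ("P", "1"):
                im = im.convert("L")
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    return as_gray_image(to_gray(arr), min_side=MIN_SIDE)


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a GrayImage or BinaryMask as an 8-bit grayscale PNG.

    Binary masks (values in {0,1}) are scaled to {0, 255} so the file is
    viewable; gray images are written verbatim, so save/load round-trips are
    lossless.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    vals = np.unique(arr)
    if np.all(np.isin(vals, (0, 1))):
        arr = (arr * 255).astype(np.uint8)
    else:
        arr = arr.astype(np.uint8)
    try:
        Image.fromarray(arr, mode="L").save(os.fspath(path), format="PNG")
    except (FileNotFoundError, OSError) as exc:
        raise OSError(f"cannot write image {path!r}: {exc}") from exc
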