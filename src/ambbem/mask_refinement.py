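"""Mask re-segmentation: median filtering, component counting, and the
classification-driven cleanup of mask 2.

After the preliminary segmentation multiplies the skull-removed image by
mask 1, small islands of non-brain tissue can survive inside the skull
outline.  Median filtering the masked image and binarizing it gives
mask 2; if mask 2 has a single connected region it is final.  Otherwise
the slice class decides the repair: single-region slices keep only the
component grown from a seed found near the bottom of the image midline
(non-brain leftovers sit above the parenchyma, so a bottom-up search lands
in brain), while multi-region slices keep the k largest components, k
being the region count the classifier reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_io import as_binary_mask
from .layer_classifier import LayerClass
from .preliminary_segmentation import denoise_median

__all__ = [
    "SeedPoint", "SeedSelectionError", "make_mask2", "count_components",
    "select_seed", "region_grow", "keep_largest_regions", "refine_mask",
]

_STRUCTS = {4: ndimage.generate_binary_structure(2, 1),
            8: ndimage.generate_binary_structure(2, 2)}

#: Rows the seed is moved up after the first bottom-up hit.
SEED_LIFT = 5


class SeedSelectionError(RuntimeError):
    """No foreground found in the midline band."""


@dataclass(frozen=True)
class SeedPoint:
    row: int
    col: int


def make_mask2(masked_image: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median-filter the masked image and binarize (>0) to mask 2."""
    filtered = denoise_median(np.asarray(masked_image), kernel)
    return (filtered > 0).astype(np.uint8)


def count_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of foreground connected components."""
    mask = as_binary_mask(mask)
    _, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    return int(n)


def select_seed(mask: np.ndarray, band_half_width: int | None = None) -> SeedPoint:
    """Bottom-up seed search in a band around the image midline.

    Rows are scanned from the bottom; within the first row holding
    foreground in the band, the pixel nearest the midline wins.  The point
    is then lifted 5 rows for robustness; if the lifted point is
    background, it steps further up the same column to the nearest
    foreground pixel.
    """
    mask = as_binary_mask(mask)
    h, w = mask.shape
    if band_half_width is None:
        band_half_width = max(1, w // 16)
    mid = w // 2
    lo, hi = max(0, mid - band_half_width), min(w, mid + band_half_width + 1)
    band = mask[:, lo:hi]
    rows = np.flatnonzero(band.any(axis=1))
    if rows.size == 0:
        raise SeedSelectionError("no foreground within the midline band")
    row = int(rows[-1])
    cols = np.flatnonzero(band[row]) + lo
    col = int(cols[np.argmin(np.abs(cols - mid))])
    row = max(0, row - SEED_LIFT)
    if mask[row, col] == 0:
        above = np.flatnonzero(mask[: row + 1, col])
        below = np.flatnonzero(mask[row:, col])
        if above.size:                       # keep stepping up the column
            row = int(above[-1])
        elif below.size:
            row = int(below[0] + row)
        else:                                # fall back into the band hit
            row = int(rows[-1])
    return SeedPoint(row=row, col=col)


def region_grow(mask: np.ndarray, seed: SeedPoint, connectivity: int = 8) -> np.ndarray:
    """Grow from the seed across the binary mask.

    With a binary homogeneity criterion, growth is exactly the seed's
    connected component; the output is always a subset of the input.
    """
    mask = as_binary_mask(mask)
    if mask[seed.row, seed.col] != 1:
        raise ValueError(f"seed {seed} does not lie on foreground")
    lab, _ = ndimage.label(mask, structure=_STRUCTS[connectivity])
    return (lab == lab[seed.row, seed.col]).astype(np.uint8)


def keep_largest_regions(mask: np.ndarray, k: int, connectivity: int = 8) -> np.ndarray:
    """Union of the k largest components (ties: smaller row-major first
    pixel wins).  Fewer than k components: the mask is returned whole."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = as_binary_mask(mask)
    lab, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    if n <= k:
        return mask.copy()
    areas = np.bincount(lab.ravel())[1:]
    first_pix = ndimage.minimum(
        np.arange(mask.size).reshape(mask.shape), lab, index=range(1, n + 1))
    order = sorted(range(n), key=lambda i: (-areas[i], first_pix[i]))
    keep = np.array([i + 1 for i in order[:k]])
    return np.isin(lab, keep).astype(np.uint8)


def refine_mask(mask2: np.ndarray, layer: LayerClass, *,
                band_half_width: int | None = None,
                connectivity: int = 8) -> np.ndarray:
    """Dispatch the re-segmentation of mask 2 by slice class.

    Single-component masks pass through.  Basis cranii and single-region
    slices take the region-growing path (falling back to the largest
    component if no seed is found in the midline band); two- and
    multi-region slices keep the 2 or 3 largest components.
    """
    mask2 = as_binary_mask(mask2)
    if count_components(mask2, connectivity) <= 1:
        return mask2.copy()
    if layer in (LayerClass.BASIS_CRANII, LayerClass.SINGLE_REGION):
        try:
            seed = select_seed(mask2, band_half_width)
            return region_grow(mask2, seed, connectivity)
        except SeedSelectionError:
            return keep_largest_regions(mask2, 1, connectivity)
    k = 2 if layer == LayerClass.TWO_REGIONS else 3
    return keep_largest_regions(mask2, k, connectivity)
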