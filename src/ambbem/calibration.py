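"""Calibration of the TV regression model on the phantom generator.

The closure loop's acceptance threshold TV is predicted per slice from the
skull-to-soft-tissue area ratio.  The shipped coefficients are obtained by
running this calibration once on 142 seeded phantoms spanning the
non-basis layer classes, measuring for each the soft-tissue area (nonzero
support of the skull-removed image), the skull area, and the filled
fraction of the completely filled mask, then fitting the regression.
"""

from __future__ import annotations

import numpy as np

from .layer_classifier import LayerClass
from .phantom import generate_dataset
from .preliminary_segmentation import extract_skull, fill_holes, remove_skull
from .skull_closure import TVModel, fit_tv_model, measure_soft_tissue_area

__all__ = ["calibration_samples", "calibrate_tv_model"]

CALIBRATION_N = 142
CALIBRATION_SEED = 20240311
CALIBRATION_IMAGE_SIZE = 256

_NON_BASIS_MIX = {LayerClass.SINGLE_REGION: 0.5,
                  LayerClass.TWO_REGIONS: 0.3,
                  LayerClass.MULTI_REGION: 0.2}


def calibration_samples(n: int = CALIBRATION_N, seed: int = CALIBRATION_SEED,
                        image_size: int = CALIBRATION_IMAGE_SIZE
                        ) -> list[tuple[float, float, float]]:
    """(soft_tissue_area, skull_area, complete-fill fraction) per phantom.

    Gap-free phantoms only: the regression models the *complete* mask, so
    the fill must succeed without any closing.
    """
    samples = []
    for sample in generate_dataset(n, _NON_BASIS_MIX, seed,
                                   image_size=image_size, gap_prob=0.0):
        e1 = extract_skull(sample.image)
        mask = fill_holes(e1)
        s_e1, s_mask = int(e1.sum()), int(mask.sum())
        soft = measure_soft_tissue_area(remove_skull(sample.image))
        samples.append((float(soft), float(s_e1), (s_mask - s_e1) / s_mask))
    return samples


def calibrate_tv_model(n: int = CALIBRATION_N, seed: int = CALIBRATION_SEED,
                       image_size: int = CALIBRATION_IMAGE_SIZE) -> TVModel:
    """Fit the TV regression on freshly generated phantoms."""
    return fit_tv_model(calibration_samples(n, seed, image_size))
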