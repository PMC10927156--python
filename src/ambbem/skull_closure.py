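"""Fill detection and adaptive skull-gap closure.

Filling the thresholded skull only yields a usable mask when the bone ring
actually encloses the brain.  On slices where it does not, this module
detects the failure through the filled-area fraction

    q = (S_i - S_e1) / S_i

(``S_i``: mask area after the i-th cycle, ``S_e1``: skull area) and repairs
the ring by morphological closing with a disk whose radius grows by one
each cycle, refilling and re-testing against an adaptive threshold ``TV``.
``TV`` is predicted per slice by a linear regression of the complete-mask
filled fraction on the skull-to-soft-tissue area ratio; on basis cranii
slices — where the brain is a small part of the mask and the regression
extrapolates poorly — ``TV`` is reassigned once to the fixed constant
0.2485.  The loop is capped at 5 cycles so slices whose complete fill
still sits below ``TV`` cannot spin forever.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.morphology import closing, disk

from .ct_io import as_binary_mask
from .layer_classifier import LayerClass
from .preliminary_segmentation import fill_holes

__all__ = [
    "BASIS_CRANII_TV", "MAX_CYCLES", "ClosureState", "TVModel",
    "compute_q", "predict_tv", "fit_tv_model", "close_skull_loop",
    "measure_soft_tissue_area", "trace_to_json", "DEFAULT_TV_MODEL",
]

#: Mean brain-area fraction of the complete mask at the basis cranii layer.
BASIS_CRANII_TV = 0.2485
#: Hard cap on closing cycles.
MAX_CYCLES = 5

_TV_CLAMP = (0.01, 0.99)


@dataclass(frozen=True)
class ClosureState:
    """One record of the closure loop's bookkeeping."""

    i: int                # cycle index (0 = initial fill, no closing yet)
    S_i: int              # mask area after this cycle, pixels
    S_e1: int             # skull area, pixels (fixed at entry)
    q: float              # filled-area fraction (S_i - S_e1) / S_i
    TV: float             # acceptance threshold in force at this cycle
    tv_source: str        # "regression" or "basis_cranii_constant"


@dataclass(frozen=True)
class TVModel:
    """Linear TV predictor: TV = intercept + slope * (skull/soft-tissue)."""

    intercept: float
    slope: float
    r: float = float("nan")          # fit diagnostic (Pearson R of the fit)
    basis_cranii_constant: float = BASIS_CRANII_TV


def compute_q(S_i: int, S_e1: int) -> float:
    """Filled-area fraction of the mask: (S_i - S_e1) / S_i."""
    if S_i <= 0:
        raise ValueError("mask area S_i must be positive")
    if S_e1 > S_i:
        raise ValueError("skull area cannot exceed the mask area")
    return (S_i - S_e1) / S_i


def predict_tv(model: TVModel, soft_tissue_area: int, skull_area: int,
               layer: LayerClass | None = None) -> float:
    """Per-slice TV.  Basis cranii slices get the fixed constant; other
    layers get the clamped linear prediction on skull/soft-tissue ratio."""
    if layer == LayerClass.BASIS_CRANII:
        return model.basis_cranii_constant
    if soft_tissue_area <= 0 or skull_area <= 0:
        raise ValueError("areas must be positive to predict TV")
    tv = model.intercept + model.slope * (skull_area / soft_tissue_area)
    return float(np.clip(tv, *_TV_CLAMP))


def fit_tv_model(samples: list[tuple[float, float, float]]) -> TVModel:
    """OLS fit of complete-mask brain fraction on skull/soft-tissue ratio.

    ``samples`` holds (soft_tissue_area, skull_area, brain_fraction)
    triples.  Requires at least 3 non-collinear samples.
    """
    if len(samples) < 3:
        raise ValueError("TV regression needs at least 3 samples")
    soft = np.array([s[0] for s in samples], dtype=float)
    skull = np.array([s[1] for s in samples], dtype=float)
    frac = np.array([s[2] for s in samples], dtype=float)
    if np.any(soft <= 0):
        raise ValueError("soft-tissue areas must be positive")
    ratio = skull / soft
    if np.ptp(ratio) == 0:
        raise ValueError("rank-deficient design: covariate is constant")
    X = np.column_stack([np.ones_like(ratio), ratio])
    (intercept, slope), *_ = np.linalg.lstsq(X, frac, rcond=None)
    pred = X @ (intercept, slope)
    ss_res = float(np.sum((frac - pred) ** 2))
    ss_tot = float(np.sum((frac - frac.mean()) ** 2))
    r = 1.0 if ss_tot == 0 else float(np.sqrt(max(0.0, 1.0 - ss_res / ss_tot)))
    return TVModel(intercept=float(intercept), slope=float(slope), r=r)


#: Calibrated on 142 seeded phantoms from this package's generator (see
#: ambbem.calibration.calibrate_tv_model, which reproduces these numbers).
DEFAULT_TV_MODEL = TVModel(intercept=0.9489, slope=-0.8277, r=0.9599)


def measure_soft_tissue_area(e2: np.ndarray) -> int:
    """Pixel count of the skull-removed image's nonzero support."""
    return int(np.count_nonzero(np.asarray(e2)))


def close_skull_loop(e1: np.ndarray, layer: LayerClass,
                     model: TVModel = DEFAULT_TV_MODEL,
                     max_cycles: int = MAX_CYCLES, *,
                     soft_tissue_area: int | None = None,
                     tv: float | None = None,
                     mask_log: list | None = None) -> tuple[np.ndarray, list[ClosureState]]:
    """Run the closure loop on a skull mask and return (mask 1, trace).

    The skull is filled once; while the filled fraction ``q`` stays at or
    below ``TV`` and cycles remain, the skull is closed with a disk of
    radius equal to the cycle index and refilled.  On a basis cranii slice
    the first failed test reassigns ``TV`` to the 0.2485 constant (at most
    once) and re-tests before any closing.  Hitting ``max_cycles`` is not
    an error: the best mask so far is returned and the trace shows the
    loop ran dry.

    ``tv`` may supply a precomputed regression threshold; otherwise it is
    predicted from ``soft_tissue_area`` via ``model``.  When ``mask_log``
    is a list, the filled mask of every cycle (including the initial fill)
    is appended to it, aligned with the trace.
    """
    e1 = as_binary_mask(e1)
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    if tv is None:
        if soft_tissue_area is None:
            raise ValueError("need soft_tissue_area (or a precomputed tv)")
        tv = predict_tv(model, soft_tissue_area, int(e1.sum()) or 1, layer=None)
    tv = float(tv)
    tv_source = "regression"

    S_e1 = int(e1.sum())
    mask = fill_holes(e1)
    skull = e1.astype(bool)
    trace: list[ClosureState] = []

    def record(i: int, m: np.ndarray) -> float:
        q = compute_q(int(m.sum()), S_e1)
        trace.append(ClosureState(i=i, S_i=int(m.sum()), S_e1=S_e1, q=q,
                                  TV=tv, tv_source=tv_source))
        if mask_log is not None:
            mask_log.append(m.copy())
        return q

    q = record(0, mask)
    reassigned = False
    i = 0
    while q <= tv and i < max_cycles:
        if layer == LayerClass.BASIS_CRANII and not reassigned:
            tv = model.basis_cranii_constant
            tv_source = "basis_cranii_constant"
            reassigned = True
            trace[-1] = ClosureState(i=trace[-1].i, S_i=trace[-1].S_i,
                                     S_e1=S_e1, q=trace[-1].q, TV=tv,
                                     tv_source=tv_source)
            q = trace[-1].q
            continue
        i += 1
        skull = closing(skull, disk(i))
        mask = fill_holes(skull.astype(np.uint8))
        mask[e1 == 1] = 1                # mask 1 always contains the skull
        q = record(i, mask)
    return mask, trace


def trace_to_json(trace: list[ClosureState]) -> str:
    """Serialize a closure trace as JSON lines (one record per cycle)."""
    return "\n".join(json.dumps(asdict(state)) for state in trace)
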