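"""Synthetic axial head-CT phantoms with pixel-perfect ground truth.

Each phantom reproduces the intensity structure a brain-extraction
pipeline exploits on real head CT: a bright elliptical skull ring near the
slice maximum, brain parenchyma as a Gaussian intensity peak far below it
(the d1 peak), optional hematoma at an intermediate peak (d2), extracranial
scalp at an intensity close to parenchyma, and an optional pillow arc under
the head.  Slice taxonomy follows the axial anatomy the pipeline cares
about:

* ``SINGLE_REGION`` — one brain blob inside a closed (or gapped) ring;
* ``TWO_REGIONS`` / ``MULTI_REGION`` — bone septa (sella-turcica-like)
  split the intracranial space into 2 or 3 disjoint brain areas;
* ``BASIS_CRANII`` — skull-base slice: most of the intracranial area is
  bone, the brain occupies only ~25-31% of the filled skull outline, and
  the surrounding soft tissue is thick.

Skull gaps are carved as soft-tissue breaks of a prescribed pixel width so
the ring no longer encloses its interior — the failure mode the closure
loop exists to repair.  Everything is deterministic given ``spec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .layer_classifier import LayerClass

__all__ = ["PhantomSpec", "PhantomSample", "PhantomConstructionError",
           "generate_phantom", "generate_dataset"]

# label-map codes
_BG, _SKULL, _SCALP, _BRAIN, _HEMATOMA, _PILLOW, _POCKET = range(7)

_EIGHT = np.ones((3, 3), dtype=int)


class PhantomConstructionError(ValueError):
    """Raised when a spec cannot be realised geometrically."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Intensity defaults respect the tissue ordering seen on real slices:
    skull (250) > hematoma (190) > brain (110), with scalp (100) within 30
    gray levels of brain.  ``gap_width_px`` is the opening of each skull
    break in pixels.
    """

    image_size: int = 512
    n_brain_regions: int = 1
    is_basis_cranii: bool = False
    n_skull_gaps: int = 0
    gap_width_px: int = 3
    skull_mean: int = 250
    brain_mean: int = 110
    brain_sd: float = 12.0
    hematoma_mean: int = 190
    include_hematoma: bool = False
    include_pillow: bool = False
    include_remnant: bool = False
    scalp_mean: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.skull_mean > self.hematoma_mean > self.brain_mean):
            raise ValueError("tissue ordering requires skull > hematoma > brain means")
        if abs(self.brain_mean - self.scalp_mean) > 30:
            raise ValueError("brain and scalp means must lie within 30 gray levels")
        if self.n_brain_regions not in (1, 2, 3):
            raise ValueError("n_brain_regions must be 1, 2 or 3")
        if self.is_basis_cranii and self.n_brain_regions != 1:
            raise ValueError("basis cranii slices have a single brain area")
        if self.n_skull_gaps < 0 or self.gap_width_px < 1:
            raise ValueError("invalid gap specification")
        if self.image_size < 64:
            raise PhantomConstructionError("image_size below 64 px is unsatisfiable")
        if self.n_brain_regions == 3 and self.image_size < 96:
            raise PhantomConstructionError("3 brain regions need image_size >= 96")

    @property
    def layer_class(self) -> LayerClass:
        if self.is_basis_cranii:
            return LayerClass.BASIS_CRANII
        return {1: LayerClass.SINGLE_REGION,
                2: LayerClass.TWO_REGIONS,
                3: LayerClass.MULTI_REGION}[self.n_brain_regions]


@dataclass(frozen=True)
class PhantomSample:
    """A rendered phantom: image, ground-truth brain mask, class label."""

    image: np.ndarray
    truth_mask: np.ndarray
    layer_class: LayerClass
    spec: PhantomSpec
    tissue_counts: dict = field(default_factory=dict)


def _ellipse(shape, cy, cx, ry, rx):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _carve_gaps(labels, spec, rng, cy, cx, ry, rx, blocked):
    """Turn ``n_skull_gaps`` bone wedges into soft-tissue breaks.

    Each gap is a straight channel of width ``gap_width_px`` carved along
    an outward ray, so it breaks the ring (and, on basis-cranii slices,
    the whole bone bed) at the stated width.  ``blocked`` lists elliptical
    angles (septum junctions, the remnant spur) to avoid so a gap is never
    plugged by other bone.
    """
    yy, xx = np.indices(labels.shape)
    dy, dx = yy - cy, xx - cx
    angles: list[float] = []
    for _ in range(spec.n_skull_gaps):
        for _try in range(200):
            a = rng.uniform(-np.pi, np.pi)
            if all(_angdist(a, b) > 0.5 for b in blocked) and \
               all(_angdist(a, b) > 0.45 for b in angles):
                angles.append(a)
                break
        else:  # pragma: no cover - only for absurd gap counts
            raise PhantomConstructionError("cannot place skull gaps apart from septa")
    for a in angles:
        # carve a straight channel of constant width along the outward ray
        # through the elliptical boundary point at angle a
        uy, ux = ry * np.sin(a), rx * np.cos(a)
        norm = np.hypot(uy, ux)
        uy, ux = uy / norm, ux / norm
        perp = np.abs(dy * ux - dx * uy)
        outward = dy * uy + dx * ux > 0
        # strict inequality keeps the carved corridor at MOST the stated
        # width under rasterization (a half-pixel ray offset would
        # otherwise widen it by one column)
        channel = (perp < spec.gap_width_px / 2.0) & outward
        labels[channel & (labels == _SKULL)] = _SCALP
    return angles


def _angdist(a, b):
    d = np.abs(a - b)
    return np.minimum(d, 2 * np.pi - d)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom slice deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    labels = np.zeros((n, n), dtype=np.uint8)

    cy = n * (0.48 + rng.uniform(-0.01, 0.01))
    cx = n * (0.50 + rng.uniform(-0.01, 0.01))
    ry = n * rng.uniform(0.30, 0.34)
    rx = n * rng.uniform(0.25, 0.29)
    t = max(4.0, n * rng.uniform(0.020, 0.045))        # ring thickness
    s = max(3.0, n * rng.uniform(0.025, 0.045))        # scalp thickness
    if spec.is_basis_cranii:
        s *= 2.2                                       # thick skull-base soft tissue

    outer = _ellipse(labels.shape, cy, cx, ry, rx)
    inner = _ellipse(labels.shape, cy, cx, ry - t, rx - t)
    scalp = _ellipse(labels.shape, cy, cx, ry + s, rx + s) & ~outer
    labels[scalp] = _SCALP
    labels[outer & ~inner] = _SKULL

    blocked: list[float] = []
    t_sep = max(5, int(round(0.035 * n)))

    if spec.is_basis_cranii:
        # bone-dominated interior with a small central brain area
        frac = rng.uniform(0.25, 0.31)
        labels[inner] = _SKULL
        brain = _ellipse(labels.shape, cy, cx, np.sqrt(frac) * ry, np.sqrt(frac) * rx)
        labels[brain] = _BRAIN
    else:
        labels[inner] = _BRAIN
        if spec.n_brain_regions >= 2:
            y_sep = int(round(cy + rng.uniform(0.05, 0.22) * ry))
            band = np.zeros_like(outer)
            band[y_sep:y_sep + t_sep, :] = True
            labels[band & outer] = _SKULL
            yl = (y_sep + t_sep / 2 - cy) / ry
            blocked += [np.arctan2(yl, np.sqrt(max(1e-6, 1 - yl ** 2))),
                        np.arctan2(yl, -np.sqrt(max(1e-6, 1 - yl ** 2)))]
        if spec.n_brain_regions == 3:
            x_sep = int(round(cx + rng.uniform(-0.08, 0.08) * rx))
            band = np.zeros_like(outer)
            band[y_sep:, x_sep:x_sep + t_sep] = True
            labels[band & outer] = _SKULL
            blocked.append(np.pi / 2)                   # bottom junction

    if spec.include_remnant and not spec.is_basis_cranii:
        # a non-brain soft-tissue pocket near the vertex, walled off by a
        # bone rim that is tied to the inner table by a short bone spur
        pr = 0.06 * n
        rim = max(5, int(round(0.03 * n)))
        pcy = cy - 0.55 * (ry - t)
        pcx = cx + rng.uniform(-0.08, 0.08) * rx
        pocket = _ellipse(labels.shape, pcy, pcx, pr, pr)
        wall = _ellipse(labels.shape, pcy, pcx, pr + rim, pr + rim) & ~pocket
        spur = np.zeros_like(outer)
        spur[: int(pcy), int(pcx - t_sep / 2): int(pcx + t_sep / 2)] = True
        labels[(wall | (spur & inner)) & (labels == _BRAIN)] = _SKULL
        labels[wall & inner] = _SKULL
        labels[pocket & inner] = _POCKET
        blocked.append(-np.pi / 2)                      # keep gaps off the spur

    gap_angles = []
    if spec.n_skull_gaps:
        gap_angles = _carve_gaps(labels, spec, rng, cy, cx, ry, rx, blocked)

    if spec.include_hematoma:
        lab, nlab = ndimage.label(labels == _BRAIN, structure=_EIGHT)
        if nlab:
            areas = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, nlab + 1))
            biggest = int(np.argmax(areas)) + 1
            cyh, cxh = ndimage.center_of_mass(lab == biggest)
            hem = _ellipse(labels.shape, cyh, cxh, 0.07 * n, 0.06 * n) & (lab == biggest)
            labels[hem] = _HEMATOMA

    if spec.include_pillow:
        top = cy + ry + s
        band_lo = int(min(n - 2, top + 0.03 * n))
        band_hi = int(min(n, band_lo + 0.05 * n))
        pil = np.zeros_like(outer)
        pil[band_lo:band_hi, int(0.15 * n): int(0.85 * n)] = True
        labels[pil & (labels == _BG)] = _PILLOW

    image = _render(labels, spec, rng)

    truth = np.isin(labels, (_BRAIN, _HEMATOMA))
    lab, ncomp = ndimage.label(truth, structure=_EIGHT)
    if ncomp != spec.n_brain_regions or not truth.any():
        raise PhantomConstructionError(
            f"constructed {ncomp} brain regions, wanted {spec.n_brain_regions}")

    counts = {name: int(np.sum(labels == code)) for name, code in
              [("skull", _SKULL), ("scalp", _SCALP), ("brain", _BRAIN),
               ("hematoma", _HEMATOMA), ("pillow", _PILLOW), ("pocket", _POCKET)]}
    counts["gap_angles"] = [float(a) for a in gap_angles]
    return PhantomSample(image=image, truth_mask=truth.astype(np.uint8),
                         layer_class=spec.layer_class, spec=spec,
                         tissue_counts=counts)


def _render(labels: np.ndarray, spec: PhantomSpec, rng) -> np.ndarray:
    """Per-tissue Gaussian intensities, clipped so the classes stay ordered
    and bone alone occupies the top 15 gray levels below the maximum."""
    img = np.zeros(labels.shape, dtype=np.float64)
    recipes = {
        _SKULL: (spec.skull_mean, 3.0, spec.skull_mean - 7, 255),
        _SCALP: (spec.scalp_mean, 8.0, 40, 160),
        _BRAIN: (spec.brain_mean, spec.brain_sd, 40, 160),
        _HEMATOMA: (spec.hematoma_mean, 6.0, 165, 220),
        _PILLOW: (140, 6.0, 100, 180),
        _POCKET: (spec.scalp_mean - 5, 8.0, 40, 160),
    }
    for code, (mean, sd, lo, hi) in recipes.items():
        sel = labels == code
        if sel.any():
            img[sel] = np.clip(rng.normal(mean, sd, int(sel.sum())), lo, hi)
    # pin the slice maximum at 255 inside dense bone so the Eq-1 band
    # (Max-15) is anchored regardless of noise draws
    skull_idx = np.flatnonzero(labels.ravel() == _SKULL)
    if skull_idx.size:
        img.ravel()[skull_idx[:: max(1, skull_idx.size // 5)][:5]] = 255
    return np.rint(np.clip(img, 0, 255)).astype(np.uint8)


def generate_dataset(n: int, class_mix: dict[LayerClass, float], seed: int,
                     image_size: int = 512, gap_prob: float = 0.3,
                     hematoma_prob: float = 0.3, pillow_prob: float = 0.5,
                     remnant_prob: float = 0.0) -> list[PhantomSample]:
    """Generate ``n`` phantoms with class labels in the given proportions.

    Counts per class follow largest-remainder rounding of the mix; optional
    features (gaps, hematoma, pillow, remnant) are drawn per sample with
    the stated probabilities; per-sample seeds derive from the master seed,
    so the same call is bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not class_mix:
        raise ValueError("empty class mix")
    classes = sorted(class_mix, key=int)
    props = np.array([class_mix[c] for c in classes], dtype=float)
    if props.min() < 0 or not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must be non-negative and sum to 1")

    raw = props * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1

    master = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for cls, k in zip(classes, counts):
        for _ in range(int(k)):
            sub = int(master.integers(0, 2 ** 31 - 1))
            r = np.random.default_rng(sub)
            spec = PhantomSpec(
                image_size=image_size,
                n_brain_regions=1 if cls == LayerClass.BASIS_CRANII else (cls.n_regions or 1),
                is_basis_cranii=cls == LayerClass.BASIS_CRANII,
                n_skull_gaps=int(r.integers(1, 4)) if r.random() < gap_prob else 0,
                gap_width_px=int(r.integers(1, 6)),
                include_hematoma=bool(r.random() < hematoma_prob),
                include_pillow=bool(r.random() < pillow_prob),
                include_remnant=bool(cls == LayerClass.SINGLE_REGION
                                     and r.random() < remnant_prob),
                seed=sub,
            )
            samples.append(generate_phantom(spec))
    order = np.random.default_rng(seed + 1).permutation(len(samples))
    return [samples[i] for i in order]
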