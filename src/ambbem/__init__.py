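"""AMBBEM: adaptive mask-based brain extraction for axial head-CT slices.

The package couples classical threshold-and-morphology segmentation with a
4-way slice classifier: a bright-bone threshold and hole fill build a first
mask, an adaptive closure loop repairs unclosed skulls, and the slice
class steers how a multi-component mask is re-segmented.  A synthetic
phantom generator with pixel-perfect ground truth makes every stage
testable without clinical data.
"""

from .ct_io import load_slice, save_image
from .evaluation_metrics import ConfusionCounts, MetricsReport, ass, confusion, mbf, miou, mpa
from .layer_classifier import (ClassifierConfig, HeuristicLayerClassifier,
                               ImprovedResNet50Classifier, LayerClass,
                               build_improved_resnet50, classify,
                               evaluate_classifier, preprocess, train_classifier)
from .mask_refinement import (SeedPoint, count_components, keep_largest_regions,
                              make_mask2, refine_mask, region_grow, select_seed)
from .phantom import PhantomSample, PhantomSpec, generate_dataset, generate_phantom
from .pipeline import (PipelineConfig, SegmentationResult, SliceRejectedError,
                       extract_batch, extract_brain)
from .preliminary_segmentation import (apply_mask, denoise_median, extract_skull,
                                       fill_holes, remove_skull)
from .skull_closure import (BASIS_CRANII_TV, DEFAULT_TV_MODEL, ClosureState,
                            TVModel, close_skull_loop, compute_q, fit_tv_model,
                            measure_soft_tissue_area, predict_tv)

__version__ = "0.1.0"
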