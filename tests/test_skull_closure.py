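import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import closing, disk

from ambbem.calibration import calibrate_tv_model
from ambbem.layer_classifier import LayerClass
from ambbem.phantom import PhantomSpec, generate_phantom
from ambbem.preliminary_segmentation import extract_skull, fill_holes, remove_skull
from ambbem.skull_closure import (BASIS_CRANII_TV, DEFAULT_TV_MODEL, TVModel,
                                  close_skull_loop, compute_q, fit_tv_model,
                                  measure_soft_tissue_area, predict_tv,
                                  trace_to_json)


class TestComputeQ:
    @pytest.mark.parametrize("S_i, S_e1, expected", [
        (1000, 1000, 0.0),
        (1000, 250, 0.75),
        (4000, 1000, 0.75),   # q = 0.75 whenever S_i = 4 * S_e1
        (400, 100, 0.75),
    ])
    def test_filled_fraction(self, S_i, S_e1, expected):
        assert compute_q(S_i, S_e1) == pytest.approx(expected)

    def test_degenerate_and_contract_errors(self):
        with pytest.raises(ValueError):
            compute_q(0, 0)
        with pytest.raises(ValueError):
            compute_q(10, 11)

    def test_strictly_increasing_in_mask_area(self):
        qs = [compute_q(s, 500) for s in (500, 600, 800, 1600)]
        assert all(a < b for a, b in zip(qs, qs[1:]))


class TestPredictTV:
    def test_basis_cranii_constant(self):
        model = TVModel(intercept=0.9, slope=-1.0)
        assert predict_tv(model, 10, 99999, LayerClass.BASIS_CRANII) == 0.2485
        assert BASIS_CRANII_TV == 0.2485

    def test_linear_form(self):
        model = TVModel(intercept=0.9, slope=-1.0)
        assert predict_tv(model, 1000, 200) == pytest.approx(0.7)

    def test_clamped_to_unit_interval(self):
        model = TVModel(intercept=1.3, slope=0.0)
        assert predict_tv(model, 100, 100) == 0.99
        model = TVModel(intercept=-0.2, slope=0.0)
        assert predict_tv(model, 100, 100) == 0.01

    def test_zero_soft_tissue_rejected(self):
        with pytest.raises(ValueError):
            predict_tv(DEFAULT_TV_MODEL, 0, 100)


class TestFitTVModel:
    def test_noiseless_recovery(self):
        ratios = np.linspace(0.1, 0.9, 12)
        samples = [(1.0, r, 0.8 - 0.5 * r) for r in ratios]
        model = fit_tv_model(samples)
        assert model.intercept == pytest.approx(0.8, abs=1e-9)
        assert model.slope == pytest.approx(-0.5, abs=1e-9)
        assert model.r == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_tv_model([(1.0, 0.5, 0.6), (1.0, 0.7, 0.5)])

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_tv_model([(1.0, 0.5, 0.6)] * 5)

    def test_noisy_slope_recovery_within_2_se(self, rng):
        true_int, true_slope, sigma = 0.85, -0.4, 0.02
        ratio = rng.uniform(0.2, 0.8, 142)
        frac = true_int + true_slope * ratio + rng.normal(0, sigma, 142)
        model = fit_tv_model([(1.0, r, f) for r, f in zip(ratio, frac)])
        X = np.column_stack([np.ones_like(ratio), ratio])
        resid = frac - X @ (model.intercept, model.slope)
        cov = np.linalg.inv(X.T @ X) * (resid @ resid) / (len(ratio) - 2)
        se_slope = np.sqrt(cov[1, 1])
        assert abs(model.slope - true_slope) < 2 * se_slope

    def test_shipped_model_matches_recalibration(self):
        """The frozen default coefficients are reproduced by rerunning the
        phantom calibration."""
        model = calibrate_tv_model()
        assert model.intercept == pytest.approx(DEFAULT_TV_MODEL.intercept, abs=1e-3)
        assert model.slope == pytest.approx(DEFAULT_TV_MODEL.slope, abs=1e-3)
        assert model.r > 0.9


class TestMeasureSoftTissueArea:
    def test_zero_and_count(self):
        assert measure_soft_tissue_area(np.zeros((8, 8))) == 0
        e2 = np.zeros((30, 30))
        e2[:5, :10] = 77
        assert measure_soft_tissue_area(e2) == 50

    def test_matches_phantom_construction_records(self, single_region_phantom):
        s = single_region_phantom
        soft = measure_soft_tissue_area(remove_skull(s.image))
        expected = sum(s.tissue_counts[k] for k in
                       ("scalp", "brain", "hematoma", "pillow", "pocket"))
        assert soft == pytest.approx(expected, rel=0.01)


def _ring_with_gap(size=64, gap_cols=(31, 33)):
    ring = np.zeros((size, size), dtype=np.uint8)
    ring[16:49, 16:49] = 1
    ring[20:45, 20:45] = 0
    ring[16:20, gap_cols[0]:gap_cols[1]] = 0   # 2-px break through the wall
    return ring


class TestCloseSkullLoop:
    def test_closed_ring_exits_without_closing(self, single_region_phantom):
        e1 = extract_skull(single_region_phantom.image)
        soft = measure_soft_tissue_area(remove_skull(single_region_phantom.image))
        mask, trace = close_skull_loop(e1, LayerClass.SINGLE_REGION,
                                       soft_tissue_area=soft)
        assert trace[0].q > trace[0].TV
        assert len(trace) == 1
        assert np.array_equal(mask, fill_holes(e1))

    def test_two_px_gap_closed_in_first_cycle(self):
        """A radius-1 disk bridges a 2-px gap; verified against a direct
        morphology oracle."""
        ring = _ring_with_gap()
        mask, trace = close_skull_loop(ring, LayerClass.SINGLE_REGION, tv=0.5)
        oracle = ndimage.binary_fill_holes(closing(ring.astype(bool), disk(1)))
        assert trace[-1].i == 1 and trace[-1].q > 0.5
        assert np.array_equal(mask.astype(bool) | ring.astype(bool),
                              oracle | ring.astype(bool))

    def test_basis_cranii_tv_reassignment(self, basis_cranii_phantom):
        s = basis_cranii_phantom
        e1 = extract_skull(s.image)
        soft = measure_soft_tissue_area(remove_skull(s.image))
        mask, trace = close_skull_loop(e1, LayerClass.BASIS_CRANII,
                                       soft_tissue_area=soft)
        assert trace[0].TV == 0.2485
        assert trace[0].tv_source == "basis_cranii_constant"
        assert len(trace) == 1          # complete fill beats 0.2485 at once
        assert trace[0].q > 0.2485

    def test_max_cycle_exit_returns_best_mask(self):
        ring = _ring_with_gap()
        mask, trace = close_skull_loop(ring, LayerClass.SINGLE_REGION, tv=0.99)
        assert trace[-1].i == 5
        assert len(trace) == 6
        assert trace[-1].q <= 0.99
        assert np.all(mask >= ring)

    def test_trace_q_nondecreasing_and_mask_contains_skull(self, gapped_phantom):
        s = gapped_phantom
        e1 = extract_skull(s.image)
        soft = measure_soft_tissue_area(remove_skull(s.image))
        mask, trace = close_skull_loop(e1, s.layer_class, soft_tissue_area=soft)
        qs = [st.q for st in trace]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert np.all(mask >= e1)
        assert len(trace) <= 6

    def test_gap_free_equivalent_to_fill_holes(self):
        for seed in range(4):
            s = generate_phantom(PhantomSpec(image_size=128, seed=seed))
            e1 = extract_skull(s.image)
            soft = measure_soft_tissue_area(remove_skull(s.image))
            mask, _ = close_skull_loop(e1, s.layer_class, soft_tissue_area=soft)
            assert np.array_equal(mask, fill_holes(e1))

    def test_gapped_phantoms_fill_within_three_cycles(self):
        """Skull gaps up to 5 px close within 3 growing-radius cycles."""
        for seed, width in [(0, 5), (1, 3), (2, 1)]:
            s = generate_phantom(PhantomSpec(image_size=256, n_skull_gaps=2,
                                             gap_width_px=width, seed=seed))
            e1 = extract_skull(s.image)
            soft = measure_soft_tissue_area(remove_skull(s.image))
            masks = []
            close_skull_loop(e1, s.layer_class, soft_tissue_area=soft,
                             mask_log=masks)
            truth = s.truth_mask.astype(bool)
            covered = [i for i, m in enumerate(masks)
                       if not np.any(truth & ~m.astype(bool))]
            assert covered and covered[0] <= 3

    def test_trace_serializes_to_json_lines(self):
        import json
        ring = _ring_with_gap()
        _, trace = close_skull_loop(ring, LayerClass.SINGLE_REGION, tv=0.6)
        lines = trace_to_json(trace).splitlines()
        assert len(lines) == len(trace)
        rec = json.loads(lines[0])
        assert set(rec) == {"i", "S_i", "S_e1", "q", "TV", "tv_source"}
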