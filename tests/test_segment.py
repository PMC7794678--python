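import numpy as np
import pytest
from scipy import stats

from swardmap import hierarchy as hi
from swardmap.segment import (OracleSegmenter, SegmentationResult, Segmenter,
                              cascade, evaluate_iou, multiscale_predict,
                              result_from_prob, train_reference_segmenter,
                              weighted_cross_entropy)
from swardmap.weights import compute_weights, count_pixels


def _random_stage_pair(rng, shape=(24, 24)):
    p1 = rng.dirichlet(np.ones(4), size=shape)
    p2 = rng.dirichlet(np.ones(2), size=shape)
    return (result_from_prob(p1, 1, hi.TOP_NAMES),
            result_from_prob(p2, 2, hi.STAGE2_NAMES))


class TestOracleSegmenter:
    def test_zero_corruption_reproduces_truth(self, scene):
        res = OracleSegmenter(scene, 1, 0.0).predict(scene.image)
        assert np.array_equal(res.labels, scene.label_top)
        assert res.prob.max() == 1.0

    def test_full_corruption_zero_accuracy(self, scene):
        res = OracleSegmenter(scene, 1, 1.0, rng_seed=1).predict(scene.image)
        assert (res.labels == scene.label_top).mean() == 0.0

    def test_partial_corruption_within_binomial_bounds(self, scene):
        res = OracleSegmenter(scene, 1, 0.1, rng_seed=2).predict(scene.image)
        acc = (res.labels == scene.label_top).mean()
        n = scene.label_top.size
        lo, hiq = stats.binom.ppf([0.005, 0.995], n, 0.9) / n
        assert lo <= acc <= hiq

    def test_invalid_corruption_rejected(self, scene):
        with pytest.raises(ValueError):
            OracleSegmenter(scene, 1, 1.5)


class TestMultiscalePredict:
    def test_single_scale_identity(self, scene):
        seg = OracleSegmenter(scene, 1, 0.0)
        direct = seg.predict(scene.image)
        fused = multiscale_predict(seg, scene.image, scales=(1.0,))
        assert np.array_equal(fused.labels, direct.labels)
        assert np.array_equal(fused.prob, direct.prob)

    def test_uniform_segmenter_fusion_identity(self, scene):
        """Averaging identical per-scale maps equals any single map."""

        class Uniform(Segmenter):
            stage, class_order = 1, hi.TOP_NAMES

            def predict(self, image):
                h, w = np.asarray(image).shape[:2]
                prob = np.zeros((h, w, 4))
                prob[..., 0], prob[..., 2] = 0.7, 0.3
                return result_from_prob(prob, 1, hi.TOP_NAMES)

        fused = multiscale_predict(Uniform(), scene.image, (1.0, 0.75, 0.5))
        single = Uniform().predict(scene.image)
        assert np.allclose(fused.prob, single.prob)
        assert np.array_equal(fused.labels, single.labels)

    def test_two_by_two_hand_computed_average(self):
        """Fusion of a full-scale 2x2 map with a half-scale 1x1 map."""
        p_full = np.zeros((2, 2, 4))
        p_full[..., 0] = [[1.0, 0.2], [0.6, 0.4]]
        p_full[..., 1] = 1.0 - p_full[..., 0]
        p_half = np.zeros((1, 1, 4))
        p_half[..., 0], p_half[..., 1] = 0.5, 0.5

        class Stub(Segmenter):
            stage, class_order = 1, hi.TOP_NAMES

            def predict(self, image):
                p = p_full if image.shape[0] == 2 else p_half
                return result_from_prob(p.copy(), 1, hi.TOP_NAMES)

        fused = multiscale_predict(Stub(), np.zeros((2, 2, 3)), (1.0, 0.5))
        expected0 = (p_full[..., 0] + 0.5) / 2.0  # 1x1 upsamples to constant
        assert np.allclose(fused.prob[..., 0], expected0)
        assert np.allclose(fused.prob[..., 1], 1.0 - expected0)

    def test_degenerate_scale_rejected(self, scene):
        with pytest.raises(ValueError):
            multiscale_predict(OracleSegmenter(scene, 1), scene.image, (0.001,))
        with pytest.raises(ValueError):
            multiscale_predict(OracleSegmenter(scene, 1), scene.image, ())


class TestCascade:
    def test_no_clover_independent_of_stage2(self, scene_factory):
        sc = scene_factory(seed=41, size=48, coverage=0.5, mix=(0.7, 0.0, 0.0, 0.3))
        s1 = OracleSegmenter(sc, 1, 0.0).predict(sc.image)
        rng = np.random.default_rng(0)
        fines = []
        for _ in range(2):
            p2 = rng.dirichlet(np.ones(2), size=sc.label_top.shape)
            fines.append(cascade(s1, result_from_prob(p2, 2, hi.STAGE2_NAMES)))
        assert np.array_equal(fines[0], fines[1])
        assert hi.FINE_RED_CLOVER not in fines[0]

    def test_all_red_stage2(self, scene):
        s1 = OracleSegmenter(scene, 1, 0.0).predict(scene.image)
        p2 = np.zeros(scene.label_top.shape + (2,))
        p2[..., hi.STAGE2_RED] = 1.0
        fine = cascade(s1, result_from_prob(p2, 2, hi.STAGE2_NAMES))
        clover = scene.label_top == hi.CLOVER
        assert (fine[clover] == hi.FINE_RED_CLOVER).all()

    def test_collapse_reproduces_stage1(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s1, s2 = _random_stage_pair(rng)
            fine = cascade(s1, s2)
            assert np.array_equal(hi.collapse_fine_to_top(fine), s1.labels)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        s1, _ = _random_stage_pair(rng, (8, 8))
        _, s2 = _random_stage_pair(rng, (9, 9))
        with pytest.raises(ValueError):
            cascade(s1, s2)


class TestEvaluateIoU:
    def test_perfect_prediction(self, scene):
        out = evaluate_iou(scene.label_top, scene.label_top, hi.TOP_NAMES)
        present = [v for v in out["per_class"].values() if not np.isnan(v)]
        assert all(v == 1.0 for v in present)
        assert out["mean"] == 1.0

    def test_disjoint_single_class(self):
        pred = np.zeros((4, 4), int)
        truth = np.ones((4, 4), int)
        out = evaluate_iou(pred, truth, ("a", "b"))
        assert out["per_class"] == {"a": 0.0, "b": 0.0}

    def test_hand_built_confusion_case(self):
        # 4x4: truth has an 8-px class-1 block; pred overlaps 4 of them and
        # adds 2 false positives -> IoU_1 = 4 / (8 + 2) = 0.4
        truth = np.zeros((4, 4), int)
        truth[:2, :] = 1
        pred = np.zeros((4, 4), int)
        pred[1:3, :2] = 1
        pred[1, 2:] = 1
        out = evaluate_iou(pred, truth, ("bg", "c1"))
        inter = ((pred == 1) & (truth == 1)).sum()
        union = ((pred == 1) | (truth == 1)).sum()
        assert out["per_class"]["c1"] == pytest.approx(inter / union)
        assert out["per_class"]["c1"] == pytest.approx(4 / 10)

    def test_absent_class_excluded_from_mean(self):
        pred = truth = np.zeros((3, 3), int)
        out = evaluate_iou(pred, truth, ("a", "b"))
        assert np.isnan(out["per_class"]["b"])
        assert out["mean"] == 1.0


class TestWeightedCrossEntropy:
    def test_all_off_mask_zero_loss(self):
        prob = np.full((4, 4, 2), 0.5)
        labels = np.zeros((4, 4), int)
        assert weighted_cross_entropy(prob, labels, np.zeros((4, 4), bool)) == 0.0

    def test_perfect_probabilities_zero_loss(self):
        labels = np.random.default_rng(0).integers(0, 2, (5, 5))
        prob = np.zeros((5, 5, 2))
        np.put_along_axis(prob, labels[..., None], 1.0, axis=2)
        assert weighted_cross_entropy(prob, labels) == pytest.approx(0.0, abs=1e-10)

    def test_class_weights_reweight_loss(self):
        labels = np.array([[0, 1]])
        prob = np.full((1, 2, 2), 0.5)
        base = weighted_cross_entropy(prob, labels)
        up = weighted_cross_entropy(prob, labels, class_weights=np.array([1.0, 3.0]))
        assert base == pytest.approx(np.log(2.0))
        assert up == pytest.approx(np.log(2.0))  # same nll both classes


class TestReferenceSegmenter:
    def test_single_class_scene_converges_to_constant(self, scene_factory):
        scenes = [scene_factory(seed=50 + i, size=64, coverage=0.0)
                  for i in range(3)]
        seg = train_reference_segmenter(scenes, None, stage=1)
        res = seg.predict(scenes[0].image)
        out = evaluate_iou(res.labels, scenes[0].label_top, hi.TOP_NAMES)
        assert out["per_class"]["soil"] == 1.0

    def test_probabilities_well_formed(self, scene_set):
        tab = compute_weights(count_pixels(scene_set[:4], "top"))
        seg = train_reference_segmenter(scene_set[:4], tab, stage=1)
        res = seg.predict(scene_set[4].image)
        assert res.prob.shape == scene_set[4].label_top.shape + (4,)
        assert np.allclose(res.prob.sum(axis=2), 1.0, atol=1e-6)

    def test_stage2_trains_only_on_masked_pixels(self, scene_set):
        seg = train_reference_segmenter(scene_set, None, stage=2)
        assert seg.stage == 2
        assert seg.class_order == hi.STAGE2_NAMES


class TestSegmentationResult:
    def test_rejects_unnormalised_probabilities(self):
        bad = np.full((2, 2, 4), 0.5)
        with pytest.raises(ValueError):
            SegmentationResult(bad, np.zeros((2, 2), int), 1, hi.TOP_NAMES)
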