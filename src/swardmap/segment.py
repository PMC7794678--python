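"""Segmenter contract, multi-scale inference and the two-stage cascade.

The pipeline separates *what* produces per-pixel class probabilities (a
:class:`Segmenter`) from the inference logic around it:

* :func:`multiscale_predict` runs a segmenter at several image scales
  (default 100%, 75%, 50%), resamples each probability map back to native
  resolution, averages the probabilities pixelwise and takes the argmax -
  improving scale invariance of the final map;
* :func:`cascade` combines a stage-1 result (soil/clover/grass/weed) with a
  stage-2 result (red vs. white clover): stage-2 only refines the pixels
  stage 1 called clover, so collapsing the species back always reproduces
  the stage-1 map exactly.

Two segmenters are provided: an *oracle* wrapping a synthetic scene's
ground-truth labels with a controllable pixel corruption rate (the test
double for a trained network), and a compact trainable reference built from
a fixed multi-scale convolutional filter bank with a multinomial logistic
output layer, trained with class-weighted cross-entropy and stage-2 loss
masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from . import hierarchy as hi
from .weights import ClassWeightTable, to_prospect_labels

DEFAULT_SCALES = (1.0, 0.75, 0.5)


@dataclass
class SegmentationResult:
    """Per-pixel class probabilities and hard labels for one cascade stage.

    ``labels`` is the per-pixel argmax of ``prob`` over ``class_order``;
    argmax ties break toward the lowest class index (numpy convention),
    which is stable and documented.
    """

    prob: np.ndarray  # (H, W, C)
    labels: np.ndarray  # (H, W)
    stage: int
    class_order: tuple

    def __post_init__(self):
        if self.prob.ndim != 3 or self.prob.shape[2] != len(self.class_order):
            raise ValueError("prob must be (H, W, n_classes)")
        sums = self.prob.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-pixel probabilities must sum to 1")


def result_from_prob(prob: np.ndarray, stage: int, class_order) -> SegmentationResult:
    return SegmentationResult(prob, np.argmax(prob, axis=2).astype(np.uint8),
                              stage, tuple(class_order))


class Segmenter:
    """Interface: predict(image) -> SegmentationResult at the image's size."""

    stage: int = 1
    class_order: tuple = hi.TOP_NAMES
    metadata: dict = {}

    def predict(self, image: np.ndarray) -> SegmentationResult:  # pragma: no cover
        raise NotImplementedError


class OracleSegmenter(Segmenter):
    """Ground-truth-backed segmenter with a controllable corruption rate.

    Predicts the scene's true prospect labels for the requested stage; a
    fraction ``corruption_rate`` of pixels is flipped to a uniformly drawn
    *other* class.  Probabilities are one-hot.  When asked to predict at a
    different resolution than the scene (multi-scale inference), the truth
    raster is resampled nearest-neighbour, making the oracle scale-covariant.
    """

    def __init__(self, scene, stage: int = 1, corruption_rate: float = 0.0,
                 rng_seed: int = 0):
        if not 0.0 <= corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0, 1]")
        self.stage = stage
        self.class_order = hi.TOP_NAMES if stage == 1 else hi.STAGE2_NAMES
        self.corruption_rate = corruption_rate
        self.rng_seed = rng_seed
        truth, _mask = to_prospect_labels(scene, stage)
        self._truth = truth
        self.metadata = {"stage": stage, "kind": "oracle",
                         "corruption_rate": corruption_rate}

    def predict(self, image: np.ndarray) -> SegmentationResult:
        shape = np.asarray(image).shape[:2]
        labels = self._truth
        if shape != labels.shape:
            labels = resize(labels, shape, order=0, anti_aliasing=False,
                            preserve_range=True).astype(labels.dtype)
        labels = labels.copy()
        n_classes = len(self.class_order)
        if self.corruption_rate > 0:
            rng = np.random.default_rng(self.rng_seed)
            flip = rng.random(shape) < self.corruption_rate
            # uniform draw over the *other* classes
            offset = rng.integers(1, n_classes, size=shape)
            labels[flip] = (labels[flip] + offset[flip]) % n_classes
        prob = np.zeros(shape + (n_classes,), np.float64)
        np.put_along_axis(prob, labels[..., None].astype(np.intp), 1.0, axis=2)
        return SegmentationResult(prob, labels, self.stage, self.class_order)


def multiscale_predict(seg: Segmenter, image: np.ndarray,
                       scales=DEFAULT_SCALES) -> SegmentationResult:
    """Fuse predictions across image scales by averaging probabilities.

    The image is resized to each scale, segmented, and each probability map
    is resampled (bilinear, then renormalized per pixel) back to native
    resolution; the per-scale maps are averaged and argmaxed.  With a single
    scale of 1.0 this is exactly ``seg.predict``.
    """
    scales = tuple(scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be non-empty and positive")
    image = np.asarray(image)
    H, W = image.shape[:2]
    acc = None
    for s in scales:
        if s == 1.0:
            scaled = image
        else:
            h, w = int(round(H * s)), int(round(W * s))
            if h < 1 or w < 1:
                raise ValueError(f"scale {s} gives a degenerate image size")
            scaled = resize(image.astype(np.float64), (h, w) + image.shape[2:],
                            order=1, anti_aliasing=s < 1.0, preserve_range=True)
            if np.issubdtype(image.dtype, np.integer):
                scaled = np.clip(np.rint(scaled), 0, 255).astype(image.dtype)
        res = seg.predict(scaled)
        prob = res.prob
        if prob.shape[:2] != (H, W):
            prob = resize(prob, (H, W, prob.shape[2]), order=1,
                          anti_aliasing=False, preserve_range=True)
            prob = np.clip(prob, 0.0, None)
            prob /= prob.sum(axis=2, keepdims=True)
        acc = prob if acc is None else acc + prob
    fused = acc / len(scales)
    return result_from_prob(fused, seg.stage, seg.class_order)


def cascade(stage1: SegmentationResult, stage2: SegmentationResult) -> np.ndarray:
    """Combine the two stages into fine labels.

    Pixels stage 1 called soil/grass/weed keep their stage-1 class; pixels
    called clover take stage 2's species argmax.  Output classes follow
    :data:`swardmap.hierarchy.FINE_NAMES`.
    """
    if stage1.labels.shape != stage2.labels.shape:
        raise ValueError("stage-1 and stage-2 dimensions differ")
    if stage1.stage != 1 or stage2.stage != 2:
        raise ValueError("results passed in the wrong stage order")
    lut = np.zeros(len(hi.TOP_NAMES), np.uint8)
    lut[hi.SOIL] = hi.FINE_SOIL
    lut[hi.GRASS] = hi.FINE_GRASS
    lut[hi.WEED] = hi.FINE_WEED
    fine = lut[stage1.labels]
    clover = stage1.labels == hi.CLOVER
    species = np.where(stage2.labels == hi.STAGE2_RED,
                       hi.FINE_RED_CLOVER, hi.FINE_WHITE_CLOVER)
    fine[clover] = species[clover].astype(np.uint8)
    return fine


def evaluate_iou(pred: np.ndarray, truth: np.ndarray, classes) -> dict:
    """Per-class and mean intersection-over-union.

    IoU_c = |pred==c & truth==c| / |pred==c | truth==c|.  Classes absent
    from both rasters are excluded from the mean (reported as NaN).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth dimensions differ")
    per_class = {}
    vals = []
    for c, name in enumerate(classes):
        p = pred == c
        t = truth == c
        union = int((p | t).sum())
        if union == 0:
            per_class[name] = float("nan")
            continue
        iou = int((p & t).sum()) / union
        per_class[name] = iou
        vals.append(iou)
    return {"per_class": per_class,
            "mean": float(np.mean(vals)) if vals else float("nan")}


# ---------------------------------------------------------------------------
# weighted cross-entropy with loss masking (training diagnostic + objective)
# ---------------------------------------------------------------------------

def weighted_cross_entropy(prob: np.ndarray, labels: np.ndarray,
                           mask: np.ndarray | None = None,
                           class_weights: np.ndarray | None = None,
                           eps: float = 1e-12) -> float:
    """Mean class-weighted cross-entropy over mask-on pixels.

    An all-off mask contributes no loss (returns 0.0 exactly).
    """
    labels = np.asarray(labels)
    if mask is None:
        mask = np.ones(labels.shape, bool)
    if not mask.any():
        return 0.0
    p = np.take_along_axis(np.asarray(prob), labels[..., None].astype(np.intp),
                           axis=2)[..., 0]
    nll = -np.log(np.clip(p, eps, 1.0))
    if class_weights is not None:
        w = np.asarray(class_weights, float)[labels]
    else:
        w = np.ones(labels.shape)
    return float((nll * w)[mask].sum() / w[mask].sum())


# ---------------------------------------------------------------------------
# compact trainable reference segmenter
# ---------------------------------------------------------------------------

_FEATURE_SIGMAS = (1.0, 2.0, 4.0)


def _features(image: np.ndarray) -> np.ndarray:
    """Fixed convolutional feature stack: colour + multi-scale context.

    Per channel: raw value, Gaussian-smoothed responses at several scales
    and a local-contrast (std-like) response; appended a green-excess index
    that separates vegetation from soil.  Shape (H, W, F).
    """
    img = np.asarray(image, np.float64) / 255.0
    if img.ndim == 2:
        img = img[..., None].repeat(3, axis=2)
    feats = [img[..., k] for k in range(3)]
    for sigma in _FEATURE_SIGMAS:
        for k in range(3):
            feats.append(gaussian_filter(img[..., k], sigma))
    for k in range(3):
        mu = gaussian_filter(img[..., k], 2.0)
        mu2 = gaussian_filter(img[..., k] ** 2, 2.0)
        feats.append(np.sqrt(np.clip(mu2 - mu ** 2, 0, None)))
    exg = 2 * img[..., 1] - img[..., 0] - img[..., 2]
    feats.append(exg)
    feats.append(gaussian_filter(exg, 2.0))
    return np.stack(feats, axis=-1)


@dataclass
class TrainConfig:
    pixels_per_scene: int = 1500
    max_iter: int = 300
    regularization_c: float = 10.0
    rng_seed: int = 0


class ReferenceSegmenter(Segmenter):
    """Filter-bank + multinomial-logistic segmenter (desk-scale reference)."""

    def __init__(self, model, stage: int, class_order, metadata=None):
        self._model = model
        self.stage = stage
        self.class_order = tuple(class_order)
        self.metadata = metadata or {}

    def predict(self, image: np.ndarray) -> SegmentationResult:
        X = _features(image)
        H, W, F = X.shape
        raw = self._model.predict_proba(X.reshape(-1, F))
        n_classes = len(self.class_order)
        prob = np.zeros((H * W, n_classes))
        for j, cls in enumerate(self._model.classes_):
            prob[:, int(cls)] = raw[:, j]
        missing = prob.sum(axis=1) == 0
        prob[missing] = 1.0 / n_classes
        prob /= prob.sum(axis=1, keepdims=True)
        return result_from_prob(prob.reshape(H, W, n_classes), self.stage,
                                self.class_order)


def train_reference_segmenter(scenes, weights: ClassWeightTable | None,
                              stage: int = 1,
                              config: TrainConfig | None = None) -> Segmenter:
    """Train the compact reference segmenter on labelled scenes.

    The objective is class-weighted cross-entropy: each sampled pixel gets
    the frequency weight of its class from ``weights`` (uniform if None).
    For stage 2 the loss mask confines training to clover pixels of known
    species.  Reproducible for a fixed config seed up to floating-point
    nondeterminism of the solver.
    """
    try:
        from sklearn.linear_model import LogisticRegression
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "training the reference segmenter requires scikit-learn") from exc
    if len(scenes) < 1:
        raise ValueError("at least one training scene is required")
    config = config or TrainConfig()
    class_order = hi.TOP_NAMES if stage == 1 else hi.STAGE2_NAMES
    rng = np.random.default_rng(config.rng_seed)

    Xs, ys = [], []
    for sc in scenes:
        labels, mask = to_prospect_labels(sc, stage)
        feats = _features(sc.image)
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        n = min(config.pixels_per_scene, rows.size)
        pick = rng.choice(rows.size, size=n, replace=False)
        Xs.append(feats[rows[pick], cols[pick]])
        ys.append(labels[rows[pick], cols[pick]])
    if not Xs:
        raise ValueError("no unmasked training pixels available")
    X = np.concatenate(Xs)
    y = np.concatenate(ys).astype(int)

    if weights is not None:
        wmap = {name: weights.weights.get(name, 1.0) for name in class_order}
        sample_w = np.array([wmap[class_order[c]] for c in y])
        sample_w = np.where(sample_w > 0, sample_w, 1e-3)
    else:
        sample_w = None

    if np.unique(y).size < 2:
        # degenerate task (e.g. all-soil scenes): constant predictor
        from sklearn.dummy import DummyClassifier
        model = DummyClassifier(strategy="prior")
        model.fit(X, y)
    else:
        model = LogisticRegression(max_iter=config.max_iter,
                                   C=config.regularization_c,
                                   random_state=config.rng_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y, sample_weight=sample_w)
    meta = {"stage": stage, "kind": "reference-filterbank",
            "n_train_px": int(X.shape[0]), "config": config}
    return ReferenceSegmenter(model, stage, class_order, meta)
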