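"""Training-time augmentation for sward scenes.

Two families of augmentation reduce the gap between composited training
scenes and field imagery:

* an *online* stack of aggressive geometric scaling (uniform scale factor
  around 1, by default +/-60%) with identical geometry applied to image and
  labels (labels resampled nearest-neighbour only), plus photometric jitter
  of brightness, contrast, hue and saturation applied to the image alone;

* an *offline* augmentation of the training pool in which a small fraction
  of draws come from a "styled" set whose vegetation carries the specular
  speckle and washed-out local contrast typical of dew- or rain-wetted
  leaves.  The procedural moisture effect stands in for an image-to-image
  style transfer; crucially, labels are never altered by it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2hsv, hsv2rgb
from skimage.transform import resize

from . import hierarchy as hi
from .scene import LabeledScene


@dataclass
class AugmentSpec:
    """Ranges of the online augmentation stack; all sampled uniformly."""

    scale_range: tuple = (0.4, 1.6)
    brightness_range: tuple = (0.8, 1.2)
    contrast_range: tuple = (0.8, 1.2)
    hue_shift_range_deg: tuple = (-15.0, 15.0)
    saturation_range: tuple = (0.7, 1.3)
    crop_size: int | None = None
    rng_seed: int = 0

    def __post_init__(self):
        # proper jitter intervals must contain the identity (1, or 0 for
        # hue); a degenerate lo == hi interval pins the value deliberately
        lo, hiva = self.scale_range
        if lo <= 0 or lo > hiva or (lo != hiva and not lo <= 1.0 <= hiva):
            raise ValueError("scale_range must be positive and contain 1")
        for name in ("brightness_range", "contrast_range", "saturation_range"):
            lo, hiva = getattr(self, name)
            if lo > hiva or (lo != hiva and not lo <= 1.0 <= hiva):
                raise ValueError(f"{name} must contain 1")
        lo, hiva = self.hue_shift_range_deg
        if lo > hiva or (lo != hiva and not lo <= 0.0 <= hiva):
            raise ValueError("hue_shift_range_deg must contain 0")


@dataclass
class OfflineMix:
    """A base pool plus a styled pool mixed at ``styled_fraction``."""

    base_set: list
    styled_set: list
    styled_fraction: float = 0.06

    def __post_init__(self):
        if not 0.0 <= self.styled_fraction <= 1.0:
            raise ValueError("styled_fraction must be in [0, 1]")


def _is_identity(spec: AugmentSpec) -> bool:
    return (spec.scale_range == (1.0, 1.0)
            and spec.brightness_range == (1.0, 1.0)
            and spec.contrast_range == (1.0, 1.0)
            and spec.hue_shift_range_deg == (0.0, 0.0)
            and spec.saturation_range == (1.0, 1.0)
            and spec.crop_size is None)


def augment_pair(image: np.ndarray, labels: np.ndarray, spec: AugmentSpec):
    """One augmented (image, labels) draw.

    Geometry (scale, then optional crop to ``crop_size``) is applied
    identically to image and labels; labels use nearest-neighbour
    resampling so class indices are never interpolated.  Photometric jitter
    touches the image only.  Deterministic for a fixed ``rng_seed``.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape[:2] != labels.shape[:2]:
        raise ValueError("image and labels dimensions differ")
    if _is_identity(spec):
        return image.copy(), labels.copy()

    rng = np.random.default_rng(spec.rng_seed)
    scale = rng.uniform(*spec.scale_range)
    img = image.astype(np.float64) / 255.0
    lab = labels
    if scale != 1.0:
        h = max(1, int(round(image.shape[0] * scale)))
        w = max(1, int(round(image.shape[1] * scale)))
        img = resize(img, (h, w) + img.shape[2:], order=1,
                     anti_aliasing=scale < 1.0, preserve_range=True)
        lab = resize(lab, (h, w), order=0, anti_aliasing=False,
                     preserve_range=True).astype(labels.dtype)
    if spec.crop_size is not None:
        cs = spec.crop_size
        if img.shape[0] < cs or img.shape[1] < cs:
            warnings.warn("scaled image smaller than crop; padding by reflection")
            pr = max(0, cs - img.shape[0])
            pc = max(0, cs - img.shape[1])
            img = np.pad(img, ((0, pr), (0, pc)) + ((0, 0),) * (img.ndim - 2),
                         mode="reflect")
            lab = np.pad(lab, ((0, pr), (0, pc)), mode="reflect")
        r0 = rng.integers(0, img.shape[0] - cs + 1)
        c0 = rng.integers(0, img.shape[1] - cs + 1)
        img = img[r0:r0 + cs, c0:c0 + cs]
        lab = lab[r0:r0 + cs, c0:c0 + cs]

    # photometric jitter: image only
    b = rng.uniform(*spec.brightness_range)
    c = rng.uniform(*spec.contrast_range)
    hshift = rng.uniform(*spec.hue_shift_range_deg)
    s = rng.uniform(*spec.saturation_range)
    img = np.clip((img - 0.5) * c + 0.5, 0, 1)
    img = np.clip(img * b, 0, 1)
    if img.ndim == 3 and img.shape[2] == 3 and (hshift != 0.0 or s != 1.0):
        hsv = rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + hshift / 360.0) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * s, 0, 1)
        img = hsv2rgb(hsv)
    out = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    return out, lab.copy()


def moisture_stylize(scene: LabeledScene, intensity: float,
                     rng_seed: int = 0) -> LabeledScene:
    """Procedural wet-leaf appearance on vegetation pixels only.

    Adds specular highlight speckles (droplet glints) and reduces local
    contrast on vegetation; soil pixels and all label rasters are untouched.
    ``intensity`` in [0, 1]; 0 is the identity.
    """
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    if intensity == 0.0:
        return replace(scene, image=scene.image.copy())
    rng = np.random.default_rng(rng_seed)
    veg = scene.label_top != hi.SOIL
    img = scene.image.astype(np.float64)

    if veg.any():
        # local contrast loss: blend vegetation toward its smoothed version
        blurred = np.stack([gaussian_filter(img[..., k], 2.0) for k in range(3)], -1)
        alpha = 0.5 * intensity
        img[veg] = (1 - alpha) * img[veg] + alpha * blurred[veg]
        # specular droplet glints
        rows, cols = np.nonzero(veg)
        n_speck = max(1, int(intensity * 0.01 * rows.size))
        pick = rng.choice(rows.size, size=n_speck, replace=False)
        glint = np.zeros(scene.image.shape[:2])
        glint[rows[pick], cols[pick]] = 255.0
        glint = gaussian_filter(glint, 1.0) * 6.0 * intensity
        img[veg] = np.minimum(img[veg] + glint[veg, None] + 4.0 * intensity, 255.0)

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    out[~veg] = scene.image[~veg]
    return replace(scene, image=out)


def mix_offline(mix: OfflineMix, n_draws: int, rng_seed: int = 0) -> list:
    """Sample a training list with an expected styled share of ``styled_fraction``."""
    if mix.styled_fraction > 0 and not mix.styled_set:
        raise ValueError("styled_fraction > 0 but styled_set is empty")
    if mix.styled_fraction < 1 and not mix.base_set:
        raise ValueError("styled_fraction < 1 but base_set is empty")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_draws):
        if rng.random() < mix.styled_fraction:
            out.append(mix.styled_set[rng.integers(len(mix.styled_set))])
        else:
            out.append(mix.base_set[rng.integers(len(mix.base_set))])
    return out
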