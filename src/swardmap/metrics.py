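"""Canopy composition metrics.

The biomass composition of a mixed sward is estimated from the *visible*
canopy: every pixel of a top-down image is classified, and species
fractions are pixel-count ratios relative to the detected vegetation
(non-soil) area.  Two metrics drive field-scale mapping: canopy coverage
(vegetation pixels / all pixels) and the clover fraction of the canopy.

Biomass sample crops follow a fixed-frame protocol: the 0.5 x 0.5 m frame
region is resampled to a square of ``target_px`` pixels and extended by a
``margin_px`` context margin on all sides; the margin gives the segmenter
context but is discarded before any metric is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from skimage.transform import resize

from . import hierarchy as hi


@dataclass
class CanopyMetrics:
    """Pixel-count composition of a labelled canopy raster.

    ``clover/grass/weed_fraction`` are relative to the vegetation canopy,
    not the full image.  On an empty canopy the fractions are undefined:
    ``defined`` is False and the fraction fields are NaN (never silently 0,
    which would bias any downstream calibration).
    """

    canopy_coverage: float
    clover_fraction: float
    grass_fraction: float
    weed_fraction: float
    red_fraction: float | None = None
    white_fraction: float | None = None
    defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def canopy_metrics(
    label_top: np.ndarray,
    label_sub: np.ndarray | None = None,
    region: tuple[int, int, int, int] | None = None,
) -> CanopyMetrics:
    """Compute composition metrics from a top-level label raster.

    Parameters
    ----------
    label_top : 2-D integer raster of stage-1 classes.
    label_sub : optional sub-class raster; if given, red/white clover
        fractions of canopy are also computed (unknown-clover pixels count
        toward clover but toward neither species).
    region : optional half-open box (r0, c0, r1, c1) restricting the count.
    """
    lt = np.asarray(label_top)
    if lt.ndim != 2:
        raise ValueError("label_top must be a 2-D raster")
    ls = None if label_sub is None else np.asarray(label_sub)
    if region is not None:
        r0, c0, r1, c1 = region
        if not (0 <= r0 <= r1 <= lt.shape[0] and 0 <= c0 <= c1 <= lt.shape[1]):
            raise ValueError(f"region {region} outside raster {lt.shape}")
        lt = lt[r0:r1, c0:c1]
        if ls is not None:
            ls = ls[r0:r1, c0:c1]

    n_total = lt.size
    counts = np.bincount(lt.ravel(), minlength=len(hi.TOP_NAMES))
    n_veg = int(n_total - counts[hi.SOIL])
    coverage = n_veg / n_total if n_total else 0.0

    if n_veg == 0:
        return CanopyMetrics(coverage, np.nan, np.nan, np.nan, defined=False)

    clover = counts[hi.CLOVER] / n_veg
    grass = counts[hi.GRASS] / n_veg
    weed = counts[hi.WEED] / n_veg
    red = white = None
    if ls is not None:
        sub_counts = np.bincount(ls.ravel(), minlength=len(hi.SUB_NAMES))
        red = (sub_counts[hi.RED_CLOVER_LEAF] + sub_counts[hi.RED_CLOVER_FLOWER]) / n_veg
        white = (sub_counts[hi.WHITE_CLOVER_LEAF] + sub_counts[hi.WHITE_CLOVER_FLOWER]) / n_veg
    return CanopyMetrics(coverage, clover, grass, weed, red, white)


def metrics_from_fine(fine: np.ndarray, region=None) -> CanopyMetrics:
    """Metrics from cascaded fine labels (soil/grass/weed/red/white)."""
    f = np.asarray(fine)
    if region is not None:
        r0, c0, r1, c1 = region
        f = f[r0:r1, c0:c1]
    counts = np.bincount(f.ravel(), minlength=len(hi.FINE_NAMES))
    n_total = f.size
    n_veg = int(n_total - counts[hi.FINE_SOIL])
    coverage = n_veg / n_total if n_total else 0.0
    if n_veg == 0:
        return CanopyMetrics(coverage, np.nan, np.nan, np.nan, defined=False)
    red = counts[hi.FINE_RED_CLOVER] / n_veg
    white = counts[hi.FINE_WHITE_CLOVER] / n_veg
    # integer sum before division: exact agreement with top-level counting
    clover = int(counts[hi.FINE_RED_CLOVER] + counts[hi.FINE_WHITE_CLOVER]) / n_veg
    return CanopyMetrics(
        coverage,
        clover,
        counts[hi.FINE_GRASS] / n_veg,
        counts[hi.FINE_WEED] / n_veg,
        red,
        white,
    )


def crop_with_margin(
    image: np.ndarray,
    frame_box: tuple[int, int, int, int],
    target_px: int = 3000,
    margin_px: int = 200,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Resample a frame crop to ``target_px`` square plus a context margin.

    ``frame_box`` is the half-open (r0, c0, r1, c1) box of the sampling
    frame in the source image.  The box is extended on all sides by the
    source-space equivalent of ``margin_px`` output pixels (reflected where
    it would leave the image, with a warning), and the extended crop is
    resampled to ``(target_px + 2 * margin_px)`` square.  Returns the crop
    and the half-open ``inner_box`` marking the margin-free region to use
    after segmentation.
    """
    if target_px <= 0 or margin_px < 0:
        raise ValueError("target_px must be positive, margin_px non-negative")
    img = np.asarray(image)
    r0, c0, r1, c1 = frame_box
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise ValueError(f"frame_box {frame_box} outside image {img.shape[:2]}")

    # margin in source pixels, per axis (the frame may not be square)
    mr = int(round(margin_px * (r1 - r0) / target_px))
    mc = int(round(margin_px * (c1 - c0) / target_px))
    er0, er1 = r0 - mr, r1 + mr
    ec0, ec1 = c0 - mc, c1 + mc
    pad_r = max(0, -er0, er1 - img.shape[0])
    pad_c = max(0, -ec0, ec1 - img.shape[1])
    if pad_r or pad_c:
        warnings.warn("frame_box margin exceeds image; padding by reflection")
        pad = [(pad_r, pad_r), (pad_c, pad_c)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad, mode="reflect")
        er0, er1 = er0 + pad_r, er1 + pad_r
        ec0, ec1 = ec0 + pad_c, ec1 + pad_c

    ext = img[er0:er1, ec0:ec1]
    side = target_px + 2 * margin_px
    out_shape = (side, side) + ext.shape[2:]
    crop = resize(ext, out_shape, order=1, anti_aliasing=True, preserve_range=True)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        crop = np.clip(np.rint(crop), np.iinfo(np.asarray(image).dtype).min,
                       np.iinfo(np.asarray(image).dtype).max).astype(np.asarray(image).dtype)
    inner_box = (margin_px, margin_px, margin_px + target_px, margin_px + target_px)
    return crop, inner_box
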