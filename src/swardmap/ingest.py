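"""Raw-image ingest: linear demosaicing and flat-field correction.

Survey cameras deliver single-channel Bayer-pattern frames.  Demosaicing
uses gradient-corrected linear interpolation (Malvar-He-Cutler): fixed 5x5
kernels in which the luminance gradient of the current channel corrects the
bilinear estimate of the missing channels.  Borders are handled by
reflective padding.

Vignetting and uneven flash illumination are removed with a flat-field
profile: the per-channel mean image of an acquisition day, smoothed with a
large-kernel blur to suppress scene content, normalised to mean one, and
divided out of every frame (multiplicative gain correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, gaussian_filter

PATTERNS = ("RGGB", "BGGR", "GRBG", "GBRG")

# Malvar-He-Cutler 5x5 kernels (x 1/8)
_K_G_AT_RB = np.array([
    [0, 0, -1, 0, 0],
    [0, 0, 2, 0, 0],
    [-1, 2, 4, 2, -1],
    [0, 0, 2, 0, 0],
    [0, 0, -1, 0, 0]], float) / 8.0
_K_RB_AT_G_HORIZ = np.array([  # missing channel's neighbours left/right
    [0, 0, 0.5, 0, 0],
    [0, -1, 0, -1, 0],
    [-1, 4, 5, 4, -1],
    [0, -1, 0, -1, 0],
    [0, 0, 0.5, 0, 0]], float) / 8.0
_K_RB_AT_G_VERT = _K_RB_AT_G_HORIZ.T
_K_RB_AT_BR = np.array([
    [0, 0, -1.5, 0, 0],
    [0, 2, 0, 2, 0],
    [-1.5, 0, 6, 0, -1.5],
    [0, 2, 0, 2, 0],
    [0, 0, -1.5, 0, 0]], float) / 8.0


@dataclass
class BayerImage:
    """Single-channel colour-filter-array frame."""

    raster: np.ndarray
    pattern: str = "RGGB"
    bit_depth: int = 8

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        if self.raster.shape[0] % 2 or self.raster.shape[1] % 2:
            raise ValueError("Bayer raster dimensions must be even")


def _cfa_masks(shape, pattern):
    """Boolean (R, G, B) site masks for a 2x2-periodic CFA pattern."""
    layout = {"RGGB": "RGGB", "BGGR": "BGGR", "GRBG": "GRBG", "GBRG": "GBRG"}[pattern]
    rows = np.arange(shape[0])[:, None] % 2
    cols = np.arange(shape[1])[None, :] % 2
    cell = 2 * rows + cols  # 0: (0,0), 1: (0,1), 2: (1,0), 3: (1,1)
    masks = {}
    for ch in "RGB":
        m = np.zeros(shape, bool)
        for pos, letter in enumerate(layout):
            if letter == ch:
                m |= cell == pos
        masks[ch] = m
    return masks["R"], masks["G"], masks["B"]


def demosaic(b: BayerImage) -> np.ndarray:
    """Gradient-corrected linear demosaicing to a full-resolution RGB raster.

    A constant mosaic demosaics to the constant grey RGB (all kernel rows
    sum to one); output is clipped to the declared bit-depth range.
    """
    M = b.raster.astype(np.float64)
    Rm, Gm, Bm = _cfa_masks(M.shape, b.pattern)
    conv = lambda k: convolve(M, k, mode="reflect")
    cG = conv(_K_G_AT_RB)
    cH = conv(_K_RB_AT_G_HORIZ)
    cV = conv(_K_RB_AT_G_VERT)
    cX = conv(_K_RB_AT_BR)
    # G pixels whose horizontal neighbours are R (resp. B) sites
    g_in_r_row = Gm & np.roll(Rm, 1, axis=1)
    g_in_b_row = Gm & np.roll(Bm, 1, axis=1)
    R = np.where(Rm, M, np.where(g_in_r_row, cH, np.where(g_in_b_row, cV, cX)))
    B = np.where(Bm, M, np.where(g_in_b_row, cH, np.where(g_in_r_row, cV, cX)))
    G = np.where(Gm, M, cG)
    rgb = np.stack([R, G, B], axis=-1)
    return np.clip(rgb, 0, 2 ** b.bit_depth - 1)


@dataclass
class IlluminationProfile:
    """Per-channel multiplicative gain raster, normalised to mean one."""

    gain: np.ndarray  # (H, W, 3), strictly positive

    def __post_init__(self):
        if (self.gain <= 0).any():
            raise ValueError("gain must be strictly positive")
        means = self.gain.reshape(-1, self.gain.shape[-1]).mean(axis=0)
        if not np.allclose(means, 1.0, atol=1e-6):
            raise ValueError("gain channels must be normalised to mean 1")


def build_profile(images, smooth_sigma: float | None = None) -> IlluminationProfile:
    """Flat-field profile from the mean of an acquisition day's images.

    The per-channel mean image is blurred with a large Gaussian kernel
    (default sigma = min(H, W) / 16; strong enough to suppress residual
    scene content while barely distorting the low-frequency vignette),
    then normalised per channel to mean one.
    """
    if len(images) < 10:
        raise ValueError("profile estimation needs at least 10 images")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValueError("all images must share dimensions")
    mean = np.zeros(np.asarray(images[0]).shape, np.float64)
    for im in images:
        mean += np.asarray(im, np.float64)
    mean /= len(images)
    if mean.ndim == 2:
        mean = mean[..., None]
    if smooth_sigma is None:
        smooth_sigma = min(mean.shape[:2]) / 16.0
    smoothed = np.stack(
        [gaussian_filter(mean[..., k], smooth_sigma) for k in range(mean.shape[-1])], -1)
    smoothed = np.clip(smoothed, 1e-9, None)
    gain = smoothed / smoothed.reshape(-1, smoothed.shape[-1]).mean(axis=0)
    return IlluminationProfile(np.clip(gain, 1e-6, None)
                               / np.clip(gain, 1e-6, None).reshape(-1, gain.shape[-1]).mean(axis=0))


def apply_profile(image: np.ndarray, profile: IlluminationProfile,
                  clip_max: float | None = None) -> np.ndarray:
    """Divide out the illumination gain (a unit profile is the identity)."""
    img = np.asarray(image, np.float64)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[..., None]
    if img.shape != profile.gain.shape:
        raise ValueError("image and profile dimensions differ")
    out = img / profile.gain
    if clip_max is not None:
        out = np.clip(out, 0, clip_max)
    return out[..., 0] if squeeze else out


def gray_world_white_balance(image: np.ndarray) -> np.ndarray:
    """Simple gray-world white balance (rough stand-in for a manually
    calibrated per-day colour profile; clearly an approximation)."""
    img = np.asarray(image, np.float64)
    means = img.reshape(-1, img.shape[-1]).mean(axis=0)
    return img * (means.mean() / np.clip(means, 1e-9, None))
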