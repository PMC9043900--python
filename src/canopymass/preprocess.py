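"""RGB-D preprocessing: depth filtering, jet encoding, cropping, augmentation.

The depth branch of the regression network consumes a 3-channel image, so
single-channel depth is normalized and mapped through the classic
piecewise-linear jet colormap (blue = near, red = far).  Depth values
beyond the tray plane are clamped at 380 mm before normalization, which
stretches the usable contrast of the encoding; missing depth (0) is kept
at 0 and therefore encodes as deep blue, never aliased with background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv, hsv2rgb
from skimage.transform import rotate as _sk_rotate

from .scene import RGBDSample, MAX_SCENE_DEPTH

MAX_VALID_DEPTH = 3800  # 0.1 mm units == 380 mm: everything farther is non-plant scene
CROP_SIZE = 480


@dataclass
class ModelInputPair:
    """Model-ready tensors: normalized color and jet-encoded depth, both
    square float32 images with values in [0, 1]."""

    rgb_norm: np.ndarray  # S x S x 3 float32 in [0,1]
    depth_jet: np.ndarray  # S x S x 3 float32 in [0,1]

    def __post_init__(self) -> None:
        if self.rgb_norm.shape != self.depth_jet.shape:
            raise ValueError("rgb_norm and depth_jet must share shape")


@dataclass
class AugmentConfig:
    """Train-time augmentation ranges (shared rotation; color ops on RGB only)."""

    rotation_degrees: tuple[float, float] = (0.0, 360.0)
    brightness: tuple[float, float] = (0.5, 1.5)
    contrast: tuple[float, float] = (0.5, 1.5)
    saturation: tuple[float, float] = (0.5, 1.5)
    hue_offset: tuple[float, float] = (-0.1, 0.1)
    grayscale_p: float = 0.1


def filter_depth(depth: np.ndarray, max_depth: int = MAX_VALID_DEPTH) -> np.ndarray:
    """Clamp far (non-plant) depth values to ``max_depth``.

    Values above the threshold belong to the scene beyond the tray and are
    clamped (not zeroed) so background still encodes as "farthest"/red and
    is never confused with missing pixels (0).
    """
    depth = np.asarray(depth)
    if depth.size and depth.min() < 0:
        raise ValueError("negative depth values are invalid")
    return np.minimum(depth, max_depth)


def normalize_depth(depth_filtered: np.ndarray, max_depth: int = MAX_VALID_DEPTH) -> np.ndarray:
    """Linear map [0, max_depth] -> [0, 1] as float32; input must be pre-filtered."""
    depth_filtered = np.asarray(depth_filtered)
    if depth_filtered.size and (
        depth_filtered.min() < 0 or depth_filtered.max() > max_depth
    ):
        raise ValueError("depth must be filtered to [0, %d] first" % max_depth)
    return (depth_filtered / float(max_depth)).astype(np.float32)


def jet_encode(depth_norm: np.ndarray) -> np.ndarray:
    """Classic 4-segment piecewise-linear jet colormap on values in [0, 1].

    0 -> (0, 0, 0.5) deep blue (nearest / missing), 1 -> (0.5, 0, 0) deep
    red (farthest), 0.5 -> green at full intensity.  Channel c(x) =
    clip(1.5 - |4x - k_c|, 0, 1) with k = 3, 2, 1 for R, G, B.
    """
    x = np.asarray(depth_norm, dtype=np.float32)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("jet_encode expects values in [0, 1]")
    out = np.empty(x.shape + (3,), dtype=np.float32)
    out[..., 0] = np.clip(1.5 - np.abs(4.0 * x - 3.0), 0.0, 1.0)
    out[..., 1] = np.clip(1.5 - np.abs(4.0 * x - 2.0), 0.0, 1.0)
    out[..., 2] = np.clip(1.5 - np.abs(4.0 * x - 1.0), 0.0, 1.0)
    return out


def center_crop(image: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Crop the central ``size`` x ``size`` window (error if input is smaller)."""
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"input {h}x{w} smaller than crop {size}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return image[r0 : r0 + size, c0 : c0 + size]


def preprocess_pair(sample: RGBDSample, crop_size: int = CROP_SIZE) -> ModelInputPair:
    """Raw sensor pair -> model input: depth filter/normalize/jet/crop, rgb /255/crop."""
    depth = np.asarray(sample.depth)
    if depth.size and depth.max() <= 1 and np.issubdtype(depth.dtype, np.floating):
        raise ValueError("depth looks already normalized; expected 0.1 mm integers")
    if depth.size and depth.max() > MAX_SCENE_DEPTH:
        raise ValueError("depth exceeds the 12000 scene maximum")
    djet = jet_encode(normalize_depth(filter_depth(depth)))
    rgb = (np.asarray(sample.rgb, dtype=np.float32) / 255.0).astype(np.float32)
    return ModelInputPair(
        rgb_norm=np.ascontiguousarray(center_crop(rgb, crop_size)),
        depth_jet=np.ascontiguousarray(center_crop(djet, crop_size)),
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def rotate_image(image: np.ndarray, angle_degrees: float, order: int = 1) -> np.ndarray:
    """Rotate about the image center, zero-filling the corners."""
    if angle_degrees % 360.0 == 0.0:
        return image.astype(np.float32, copy=True)
    return _sk_rotate(
        image, angle_degrees, resize=False, center=None, order=order, mode="constant", cval=0.0
    ).astype(np.float32)


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def color_jitter(
    rgb: np.ndarray,
    brightness: float = 1.0,
    contrast: float = 1.0,
    saturation: float = 1.0,
    hue_offset: float = 0.0,
) -> np.ndarray:
    """Brightness/contrast/saturation scaling and hue rotation on a [0,1] image."""
    out = np.asarray(rgb, dtype=np.float32)
    if brightness != 1.0:
        out = out * brightness
    if contrast != 1.0:
        mean = float(_luminance(np.clip(out, 0, 1)).mean())
        out = mean + (out - mean) * contrast
    if saturation != 1.0:
        gray = _luminance(np.clip(out, 0, 1))[..., None]
        out = gray + (out - gray) * saturation
    out = np.clip(out, 0.0, 1.0)
    if hue_offset != 0.0:
        hsv = rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + hue_offset) % 1.0
        out = hsv2rgb(hsv)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    g = _luminance(rgb)
    return np.repeat(g[..., None], 3, axis=2).astype(np.float32)


def apply_augmentation(
    pair: ModelInputPair,
    angle_degrees: float = 0.0,
    brightness: float = 1.0,
    contrast: float = 1.0,
    saturation: float = 1.0,
    hue_offset: float = 0.0,
    grayscale: bool = False,
    rotation_order: int = 1,
) -> ModelInputPair:
    """Deterministic augmentation: one shared rotation for both modalities;
    color jitter and grayscale touch the RGB image only (the jet-encoded
    depth carries geometry in its colors and must not be color-perturbed)."""
    rgb = rotate_image(pair.rgb_norm, angle_degrees, order=rotation_order)
    djet = rotate_image(pair.depth_jet, angle_degrees, order=rotation_order)
    rgb = color_jitter(rgb, brightness, contrast, saturation, hue_offset)
    if grayscale:
        rgb = to_grayscale(rgb)
    return ModelInputPair(rgb_norm=rgb, depth_jet=djet)


def augment_pair(
    pair: ModelInputPair,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> ModelInputPair:
    """Sample augmentation parameters from ``rng`` and apply them."""
    cfg = config or AugmentConfig()
    angle = rng.uniform(*cfg.rotation_degrees)
    b = rng.uniform(*cfg.brightness)
    c = rng.uniform(*cfg.contrast)
    s = rng.uniform(*cfg.saturation)
    h = rng.uniform(*cfg.hue_offset)
    gray = rng.random() < cfg.grayscale_p
    return apply_augmentation(pair, angle, b, c, s, h, gray)
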