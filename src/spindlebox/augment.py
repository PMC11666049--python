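"""Box-aware image augmentation.

Three augmentations are applied to rendered waveform images, never to the
underlying signal: random x/y scaling in [0.9, 1.1], horizontal/vertical
translation in [−30, 30] px, and hue/saturation/brightness shifts in
[−0.2, 0.2].  Bounding boxes are carried through the same affine map as the
pixels; if any box would leave the canvas the draw is redone (bounded
retries), so augmented datasets only ever contain fully in-canvas events.

Scaling is about the canvas origin and content is resampled back onto the
original canvas size (background-filled), so image dimensions never change.
HSV offsets act on [0, 1]-normalized channels; hue wraps, saturation and
brightness are clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

from .render import BoundingBox, LabeledImage

__all__ = ["AugmentParams", "apply_geometric", "apply_color", "augment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the three augmentations; x/y and H/S/V drawn independently."""

    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_range_px: tuple[float, float] = (-30.0, 30.0)
    hsv_range: tuple[float, float] = (-0.2, 0.2)
    max_retries: int = 25

    def __post_init__(self) -> None:
        for name in ("scale_range", "translate_range_px", "hsv_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} must be well-ordered, got ({lo}, {hi})")
        if self.scale_range[0] <= 0:
            raise ValueError("scale factors must be positive")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")


def _map_boxes(
    boxes: list[BoundingBox], sx: float, sy: float, tx: float, ty: float
) -> list[BoundingBox]:
    """Map each box corner by (x, y) ↦ (sx·x + tx, sy·y + ty)."""
    return [
        BoundingBox(
            b.event_class,
            sx * b.x_min + tx,
            sy * b.y_min + ty,
            sx * b.width,
            sy * b.height,
        )
        for b in boxes
    ]


def apply_geometric(
    pixels: np.ndarray,
    boxes: list[BoundingBox],
    sx: float,
    sy: float,
    tx: float,
    ty: float,
    background: tuple[int, int, int] = (255, 255, 255),
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Scale about the origin and translate, on a fixed canvas.

    Content is resampled (bilinear) onto the original canvas size with the
    background color filling exposed regions; boxes go through the same
    affine.  Identity parameters return the inputs bit-exactly.
    """
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    new_boxes = _map_boxes(boxes, sx, sy, tx, ty)
    if (sx, sy, tx, ty) == (1.0, 1.0, 0.0, 0.0):
        return pixels.copy(), new_boxes
    img = Image.fromarray(pixels)
    # PIL's AFFINE takes the output→input map: x_in = (x_out − tx)/sx
    coeffs = (1.0 / sx, 0.0, -tx / sx, 0.0, 1.0 / sy, -ty / sy)
    moved = img.transform(
        img.size,
        Image.Transform.AFFINE,
        coeffs,
        resample=Image.Resampling.BILINEAR,
        fillcolor=tuple(background),
    )
    return np.asarray(moved, dtype=np.uint8), new_boxes


def apply_color(pixels: np.ndarray, dh: float, ds: float, dv: float) -> np.ndarray:
    """Shift hue (wrapping), saturation and brightness (clipped) in HSV space.

    Channels are [0, 1]-normalized; the round trip through HSV changes pixel
    values by at most one intensity level.
    """
    hsv = rgb_to_hsv(pixels.astype(np.float64) / 255.0)
    hsv[..., 0] = np.mod(hsv[..., 0] + dh, 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] + ds, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] + dv, 0.0, 1.0)
    rgb = hsv_to_rgb(hsv)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def augment(
    image: LabeledImage, params: AugmentParams, rng: np.random.Generator
) -> LabeledImage:
    """One randomized augmentation of a labeled image.

    Draws scale/translation/HSV offsets uniformly from the configured ranges
    and applies geometry then color.  If the drawn geometry pushes any box
    out of the canvas the draw is redone, up to ``params.max_retries``; on
    exhaustion the input is returned unchanged with a logged warning.
    """
    h, w = image.pixels.shape[:2]
    for _ in range(params.max_retries):
        sx, sy = rng.uniform(*params.scale_range, size=2)
        tx, ty = rng.uniform(*params.translate_range_px, size=2)
        candidate = _map_boxes(image.boxes, sx, sy, tx, ty)
        if all(b.is_inside(w, h) for b in candidate):
            pixels, boxes = apply_geometric(
                image.pixels, image.boxes, sx, sy, tx, ty,
                background=image.geometry.background,
            )
            dh, ds, dv = rng.uniform(*params.hsv_range, size=3)
            pixels = apply_color(pixels, dh, ds, dv)
            return LabeledImage(
                pixels,
                image.geometry,
                boxes,
                replace(image.provenance, augmented=True),
            )
    logger.warning(
        "augmentation of %s exhausted %d retries; returning the input unchanged",
        image.name,
        params.max_retries,
    )
    return image
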