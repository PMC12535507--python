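"""Input-gradient saliency maps and mask-overlap metrics.

The saliency of a pixel is the magnitude of the gradient of a target
class's score with respect to that pixel (vanilla gradient saliency,
channel-aggregated by the maximum absolute value).  Thresholding the map at
a quantile yields a binary mask whose overlap with an expert annotation is
scored by intersection-over-union, coverage accuracy (intersection over the
annotation area) and coverage precision (intersection over the mask area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cascade import CascadeModel

__all__ = [
    "SaliencyMap",
    "BinaryMask",
    "saliency_map",
    "mask_from_saliency",
    "iou",
    "coverage_accuracy",
    "coverage_precision",
    "read_mask_png",
    "write_mask_png",
]

#: default fraction of pixels kept by the saliency threshold
DEFAULT_THRESHOLD_FRACTION = 0.15


@dataclass(frozen=True)
class SaliencyMap:
    """Non-negative per-pixel saliency grid (height × width)."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("saliency grid must be 2-D (height, width)")
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            raise ValueError("saliency values must be finite and non-negative")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean pixel mask paired with an image or annotation."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError("mask must be 2-D (height, width)")
        object.__setattr__(self, "grid", g.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def area(self) -> int:
        return int(self.grid.sum())


def saliency_map(
    model: CascadeModel, image: np.ndarray, target_class: int,
    stage: int | None = None,
) -> SaliencyMap:
    """Gradient saliency of ``target_class``'s score for one image.

    The model must have been built on image-shaped inputs (2-D, or 3-D with
    a trailing channel axis); for multi-channel images the per-pixel value
    is the maximum absolute gradient over channels.
    """
    if len(model.input_shape) not in (2, 3):
        raise ValueError(
            f"saliency needs an image model; input shape {model.input_shape} "
            "is not 2-D/3-D"
        )
    image = np.asarray(image, dtype=float)
    if image.shape != model.input_shape:
        raise ValueError(
            f"image shape {image.shape} != model input {model.input_shape}"
        )
    grad = model.input_gradient(image[None], target_class, stage=stage)[0]
    grad = np.abs(grad)
    if grad.ndim == 3:
        grad = grad.max(axis=-1)
    return SaliencyMap(grad)


def mask_from_saliency(
    smap: SaliencyMap,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> BinaryMask:
    """Keep the top ``threshold_fraction`` of salience by quantile.

    Pixels at or above the ``1 - threshold_fraction`` quantile are set; ties
    with the threshold value are included, so a constant map becomes an
    all-true mask (with a warning).
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    g = smap.grid
    if np.ptp(g) == 0:
        warnings.warn("constant saliency map; mask covers the whole image")
        return BinaryMask(np.ones_like(g, dtype=bool))
    cut = np.quantile(g, 1.0 - threshold_fraction)
    return BinaryMask(g >= cut)


def _check_shapes(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union; 0 when both masks are empty."""
    _check_shapes(a, b)
    union = np.logical_or(a.grid, b.grid).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a.grid, b.grid).sum() / union)


def coverage_accuracy(mask: BinaryMask, annotation: BinaryMask) -> float:
    """Intersection over the annotation area: how much of the annotated
    region the saliency mask covers."""
    _check_shapes(mask, annotation)
    if annotation.area == 0:
        raise ValueError("annotation mask is empty")
    return float(np.logical_and(mask.grid, annotation.grid).sum()
                 / annotation.area)


def coverage_precision(mask: BinaryMask, annotation: BinaryMask) -> float:
    """Intersection over the mask area: how much of the saliency mask lies
    inside the annotated region."""
    _check_shapes(mask, annotation)
    if mask.area == 0:
        raise ValueError("saliency mask is empty")
    return float(np.logical_and(mask.grid, annotation.grid).sum() / mask.area)


def read_mask_png(path) -> BinaryMask:
    """Single-channel PNG, 0 = background, anything else = foreground."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask(arr > 0)


def write_mask_png(path, mask: BinaryMask) -> None:
    from PIL import Image

    Image.fromarray((mask.grid * np.uint8(255))).save(path)
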