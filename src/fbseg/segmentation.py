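"""Patch-based pixel classification and mask refinement.

The pipeline labels every pixel of a grayscale image by classifying the
fixed-size patch (default 25×25) centred on it, producing an initial binary
mask.  Two refinement stages follow: an intensity band-pass that drops mask
pixels whose gray value falls outside μ ± k·σ of the foreground intensity
distribution, and morphological opening + closing to remove isolated specks
and fill small gaps.  Overlap against a reference mask is quantified with
the Dice ratio, IoU and pixel accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.morphology import closing, opening

from .exceptions import ConfigurationError, DegenerateRangeError, ShapeError
from .net_core import NetworkModel, run_forward

__all__ = [
    "PatchSample",
    "SegmentationConfig",
    "SegmentationOutcome",
    "normalize_image",
    "extract_patches",
    "dense_predict",
    "threshold_refine",
    "morphological_refine",
    "evaluate",
    "segment_image",
]

logger = logging.getLogger(__name__)


@dataclass
class PatchSample:
    """One training/inference sample: a normalized patch, the (row, col) of
    its centre pixel in the source image, and optionally that pixel's class."""

    pixels: np.ndarray
    center: tuple[int, int]
    label: int | None = None


@dataclass
class SegmentationConfig:
    patch_size: int = 25
    stride: int = 1
    threshold_k: float = 2.0
    morph_radius: int = 1
    morph_order: tuple[str, str] = ("open", "close")
    class_of_interest: int = 1

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ConfigurationError("patch_size must be odd and >= 3")
        if self.stride < 1:
            raise ConfigurationError("stride must be >= 1")
        if self.threshold_k <= 0:
            raise ConfigurationError("threshold_k must be > 0")
        if self.morph_radius < 1:
            raise ConfigurationError("morph_radius must be >= 1")
        if sorted(self.morph_order) != ["close", "open"]:
            raise ConfigurationError(
                'morph_order must contain "open" and "close" once each')


@dataclass
class SegmentationOutcome:
    initial_mask: np.ndarray
    threshold_mask: np.ndarray
    final_mask: np.ndarray
    metrics: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_image(image: np.ndarray) -> np.ndarray:
    """Min-max rescale of the gray values to [0, 1]:
    f' = (f − min)/(max − min)."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise DegenerateRangeError("constant image: normalization undefined")
    return (image - lo) / (hi - lo)


def _padded_windows(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Reflect-pad so that every pixel can be a patch centre; returns the
    (H, W, p, p) view of all centred patches."""
    half = patch_size // 2
    padded = np.pad(image, half, mode="reflect")
    return sliding_window_view(padded, (patch_size, patch_size))


def extract_patches(image: np.ndarray, config: SegmentationConfig,
                    with_labels: np.ndarray | None = None) -> list[PatchSample]:
    """One patch per stride-spaced pixel centre; borders are reflect-padded.
    If a label mask is given each patch carries its centre pixel's class."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError("extract_patches expects a 2-D grayscale image")
    if with_labels is not None and with_labels.shape != image.shape:
        raise ShapeError("label mask shape differs from image shape")
    windows = _padded_windows(image, config.patch_size)
    samples = []
    for r in range(0, image.shape[0], config.stride):
        for c in range(0, image.shape[1], config.stride):
            label = int(with_labels[r, c]) if with_labels is not None else None
            samples.append(PatchSample(windows[r, c].copy(), (r, c), label))
    return samples


# ---------------------------------------------------------------------------
# dense prediction
# ---------------------------------------------------------------------------

def dense_predict(model: NetworkModel, image: np.ndarray,
                  config: SegmentationConfig,
                  chunk: int = 1024) -> np.ndarray:
    """Classify every stride-spaced centre pixel and return the initial
    binary mask (class == class_of_interest).  With stride > 1 the skipped
    pixels take the class of their nearest evaluated centre."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    ps = config.patch_size
    if tuple(model.input_shape) != (ps, ps, 1):
        raise ShapeError(
            f"model input_shape {model.input_shape} does not match "
            f"patch_size {ps}")
    windows = _padded_windows(image, ps)
    rows = np.arange(0, h, config.stride)
    cols = np.arange(0, w, config.stride)
    patches = windows[np.ix_(rows, cols)].reshape(-1, ps, ps, 1)

    preds = np.empty(patches.shape[0], dtype=int)
    stop = model.logits_layer
    for start in range(0, patches.shape[0], chunk):
        batch = patches[start:start + chunk]
        records = run_forward(model, batch, stop_after=stop)
        preds[start:start + len(batch)] = records[-1]["y"].argmax(axis=1)
    grid = preds.reshape(len(rows), len(cols))

    # nearest-centre fill for stride > 1
    ri = np.clip(np.round(np.arange(h) / config.stride).astype(int),
                 0, len(rows) - 1)
    ci = np.clip(np.round(np.arange(w) / config.stride).astype(int),
                 0, len(cols) - 1)
    labels = grid[np.ix_(ri, ci)]
    return (labels == config.class_of_interest).astype(np.uint8)


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def threshold_refine(image: np.ndarray, initial_mask: np.ndarray,
                     config: SegmentationConfig) -> np.ndarray:
    """Keep only mask pixels whose intensity lies inside the foreground band
    μ ± k·σ (closed interval), where μ/σ are computed over the pixels the
    initial mask marks as foreground.  Never adds pixels."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(initial_mask).astype(bool)
    if image.shape != mask.shape:
        raise ShapeError("image and mask shapes differ")
    if not mask.any():
        logger.warning("threshold_refine: empty initial mask")
        return np.zeros_like(mask, dtype=np.uint8)
    vals = image[mask]
    mu, sigma = vals.mean(), vals.std()
    band = (image >= mu - config.threshold_k * sigma) & \
           (image <= mu + config.threshold_k * sigma)
    return (mask & band).astype(np.uint8)


def morphological_refine(mask: np.ndarray,
                         config: SegmentationConfig) -> np.ndarray:
    """Morphological opening (erode→dilate) and closing (dilate→erode) with
    a square structuring element of side 2·morph_radius+1, in the configured
    order.  Opening removes isolated specks and edge bulges; closing fills
    small gaps and concavities."""
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.isin(uniq, (0, 1)).all():
        raise TypeError("morphological_refine expects a binary {0,1} mask")
    footprint = np.ones((2 * config.morph_radius + 1,) * 2, dtype=bool)
    out = mask.astype(bool)
    for op in config.morph_order:
        if op == "open":
            out = opening(out, footprint)
        else:
            out = closing(out, footprint)
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(pred_mask: np.ndarray, truth_mask: np.ndarray) -> dict[str, float]:
    """Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B|, pixel accuracy.  Two
    empty masks count as perfect agreement (Dice = IoU = 1)."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(truth_mask).astype(bool)
    if a.shape != b.shape:
        raise ShapeError("mask shapes differ")
    inter = float(np.logical_and(a, b).sum())
    union = float(np.logical_or(a, b).sum())
    size = float(a.sum() + b.sum())
    dice = 1.0 if size == 0 else 2.0 * inter / size
    iou = 1.0 if union == 0 else inter / union
    accuracy = float((a == b).mean())
    return {"dice": dice, "iou": iou, "accuracy": accuracy}


def segment_image(model: NetworkModel, raw_image: np.ndarray,
                  config: SegmentationConfig,
                  truth_mask: np.ndarray | None = None) -> SegmentationOutcome:
    """Full pipeline: normalize → dense patch classification → intensity
    band-pass → morphological smoothing; all three masks are retained."""
    norm = normalize_image(raw_image)
    initial = dense_predict(model, norm, config)
    thresholded = threshold_refine(norm, initial, config)
    final = morphological_refine(thresholded, config)
    metrics = None
    if truth_mask is not None:
        metrics = evaluate(final, truth_mask)
    return SegmentationOutcome(initial, thresholded, final, metrics)
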