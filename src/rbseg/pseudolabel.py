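"""Unsupervised pixel pseudo-labeling of fundus images.

The first stage of the method: the target image is stacked with three healthy
reference fundus images so that healthy retina is guaranteed to dominate the
pixel population, the grayscale composite is clustered with a Gaussian
mixture, the most populous cluster is declared healthy, every other cluster is
merged into a "suspected" mask, and the mask restricted to the target block is
cleaned with a median filter, morphological closing and small-component
removal.

Clustering runs on the 256-level quantized intensity histogram with bin
counts as sample weights, which is mathematically identical to per-pixel EM
on the quantized composite (fundus photographs are 8-bit to begin with) and
removes the per-pixel cost of ~6e5-point E-steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .gmm import fit_gmm, assign_clusters

logger = logging.getLogger(__name__)

STANDARD_SHAPE = (320, 480)

#: ITU-R 601 luminance weights for the grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Quantization levels for histogram-weighted clustering.
N_LEVELS = 256


@dataclass
class LabelConfig:
    """Knobs of the unsupervised labeling stage."""

    K: int = 6
    n_init: int = 25
    seed: int = 0
    median_size: int = 5
    close_size: int = 5
    min_area: int = 100
    shape: tuple[int, int] = STANDARD_SHAPE
    tol: float = 1e-6
    max_iter: int = 200


@dataclass
class CompositeLayout:
    """A vertical stack of the target image and the healthy references."""

    composite: np.ndarray
    target_slice: slice
    axis: int = 0

    @property
    def target(self) -> np.ndarray:
        return self.composite[self.target_slice]


def standardize_image(
    image: np.ndarray, shape: tuple[int, int] = STANDARD_SHAPE
) -> np.ndarray:
    """Resize to the working resolution and convert to [0,1] luminance.

    Accepts 2-D grayscale or (H, W, 3+) color rasters, integer (8/16-bit) or
    float; bilinear resampling with anti-aliasing, then the ITU-R 601 luma
    0.299 R + 0.587 G + 0.114 B.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            arr = arr[:, :, :3] @ LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {arr.shape}")
    if arr.shape != shape:
        arr = resize(arr, shape, order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(arr, 0.0, 1.0)


def build_composite(target: np.ndarray, references: list[np.ndarray]) -> CompositeLayout:
    """Stack [target; ref1; ref2; ref3] along the row axis (target first)."""
    if len(references) != 3:
        raise ValueError("exactly three healthy reference images are required")
    for img in (target, *references):
        if img.shape != target.shape or img.ndim != 2:
            raise ValueError("target and references must share one 2-D shape")
    composite = np.concatenate([target, *references], axis=0)
    return CompositeLayout(composite=composite, target_slice=slice(0, target.shape[0]))


def labels_to_raw_mask(labels: np.ndarray, layout: CompositeLayout) -> np.ndarray:
    """Majority cluster over the whole composite is healthy; the rest is lesion.

    Ties on the pixel count go to the lowest label.  The returned mask covers
    only the target block of the composite.
    """
    labels = np.asarray(labels)
    if labels.size != layout.composite.size:
        raise ValueError("labels must cover the full composite")
    labels = labels.reshape(layout.composite.shape)
    counts = np.bincount(labels.ravel())
    healthy = int(np.argmax(counts))  # argmax takes the lowest on ties
    return (labels[layout.target_slice] != healthy).astype(np.uint8)


def postprocess_mask(
    mask: np.ndarray, median_size: int = 5, close_size: int = 5, min_area: int = 100
) -> np.ndarray:
    """Median filter, then morphological closing, then small-object removal."""
    if median_size % 2 == 0:
        raise ValueError("median_size must be odd")
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    out = ndimage.median_filter(mask.astype(np.uint8), size=median_size)
    out = out.astype(bool)
    if close_size > 1:
        out = ndimage.binary_closing(
            out,
            structure=np.ones((close_size, close_size), dtype=bool),
            border_value=1,  # treat the outside as foreground: constants survive
        )
    if min_area > 1:
        labels, n = ndimage.label(out, structure=np.ones((3, 3), dtype=bool))
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            out = (sizes >= min_area)[labels]
    return out.astype(np.uint8)


def quantize(gray: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    """Quantize [0,1] intensities onto ``n_levels`` uniform levels."""
    return np.round(np.clip(gray, 0, 1) * (n_levels - 1)) / (n_levels - 1)


def _cluster_composite(composite: np.ndarray, cfg: LabelConfig) -> np.ndarray:
    """Cluster composite pixels by intensity; returns per-pixel labels.

    EM runs on the histogram of quantized levels (counts as weights); the
    per-level hard assignments are then broadcast back to the pixels, which is
    exactly the per-pixel assignment for the quantized composite.
    """
    levels = np.round(np.clip(composite, 0, 1) * (N_LEVELS - 1)).astype(np.int64)
    counts = np.bincount(levels.ravel(), minlength=N_LEVELS).astype(float)
    present = counts > 0
    values = (np.nonzero(present)[0] / (N_LEVELS - 1))[:, None]
    fit = fit_gmm(
        values,
        K=cfg.K,
        n_init=cfg.n_init,
        seed=cfg.seed,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        sample_weight=counts[present],
    )
    level_label = np.zeros(N_LEVELS, dtype=np.int64)
    level_label[present] = assign_clusters(values, fit.model)
    return level_label[levels]


def pseudo_label_image(
    target_rgb: np.ndarray,
    references: list[np.ndarray],
    cfg: LabelConfig | None = None,
) -> np.ndarray:
    """Full unsupervised pass: composite, cluster, majority rule, cleanup.

    ``references`` may be raw color images or already-standardized grayscale
    rasters; everything is standardized to ``cfg.shape`` first.  Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg or LabelConfig()
    if cfg.K < 2:
        raise ValueError("K must be >= 2")
    target = standardize_image(target_rgb, shape=cfg.shape)
    refs = [standardize_image(r, shape=cfg.shape) for r in references]
    layout = build_composite(target, refs)
    labels = _cluster_composite(layout.composite, cfg)
    raw = labels_to_raw_mask(labels, layout)
    return postprocess_mask(
        raw,
        median_size=cfg.median_size,
        close_size=cfg.close_size,
        min_area=cfg.min_area,
    )
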