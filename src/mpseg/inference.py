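"""Probability-heatmap inference: sliding-window, tiled, and whole-image.

All three modes produce a full-resolution map of P(MP) aligned with the
stain-normalized input image.

* **patch mode** — a patch classifier is slid across the image with a small
  stride (default 10 px, i.e. ~96% window overlap); each window's
  probability is assigned to its central pixel, giving a coarse map that is
  upsampled back to full resolution with nearest-neighbour interpolation
  and smoothed with a box filter to suppress upsampling artifacts.
* **tiled mode** — a segmenter is run on 240x240 tiles and the per-tile
  probability maps are reassembled at their origins (overlapping pixels
  averaged when an overlapping grid is requested).
* **whole mode** — the segmenter consumes the full image in one pass
  (padded to its required size multiple and cropped back).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import uniform_filter

from .patch_dataset import PATCH

STRIDE = 10
#: default box kernel for post-upsampling smoothing of the coarse heatmap
SMOOTH_KERNEL = 25


@dataclass(frozen=True)
class SlidingGrid:
    """Dense overlapping window grid for patch-mode inference."""

    patch: int
    stride: int
    origins: tuple[tuple[int, int], ...]
    coarse_shape: tuple[int, int]


def sliding_positions(
    height: int, width: int, patch: int = PATCH, stride: int = STRIDE
) -> SlidingGrid:
    """Row-major window origins 0, stride, 2*stride, ... fully inside the image."""
    if height < patch or width < patch:
        raise ValueError(f"image {height}x{width} smaller than patch {patch}")
    n_rows = (height - patch) // stride + 1
    n_cols = (width - patch) // stride + 1
    origins = tuple(
        (r * stride, c * stride) for r in range(n_rows) for c in range(n_cols)
    )
    return SlidingGrid(patch=patch, stride=stride, origins=origins, coarse_shape=(n_rows, n_cols))


def overlap_fraction(patch: int = PATCH, stride: int = STRIDE) -> float:
    """Fractional overlap between adjacent windows, e.g. (240-10)/240."""
    return (patch - stride) / patch


def _coarse_probabilities(clf, image: np.ndarray, grid: SlidingGrid) -> np.ndarray:
    if hasattr(clf, "predict_proba_grid"):
        probs = np.asarray(clf.predict_proba_grid(image, list(grid.origins), grid.patch))
    else:
        probs = np.array(
            [
                clf.predict_proba(image[r : r + grid.patch, c : c + grid.patch])
                for r, c in grid.origins
            ]
        )
    return probs.reshape(grid.coarse_shape)


def upsample_coarse(
    coarse: np.ndarray, full_shape: tuple[int, int], patch: int = PATCH, stride: int = STRIDE
) -> np.ndarray:
    """Nearest-neighbour upsampling of the coarse window map.

    Coarse cell (i, j) represents the window whose centre sits at full-image
    pixel (stride*i + patch//2, stride*j + patch//2); every full-resolution
    pixel takes the value of the nearest window centre, so the border margin
    (first/last patch//2 pixels) replicates the outermost cells.
    """
    h, w = full_shape
    half = patch // 2
    rows = np.clip(np.rint((np.arange(h) - half) / stride).astype(int), 0, coarse.shape[0] - 1)
    cols = np.clip(np.rint((np.arange(w) - half) / stride).astype(int), 0, coarse.shape[1] - 1)
    return coarse[np.ix_(rows, cols)]


def patch_heatmap_inference(
    clf,
    image: np.ndarray,
    grid: SlidingGrid | None = None,
    smooth_kernel: int = SMOOTH_KERNEL,
) -> np.ndarray:
    """Full-resolution P(MP) heatmap from a patch classifier.

    The coarse per-window map is upsampled (nearest neighbour) and then
    smoothed with an odd box kernel; smoothing is a convex average so the
    values stay in [0, 1].
    """
    h, w = image.shape[:2]
    if grid is None:
        grid = sliding_positions(h, w)
    coarse = _coarse_probabilities(clf, image, grid)
    full = upsample_coarse(coarse, (h, w), grid.patch, grid.stride)
    if smooth_kernel and smooth_kernel > 1:
        if smooth_kernel % 2 == 0:
            raise ValueError("smoothing kernel must be odd")
        full = uniform_filter(full, size=smooth_kernel, mode="nearest")
    return np.clip(full, 0.0, 1.0)


def tiled_segmentation_inference(
    seg, image: np.ndarray, patch: int = PATCH, stride: int | None = None
) -> np.ndarray:
    """Assemble per-tile segmenter probability maps into a full heatmap.

    Default is the non-overlapping grid (image must be divisible by the
    patch size); with ``stride`` set, overlapping tiles are averaged where
    they cover the same pixel.
    """
    h, w = image.shape[:2]
    if stride is None:
        if h % patch or w % patch:
            raise ValueError(
                f"image {h}x{w} not divisible by patch {patch}; pass stride for overlap"
            )
        origins = [(r, c) for r in range(0, h, patch) for c in range(0, w, patch)]
    else:
        grid = sliding_positions(h, w, patch, stride)
        origins = list(grid.origins)
        # make sure the right/bottom edges are covered when stride misses them
        last_r, last_c = h - patch, w - patch
        if origins[-1][0] != last_r:
            origins += [(last_r, c) for c in sorted({o[1] for o in origins})]
        if max(o[1] for o in origins) != last_c:
            origins += [(r, last_c) for r in sorted({o[0] for o in origins})]
    acc = np.zeros((h, w))
    cover = np.zeros((h, w))
    for r, c in origins:
        acc[r : r + patch, c : c + patch] += seg.predict_proba_map(
            image[r : r + patch, c : c + patch]
        )
        cover[r : r + patch, c : c + patch] += 1.0
    return np.clip(acc / cover, 0.0, 1.0)


def whole_image_inference(seg, image: np.ndarray) -> np.ndarray:
    """Single forward pass over the full image, padded to the backend's
    required size multiple (edge replication) and cropped back."""
    h, w = image.shape[:2]
    mult = int(getattr(seg, "size_multiple", 1))
    pad_h = (-h) % mult
    pad_w = (-w) % mult
    if pad_h or pad_w:
        padded = np.pad(image, ((0, pad_h), (0, pad_w), (0, 0)), mode="edge")
        out = seg.predict_proba_map(padded)[:h, :w]
    else:
        out = seg.predict_proba_map(image)
    if out.shape != (h, w):
        raise ValueError(f"backend returned shape {out.shape}, expected {(h, w)}")
    return np.clip(out, 0.0, 1.0)


def save_heatmap(heatmap: np.ndarray, path: str | Path) -> Path:
    """Persist a heatmap as a 32-bit single-channel TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, heatmap.astype(np.float32))
    return path


def load_heatmap(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)
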