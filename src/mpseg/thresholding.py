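"""Heatmap binarization via Youden's-J adaptive thresholding, plus the
median / average / Otsu post-processing chain.

Youden's J statistic for a threshold t is ``Y_t = TPR - FPR`` computed at
pixel level between the thresholded heatmap and a binary reference; the
adaptive threshold is the (smallest) t maximizing Y. Because the optimum is
selected against the reference, this is an evaluation-time oracle: an
honest fixed-threshold mode is provided alongside it and reported metrics
must name which mode produced them.

Post-processing removes isolated noisy pixels and smooths region borders:
a 155x155 median filter, a 25x25 box (averaging) filter, then Otsu
binarization of the filtered grayscale. On binary input the median filter
is exactly the window majority vote, which is how it is computed here
(odd x odd windows cannot tie).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu

from .slide_io import MP

logger = logging.getLogger(__name__)

MEDIAN_KERNEL = 155
MEAN_KERNEL = 25

#: default threshold grid: the 256 8-bit probability levels {0, 1/255, ..., 1}
DEFAULT_GRID = np.arange(256) / 255.0


@dataclass
class ThresholdScan:
    """Candidate thresholds with their Youden statistics and the optimum."""

    thresholds: np.ndarray
    youden: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    t_hat: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "youden": self.youden,
            }
        )


def _rates(heatmap: np.ndarray, reference: np.ndarray, thresholds: np.ndarray):
    """Vectorized TPR/FPR over a threshold grid via sorted score counts."""
    pos = np.sort(heatmap[reference == MP].ravel())
    neg = np.sort(heatmap[reference != MP].ravel())
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            "reference contains a single class; Youden's J is undefined — "
            "use fixed-threshold mode"
        )
    # prediction is positive where value >= t
    tp = pos.size - np.searchsorted(pos, thresholds, side="left")
    fp = neg.size - np.searchsorted(neg, thresholds, side="left")
    return tp / pos.size, fp / neg.size


def youden_scan(
    heatmap: np.ndarray,
    reference: np.ndarray,
    thresholds: np.ndarray | str = "grid256",
) -> ThresholdScan:
    """Scan thresholds and select the one maximizing Youden's J = TPR - FPR.

    ``thresholds`` may be an explicit grid, ``"grid256"`` (the 8-bit
    levels), or ``"unique"`` (the distinct heatmap values). Ties on the
    maximum are broken toward the smallest threshold (favors recall,
    deterministic).
    """
    if heatmap.shape != reference.shape:
        raise ValueError("heatmap/reference shape mismatch")
    if isinstance(thresholds, str):
        if thresholds == "grid256":
            grid = DEFAULT_GRID
        elif thresholds == "unique":
            grid = np.unique(heatmap)
        else:
            raise ValueError(f"unknown threshold grid {thresholds!r}")
    else:
        grid = np.asarray(thresholds, dtype=np.float64)
    tpr, fpr = _rates(heatmap, reference, grid)
    youden = tpr - fpr
    t_hat = float(grid[int(np.argmax(youden))])  # argmax returns first (smallest t)
    return ThresholdScan(thresholds=grid, youden=youden, tpr=tpr, fpr=fpr, t_hat=t_hat)


def binarize(heatmap: np.ndarray, t: float) -> np.ndarray:
    """Pixel = 255 iff its probability >= t."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0, 1]")
    return np.where(heatmap >= t, MP, 0).astype(np.uint8)


def _clip_kernel(kernel: int, shape: tuple[int, int]) -> int:
    limit = min(shape)
    if kernel <= limit:
        return kernel
    clipped = limit if limit % 2 == 1 else limit - 1
    logger.warning("kernel %d exceeds image %s; clipped to %d", kernel, shape, clipped)
    return max(clipped, 1)


def postprocess(
    binary: np.ndarray,
    median_kernel: int = MEDIAN_KERNEL,
    mean_kernel: int = MEAN_KERNEL,
) -> np.ndarray:
    """Median (155x155) -> box mean (25x25) -> Otsu, with border replication.

    Input must be binary {0, 255}. Kernels larger than the image are
    clipped to the largest odd size that fits (logged).
    """
    vals = set(np.unique(binary).tolist())
    if not vals <= {0, MP}:
        raise ValueError("postprocess expects a binary {0,255} mask")
    median_kernel = _clip_kernel(median_kernel, binary.shape)
    mean_kernel = _clip_kernel(mean_kernel, binary.shape)
    # median of a binary image == majority vote in the window
    frac = uniform_filter((binary == MP).astype(np.float64), size=median_kernel, mode="nearest")
    med = np.where(frac > 0.5, MP, 0).astype(np.float64)
    smoothed = uniform_filter(med, size=mean_kernel, mode="nearest")
    gray = np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)
    if np.unique(gray).size < 2:
        return np.where(gray >= 128, MP, 0).astype(np.uint8)
    t = threshold_otsu(gray)
    return np.where(gray > t, MP, 0).astype(np.uint8)


def heatmap_to_mask(
    heatmap: np.ndarray,
    reference: np.ndarray | None = None,
    mode: str = "youden",
    fixed_t: float = 0.5,
    thresholds: np.ndarray | str = "grid256",
    median_kernel: int = MEDIAN_KERNEL,
    mean_kernel: int = MEAN_KERNEL,
    apply_postprocess: bool = True,
) -> tuple[np.ndarray, ThresholdScan | None]:
    """Heatmap -> clean binary mask, by adaptive or fixed thresholding.

    In ``youden`` mode the threshold is chosen against ``reference`` (the
    per-image oracle); in ``fixed`` mode ``fixed_t`` is used and no
    reference is needed.
    """
    if mode == "youden":
        if reference is None:
            raise ValueError("youden mode needs a reference mask")
        scan = youden_scan(heatmap, reference, thresholds)
        t = scan.t_hat
    elif mode == "fixed":
        scan = None
        t = fixed_t
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    mask = binarize(heatmap, t)
    if apply_postprocess:
        mask = postprocess(mask, median_kernel, mean_kernel)
    return mask, scan
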