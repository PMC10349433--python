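"""Reading, writing and geometric normalization of slide images and masks.

Conventions used throughout the package:

* arrays are row-major with a top-left origin and 0-based indices;
* rectangles are half-open ``[r0, r1) x [c0, c1)``;
* an RGB image is a ``H x W x 3`` uint8 array;
* a binary mask is a ``H x W`` uint8 array with values in ``{0, 255}``,
  where 255 marks the muscularis propria (MP) class;
* the canonical slide size is 1440 rows x 1920 columns (printed as
  1920 x 1440 in width x height order in file names and reports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

logger = logging.getLogger(__name__)

#: canonical slide size as (height, width)
CANONICAL_SHAPE = (1440, 1920)

#: value of the positive (MP) class in masks
MP = 255

COHORTS = ("RC", "TUR")


@dataclass
class SlidePair:
    """An RGB slide image with its pixel-aligned binary ground-truth mask."""

    image: np.ndarray
    mask: np.ndarray
    slide_id: str
    cohort: str

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image/mask dimension mismatch for slide {self.slide_id!r}: "
                f"{self.image.shape[:2]} vs {self.mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def coerce_binary(mask: np.ndarray, threshold: int = 128) -> np.ndarray:
    """Map an arbitrary 8-bit mask to {0, 255} by thresholding.

    Values >= ``threshold`` (midpoint of the 8-bit range by default, to
    absorb anti-aliased annotation exports) become 255, the rest 0.
    """
    mask = np.asarray(mask)
    if mask.ndim == 3:  # RGB(A) export of a binary mask
        mask = mask[..., 0]
    return np.where(mask >= threshold, MP, 0).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image file, dropping any alpha channel."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def read_slide_pair(
    image_path: str | Path, mask_path: str | Path, cohort: str, slide_id: str | None = None
) -> SlidePair:
    """Read an image + mask pair from disk.

    The mask is coerced to {0, 255}; a mask that had more than two distinct
    values before coercion is accepted but logged. Image and mask must have
    equal spatial dimensions.
    """
    image = read_image(image_path)
    raw_mask = iio.imread(mask_path)
    n_distinct = len(np.unique(raw_mask))
    if n_distinct > 2:
        logger.warning(
            "mask %s has %d distinct values; coercing to binary at 128", mask_path, n_distinct
        )
    mask = coerce_binary(raw_mask)
    if slide_id is None:
        slide_id = Path(image_path).stem
    return SlidePair(image=image, mask=mask, slide_id=slide_id, cohort=cohort)


def canonical_resize(pair: SlidePair, target: tuple[int, int] = CANONICAL_SHAPE) -> SlidePair:
    """Resize a pair to the canonical shape.

    The image is resampled with bilinear interpolation, the mask with
    nearest-neighbour so it stays binary. Already-canonical pairs are
    returned unchanged (mask pixel-exact).
    """
    if pair.shape == tuple(target):
        return pair
    image = resize(
        pair.image, target, order=1, preserve_range=True, anti_aliasing=False
    )
    mask = resize(pair.mask, target, order=0, preserve_range=True, anti_aliasing=False)
    return replace(
        pair,
        image=np.clip(np.rint(image), 0, 255).astype(np.uint8),
        mask=mask.astype(np.uint8),
    )


def write_mask(mask: np.ndarray, out_path: str | Path) -> Path:
    """Write a binary mask as an 8-bit single-channel PNG."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, mask.astype(np.uint8))
    return out_path


def write_overlay(
    image: np.ndarray,
    prediction: np.ndarray,
    out_path: str | Path,
    color: tuple[int, int, int] = (0, 180, 0),
    alpha: float = 0.4,
) -> Path:
    """Render the predicted MP region as a colored tint over the image.

    Pixels where ``prediction == 255`` are alpha-blended with ``color``;
    all other pixels are untouched.
    """
    if image.shape[:2] != prediction.shape:
        raise ValueError("image/prediction shape mismatch")
    out = image.astype(np.float64).copy()
    sel = prediction == MP
    tint = np.asarray(color, dtype=np.float64)
    out[sel] = (1.0 - alpha) * out[sel] + alpha * tint
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, np.clip(np.rint(out), 0, 255).astype(np.uint8))
    return out_path


# ---------------------------------------------------------------------------
# dataset manifests

MANIFEST_COLUMNS = ["slide_id", "image_path", "mask_path", "cohort"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV (slide_id, image_path, mask_path, cohort)."""
    df = pd.read_csv(path, dtype={"slide_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return df[MANIFEST_COLUMNS]


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def load_pairs(manifest: pd.DataFrame, root: str | Path | None = None) -> list[SlidePair]:
    """Load every slide pair named by a manifest.

    Relative paths are resolved against ``root`` when given.
    """
    root = Path(root) if root is not None else None

    def _resolve(p: str) -> Path:
        path = Path(p)
        if root is not None and not path.is_absolute():
            path = root / path
        return path

    return [
        read_slide_pair(
            _resolve(row.image_path), _resolve(row.mask_path), row.cohort, slide_id=row.slide_id
        )
        for row in manifest.itertuples()
    ]
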