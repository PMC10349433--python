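"""Reinhard color-transfer stain normalization.

H&E slides from different specimens (and especially across the RC and TUR
cohorts) vary noticeably in staining intensity. Reinhard normalization
imposes a common stain appearance by matching the per-channel first and
second moments of each image, in a decorrelated color space, to those of a
chosen reference. The default space is CIE Lab (D65, standard sRGB
pipeline); the original Ruderman l-alpha-beta space is available via
``space="lalphabeta"`` — the contract (moment matching) is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2lab

#: guard against division by a vanishing source standard deviation
EPS = 1e-6

# Ruderman et al. RGB -> LMS -> l-alpha-beta transform
_RGB2LMS = np.array(
    [[0.3811, 0.5783, 0.0402], [0.1967, 0.7244, 0.0782], [0.0241, 0.1288, 0.8444]]
)
_LMS2LAB_A = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)])
_LMS2LAB_B = np.array([[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float)
_LMS2LAB = _LMS2LAB_A @ _LMS2LAB_B


@dataclass(frozen=True)
class StainStats:
    """Per-channel mean and population standard deviation in color space."""

    lab_mean: tuple[float, float, float]
    lab_std: tuple[float, float, float]
    space: str = "lab"

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.lab_std):
            raise ValueError("standard deviations must be non-negative")


def _to_space(image: np.ndarray, space: str) -> np.ndarray:
    rgb = np.asarray(image, dtype=np.float64) / 255.0
    if space == "lab":
        return rgb2lab(rgb)
    if space == "lalphabeta":
        lms = rgb @ _RGB2LMS.T
        log_lms = np.log10(np.maximum(lms, 1e-6))
        return log_lms @ _LMS2LAB.T
    raise ValueError(f"unknown color space {space!r}")


def _from_space(arr: np.ndarray, space: str) -> np.ndarray:
    if space == "lab":
        rgb = lab2rgb(arr)
    elif space == "lalphabeta":
        log_lms = arr @ np.linalg.inv(_LMS2LAB).T
        lms = np.power(10.0, log_lms)
        rgb = lms @ np.linalg.inv(_RGB2LMS).T
    else:
        raise ValueError(f"unknown color space {space!r}")
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def compute_stain_stats(image: np.ndarray, space: str = "lab") -> StainStats:
    """Per-channel mean and population std of an RGB image in color space."""
    arr = _to_space(image, space)
    mean = arr.reshape(-1, 3).mean(axis=0)
    std = arr.reshape(-1, 3).std(axis=0)  # population (ddof=0)
    return StainStats(tuple(mean), tuple(std), space=space)


def reinhard_transfer(image: np.ndarray, ref: StainStats) -> np.ndarray:
    """Impose the reference stain appearance on an image.

    In the chosen color space each channel is remapped as

        x' = (x - mu_src) * (sigma_ref / sigma_src) + mu_ref

    then converted back to RGB and clipped to [0, 255]. Channels whose
    source standard deviation is below ``EPS`` (constant images) are shifted
    to the reference mean without scaling.
    """
    if not all(np.isfinite(ref.lab_mean)) or not all(np.isfinite(ref.lab_std)):
        raise ValueError("reference stats must be finite")
    arr = _to_space(image, ref.space)
    src_mean = arr.reshape(-1, 3).mean(axis=0)
    src_std = arr.reshape(-1, 3).std(axis=0)
    scale = np.where(src_std < EPS, 1.0, np.asarray(ref.lab_std) / np.maximum(src_std, EPS))
    out = (arr - src_mean) * scale + np.asarray(ref.lab_mean)
    return _from_space(out, ref.space)


def normalize_batch(images: list[np.ndarray], ref: StainStats) -> list[np.ndarray]:
    """Apply the same reference transfer to a batch of images."""
    return [reinhard_transfer(img, ref) for img in images]
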