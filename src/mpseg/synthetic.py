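"""Synthetic H&E-like slides with paired ground-truth masks.

Real bladder sections show muscularis propria (MP) as thick, coherently
oriented smooth-muscle bundles, against non-MP tissue whose muscularis
mucosae fascicles are thin, wispy and wavy on a paler eosin background.
The generator emulates exactly the features the pipeline depends on:

* two visually distinct procedural fiber textures — coarse oriented
  striping (bundles) inside the MP region, fine high-frequency wavy
  striping (fascicles) outside it;
* H&E-like color statistics, with a per-slide Lab stain shift simulating
  inter-slide staining variability (what Reinhard normalization removes);
* a pixel-aligned binary mask whose MP area fraction is controlled.

It does not attempt photorealism: no nuclei, glands or tissue tears. A
green end-to-end test on these slides establishes that the pipeline's
mechanics work, not clinical-grade accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import lab2rgb, rgb2lab
from skimage.transform import resize

from .slide_io import MP, SlidePair, write_manifest, write_mask
import imageio.v3 as iio

#: unit-test canvas (divisible by 240), and the full-scale canonical canvas
UNIT_SHAPE = (480, 720)
FULL_SHAPE = (1440, 1920)
#: native (pre-resize) TUR sizes per preset, emulating the larger biopsy scans
UNIT_TUR_SHAPE = (640, 960)
FULL_TUR_SHAPE = (1920, 2448)

# eosin-like base colors (RGB): MP muscle stains a deeper pink than the
# paler non-MP stroma/fascicle background; both sit far enough inside the
# sRGB gamut that Lab stain shifts up to ~+-10 survive the round trip
_MP_BASE = np.array([180.0, 120.0, 155.0])
_NONMP_BASE = np.array([210.0, 165.0, 190.0])


@dataclass(frozen=True)
class SyntheticSlideSpec:
    height: int = UNIT_SHAPE[0]
    width: int = UNIT_SHAPE[1]
    mp_fraction: float = 0.45
    bundle_wavelength: float = 48.0
    fascicle_wavelength: float = 9.0
    orientation_noise: float = 0.35
    stain_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mp_fraction <= 1.0:
            raise ValueError("mp_fraction must lie in [0, 1]")


def generate_mask(spec: SyntheticSlideSpec) -> np.ndarray:
    """Smooth blob-union MP region hitting the requested area fraction.

    A Gaussian random field is thresholded at the (1 - mp_fraction)
    quantile, so the realized fraction matches the request to within pixel
    quantization. Deterministic given the spec seed.
    """
    if spec.mp_fraction == 0.0:
        return np.zeros((spec.height, spec.width), dtype=np.uint8)
    if spec.mp_fraction == 1.0:
        return np.full((spec.height, spec.width), MP, dtype=np.uint8)
    rng = np.random.default_rng(spec.seed)
    # a coarse random field upsampled to full resolution keeps the blob
    # scale proportional to the canvas at any slide size
    scale = max(1, min(spec.height, spec.width) // 120)
    coarse_shape = (-(-spec.height // scale), -(-spec.width // scale))
    noise = rng.standard_normal(coarse_shape)
    blobs = gaussian_filter(noise, sigma=min(coarse_shape) / 4.0)
    blobs = resize(blobs, (spec.height, spec.width), order=1, anti_aliasing=False)
    cut = np.quantile(blobs, 1.0 - spec.mp_fraction)
    return np.where(blobs >= cut, MP, 0).astype(np.uint8)


def _stripe_field(
    shape: tuple[int, int],
    wavelength: float,
    wobble_scale: float,
    wobble_sigma: float,
    angle: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Oriented sinusoidal striping with band-limited waviness, in [0, 1]."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    u = rr * np.cos(angle) + cc * np.sin(angle)
    wobble = gaussian_filter(rng.standard_normal(shape), wobble_sigma)
    wobble = wobble / max(wobble.std(), 1e-9) * wobble_scale
    return 0.5 + 0.5 * np.sin(2.0 * np.pi * (u + wobble) / wavelength)


def render_slide(mask: np.ndarray, spec: SyntheticSlideSpec) -> np.ndarray:
    """Render the two-texture H&E-like image for a mask.

    MP pixels get coarse bundle striping over the deep-pink base; non-MP
    pixels get fine wavy fascicle striping over the pale base. The
    per-slide ``stain_shift`` is then added in Lab space.
    """
    if mask.shape != (spec.height, spec.width):
        raise ValueError("mask shape inconsistent with spec")
    rng = np.random.default_rng(spec.seed + 1)
    angle_mp = rng.uniform(0, np.pi)
    angle_non = rng.uniform(0, np.pi)
    bundles = _stripe_field(
        mask.shape, spec.bundle_wavelength, spec.orientation_noise * spec.bundle_wavelength,
        wobble_sigma=24.0, angle=angle_mp, rng=rng,
    )
    fascicles = _stripe_field(
        mask.shape, spec.fascicle_wavelength, 2.5 * spec.orientation_noise * spec.fascicle_wavelength,
        wobble_sigma=6.0, angle=angle_non, rng=rng,
    )
    grain = gaussian_filter(rng.standard_normal(mask.shape), 1.0) * 3.0

    img = np.empty((*mask.shape, 3))
    mp_sel = mask == MP
    # stripe contrast: +-28 / +-20 around the two bases
    img[mp_sel] = _MP_BASE + (bundles[mp_sel, None] - 0.5) * 56.0
    img[~mp_sel] = _NONMP_BASE + (fascicles[~mp_sel, None] - 0.5) * 40.0
    img += grain[..., None]

    if any(abs(s) > 0 for s in spec.stain_shift):
        lab = rgb2lab(np.clip(img, 0, 255) / 255.0)
        lab += np.asarray(spec.stain_shift)
        img = lab2rgb(lab) * 255.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_pair(spec: SyntheticSlideSpec, slide_id: str, cohort: str) -> SlidePair:
    mask = generate_mask(spec)
    return SlidePair(image=render_slide(mask, spec), mask=mask, slide_id=slide_id, cohort=cohort)


@dataclass(frozen=True)
class CohortVariability:
    """Per-slide parameter ranges emulating a heterogeneous slide archive."""

    mp_fraction: tuple[float, float] = (0.25, 0.65)
    stain_shift_l: tuple[float, float] = (-6.0, 6.0)
    stain_shift_ab: tuple[float, float] = (-5.0, 5.0)


def _draw_spec(
    rng: np.random.Generator,
    shape: tuple[int, int],
    var: CohortVariability,
) -> SyntheticSlideSpec:
    return SyntheticSlideSpec(
        height=shape[0],
        width=shape[1],
        mp_fraction=float(rng.uniform(*var.mp_fraction)),
        stain_shift=(
            float(rng.uniform(*var.stain_shift_l)),
            float(rng.uniform(*var.stain_shift_ab)),
            float(rng.uniform(*var.stain_shift_ab)),
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_rc: int,
    n_tur: int,
    out_dir: str | Path,
    seed: int = 0,
    preset: str = "unit",
    variability: CohortVariability = CohortVariability(),
) -> Path:
    """Write a synthetic RC + TUR cohort to disk and return the manifest path.

    RC slides are emitted at the preset's canonical size; TUR slides at the
    larger native size so the canonical-resize step is exercised, mirroring
    the real cohort where biopsy scans arrive bigger than the training
    geometry.
    """
    if preset == "unit":
        rc_shape, tur_shape = UNIT_SHAPE, UNIT_TUR_SHAPE
    elif preset == "full":
        rc_shape, tur_shape = FULL_SHAPE, FULL_TUR_SHAPE
    else:
        raise ValueError(f"unknown preset {preset!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, count, shape in (("RC", n_rc, rc_shape), ("TUR", n_tur, tur_shape)):
        for i in range(count):
            slide_id = f"{cohort.lower()}_{i:03d}"
            pair = generate_pair(_draw_spec(rng, shape, variability), slide_id, cohort)
            image_path = out_dir / f"{slide_id}.png"
            mask_path = out_dir / f"{slide_id}_mask.png"
            iio.imwrite(image_path, pair.image)
            write_mask(pair.mask, mask_path)
            rows.append(
                {
                    "slide_id": slide_id,
                    "image_path": image_path.name,
                    "mask_path": mask_path.name,
                    "cohort": cohort,
                }
            )
    return write_manifest(rows, out_dir / "manifest.csv")
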