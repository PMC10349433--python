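"""Patch datasets, stratified splitting, class weights, and the CV partition.

Two labeling modes correspond to the two modeling tracks:

* **patch mode** — only tiles that are purely MP or purely non-MP are kept,
  each carrying a single label; mixed tiles are discarded. Used to train
  whole-patch binary classifiers.
* **pixel mode** — every tile is kept together with its 240x240 mask patch,
  so the whole image is used. Used to train per-pixel segmenters.

Cross-validation follows the cohort design: the TUR slides are partitioned
into nine equal test folds, while every training split additionally contains
all RC slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .slide_io import MP, SlidePair

PATCH = 240

LABEL_MP = "MP"
LABEL_NONMP = "nonMP"


@dataclass
class PatchRecord:
    """One 240x240 training tile in either labeling mode."""

    pixels: np.ndarray
    origin: tuple[int, int]
    slide_id: str
    label: str | None = None
    mask_patch: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.label is None) == (self.mask_patch is None):
            raise ValueError("exactly one of label / mask_patch must be set")

    @property
    def stratum(self) -> str:
        """Stratification class: the label, or the tile's majority class."""
        if self.label is not None:
            return self.label
        frac = float(np.mean(self.mask_patch == MP))
        return LABEL_MP if frac >= 0.5 else LABEL_NONMP


@dataclass
class FoldSpec:
    fold_index: int
    test_ids: list[str]
    train_ids: list[str]


@dataclass(frozen=True)
class ClassWeights:
    w_MP: float
    w_nonMP: float

    def __post_init__(self) -> None:
        if self.w_MP <= 0 or self.w_nonMP <= 0:
            raise ValueError("class weights must be positive")

    def of(self, label: str) -> float:
        return self.w_MP if label == LABEL_MP else self.w_nonMP


def tile_grid(height: int, width: int, patch: int = PATCH) -> list[tuple[int, int]]:
    """Non-overlapping tile origins in row-major order.

    Both dimensions must be divisible by the patch size (guaranteed by the
    canonical resize).
    """
    if height % patch or width % patch:
        raise ValueError(f"dimensions {height}x{width} not divisible by patch {patch}")
    return [(r, c) for r in range(0, height, patch) for c in range(0, width, patch)]


def extract_pure_patches(pair: SlidePair, patch: int = PATCH) -> list[PatchRecord]:
    """Patch-mode extraction: keep only tiles that are entirely one class."""
    records = []
    for r, c in tile_grid(*pair.shape, patch):
        tile_mask = pair.mask[r : r + patch, c : c + patch]
        if np.all(tile_mask == MP):
            label = LABEL_MP
        elif np.all(tile_mask == 0):
            label = LABEL_NONMP
        else:
            continue  # mixed tile: unused in this mode
        records.append(
            PatchRecord(
                pixels=pair.image[r : r + patch, c : c + patch],
                origin=(r, c),
                slide_id=pair.slide_id,
                label=label,
            )
        )
    return records


def extract_pixel_patches(pair: SlidePair, patch: int = PATCH) -> list[PatchRecord]:
    """Pixel-mode extraction: every tile with its aligned mask patch."""
    return [
        PatchRecord(
            pixels=pair.image[r : r + patch, c : c + patch],
            origin=(r, c),
            slide_id=pair.slide_id,
            mask_patch=pair.mask[r : r + patch, c : c + patch],
        )
        for r, c in tile_grid(*pair.shape, patch)
    ]


def stratified_split(
    records: list[PatchRecord], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[PatchRecord], list[PatchRecord]]:
    """Split records into train/validation preserving per-stratum proportions.

    Deterministic given the seed; each stratum contributes
    ``round(train_frac * n)`` records to the training side.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    rng = np.random.default_rng(seed)
    train: list[PatchRecord] = []
    val: list[PatchRecord] = []
    strata = sorted({rec.stratum for rec in records})
    for stratum in strata:
        members = [rec for rec in records if rec.stratum == stratum]
        order = rng.permutation(len(members))
        n_train = int(round(train_frac * len(members)))
        for i, idx in enumerate(order):
            (train if i < n_train else val).append(members[idx])
    return train, val


def class_weights(records: list[PatchRecord], mode: str) -> ClassWeights:
    """Reciprocal-count class weights, normalized to sum to 2.

    In patch mode each patch counts once toward its label; in pixel mode
    every pixel of every mask patch counts toward its class. Only the weight
    ratio matters for the loss; the sum-to-2 normalization keeps balanced
    data at weight 1 per class.
    """
    if mode == "patch":
        n_mp = sum(1 for r in records if r.label == LABEL_MP)
        n_non = sum(1 for r in records if r.label == LABEL_NONMP)
    elif mode == "pixel":
        n_mp = int(sum(np.count_nonzero(r.mask_patch == MP) for r in records))
        n_non = int(sum(np.count_nonzero(r.mask_patch == 0) for r in records))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n_mp == 0 or n_non == 0:
        raise ValueError("both classes must be present to define reciprocal weights")
    raw = np.array([1.0 / n_mp, 1.0 / n_non])
    w = 2.0 * raw / raw.sum()
    return ClassWeights(w_MP=float(w[0]), w_nonMP=float(w[1]))


def make_cv_folds(tur_ids: list[str], rc_ids: list[str], seed: int = 0) -> list[FoldSpec]:
    """Ninefold CV over the TUR cohort.

    The TUR ids are shuffled with the seed and chunked into 9 equal disjoint
    test sets; each training split holds all RC ids plus the TUR ids outside
    its own test set. The TUR count must be divisible by 9 (63 at full
    scale; any multiple of 9 for desk-scale runs).
    """
    n_folds = 9
    if len(tur_ids) % n_folds:
        raise ValueError(f"TUR count {len(tur_ids)} not divisible by {n_folds}")
    rng = np.random.default_rng(seed)
    shuffled = [tur_ids[i] for i in rng.permutation(len(tur_ids))]
    per_fold = len(tur_ids) // n_folds
    folds = []
    for k in range(n_folds):
        test = shuffled[k * per_fold : (k + 1) * per_fold]
        train = list(rc_ids) + [t for t in shuffled if t not in test]
        folds.append(FoldSpec(fold_index=k + 1, test_ids=test, train_ids=train))
    return folds


def apply_exclusions(ids: list[str], *excluded: list[str]) -> list[str]:
    """Filter a collected slide list by one or more exclusion lists.

    Mirrors cohort curation where slides are dropped for stated reasons
    (e.g. mixed MM/MP content precluding patch extraction, or morphology
    too ambiguous to annotate). Order is preserved; exclusion lists may
    overlap the ids but not each other.
    """
    drop = set()
    for lst in excluded:
        if drop & set(lst):
            raise ValueError("exclusion lists overlap")
        drop |= set(lst)
    return [i for i in ids if i not in drop]
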