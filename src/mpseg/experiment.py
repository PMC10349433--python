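"""End-to-end experiment orchestration: train -> infer -> threshold ->
evaluate across CV folds, with reproducible seeding and persisted
intermediates (checkpoints, heatmaps, masks, metric tables).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, inference, model_backends, patch_dataset, slide_io, stain_norm, thresholding

logger = logging.getLogger(__name__)

APPROACH_MODES = {"patch": ("patch",), "pixel": ("tiled", "whole")}

#: seven headline metrics reported per model, in display order
COMPARISON_METRICS = [
    "mean_jaccard",
    "mean_dice",
    "pixel_accuracy",
    "precision",
    "recall",
    "specificity",
    "f1",
]


@dataclass
class ExperimentConfig:
    manifest: str
    out_dir: str
    approach: str = "pixel"
    backend_id: str = "tiny_unet"
    inference_mode: str = "whole"
    threshold_mode: str = "youden"
    fixed_t: float = 0.5
    seed: int = 0
    epochs: int | None = None
    n_folds: int | None = None  # run only the first k folds (desk scale)
    stride: int = inference.STRIDE
    smooth_kernel: int = inference.SMOOTH_KERNEL
    median_kernel: int = thresholding.MEDIAN_KERNEL
    mean_kernel: int = thresholding.MEAN_KERNEL
    reference_slide: str | None = None  # default: first RC slide, logged
    reference_stats: list[float] | None = None  # [L, a, b, sL, sa, sb]
    canonical_shape: tuple[int, int] | None = None  # default: first RC shape

    def __post_init__(self) -> None:
        if self.approach not in APPROACH_MODES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.inference_mode not in APPROACH_MODES[self.approach]:
            raise ValueError(
                f"inference mode {self.inference_mode!r} is incompatible with the "
                f"{self.approach!r} approach (allowed: {APPROACH_MODES[self.approach]})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("canonical_shape") is not None:
            data["canonical_shape"] = tuple(data["canonical_shape"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data["canonical_shape"] is not None:
            data["canonical_shape"] = list(data["canonical_shape"])
        Path(path).write_text(yaml.safe_dump(data))


def _stage_seed(seed: int, fold: int, stage: int) -> int:
    return (seed * 9973 + fold * 97 + stage) % (2**31 - 1)


def _hyperparameters(config: ExperimentConfig) -> model_backends.Hyperparameters:
    base = model_backends.PATCH_HP if config.approach == "patch" else model_backends.PIXEL_HP
    if config.epochs is not None:
        base = dataclasses.replace(base, epochs=config.epochs)
    return base


def prepare_slides(config: ExperimentConfig) -> list[slide_io.SlidePair]:
    """Load, canonically resize, and stain-normalize every manifest slide."""
    manifest = slide_io.read_manifest(config.manifest)
    pairs = slide_io.load_pairs(manifest, root=Path(config.manifest).parent)
    rc = [p for p in pairs if p.cohort == "RC"]
    if config.canonical_shape is not None:
        target = tuple(config.canonical_shape)
    elif rc:
        target = rc[0].shape
    else:
        target = slide_io.CANONICAL_SHAPE
    pairs = [slide_io.canonical_resize(p, target) for p in pairs]

    if config.reference_stats is not None:
        v = config.reference_stats
        ref = stain_norm.StainStats(tuple(v[:3]), tuple(v[3:]))
    else:
        ref_id = config.reference_slide
        if ref_id is None:
            ref_id = next(p.slide_id for p in pairs if p.cohort == "RC")
            logger.info("stain reference defaulted to first RC slide %s", ref_id)
        ref_pair = next(p for p in pairs if p.slide_id == ref_id)
        ref = stain_norm.compute_stain_stats(ref_pair.image)
    return [
        dataclasses.replace(p, image=stain_norm.reinhard_transfer(p.image, ref)) for p in pairs
    ]


def _train_for_fold(
    config: ExperimentConfig,
    train_pairs: list[slide_io.SlidePair],
    fold_index: int,
):
    if config.approach == "patch":
        records = [r for p in train_pairs for r in patch_dataset.extract_pure_patches(p)]
        mode = "patch"
    else:
        records = [r for p in train_pairs for r in patch_dataset.extract_pixel_patches(p)]
        mode = "pixel"
    train, val = patch_dataset.stratified_split(
        records, seed=_stage_seed(config.seed, fold_index, 1)
    )
    weights = patch_dataset.class_weights(train, mode=mode)
    hp = _hyperparameters(config)
    train_seed = _stage_seed(config.seed, fold_index, 2)
    if config.approach == "patch":
        backend = model_backends.train_patch_classifier(
            train, val, hp, weights, config.backend_id, train_seed
        )
    else:
        backend = model_backends.train_segmenter(
            train, val, hp, weights, config.backend_id, train_seed
        )
    return backend, hp, weights, train_seed


def _infer(config: ExperimentConfig, backend, image: np.ndarray) -> np.ndarray:
    if config.inference_mode == "patch":
        grid = inference.sliding_positions(*image.shape[:2], stride=config.stride)
        return inference.patch_heatmap_inference(
            backend, image, grid, smooth_kernel=config.smooth_kernel
        )
    if config.inference_mode == "tiled":
        return inference.tiled_segmentation_inference(backend, image)
    return inference.whole_image_inference(backend, image)


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the configured CV experiment and return the results directory.

    Writes per-fold checkpoints, per-image heatmaps (float32 TIFF), final
    masks, a per-image metrics table, and a fold-level summary with mean
    and std rows. Every artifact is reproducible from the config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    pairs = prepare_slides(config)
    by_id = {p.slide_id: p for p in pairs}
    tur_ids = [p.slide_id for p in pairs if p.cohort == "TUR"]
    rc_ids = [p.slide_id for p in pairs if p.cohort == "RC"]
    folds = patch_dataset.make_cv_folds(tur_ids, rc_ids, seed=_stage_seed(config.seed, 0, 0))
    if config.n_folds is not None:
        folds = folds[: config.n_folds]

    image_rows: list[dict] = []
    fold_reports: list[dict[str, float]] = []
    for fold in folds:
        logger.info("fold %d: training on %d slides", fold.fold_index, len(fold.train_ids))
        backend, hp, weights, train_seed = _train_for_fold(
            config, [by_id[i] for i in fold.train_ids], fold.fold_index
        )
        model_backends.save_checkpoint(
            backend,
            out / f"fold{fold.fold_index}" / "checkpoint",
            hp,
            weights,
            train_seed,
        )
        reports = []
        for slide_id in fold.test_ids:
            pair = by_id[slide_id]
            heatmap = _infer(config, backend, pair.image)
            inference.save_heatmap(heatmap, out / f"fold{fold.fold_index}" / f"{slide_id}.tif")
            mask, _ = thresholding.heatmap_to_mask(
                heatmap,
                reference=pair.mask,
                mode=config.threshold_mode,
                fixed_t=config.fixed_t,
                median_kernel=config.median_kernel,
                mean_kernel=config.mean_kernel,
            )
            slide_io.write_mask(mask, out / f"fold{fold.fold_index}" / f"{slide_id}_pred.png")
            report = evaluation.evaluate_mask(mask, pair.mask)
            reports.append(report)
            image_rows.append(
                {
                    "fold": fold.fold_index,
                    "slide_id": slide_id,
                    "approach": config.approach,
                    "backend": config.backend_id,
                    "inference_mode": config.inference_mode,
                    "threshold_mode": config.threshold_mode,
                    **report,
                }
            )
        fold_reports.append(evaluation.mean_report(reports))

    pd.DataFrame(image_rows).to_csv(out / "per_image_metrics.csv", index=False)
    evaluation.aggregate_folds(fold_reports).to_csv(out / "summary.csv", index=False)
    return out


def load_summary(result_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(result_dir) / "summary.csv")


def compare_groups(result_dirs: list[str | Path], out_path: str | Path | None = None) -> pd.DataFrame:
    """Cross-experiment comparison table: one row per model plus group means.

    Experiments must share a fold structure (same number of folds). The
    approach of each experiment is read from its persisted config.
    """
    if len(result_dirs) < 2:
        raise ValueError("need at least two result sets to compare")
    rows = []
    n_folds = None
    for d in result_dirs:
        d = Path(d)
        cfg = yaml.safe_load((d / "config.yaml").read_text())
        summary = load_summary(d)
        fold_rows = summary[~summary["fold"].isin(["mean", "std"])]
        if n_folds is None:
            n_folds = len(fold_rows)
        elif len(fold_rows) != n_folds:
            raise ValueError("result sets have mismatched fold structure")
        mean = summary[summary["fold"] == "mean"].iloc[0]
        rows.append(
            {
                "model": f"{cfg['backend_id']} ({cfg['inference_mode']})",
                "approach": cfg["approach"],
                **{m: float(mean[m]) for m in COMPARISON_METRICS},
            }
        )
    table = pd.DataFrame(rows)
    for approach in sorted(table["approach"].unique()):
        members = table[table["approach"] == approach]
        rows.append(
            {
                "model": f"group mean ({approach})",
                "approach": approach,
                **{m: float(members[m].mean()) for m in COMPARISON_METRICS},
            }
        )
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table


def plot_comparison(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Seven-panel bar chart of the comparison table (one panel per metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = table[~table["model"].str.startswith("group mean")]
    groups = table[table["model"].str.startswith("group mean")]
    colors = {"patch": "tab:blue", "pixel": "tab:orange"}
    fig, axes = plt.subplots(1, len(COMPARISON_METRICS), figsize=(3 * len(COMPARISON_METRICS), 4))
    for ax, metric in zip(axes, COMPARISON_METRICS):
        ax.bar(
            range(len(models)),
            models[metric],
            color=[colors.get(a, "gray") for a in models["approach"]],
        )
        for _, g in groups.iterrows():
            ax.axhline(g[metric], color="black", linestyle="--", linewidth=1)
        ax.set_title(metric)
        ax.set_xticks(range(len(models)))
        ax.set_xticklabels(models["model"], rotation=90, fontsize=7)
        ax.set_ylim(0, 1.05)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
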