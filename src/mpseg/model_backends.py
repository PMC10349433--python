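"""Trainable backends for patch classification and pixel segmentation.

The training contract is shared by both tracks and mirrors the experimental
design of the study this package supports:

* class-weighted cross-entropy loss (weights are reciprocal class counts,
  see :func:`mpseg.patch_dataset.class_weights`);
* weighted random subsampling **with replacement** each epoch, so batches
  see the two classes in balanced proportion despite dataset imbalance;
* SGD (patch track, lr 0.001) or Adam (pixel track, lr 0.0001,
  betas 0.9/0.999) with a static learning rate;
* model selection by minimum validation loss across epochs;
* full determinism given a seed.

Backends are registered by string id. The CPU-native reference backends are
``tiny_cnn`` (a logistic head over filter-bank patch statistics) and
``tiny_unet`` (a per-pixel logistic head over a filter-bank feature stack).
The eight named ImageNet architectures (vgg16, resnet18, squeezenet,
mobilenet_v2, unet, manet, deeplabv3plus, fpn) are registered but require
PyTorch, which this distribution does not depend on; constructing them
raises :class:`BackendUnavailableError` unless torch is importable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .patch_dataset import LABEL_MP, ClassWeights, PatchRecord, class_weights
from .slide_io import MP


class BackendUnavailableError(RuntimeError):
    """Raised when a registered backend's runtime dependency is missing."""


@dataclass(frozen=True)
class Hyperparameters:
    batch_size: int
    epochs: int
    optimizer: str
    learning_rate: float
    adam_betas: tuple[float, float] = (0.9, 0.999)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


#: defaults for the patch-classification track
PATCH_HP = Hyperparameters(batch_size=32, epochs=30, optimizer="sgd", learning_rate=0.001)
#: defaults for the pixel-segmentation track
PIXEL_HP = Hyperparameters(batch_size=4, epochs=30, optimizer="adam", learning_rate=0.0001)


# ---------------------------------------------------------------------------
# filter-bank features

def pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack (H x W x 8, float32).

    Channels: normalized R, G, B; Gaussian-smoothed luminance; local
    standard deviation of luminance at two scales; band-limited texture
    energy at high and mid spatial frequency. The two energy channels are
    what separates coarse muscle-bundle striping from fine wispy fascicles.
    """
    rgb = np.asarray(image, dtype=np.float32) / 255.0
    gray = rgb @ np.array([0.299, 0.587, 0.114], dtype=np.float32)

    def local_std(sig: float) -> np.ndarray:
        mu = gaussian_filter(gray, sig)
        var = gaussian_filter(gray * gray, sig) - mu * mu
        return np.sqrt(np.maximum(var, 0.0))

    hi = gray - gaussian_filter(gray, 1.0)
    mid = gray - gaussian_filter(gray, 4.0)
    feats = [
        rgb[..., 0],
        rgb[..., 1],
        rgb[..., 2],
        gaussian_filter(gray, 3.0),
        local_std(1.5),
        local_std(6.0),
        np.sqrt(gaussian_filter(hi * hi, 4.0)),
        np.sqrt(gaussian_filter(mid * mid, 4.0)),
    ]
    return np.stack(feats, axis=-1).astype(np.float32)


N_PIXEL_FEATURES = 8


def patch_features(patch: np.ndarray) -> np.ndarray:
    """Summary vector for a whole patch: mean and std of each pixel feature."""
    f = pixel_features(patch).reshape(-1, N_PIXEL_FEATURES)
    return np.concatenate([f.mean(axis=0), f.std(axis=0)])


# ---------------------------------------------------------------------------
# optimizer

class _Optimizer:
    """Static-learning-rate SGD / Adam on a flat parameter vector."""

    def __init__(self, hp: Hyperparameters, n_params: int) -> None:
        self.hp = hp
        self.t = 0
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.hp.optimizer == "sgd":
            return params - self.hp.learning_rate * grad
        b1, b2 = self.hp.adam_betas
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * grad
        self.v = b2 * self.v + (1 - b2) * grad * grad
        m_hat = self.m / (1 - b1**self.t)
        v_hat = self.v / (1 - b2**self.t)
        return params - self.hp.learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _weighted_ce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.mean(w * -(y * np.log(p) + (1 - y) * np.log(1 - p))))


# ---------------------------------------------------------------------------
# backends

class TinyPatchClassifier:
    """Logistic classifier over filter-bank patch statistics.

    Satisfies the ``ClassifierBackend`` contract: ``predict_proba`` maps a
    240x240x3 patch to P(MP) in [0, 1]. Also exposes a fast sliding-window
    path (``predict_proba_grid``) that evaluates every window of an image
    via integral images of the shared pixel-feature stack.
    """

    backend_id = "tiny_cnn"
    kind = "classifier"

    def __init__(self) -> None:
        n = 2 * N_PIXEL_FEATURES
        self.w = np.zeros(n)
        self.b = 0.0
        self.feat_mean = np.zeros(n)
        self.feat_std = np.ones(n)
        self.history: dict = {}

    # -- inference ---------------------------------------------------------
    def _decision(self, X: np.ndarray) -> np.ndarray:
        Xn = (X - self.feat_mean) / self.feat_std
        return Xn @ self.w + self.b

    def predict_proba(self, patch: np.ndarray) -> float:
        return float(_sigmoid(self._decision(patch_features(patch)[None, :]))[0])

    def predict_proba_grid(
        self, image: np.ndarray, origins: list[tuple[int, int]], patch: int
    ) -> np.ndarray:
        """P(MP) for every window origin, via integral-image patch moments."""
        feats = pixel_features(image).astype(np.float64)
        area = float(patch * patch)
        # summed-area tables with a zero row/col prepended
        s1 = np.pad(feats, ((1, 0), (1, 0), (0, 0))).cumsum(axis=0).cumsum(axis=1)
        s2 = np.pad(feats * feats, ((1, 0), (1, 0), (0, 0))).cumsum(axis=0).cumsum(axis=1)
        rows = np.array([o[0] for o in origins])
        cols = np.array([o[1] for o in origins])

        def box(tab: np.ndarray) -> np.ndarray:
            return (
                tab[rows + patch, cols + patch]
                - tab[rows, cols + patch]
                - tab[rows + patch, cols]
                + tab[rows, cols]
            )

        mean = box(s1) / area
        var = np.maximum(box(s2) / area - mean * mean, 0.0)
        X = np.concatenate([mean, np.sqrt(var)], axis=1)
        return _sigmoid(self._decision(X))

    # -- training ----------------------------------------------------------
    def fit(
        self,
        train: list[PatchRecord],
        val: list[PatchRecord],
        hp: Hyperparameters,
        weights: ClassWeights,
        seed: int,
    ) -> "TinyPatchClassifier":
        rng = np.random.default_rng(seed)
        X = np.stack([patch_features(r.pixels) for r in train])
        y = np.array([1.0 if r.label == LABEL_MP else 0.0 for r in train])
        Xv = np.stack([patch_features(r.pixels) for r in val]) if val else X
        yv = (
            np.array([1.0 if r.label == LABEL_MP else 0.0 for r in val]) if val else y
        )
        self.feat_mean = X.mean(axis=0)
        self.feat_std = np.maximum(X.std(axis=0), 1e-8)

        sample_w = np.where(y == 1.0, weights.w_MP, weights.w_nonMP)
        sample_p = sample_w / sample_w.sum()
        wv = np.where(yv == 1.0, weights.w_MP, weights.w_nonMP)

        params = np.zeros(self.w.size + 1)
        opt = _Optimizer(hp, params.size)
        best_val, best_params = np.inf, params.copy()
        hist: dict = {"train_loss": [], "val_loss": [], "sampled_mp_frac": []}
        for _ in range(hp.epochs):
            drawn = rng.choice(len(train), size=len(train), replace=True, p=sample_p)
            hist["sampled_mp_frac"].append(float(np.mean(y[drawn])))
            epoch_losses = []
            for start in range(0, len(drawn), hp.batch_size):
                idx = drawn[start : start + hp.batch_size]
                Xb = (X[idx] - self.feat_mean) / self.feat_std
                yb, wb = y[idx], sample_w[idx]
                p = _sigmoid(Xb @ params[:-1] + params[-1])
                epoch_losses.append(_weighted_ce(p, yb, wb))
                err = wb * (p - yb) / len(idx)
                grad = np.concatenate([Xb.T @ err, [err.sum()]])
                params = opt.step(params, grad)
            self.w, self.b = params[:-1], params[-1]
            pv = _sigmoid(self._decision(Xv))
            vloss = _weighted_ce(pv, yv, wv)
            hist["train_loss"].append(float(np.mean(epoch_losses)))
            hist["val_loss"].append(vloss)
            if vloss < best_val:
                best_val, best_params = vloss, params.copy()
        self.w, self.b = best_params[:-1], best_params[-1]
        self.history = hist
        return self

    # -- persistence -------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        return {
            "w": self.w,
            "b": np.array([self.b]),
            "feat_mean": self.feat_mean,
            "feat_std": self.feat_std,
        }

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.w = state["w"]
        self.b = float(state["b"][0])
        self.feat_mean = state["feat_mean"]
        self.feat_std = state["feat_std"]


class TinySegmenter:
    """Per-pixel logistic head over the filter-bank feature stack.

    Satisfies the ``SegmenterBackend`` contract: ``predict_proba_map`` maps
    an H x W x 3 image to an H x W map of P(MP). Accepts any spatial size
    (``size_multiple = 1``).
    """

    backend_id = "tiny_unet"
    kind = "segmenter"
    size_multiple = 1

    #: pixels subsampled per patch for each gradient step
    PIXELS_PER_PATCH = 2048

    def __init__(self) -> None:
        self.w = np.zeros(N_PIXEL_FEATURES)
        self.b = 0.0
        self.feat_mean = np.zeros(N_PIXEL_FEATURES)
        self.feat_std = np.ones(N_PIXEL_FEATURES)
        self.history: dict = {}

    # -- inference ---------------------------------------------------------
    def predict_proba_map(self, image: np.ndarray) -> np.ndarray:
        f = pixel_features(image)
        fn = (f - self.feat_mean) / self.feat_std
        return _sigmoid(fn @ self.w + self.b)

    # -- training ----------------------------------------------------------
    def fit(
        self,
        train: list[PatchRecord],
        val: list[PatchRecord],
        hp: Hyperparameters,
        weights: ClassWeights,
        seed: int,
    ) -> "TinySegmenter":
        rng = np.random.default_rng(seed)
        feats = [pixel_features(r.pixels).reshape(-1, N_PIXEL_FEATURES) for r in train]
        labels = [(r.mask_patch.reshape(-1) == MP).astype(np.float64) for r in train]
        allf = np.concatenate(feats)
        self.feat_mean = allf.mean(axis=0)
        self.feat_std = np.maximum(allf.std(axis=0), 1e-8)
        feats = [(f - self.feat_mean) / self.feat_std for f in feats]

        vsrc = val if val else train
        vstep = 16  # deterministic pixel subsample for validation loss
        vf = np.concatenate(
            [
                ((pixel_features(r.pixels).reshape(-1, N_PIXEL_FEATURES) - self.feat_mean)
                 / self.feat_std)[::vstep]
                for r in vsrc
            ]
        )
        vy = np.concatenate([(r.mask_patch.reshape(-1) == MP)[::vstep] for r in vsrc])
        vy = vy.astype(np.float64)
        vw = np.where(vy == 1.0, weights.w_MP, weights.w_nonMP)

        # per-patch sampling weight: mean pixel class weight of the tile
        mp_frac = np.array([lab.mean() for lab in labels])
        patch_w = mp_frac * weights.w_MP + (1 - mp_frac) * weights.w_nonMP
        patch_p = patch_w / patch_w.sum()

        params = np.zeros(N_PIXEL_FEATURES + 1)
        opt = _Optimizer(hp, params.size)
        best_val, best_params = np.inf, params.copy()
        hist: dict = {"train_loss": [], "val_loss": [], "sampled_mp_frac": []}
        for _ in range(hp.epochs):
            drawn = rng.choice(len(train), size=len(train), replace=True, p=patch_p)
            epoch_losses, epoch_mp = [], []
            for start in range(0, len(drawn), hp.batch_size):
                idx = drawn[start : start + hp.batch_size]
                Xb_parts, yb_parts = [], []
                for i in idx:
                    sel = rng.integers(0, feats[i].shape[0], size=self.PIXELS_PER_PATCH)
                    Xb_parts.append(feats[i][sel])
                    yb_parts.append(labels[i][sel])
                Xb = np.concatenate(Xb_parts)
                yb = np.concatenate(yb_parts)
                wb = np.where(yb == 1.0, weights.w_MP, weights.w_nonMP)
                p = _sigmoid(Xb @ params[:-1] + params[-1])
                epoch_losses.append(_weighted_ce(p, yb, wb))
                epoch_mp.append(float(yb.mean()))
                err = wb * (p - yb) / len(yb)
                grad = np.concatenate([Xb.T @ err, [err.sum()]])
                params = opt.step(params, grad)
            pv = _sigmoid(vf @ params[:-1] + params[-1])
            vloss = _weighted_ce(pv, vy, vw)
            hist["train_loss"].append(float(np.mean(epoch_losses)))
            hist["val_loss"].append(vloss)
            hist["sampled_mp_frac"].append(float(np.mean(epoch_mp)))
            if vloss < best_val:
                best_val, best_params = vloss, params.copy()
        self.w, self.b = best_params[:-1], best_params[-1]
        self.history = hist
        return self

    # -- persistence -------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        return {
            "w": self.w,
            "b": np.array([self.b]),
            "feat_mean": self.feat_mean,
            "feat_std": self.feat_std,
        }

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.w = state["w"]
        self.b = float(state["b"][0])
        self.feat_mean = state["feat_mean"]
        self.feat_std = state["feat_std"]


class ConstantClassifier:
    """Test helper: predicts a fixed probability for any patch."""

    kind = "classifier"

    def __init__(self, p: float) -> None:
        self.p = float(p)

    def predict_proba(self, patch: np.ndarray) -> float:
        return self.p


class ConstantSegmenter:
    """Test helper: predicts a fixed probability at every pixel."""

    kind = "segmenter"
    size_multiple = 1

    def __init__(self, p: float) -> None:
        self.p = float(p)

    def predict_proba_map(self, image: np.ndarray) -> np.ndarray:
        return np.full(image.shape[:2], self.p)


# ---------------------------------------------------------------------------
# registry

def _torch_factory(name: str, kind: str):
    def make() -> None:
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                f"backend {name!r} requires PyTorch, which is not installed; "
                "use 'tiny_cnn' / 'tiny_unet' for CPU-native runs"
            ) from exc
        raise BackendUnavailableError(
            f"backend {name!r} is registered as a {kind} id but no torch "
            "implementation ships with this package"
        )

    return make


BACKENDS: dict[str, object] = {
    "tiny_cnn": TinyPatchClassifier,
    "tiny_unet": TinySegmenter,
    # named deep architectures: ids reserved, torch required
    **{
        name: _torch_factory(name, "classifier")
        for name in ("vgg16", "resnet18", "squeezenet", "mobilenet_v2")
    },
    **{
        name: _torch_factory(name, "segmenter")
        for name in ("unet", "manet", "deeplabv3plus", "fpn")
    },
}


def make_backend(backend_id: str):
    if backend_id not in BACKENDS:
        raise KeyError(f"unknown backend id {backend_id!r}; known: {sorted(BACKENDS)}")
    return BACKENDS[backend_id]()


def train_patch_classifier(
    train: list[PatchRecord],
    val: list[PatchRecord],
    hp: Hyperparameters | None = None,
    weights: ClassWeights | None = None,
    backend_id: str = "tiny_cnn",
    seed: int = 0,
) -> TinyPatchClassifier:
    """Train a patch classifier under the weighted-CE / weighted-sampling contract."""
    if not train:
        raise ValueError("empty training set")
    hp = hp or PATCH_HP
    weights = weights or class_weights(train, mode="patch")
    backend = make_backend(backend_id)
    return backend.fit(train, val, hp, weights, seed)


def train_segmenter(
    train: list[PatchRecord],
    val: list[PatchRecord],
    hp: Hyperparameters | None = None,
    weights: ClassWeights | None = None,
    backend_id: str = "tiny_unet",
    seed: int = 0,
) -> TinySegmenter:
    """Train a pixel segmenter under the weighted-CE / weighted-sampling contract."""
    if not train:
        raise ValueError("empty training set")
    hp = hp or PIXEL_HP
    weights = weights or class_weights(train, mode="pixel")
    backend = make_backend(backend_id)
    return backend.fit(train, val, hp, weights, seed)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(
    backend, path: str | Path, hp: Hyperparameters, weights: ClassWeights, seed: int,
    manifest_hash: str = "",
) -> Path:
    """Persist a trained backend as .npz plus a JSON sidecar of its context."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **backend.state())
    sidecar = {
        "backend_id": backend.backend_id,
        "kind": backend.kind,
        "hyperparameters": {
            "batch_size": hp.batch_size,
            "epochs": hp.epochs,
            "optimizer": hp.optimizer,
            "learning_rate": hp.learning_rate,
            "adam_betas": list(hp.adam_betas),
        },
        "class_weights": {"w_MP": weights.w_MP, "w_nonMP": weights.w_nonMP},
        "seed": seed,
        "manifest_hash": manifest_hash,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    backend = make_backend(sidecar["backend_id"])
    with np.load(path.with_suffix(".npz")) as data:
        backend.load_state({k: data[k] for k in data.files})
    return backend
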