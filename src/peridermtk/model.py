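"""Trainable per-pixel tissue segmenter over slide patches.

The segmenter couples a multiscale convolutional feature bank (Gaussian
intensity pyramids and smoothed gradient-energy maps of the fluorescence
channel, computed per pixel) with a small multilayer-perceptron classifier
trained with the Adam optimizer. Periderm shows a dense net of bright cell
walls (high fine-scale edge energy), endodermis a sparse pattern of long
rectangular cells, and background is dark — these statistics separate the
four classes at the pixel level. Because every feature is an isotropic
filter response, the classifier is equivariant under flips and rotations of
the patch by construction.

Training follows the usual checkpointing contract: patches are split
60/20/20 into train/validation/test by a seeded shuffle, one optimizer pass
runs per epoch, the composite loss (cross-entropy + soft Dice) and the
validation IoU are recorded every epoch, and the epoch with the highest
validation IoU is kept as the trained model.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import joblib
import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

from .io_formats import CLASS_MAP, LabelMask, RasterImage
from .tiling import TilingConfig, stitch_masks, tile_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the pixel segmenter.

    ``feature_sigmas`` are the scales (px) of the Gaussian feature bank;
    ``hidden_layer_sizes`` is the MLP head. ``n_classes`` must match the
    class map (4: background, periderm, endoderm, lateral root).
    """

    n_classes: int = 4
    feature_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    hidden_layer_sizes: tuple[int, ...] = (64,)

    def __post_init__(self) -> None:
        if self.n_classes != len(CLASS_MAP):
            raise ValueError(f"n_classes must equal {len(CLASS_MAP)}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, initial learning rate 1e-4, 40 epochs.

    ``batch_size`` is the pixel-sample minibatch of the Adam updates;
    ``samples_per_patch`` caps how many labeled pixels are drawn from each
    training patch (class-balanced to counter background dominance).
    """

    learning_rate: float = 0.0001
    epochs: int = 40
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    batch_size: int = 256
    seed: int = 0
    samples_per_patch: int = 4000
    val_sample_size: int = 50000

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.split_fractions) <= 0 or abs(sum(self.split_fractions) - 1) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


class CompositeLoss(NamedTuple):
    """Cross-entropy + soft-Dice loss with its two terms."""

    total: float
    cross_entropy: float
    dice: float


@dataclass
class TrainHistory:
    """Per-epoch loss/IoU records and the best-validation checkpoint."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    checkpoint_path: str | None = None

    def append(self, train_loss: float, val_loss: float, val_iou: float) -> None:
        self.records.append(
            {
                "epoch": len(self.records) + 1,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_iou": val_iou,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.records).to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# splitting, loss, IoU
# ---------------------------------------------------------------------------

def split_patches(
    patches: Sequence, fractions: tuple[float, float, float], seed: int
) -> tuple[list, list, list]:
    """Shuffle and split into train/val/test of sizes round(f*n).

    Sizes are (round(f1*n), round(f2*n), remainder); the shuffle is driven
    solely by the seed, so identical seeds give identical splits.
    """
    if min(fractions) <= 0 or abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n = len(patches)
    if n < 3:
        raise ValueError(f"need >= 3 patches to populate all splits, got {n}")
    n1 = round(fractions[0] * n)
    n2 = round(fractions[1] * n)
    if n1 < 1 or n2 < 1 or n - n1 - n2 < 1:
        raise ValueError("split would leave an empty subset")
    order = np.random.default_rng(seed).permutation(n)
    items = [patches[i] for i in order]
    return items[:n1], items[n1 : n1 + n2], items[n1 + n2 :]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def composite_loss(logits: np.ndarray, target: LabelMask | np.ndarray) -> CompositeLoss:
    """Per-pixel multiclass cross-entropy plus (1 - mean soft Dice).

    ``logits`` has shape (..., n_classes) of raw class scores; ``target``
    holds class codes of the same leading shape. The Dice term averages the
    soft Dice coefficient over the non-background classes occurring in
    either the prediction or the target (1:1 weighting of the two terms).
    """
    t = target.labels if isinstance(target, LabelMask) else np.asarray(target)
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape[:-1] != t.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {t.shape}")
    n_classes = logits.shape[-1]
    if t.min() < 0 or t.max() >= n_classes:
        raise ValueError(f"target classes must be in [0, {n_classes})")
    probs = _softmax(logits).reshape(-1, n_classes)
    flat_t = t.reshape(-1).astype(int)
    ce = float(-np.mean(np.log(np.clip(probs[np.arange(len(flat_t)), flat_t], 1e-12, None))))
    dices = []
    for c in range(1, n_classes):
        p_c = probs[:, c]
        t_c = (flat_t == c).astype(float)
        denom = p_c.sum() + t_c.sum()
        if denom < 1e-12:
            continue  # class absent from both: skipped
        dices.append(2.0 * float((p_c * t_c).sum()) / float(denom))
    dice_loss = float(1.0 - np.mean(dices)) if dices else 0.0
    return CompositeLoss(ce + dice_loss, ce, dice_loss)


def iou_score(pred: LabelMask | np.ndarray, target: LabelMask | np.ndarray) -> float:
    """Mean intersection-over-union across non-background classes.

    Classes absent from both masks are skipped; a class present in only one
    of them scores 0. Symmetric in its arguments; identical masks with at
    least one non-background pixel score 1.
    """
    p = (pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)).ravel()
    t = (target.labels if isinstance(target, LabelMask) else np.asarray(target)).ravel()
    if p.shape != t.shape:
        raise ValueError("masks must have equal shape")
    ious = []
    for c in range(1, len(CLASS_MAP)):
        pc, tc = p == c, t == c
        union = np.count_nonzero(pc | tc)
        if union == 0:
            continue
        ious.append(np.count_nonzero(pc & tc) / union)
    return float(np.mean(ious)) if ious else 0.0


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_features(patch: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Per-pixel feature stack (H, W, F) of multiscale filter responses."""
    arr = np.asarray(patch)
    if arr.ndim == 3:
        green = arr[..., 1].astype(np.float32) / 255.0
    else:
        green = arr.astype(np.float32) / 255.0
    gx = ndimage.sobel(green, axis=0, mode="reflect")
    gy = ndimage.sobel(green, axis=1, mode="reflect")
    grad = np.hypot(gx, gy)
    feats = [green]
    for sigma in config.feature_sigmas:
        feats.append(ndimage.gaussian_filter(green, sigma, mode="reflect"))
    for sigma in config.feature_sigmas:
        feats.append(ndimage.gaussian_filter(grad, sigma, mode="reflect"))
    return np.stack(feats, axis=-1).astype(np.float32)


# ---------------------------------------------------------------------------
# trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted pixel segmenter with its feature scaling and class map."""

    config: ModelConfig
    mlp: MLPClassifier
    feature_mean: np.ndarray
    feature_std: np.ndarray
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_MAP))

    def _predict_features(self, feats: np.ndarray, proba: bool = False) -> np.ndarray:
        flat = feats.reshape(-1, feats.shape[-1])
        flat = (flat - self.feature_mean) / self.feature_std
        if proba:
            out = self.mlp.predict_proba(flat)
            return out.reshape(feats.shape[:-1] + (out.shape[-1],))
        labels = self.mlp.predict(flat).astype(np.uint8)
        return labels.reshape(feats.shape[:-1])

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Per-pixel class codes for one patch."""
        return self._predict_features(extract_features(patch, self.config))

    def predict_patch_proba(self, patch: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (H, W, n_classes) for one patch."""
        return self._predict_features(extract_features(patch, self.config), proba=True)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {
                "config": self.config,
                "mlp": self.mlp,
                "feature_mean": self.feature_mean,
                "feature_std": self.feature_std,
                "class_map": self.class_map,
            },
            path,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        return cls(**payload)


def _sample_pixels(
    feats: np.ndarray,
    mask: np.ndarray,
    per_patch: int,
    rng: np.random.Generator,
    balanced: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labeled pixels from one patch, class-balanced when training."""
    flat_f = feats.reshape(-1, feats.shape[-1])
    flat_m = mask.reshape(-1)
    if balanced:
        # fixed per-class quota (not per classes present), so patches that
        # are pure background contribute only one quota of easy pixels
        per_class = max(1, per_patch // len(CLASS_MAP))
        chosen = []
        for c in np.unique(flat_m):
            idx = np.flatnonzero(flat_m == c)
            take = min(per_class, idx.size)
            chosen.append(rng.choice(idx, size=take, replace=False))
        sel = np.concatenate(chosen)
    else:
        sel = rng.choice(flat_m.size, size=min(per_patch, flat_m.size), replace=False)
    return flat_f[sel], flat_m[sel]


def _rebalance(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, max_ratio: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cap over-represented classes at max_ratio x the median class count.

    Whole-slide data is dominated by background; without a cap the
    classifier buys accuracy by under-calling the tissue classes.
    """
    counts = np.bincount(y, minlength=len(CLASS_MAP))
    nonzero = counts[counts > 0]
    cap = int(max_ratio * np.median(nonzero))
    keep = []
    for c in np.flatnonzero(counts):
        idx = np.flatnonzero(y == c)
        if idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    sel = np.concatenate(keep)
    rng.shuffle(sel)
    return X[sel], y[sel]


def train(
    patches: Sequence[np.ndarray],
    masks: Sequence[np.ndarray | LabelMask],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    checkpoint_path: str | Path | None = None,
) -> tuple[TrainedModel, TrainHistory]:
    """Fit the segmenter on labeled patches.

    Patches are split train/val/test by the seeded shuffle; every epoch is
    one Adam pass over the class-balanced training pixel sample, after which
    the composite loss and validation IoU are recorded. The weights of the
    epoch with the highest validation IoU are kept (and written to
    ``checkpoint_path`` when given). A NaN loss aborts with the epoch index.
    """
    model_config = model_config or ModelConfig()
    cfg = train_config or TrainConfig()
    if len(patches) != len(masks):
        raise ValueError("patches and masks must pair up")
    mask_arrays = [m.labels if isinstance(m, LabelMask) else np.asarray(m) for m in masks]
    for p, m in zip(patches, mask_arrays):
        if p.shape[:2] != m.shape:
            raise ValueError("each mask must match its patch dimensions")

    idx_train, idx_val, idx_test = split_patches(list(range(len(patches))), cfg.split_fractions, cfg.seed)
    logger.info(
        "patch split: %d train / %d val / %d test", len(idx_train), len(idx_val), len(idx_test)
    )
    rng = np.random.default_rng(cfg.seed)

    def collect(indices: list[int], per_patch: int, balanced: bool):
        xs, ys = [], []
        for i in indices:
            feats = extract_features(patches[i], model_config)
            x, y = _sample_pixels(feats, mask_arrays[i], per_patch, rng, balanced)
            xs.append(x)
            ys.append(y)
        return np.concatenate(xs), np.concatenate(ys)

    X_train, y_train = collect(idx_train, cfg.samples_per_patch, balanced=True)
    X_train, y_train = _rebalance(X_train, y_train, rng)
    val_per_patch = max(1, cfg.val_sample_size // max(1, len(idx_val)))
    X_val, y_val = collect(idx_val, val_per_patch, balanced=False)
    counts = {CLASS_MAP[c]: int(n) for c, n in zip(*np.unique(y_train, return_counts=True))}
    logger.info("training pixel sample per class: %s", counts)

    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std[std < 1e-8] = 1.0
    Xtr = (X_train - mean) / std
    Xva = (X_val - mean) / std

    mlp = MLPClassifier(
        hidden_layer_sizes=model_config.hidden_layer_sizes,
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, len(Xtr)),
        random_state=cfg.seed,
        max_iter=1,
    )
    classes = np.arange(model_config.n_classes)
    history = TrainHistory()
    best_iou = -1.0
    best_mlp = None
    # subsample for the per-epoch loss bookkeeping
    loss_sel = rng.choice(len(Xtr), size=min(20000, len(Xtr)), replace=False)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(Xtr))
        mlp.partial_fit(Xtr[order], y_train[order], classes=classes)

        def logits_of(X):
            return np.log(np.clip(mlp.predict_proba(X), 1e-12, None))

        train_loss = composite_loss(logits_of(Xtr[loss_sel]), y_train[loss_sel])
        val_loss = composite_loss(logits_of(Xva), y_val)
        if not np.isfinite(train_loss.total):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        val_iou = iou_score(mlp.predict(Xva).astype(np.uint8), y_val)
        history.append(train_loss.total, val_loss.total, val_iou)
        logger.info(
            "epoch %d: train CE %.4f dice %.4f | val loss %.4f | val IoU %.4f",
            epoch, train_loss.cross_entropy, train_loss.dice, val_loss.total, val_iou,
        )
        if val_iou > best_iou:
            best_iou = val_iou
            best_mlp = copy.deepcopy(mlp)
            history.best_epoch = epoch

    model = TrainedModel(config=model_config, mlp=best_mlp, feature_mean=mean, feature_std=std)
    if checkpoint_path is not None:
        history.checkpoint_path = str(model.save(checkpoint_path))
    return model, history


def predict_slide(
    model: TrainedModel,
    image: RasterImage | np.ndarray,
    tiling: TilingConfig | None = None,
) -> LabelMask:
    """Segment a whole slide: tile, classify each patch, stitch back.

    The output mask has exactly the input's dimensions and the training
    class vocabulary.
    """
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {arr.shape}")
    tiling = tiling or TilingConfig()
    grid, patches = tile_image(arr, tiling)
    pred_patches = [model.predict_patch(p) for p in patches]
    return stitch_masks(grid, pred_patches)
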