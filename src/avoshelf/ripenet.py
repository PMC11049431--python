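"""Ripening-stage image classifier: augmentation, training schedule, prediction.

The training protocol mirrors transfer-learning practice for stage
classification: subtle geometric augmentation (one random draw per image
per epoch), minibatch SGD with momentum, a step learning-rate schedule
(drop by 0.1 every 10 epochs), periodic validation (every 10 iterations),
early stopping after 150 iterations without validation improvement, and
selection of the checkpoint with the best validation accuracy (ties broken
by lower validation loss, then earliest).

The default backbone is a small convolutional network (two conv blocks and
a linear head) written in numpy, sized to train on one CPU in minutes;
heavier pretrained backbones can be plugged in behind the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from . import _nn

__all__ = [
    "AugmentationConfig",
    "TrainingConfig",
    "TrainedClassifier",
    "augment_image",
    "draw_augmentation",
    "lr_at_epoch",
    "select_best_checkpoint",
    "train_classifier",
    "predict",
]


@dataclass(frozen=True)
class AugmentationConfig:
    reflect: bool = True
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    scale: tuple[float, float] = (0.95, 1.05)
    translate_px: tuple[float, float] = (-10.0, 10.0)

    def is_identity(self) -> bool:
        return (not self.reflect
                and self.rotation_deg == (0.0, 0.0)
                and self.scale == (1.0, 1.0)
                and self.translate_px == (0.0, 0.0))


@dataclass(frozen=True)
class TrainingConfig:
    num_classes: int = 10
    epochs: int = 30
    minibatch: int = 128
    lr_init: float = 0.01            # deep-backbone preset; 0.001 for shallow nets
    lr_drop_factor: float = 0.1
    lr_drop_period_epochs: int = 10
    val_every_iters: int = 10
    patience_iters: int = 150
    backbone: str = "small_cnn"      # "small_cnn" | "linear"
    input_size: int = 32
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes not in (5, 10):
            raise ValueError("num_classes must be 5 or 10")
        for name in ("epochs", "minibatch", "lr_drop_period_epochs",
                     "val_every_iters", "patience_iters", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def draw_augmentation(cfg: AugmentationConfig, rng: np.random.Generator):
    """Sample one augmentation: (rotation_deg, scale, tx_px, ty_px, reflect)."""
    return (rng.uniform(*cfg.rotation_deg), rng.uniform(*cfg.scale),
            rng.uniform(*cfg.translate_px), rng.uniform(*cfg.translate_px),
            bool(cfg.reflect and rng.random() < 0.5))


def augment_image(image: np.ndarray, cfg: AugmentationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """One random geometric augmentation draw; output dimensions unchanged."""
    if cfg.is_identity():
        return image.copy()
    img = image.astype(float) / 255.0 if image.dtype == np.uint8 else image
    h, w = img.shape[:2]
    rot_deg, scale, tx, ty, reflect = draw_augmentation(cfg, rng)
    angle = math.radians(rot_deg)
    center = np.array([w / 2.0, h / 2.0])
    tf = (sktransform.AffineTransform(translation=-center)
          + sktransform.AffineTransform(rotation=angle, scale=(scale, scale))
          + sktransform.AffineTransform(translation=center + [tx, ty]))
    out = sktransform.warp(img, tf.inverse, mode="edge", order=1)
    if reflect:
        out = out[:, ::-1]
    if image.dtype == np.uint8:
        out = (np.clip(out, 0, 1) * 255.0 + 0.5).astype(np.uint8)
    return out


def lr_at_epoch(epoch: int, tcfg: TrainingConfig) -> float:
    """Step schedule: lr_init * factor^floor(epoch / period) (epoch 0-based)."""
    return tcfg.lr_init * tcfg.lr_drop_factor ** (epoch // tcfg.lr_drop_period_epochs)


def select_best_checkpoint(history: pd.DataFrame) -> int:
    """Index of the best validation checkpoint.

    Maximal validation accuracy; ties broken by lower validation loss
    (when recorded), then by earliest occurrence.
    """
    acc = history["val_accuracy"].to_numpy(float)
    loss = (history["val_loss"].to_numpy(float)
            if "val_loss" in history else np.zeros(len(acc)))
    best = 0
    for i in range(1, len(acc)):
        if acc[i] > acc[best] + 1e-12 or (
                abs(acc[i] - acc[best]) <= 1e-12 and loss[i] < loss[best] - 1e-12):
            best = i
    return best


def _prep_image(img: np.ndarray, size: int) -> np.ndarray:
    """Aspect-preserving pad to square, then resize to the backbone input."""
    x = img.astype(float) / 255.0 if img.dtype == np.uint8 else np.asarray(img, float)
    h, w = x.shape[:2]
    if h != w:
        d = abs(h - w)
        pad = ((d // 2, d - d // 2), (0, 0), (0, 0)) if h < w else \
              ((0, 0), (d // 2, d - d // 2), (0, 0))
        x = np.pad(x, pad, mode="edge")
    if x.shape[0] != size:
        x = sktransform.resize(x, (size, size, 3), order=1, anti_aliasing=x.shape[0] > size)
    return x - 0.5   # center


def build_backbone(name: str, input_size: int, num_classes: int,
                   rng: np.random.Generator) -> _nn.Sequential:
    if name == "small_cnn":
        s = input_size // 4
        return _nn.Sequential([
            _nn.Conv2D(3, 8, 3, rng), _nn.ReLU(), _nn.MaxPool2D(2),
            _nn.Conv2D(8, 16, 3, rng), _nn.ReLU(), _nn.MaxPool2D(2),
            _nn.Flatten(), _nn.Dense(s * s * 16, num_classes, rng),
        ])
    if name == "linear":
        return _nn.Sequential([_nn.Flatten(),
                               _nn.Dense(input_size * input_size * 3, num_classes, rng)])
    raise ValueError(f"unknown backbone {name!r}")


@dataclass
class TrainedClassifier:
    backbone: str
    net: _nn.Sequential = field(repr=False)
    classes: list
    tcfg: TrainingConfig
    history: pd.DataFrame
    best_checkpoint: int

    def predict_proba(self, images) -> np.ndarray:
        xs = np.stack([_prep_image(im, self.tcfg.input_size) for im in images])
        out = []
        for i in range(0, len(xs), 256):
            out.append(_nn.softmax(self.net.forward(xs[i:i + 256], train=False)))
        return np.vstack(out)


def _load_images(db, rows: pd.DataFrame) -> list:
    return [db.load_image(r.sample_id, r.side, r.day) for r in rows.itertuples(index=False)]


def train_classifier(split, db, tcfg: TrainingConfig,
                     acfg: AugmentationConfig | None = None,
                     index: int | None = None) -> TrainedClassifier:
    """Train the stage classifier on the (oversampled) training multiset.

    Minimizes softmax cross-entropy over stage labels with momentum SGD.
    Each epoch consumes one fresh random augmentation of every training
    image; validation accuracy/loss are recorded every
    ``tcfg.val_every_iters`` iterations and training stops early once
    ``tcfg.patience_iters`` iterations pass without a new best validation
    accuracy.  The returned model carries the best-checkpoint weights and
    the full training history.
    """
    acfg = acfg if acfg is not None else AugmentationConfig()
    index = index if index is not None else tcfg.num_classes
    col = f"ri{index}"
    train_rows = split.train_records_oversampled
    if train_rows is None or train_rows.empty:
        from .splitting import oversample_training
        oversample_training(split, db, seed=tcfg.seed, index=index)
        train_rows = split.train_records_oversampled
    val_rows = db.records[db.records["sample_id"].isin(split.val_ids)]
    if val_rows.empty:
        raise ValueError("validation set is empty")
    if train_rows[col].max() > tcfg.num_classes:
        raise ValueError(f"labels span {train_rows[col].max()} stages "
                         f"but num_classes={tcfg.num_classes}")

    rng = np.random.default_rng(tcfg.seed)
    net = build_backbone(tcfg.backbone, tcfg.input_size, tcfg.num_classes, rng)
    params, grads = net.parameters()
    opt = _nn.SGDMomentum(params, grads, lr=tcfg.lr_init, momentum=tcfg.momentum)

    train_imgs = _load_images(db, train_rows)
    train_lab = train_rows[col].to_numpy(int) - 1
    val_x = np.stack([_prep_image(im, tcfg.input_size) for im in _load_images(db, val_rows)])
    val_lab = val_rows[col].to_numpy(int) - 1

    def validate():
        probs = []
        for i in range(0, len(val_x), 256):
            probs.append(_nn.softmax(net.forward(val_x[i:i + 256], train=False)))
        probs = np.vstack(probs)
        loss, _ = _nn.cross_entropy_grad(probs, val_lab)
        acc = float((probs.argmax(axis=1) == val_lab).mean())
        return acc, float(loss)

    hist = []
    iteration = 0
    best_acc, best_iter, best_weights, best_loss = -1.0, 0, net.get_weights(), np.inf
    stop = False
    n = len(train_imgs)
    for epoch in range(tcfg.epochs):
        opt.lr = lr_at_epoch(epoch, tcfg)
        order = rng.permutation(n)
        for start in range(0, n, tcfg.minibatch):
            idx = order[start:start + tcfg.minibatch]
            xb = np.stack([_prep_image(augment_image(train_imgs[i], acfg, rng),
                                       tcfg.input_size) for i in idx])
            yb = train_lab[idx]
            probs = _nn.softmax(net.forward(xb, train=True))
            loss, gout = _nn.cross_entropy_grad(probs, yb)
            net.backward(gout)
            opt.step()
            iteration += 1
            if iteration % tcfg.val_every_iters == 0:
                vacc, vloss = validate()
                hist.append({"iteration": iteration, "epoch": epoch,
                             "lr": opt.lr, "train_loss": float(loss),
                             "val_accuracy": vacc, "val_loss": vloss})
                if vacc > best_acc + 1e-12 or (abs(vacc - best_acc) <= 1e-12
                                               and vloss < best_loss - 1e-12):
                    best_acc, best_loss = vacc, vloss
                    best_weights = net.get_weights()
                    best_iter = len(hist) - 1
                if iteration - (hist[best_iter]["iteration"]) >= tcfg.patience_iters:
                    stop = True
                    break
        if stop:
            break
    if not hist:   # fewer iterations than val_every: record a final checkpoint
        vacc, vloss = validate()
        hist.append({"iteration": iteration, "epoch": tcfg.epochs - 1,
                     "lr": opt.lr, "train_loss": np.nan,
                     "val_accuracy": vacc, "val_loss": vloss})
        best_weights, best_iter = net.get_weights(), 0
    net.set_weights(best_weights)
    history = pd.DataFrame(hist)
    return TrainedClassifier(backbone=tcfg.backbone, net=net,
                             classes=list(range(1, tcfg.num_classes + 1)),
                             tcfg=tcfg, history=history, best_checkpoint=best_iter)


def predict(model: TrainedClassifier, db, records: pd.DataFrame,
            index: int | None = None) -> pd.DataFrame:
    """Per-image predictions joined to truth.

    Returns one row per photograph with sample_id, side, day, group,
    true_stage, predicted_stage and normalized class scores.  Deterministic
    for fixed model weights.
    """
    index = index if index is not None else model.tcfg.num_classes
    col = f"ri{index}"
    probs = model.predict_proba(_load_images(db, records))
    pred = probs.argmax(axis=1) + 1
    out = records[["sample_id", "side", "day", "group"]].copy().reset_index(drop=True)
    out["true_stage"] = records[col].to_numpy(int)
    out["predicted_stage"] = pred.astype(int)
    for k in range(probs.shape[1]):
        out[f"score_{k + 1}"] = probs[:, k]
    return out
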