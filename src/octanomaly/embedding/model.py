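"""Embedding model: CNN backbone + L2-Norm/Scale head trained with softmax.

Stage 1 of the detector.  A compact CNN is trained to separate AMD from
normal B-scans under the L2-constrained softmax loss; afterwards the
classification layer is discarded and the network up to (and including)
the L2-Norm + Scale head serves as the feature extractor, so every
feature lies on the hypersphere of radius ``alpha``.

The default ``tiny_cnn`` backbone is small enough to train in minutes on
one CPU: the input is grayscale-averaged and average-pool downsampled,
then passed through two 3x3 conv + ReLU + maxpool blocks and a dense
layer producing a 64-d raw descriptor.  A ``resnet50`` backbone kind is
registered for full-scale runs; it requires torch/torchvision at import
time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..data import BinaryLabel, ImageSet
from .nn import Adam, AvgPool, Conv2D, Dense, Flatten, Layer, MaxPool2, ReLU
from .ops import l2_norm_scale, softmax_cross_entropy

BINARY_CLASS_IDS = {BinaryLabel.NORMAL: 0, BinaryLabel.AMD: 1}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the study configuration:
    Adam, batch 12, learning rate 0.001, 30 epochs, alpha = 5, 224x224x3
    input, 80/20 stratified split)."""

    batch_size: int = 12
    n_classes: int = 2
    alpha: float = 5.0
    learning_rate: float = 0.001
    epochs: int = 30
    optimizer: str = "adam"
    input_size: tuple[int, int, int] = (224, 224, 3)
    train_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass(frozen=True)
class BackboneSpec:
    kind: str = "tiny_cnn"
    pretrained: bool = False
    feature_dim: int = 64

    def __post_init__(self) -> None:
        if self.kind not in ("tiny_cnn", "resnet50"):
            raise ValueError(f"unknown backbone kind: {self.kind!r}")
        if self.kind == "tiny_cnn" and self.pretrained:
            raise ValueError("tiny_cnn has no pretrained weights")


class TinyCNN:
    """Desk-scale CNN backbone mapping (N, H, W) images to raw d-dim features."""

    def __init__(self, feature_dim: int = 64, seed: int = 0):
        self.feature_dim = feature_dim
        self.seed = seed
        self.layers: list[Layer] = []
        self._built_hw: Optional[tuple[int, int]] = None

    def build(self, h: int, w: int) -> None:
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(17,)))
        pool = max(1, round(min(h, w) / 56))
        h1, w1 = h // pool, w // pool
        flat = 16 * (h1 // 2 // 2) * (w1 // 2 // 2)
        self.layers = [
            AvgPool(pool),
            Conv2D(1, 8, rng=rng),
            ReLU(),
            MaxPool2(),
            Conv2D(8, 16, rng=rng),
            ReLU(),
            MaxPool2(),
            Flatten(),
            Dense(flat, self.feature_dim, rng=rng),
        ]
        self._built_hw = (h, w)

    def _ensure_built(self, x: np.ndarray) -> None:
        if self._built_hw is None:
            self.build(x.shape[1], x.shape[2])
        elif self._built_hw != x.shape[1:3]:
            raise ValueError(
                f"backbone built for {self._built_hw} images, got {x.shape[1:3]}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W) grayscale in [0, 1] (RGB inputs are channel-averaged)."""
        if x.ndim == 4:  # (N, H, W, 3) replicated-channel input
            x = x.mean(axis=3)
        self._ensure_built(x)
        out = (x[:, None, :, :] - 0.5)  # center intensities
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]


def make_backbone(spec: BackboneSpec, seed: int = 0):
    if spec.kind == "tiny_cnn":
        return TinyCNN(feature_dim=spec.feature_dim, seed=seed)
    # resnet50: full-scale configuration, needs a deep-learning runtime
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:  # pragma: no cover - torch-less environments
        raise ImportError(
            "the resnet50 backbone requires torch and torchvision; "
            "install them or use the tiny_cnn backbone"
        ) from exc
    raise NotImplementedError(  # pragma: no cover
        "resnet50 support is limited to feature extraction via torchvision; "
        "train with tiny_cnn in this build"
    )


class EmbeddingModel:
    """Backbone + L2-Norm/Scale head (+ affine classification layer while training)."""

    def __init__(self, backbone: TinyCNN, alpha: float = 5.0, n_classes: int = 2):
        self.backbone = backbone
        self.alpha = float(alpha)
        self.n_classes = n_classes
        self.feature_dim = backbone.feature_dim
        # zero init => uniform logits => initial loss log(C) exactly
        self.W = np.zeros((self.feature_dim, n_classes))
        self.b = np.zeros(n_classes)

    # ---- inference -----------------------------------------------------
    def features(self, pixels: np.ndarray) -> np.ndarray:
        """On-sphere features (row norm alpha) of a batch; classification layer unused."""
        raw = self.backbone.forward(pixels, train=False)
        return l2_norm_scale(raw, self.alpha)

    def logits(self, pixels: np.ndarray) -> np.ndarray:
        return self.features(pixels) @ self.W + self.b

    # ---- training internals -------------------------------------------
    def _forward_train(self, pixels: np.ndarray):
        raw = self.backbone.forward(pixels, train=True)
        norms = np.linalg.norm(raw, axis=1)
        if np.any(norms < 1e-12):
            from .ops import ZeroFeatureError

            raise ZeroFeatureError("backbone produced a zero feature during training")
        sphere = self.alpha * raw / norms[:, None]
        logits = sphere @ self.W + self.b
        return raw, norms, sphere, logits

    def _backward_train(self, raw, norms, sphere, logits, y) -> float:
        m = len(y)
        zmax = logits.max(axis=1, keepdims=True)
        ez = np.exp(logits - zmax)
        p = ez / ez.sum(axis=1, keepdims=True)
        loss = float(np.mean(-np.log(p[np.arange(m), y] + 1e-300)))
        dlogits = p.copy()
        dlogits[np.arange(m), y] -= 1.0
        dlogits /= m
        self.dW = sphere.T @ dlogits
        self.db = dlogits.sum(axis=0)
        dsphere = dlogits @ self.W.T
        # back through y = alpha * x / ||x||: remove the radial component
        unit = raw / norms[:, None]
        radial = np.sum(dsphere * unit, axis=1, keepdims=True)
        draw = (self.alpha / norms[:, None]) * (dsphere - radial * unit)
        self.backbone.backward(draw)
        return loss

    def evaluate(self, pixels: np.ndarray, y: np.ndarray, batch_size: int = 64):
        """Mean loss and accuracy without touching training caches."""
        losses, correct = [], 0
        for s in range(0, len(y), batch_size):
            z = self.logits(pixels[s : s + batch_size])
            yy = y[s : s + batch_size]
            losses.append(softmax_cross_entropy(z, yy) * len(yy))
            correct += int(np.sum(z.argmax(axis=1) == yy))
        n = max(len(y), 1)
        return (float(np.sum(losses) / n), correct / n) if n else (float("nan"), float("nan"))

    # ---- persistence ---------------------------------------------------
    def save(self, model_dir: str | Path, train_config: Optional[TrainConfig] = None) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        params = self.backbone.params() + [self.W, self.b]
        np.savez(model_dir / "model.npz", **{f"p{i}": p for i, p in enumerate(params)})
        meta = {
            "alpha": self.alpha,
            "n_classes": self.n_classes,
            "feature_dim": self.feature_dim,
            "backbone": "tiny_cnn",
            "built_hw": list(self.backbone._built_hw) if self.backbone._built_hw else None,
            "backbone_seed": self.backbone.seed,
            "train_config": _config_dict(train_config) if train_config else None,
        }
        (model_dir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "EmbeddingModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        backbone = TinyCNN(feature_dim=meta["feature_dim"], seed=meta["backbone_seed"])
        if meta["built_hw"]:
            backbone.build(*meta["built_hw"])
        model = cls(backbone, alpha=meta["alpha"], n_classes=meta["n_classes"])
        with np.load(model_dir / "model.npz") as data:
            params = backbone.params() + [model.W, model.b]
            for i, p in enumerate(params):
                p[...] = data[f"p{i}"]
        return model


def _config_dict(cfg: TrainConfig) -> dict:
    d = dict(cfg.__dict__)
    d["input_size"] = list(cfg.input_size)
    return d


def stratified_split(
    labels: Sequence[int], train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/validation index split."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,)))
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(val_idx, dtype=int))


def _stack_pixels(images: ImageSet) -> np.ndarray:
    return np.stack([im.pixels for im in images])


def train(
    images: ImageSet,
    config: TrainConfig = TrainConfig(),
    backbone: BackboneSpec = BackboneSpec(),
) -> tuple[EmbeddingModel, list[dict], tuple[np.ndarray, np.ndarray]]:
    """Train the embedding on AMD + normal images.

    Returns ``(model, history, (train_idx, val_idx))``.  History row 0 is
    the pre-update evaluation of the initialized model (loss log 2 for
    balanced classes, since the classification layer starts at zero);
    rows 1..epochs follow each pass.  ``epochs=0`` returns the
    initialized model with an empty history.
    """
    y_all = np.array([BINARY_CLASS_IDS[im.binary_label] for im in images])
    if len(np.unique(y_all)) < 2:
        raise ValueError("training requires both AMD and NORMAL images")
    px_all = _stack_pixels(images)

    net = make_backbone(backbone, seed=config.seed)
    net.build(px_all.shape[1], px_all.shape[2])
    model = EmbeddingModel(net, alpha=config.alpha, n_classes=config.n_classes)

    train_idx, val_idx = stratified_split(y_all, config.train_frac, config.seed)
    x_tr, y_tr = px_all[train_idx], y_all[train_idx]
    x_va, y_va = px_all[val_idx], y_all[val_idx]

    history: list[dict] = []
    if config.epochs == 0:
        return model, history, (train_idx, val_idx)

    tr_loss, tr_acc = model.evaluate(x_tr, y_tr)
    va_loss, va_acc = model.evaluate(x_va, y_va)
    history.append(
        {"epoch": 0, "train_loss": tr_loss, "train_acc": tr_acc,
         "val_loss": va_loss, "val_acc": va_acc}
    )

    opt = Adam(
        net.params() + [model.W, model.b],
        None,  # grad refs resolved lazily below (head grads are re-bound each step)
        lr=config.learning_rate,
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(29,)))
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(y_tr))
        batch_losses = []
        for s in range(0, len(order), config.batch_size):
            sel = order[s : s + config.batch_size]
            raw, norms, sphere, logits = model._forward_train(x_tr[sel])
            loss = model._backward_train(raw, norms, sphere, logits, y_tr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the input scaling"
                )
            batch_losses.append(loss)
            opt.grad_refs = net.grads() + [model.dW, model.db]
            opt.step()
        tr_loss, tr_acc = model.evaluate(x_tr, y_tr)
        va_loss, va_acc = model.evaluate(x_va, y_va)
        history.append(
            {"epoch": epoch, "train_loss": tr_loss, "train_acc": tr_acc,
             "val_loss": va_loss, "val_acc": va_acc,
             "mean_batch_loss": float(np.mean(batch_losses))}
        )
    return model, history, (train_idx, val_idx)


def extract_features(model: EmbeddingModel, images: ImageSet, batch_size: int = 64) -> np.ndarray:
    """n x d matrix of on-sphere features; empty input gives a (0, d) matrix."""
    if len(images) == 0:
        return np.zeros((0, model.feature_dim))
    px = _stack_pixels(images)
    rows = [model.features(px[s : s + batch_size]) for s in range(0, len(px), batch_size)]
    return np.vstack(rows)
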