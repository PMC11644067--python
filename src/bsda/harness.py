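"""Training harness: wrap a feature extractor and classifier head around the
augmentation module and run the full training loop.

The augmentation sits on the penultimate feature vector, immediately before
the final linear classifier. At inference time the wrapped model is exactly
``classifier(feature_extractor(x))`` — no sampling.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, softmax_cross_entropy
from .core import (
    BSDAConfig,
    BSDAModule,
    alpha_schedule,
    total_loss,
)
from .evaluation import compute_acc, compute_auc

logger = logging.getLogger("bsda")

__all__ = [
    "TrainConfig",
    "ArraySplits",
    "SmallCNN",
    "MLPBackbone",
    "BSDAWrappedModel",
    "build_model",
    "forward_train",
    "fit",
    "predict",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
    "write_metrics_csv",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ["epoch", "split", "loss_total", "loss_task_orig",
                  "loss_task_aug", "loss_kl", "loss_recon", "acc", "auc"]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    warmup_epochs: int = 5
    weight_decay: float = 0.0
    optimizer: str = "adamw"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adamw":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class ArraySplits:
    """Train/val/test arrays; images are NCHW, feature vectors are N x k."""

    train_x: np.ndarray
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray
    num_classes: int

    def __post_init__(self):
        for name in ("train", "val", "test"):
            if len(getattr(self, f"{name}_x")) == 0:
                raise ValueError(f"empty {name} split")

    @classmethod
    def from_blobs(cls, dataset) -> "ArraySplits":
        def prep(split):
            images, labels = dataset.split(split)
            return images.transpose(0, 3, 1, 2).astype(np.float64), labels
        train_x, train_y = prep("train")
        val_x, val_y = prep("val")
        test_x, test_y = prep("test")
        return cls(train_x, train_y, val_x, val_y, test_x, test_y,
                   num_classes=dataset.num_classes)

    @classmethod
    def from_npz_arrays(cls, arrays: dict[str, np.ndarray]) -> "ArraySplits":
        def prep(split):
            images = np.asarray(arrays[f"{split}_images"], dtype=np.float64)
            labels = np.asarray(arrays[f"{split}_labels"]).reshape(-1).astype(np.int64)
            if images.ndim == 3:  # N x H x W -> single channel
                images = images[:, None, :, :]
            elif images.ndim == 4:  # N x H x W x C -> NCHW
                images = images.transpose(0, 3, 1, 2)
            return images, labels
        train_x, train_y = prep("train")
        val_x, val_y = prep("val")
        test_x, test_y = prep("test")
        num_classes = int(max(train_y.max(), val_y.max(), test_y.max())) + 1
        return cls(train_x, train_y, val_x, val_y, test_x, test_y, num_classes)

    @classmethod
    def from_features(cls, features: np.ndarray, labels: np.ndarray,
                      seed: int = 0) -> "ArraySplits":
        from .synthetic import split_indices
        rng = np.random.default_rng(seed)
        tr, va, te = split_indices(len(labels), rng)
        num_classes = int(labels.max()) + 1
        return cls(features[tr], labels[tr], features[va], labels[va],
                   features[te], labels[te], num_classes)


# ---------------------------------------------------------------------------
# reference backbones
# ---------------------------------------------------------------------------


class SmallCNN(nn.Module):
    """Two conv blocks + global average pooling -> 64-dim features."""

    feature_dim = 64

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.blocks = nn.Sequential(
            nn.Conv2d(in_channels, 32, 3, rng, padding=1),
            nn.ReLU(),
            nn.AvgPool2d(2),
            nn.Conv2d(32, 64, 3, rng, padding=1),
            nn.ReLU(),
            nn.GlobalAvgPool2d(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.blocks(x)


class MLPBackbone(nn.Module):
    """One hidden layer with ReLU for pre-extracted feature vectors.

    The ReLU gives the penultimate representation hard zeros, matching the
    sparsity the zero-indicator mask is designed for.
    """

    def __init__(self, in_features: int, rng: np.random.Generator,
                 feature_dim: int = 64):
        super().__init__()
        self.feature_dim = feature_dim
        self.net = nn.Sequential(
            nn.Linear(in_features, feature_dim, rng),
            nn.ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


# ---------------------------------------------------------------------------
# wrapped model
# ---------------------------------------------------------------------------


class BSDAWrappedModel(nn.Module):
    """feature_extractor (f1) -> [augmentation during training] -> classifier (f2)."""

    def __init__(self, feature_extractor: nn.Module, classifier: nn.Module,
                 bsda: BSDAModule | None):
        super().__init__()
        self.feature_extractor = feature_extractor
        self.classifier = classifier
        self.bsda = bsda

    @property
    def bsda_active(self) -> bool:
        return self.bsda is not None and self.bsda.config.alpha_max > 0

    def features(self, x: Tensor) -> Tensor:
        return self.feature_extractor(x)

    def logits(self, x: Tensor) -> Tensor:
        return self.classifier(self.features(x))


def build_model(backbone: str, input_shape: tuple, num_classes: int,
                bsda_config: BSDAConfig | None, seed: int = 0,
                feature_dim: int = 64) -> BSDAWrappedModel:
    """Construct the wrapped model with separate init streams per component,
    so attaching/detaching the augmentation module never shifts backbone init.
    """
    ss = np.random.SeedSequence(seed)
    backbone_rng, head_rng, bsda_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    if backbone == "cnn":
        if len(input_shape) != 3:
            raise ValueError(f"cnn backbone expects (C, H, W) input, got {input_shape}")
        f1 = SmallCNN(input_shape[0], backbone_rng)
    elif backbone == "mlp":
        if len(input_shape) != 1:
            raise ValueError(f"mlp backbone expects (k,) input, got {input_shape}")
        f1 = MLPBackbone(input_shape[0], backbone_rng, feature_dim=feature_dim)
    else:
        raise ValueError(f"unknown backbone {backbone!r} (choose 'cnn' or 'mlp')")
    f2 = nn.Linear(f1.feature_dim, num_classes, head_rng)
    bsda = None
    if bsda_config is not None:
        if bsda_config.feature_dim != f1.feature_dim:
            raise ValueError(
                f"bsda feature_dim {bsda_config.feature_dim} != backbone "
                f"feature_dim {f1.feature_dim}"
            )
        bsda = BSDAModule(bsda_config, rng=bsda_rng)
    return BSDAWrappedModel(f1, f2, bsda)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------


def forward_train(model: BSDAWrappedModel, images: np.ndarray, labels: np.ndarray,
                  epoch: int, rng: np.random.Generator) -> tuple[Tensor, dict]:
    """One training forward pass; returns the total loss and its parts.

    Order of operations: features -> sigma -> U reparameterized draws ->
    augmented copies -> reconstruction -> combined loss with the scheduled
    alpha. The U copies go through the classifier as one enlarged batch; the
    feature extractor runs once.
    """
    if not model.training:
        raise RuntimeError("forward_train requires training mode; sampling is training-only")
    x = Tensor(np.asarray(images, dtype=np.float64))
    y = np.asarray(labels).reshape(-1)
    a = model.features(x)
    task_orig = softmax_cross_entropy(model.classifier(a), y)

    parts = {"task_orig": task_orig.item(), "task_aug": 0.0, "kl": 0.0,
             "recon": 0.0, "alpha": 0.0}
    if not model.bsda_active:
        return task_orig, parts

    cfg = model.bsda.config
    alpha = alpha_schedule(epoch, cfg)
    sigma = model.bsda.sigma_for(a)
    copies, magnitudes = model.bsda.augment_copies(a, sigma, rng)
    stacked = nn.cat(copies, axis=0)
    y_tiled = np.tile(y, cfg.num_samples)
    task_aug = softmax_cross_entropy(model.classifier(stacked), y_tiled)
    bsda_term, kl, recon = model.bsda.loss(sigma, magnitudes, a)
    total = total_loss(task_orig, task_aug, bsda_term, alpha)
    parts.update(task_aug=task_aug.item(), kl=kl.item(), recon=recon.item(),
                 alpha=alpha)
    return total, parts


def predict(model: BSDAWrappedModel, images: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Class probabilities from the plain (augmentation-free) forward pass."""
    was_training = model.training
    model.eval()
    try:
        out = []
        for start in range(0, len(images), batch_size):
            logits = model.logits(Tensor(np.asarray(
                images[start:start + batch_size], dtype=np.float64))).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(out)
    finally:
        model.train(was_training)


def extract_features(model: BSDAWrappedModel, images: np.ndarray,
                     batch_size: int = 256) -> np.ndarray:
    """Penultimate features in evaluation mode."""
    was_training = model.training
    model.eval()
    try:
        out = []
        for start in range(0, len(images), batch_size):
            out.append(model.features(Tensor(np.asarray(
                images[start:start + batch_size], dtype=np.float64))).data)
        return np.vstack(out)
    finally:
        model.train(was_training)


def _evaluate(model: BSDAWrappedModel, x: np.ndarray, y: np.ndarray) -> dict:
    probs = predict(model, x)
    return {"acc": compute_acc(probs, y), "auc": compute_auc(probs, y)}


def fit(model: BSDAWrappedModel, splits: ArraySplits, train_config: TrainConfig,
        log_rows: list | None = None, progress: bool = False) -> dict:
    """Train with AdamW + linear learning-rate warm-up; select the checkpoint
    by validation AUC (ties: ACC, then the later epoch); report test metrics.
    """
    ss = np.random.SeedSequence(train_config.seed)
    data_rng, aug_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    optimizer = nn.AdamW(model.parameters(), lr=train_config.learning_rate,
                         weight_decay=train_config.weight_decay)
    n = len(splits.train_x)
    best = None  # (auc, acc, epoch, state)
    history = []
    for epoch in range(train_config.epochs):
        model.train()
        order = data_rng.permutation(n)
        lr_scale = min(1.0, (epoch + 1) / train_config.warmup_epochs) \
            if train_config.warmup_epochs > 0 else 1.0
        sums = {"total": 0.0, "task_orig": 0.0, "task_aug": 0.0, "kl": 0.0,
                "recon": 0.0}
        n_batches = 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            total, parts = forward_train(model, splits.train_x[idx],
                                         splits.train_y[idx], epoch, aug_rng)
            optimizer.zero_grad()
            total.backward()
            optimizer.step(lr_scale=lr_scale)
            sums["total"] += total.item()
            for key in ("task_orig", "task_aug", "kl", "recon"):
                sums[key] += parts[key]
            n_batches += 1
        val = _evaluate(model, splits.val_x, splits.val_y)
        row = {
            "epoch": epoch,
            "loss_total": sums["total"] / n_batches,
            "loss_task_orig": sums["task_orig"] / n_batches,
            "loss_task_aug": sums["task_aug"] / n_batches,
            "loss_kl": sums["kl"] / n_batches,
            "loss_recon": sums["recon"] / n_batches,
            "val_acc": val["acc"],
            "val_auc": val["auc"],
        }
        history.append(row)
        if log_rows is not None:
            log_rows.append({"split": "train", **{k: row[k] for k in (
                "epoch", "loss_total", "loss_task_orig", "loss_task_aug",
                "loss_kl", "loss_recon")}, "acc": "", "auc": ""})
            log_rows.append({"split": "val", "epoch": epoch, "loss_total": "",
                             "loss_task_orig": "", "loss_task_aug": "",
                             "loss_kl": "", "loss_recon": "",
                             "acc": val["acc"], "auc": val["auc"]})
        logger.info(
            "seed=%d epoch=%d loss_total=%.4f task_orig=%.4f task_aug=%.4f "
            "kl=%.4f recon=%.4f val_acc=%.2f val_auc=%.2f",
            train_config.seed, epoch, row["loss_total"], row["loss_task_orig"],
            row["loss_task_aug"], row["loss_kl"], row["loss_recon"],
            val["acc"], val["auc"],
        )
        if progress:
            print(f"epoch {epoch:3d}  loss {row['loss_total']:.4f}  "
                  f"val acc {val['acc']:.2f}  val auc {val['auc']:.2f}")
        key = (val["auc"], val["acc"], epoch)
        if best is None or key >= best[0]:
            best = (key, [arr.copy() for arr in model.state_arrays()])
    model.load_state_arrays(best[1])
    test = _evaluate(model, splits.test_x, splits.test_y)
    if log_rows is not None:
        log_rows.append({"split": "test", "epoch": best[0][2], "loss_total": "",
                         "loss_task_orig": "", "loss_task_aug": "", "loss_kl": "",
                         "loss_recon": "", "acc": test["acc"], "auc": test["auc"]})
    return {"acc": test["acc"], "auc": test["auc"], "best_epoch": best[0][2],
            "history": history}


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def write_metrics_csv(rows: list[dict], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=METRIC_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({col: row.get(col, "") for col in METRIC_COLUMNS})


def save_checkpoint(model: BSDAWrappedModel, path, *, backbone: str,
                    input_shape: tuple, num_classes: int, seed: int,
                    train_config: TrainConfig | None = None) -> Path:
    """Single-file parameter archive with the configs embedded as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "backbone": backbone,
        "input_shape": list(input_shape),
        "num_classes": num_classes,
        "seed": seed,
        "bsda_config": asdict(model.bsda.config) if model.bsda is not None else None,
        "train_config": asdict(train_config) if train_config is not None else None,
    }
    arrays = {f"arr_{i}": arr for i, arr in enumerate(model.state_arrays())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    return path


def load_checkpoint(path) -> tuple[BSDAWrappedModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    bsda_config = (BSDAConfig(**meta["bsda_config"])
                   if meta["bsda_config"] is not None else None)
    model = build_model(meta["backbone"], tuple(meta["input_shape"]),
                        meta["num_classes"], bsda_config, seed=meta["seed"])
    model.load_state_arrays(arrays)
    return model, meta
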