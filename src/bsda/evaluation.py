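"""Metrics, the repeated-seed protocol, and feature-space visualization."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score

__all__ = [
    "RunResult",
    "compute_acc",
    "compute_auc",
    "multi_seed_protocol",
    "tsne_export",
]


@dataclass
class RunResult:
    """Per-seed metrics and their mean / standard-error aggregation."""

    per_seed: list[dict] = field(default_factory=list)
    mean_acc: float = float("nan")
    mean_auc: float = float("nan")
    stderr_acc: float = float("nan")
    stderr_auc: float = float("nan")

    @classmethod
    def aggregate(cls, per_seed: list[dict]) -> "RunResult":
        accs = np.array([r["acc"] for r in per_seed], dtype=np.float64)
        aucs = np.array([r["auc"] for r in per_seed], dtype=np.float64)
        n = len(per_seed)
        return cls(
            per_seed=list(per_seed),
            mean_acc=float(accs.mean()),
            mean_auc=float(aucs.mean()),
            stderr_acc=float(accs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            stderr_auc=float(aucs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        )

    def as_dict(self) -> dict:
        return {
            "per_seed": self.per_seed,
            "mean_acc": self.mean_acc,
            "mean_auc": self.mean_auc,
            "stderr_acc": self.stderr_acc,
            "stderr_auc": self.stderr_auc,
        }


def compute_acc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy in percent; argmax ties break toward the lowest class index."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels).reshape(-1)
    if probabilities.size == 0 or labels.size == 0:
        raise ValueError("empty input")
    if probabilities.shape[0] != labels.shape[0]:
        raise ValueError("probabilities and labels disagree on sample count")
    predictions = probabilities.argmax(axis=1)
    return float((predictions == labels).mean() * 100.0)


def compute_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC in percent; multi-class uses unweighted one-vs-rest macro."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels).reshape(-1)
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("AUC requires at least two classes present in labels")
    c = probabilities.shape[1]
    if c == 2:
        return float(roc_auc_score(labels, probabilities[:, 1]) * 100.0)
    return float(
        roc_auc_score(labels, probabilities, multi_class="ovr", average="macro",
                      labels=np.arange(c)) * 100.0
    )


def multi_seed_protocol(runner: Callable[[int], dict], seeds: Iterable[int] = (0, 1, 2)) -> RunResult:
    """Run `runner(seed) -> {'acc': %, 'auc': %}` per seed and aggregate."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two seeds for a standard error")
    per_seed = []
    for seed in seeds:
        try:
            metrics = runner(seed)
        except Exception as exc:
            raise RuntimeError(f"runner failed for seed {seed}") from exc
        record = {"seed": seed, "acc": float(metrics["acc"]), "auc": float(metrics["auc"])}
        per_seed.append(record)
    return RunResult.aggregate(per_seed)


def tsne_export(original: np.ndarray, augmented: np.ndarray, labels: np.ndarray,
                path, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Embed originals + augmented copies into 2D; write CSV and a figure.

    The CSV has columns x, y, label, is_augmented; the figure draws circles
    for original features and crosses for augmented ones. Returns the
    embedding, rows ordered originals first.
    """
    original = np.asarray(original, dtype=np.float64)
    augmented = np.asarray(augmented, dtype=np.float64).reshape(-1, original.shape[1])
    labels = np.asarray(labels).reshape(-1)
    n_orig, n_aug = original.shape[0], augmented.shape[0]
    if n_aug % n_orig != 0:
        raise ValueError("augmented rows must be a whole number of copies of the originals")
    stacked = np.vstack([original, augmented])
    n_total = stacked.shape[0]
    if n_total <= perplexity:
        raise ValueError(
            f"{n_total} points cannot support perplexity {perplexity}; "
            f"pass perplexity < {n_total} (e.g. {max(n_total // 3, 2)})"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(stacked)

    copies = n_aug // n_orig
    all_labels = np.concatenate([labels, np.tile(labels, copies)])
    is_aug = np.concatenate([np.zeros(n_orig, dtype=int), np.ones(n_aug, dtype=int)])

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "label", "is_augmented"])
        for (x, y), lab, aug in zip(coords, all_labels, is_aug):
            writer.writerow([f"{x:.6f}", f"{y:.6f}", int(lab), int(aug)])

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab10")
    for lab in np.unique(all_labels):
        sel_o = (all_labels == lab) & (is_aug == 0)
        sel_a = (all_labels == lab) & (is_aug == 1)
        ax.scatter(coords[sel_o, 0], coords[sel_o, 1], marker="o", s=18,
                   color=cmap(int(lab) % 10), label=f"class {lab}")
        ax.scatter(coords[sel_a, 0], coords[sel_a, 1], marker="x", s=18,
                   color=cmap(int(lab) % 10))
    ax.legend(loc="best", fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path.with_suffix(".png"), dpi=120)
    plt.close(fig)
    return coords
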