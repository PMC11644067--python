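"""Desk-scale synthetic datasets.

Two generators: small multi-class ellipse images whose within-class variation
is a continuous size attribute, and sparse non-negative feature vectors with
known class means and a known label-preserving perturbation radius. Both are
pure functions of their arguments (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BlobImageDataset",
    "SparseFeatureDataset",
    "make_blob_images",
    "make_sparse_features",
    "write_npz_layout",
    "read_npz_layout",
    "split_indices",
]

NPZ_KEYS = (
    "train_images", "train_labels",
    "val_images", "val_labels",
    "test_images", "test_labels",
)


@dataclass
class BlobImageDataset:
    """Grayscale ellipse images with a continuous per-image size attribute."""

    images: np.ndarray  # N x H x W x C in [0, 1]
    labels: np.ndarray  # N
    attribute: np.ndarray  # N, latent radius
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def num_classes(self) -> int:
        return int(self.labels.max()) + 1

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        idx = {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx}[name]
        return self.images[idx], self.labels[idx]


@dataclass
class SparseFeatureDataset:
    """Non-negative sparse features with exactly recoverable class structure."""

    features: np.ndarray  # N x k, >= 0
    labels: np.ndarray  # N
    class_means: np.ndarray  # c x k
    label_radius: np.ndarray  # c, half the min distance to any other mean

    def nearest_mean_labels(self, x: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(x[:, None, :] - self.class_means[None, :, :], axis=2)
        return d.argmin(axis=1)


def split_indices(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled 7:1:2 train/val/test split."""
    perm = rng.permutation(n)
    n_train = round(n * 0.7)
    n_val = round(n * 0.1)
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def _render_ellipses(size: int, centers, radii, aspect: float, angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    img = np.zeros((size, size))
    ca, sa = np.cos(angle), np.sin(angle)
    for (cy, cx), r in zip(centers, radii):
        dy, dx = yy - cy, xx - cx
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        dist2 = (u / (r * aspect)) ** 2 + (v / r) ** 2
        # soft edge so the radius attribute varies the image smoothly
        img = np.maximum(img, np.clip(1.5 - 1.5 * dist2, 0.0, 1.0))
    return img


def make_blob_images(n: int, classes: int = 3, size: int = 32,
                     noise: float = 0.05, seed: int = 0) -> BlobImageDataset:
    """Render one image per sample: class sets the shape family (ellipse
    count and eccentricity), the latent attribute (radius) varies uniformly
    within class.
    """
    if n < classes * 10:
        raise ValueError(f"need n >= {classes * 10} for {classes} classes, got {n}")
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % classes
    rng.shuffle(labels)
    images = np.empty((n, size, size, 1))
    attribute = np.empty(n)
    # per-class shape family: circle / ellipse orientation, then count
    counts = 1 + np.arange(classes) // 4
    aspects = np.where(np.arange(classes) % 4 == 0, 1.0, 3.0)
    angles = np.maximum(np.arange(classes) % 4 - 1, 0) * np.pi / 4
    lo, hi = size * 0.08, size * 0.13
    # fixed per-class center layout: within a class (at noise=0) images vary
    # only through the radius attribute
    max_count = int(counts.max())
    layout = [(size * (0.25 + 0.5 * (j % 2)), size * (0.25 + 0.5 * (j // 2)))
              for j in range(max_count)]
    for i in range(n):
        c = labels[i]
        radius = rng.uniform(lo, hi)
        attribute[i] = radius
        k = counts[c]
        centers = [layout[j] for j in range(k)]
        if k == 1:
            centers = [(size / 2.0, size / 2.0)]
        img = _render_ellipses(size, centers, [radius] * k, aspects[c], angles[c])
        if noise > 0:
            img = img + rng.normal(0.0, noise, img.shape)
        images[i, :, :, 0] = np.clip(img, 0.0, 1.0)
    train_idx, val_idx, test_idx = split_indices(n, rng)
    return BlobImageDataset(images=images, labels=labels.astype(np.int64),
                            attribute=attribute, train_idx=train_idx,
                            val_idx=val_idx, test_idx=test_idx)


def make_sparse_features(n: int, k: int = 64, classes: int = 3,
                         zero_frac: float = 0.5, sep: float = 4.0,
                         noise: float | None = None,
                         seed: int = 0) -> SparseFeatureDataset:
    """Sparse non-negative features around well-separated rectified means.

    Each class mean is supported on a random subset of coordinates (the
    complement has exact zeros, sized to hit ``zero_frac``); samples add
    truncated Gaussian noise on the support and are hard-thresholded, so the
    realized zero fraction stays within tolerance of the target and clean
    nearest-mean classification is exact by construction.
    """
    if not 0.0 <= zero_frac < 1.0:
        raise ValueError("zero_frac must be in [0, 1)")
    if sep <= 0:
        raise ValueError("sep must be > 0")
    n_support = k - int(round(zero_frac * k))
    if n_support < 1:
        raise ValueError(f"zero_frac={zero_frac} leaves no support at k={k}")
    rng = np.random.default_rng(seed)
    floor = 0.5 * sep / np.sqrt(n_support)
    means = np.zeros((classes, k))
    for c in range(classes):
        support = rng.choice(k, size=n_support, replace=False)
        means[c, support] = floor + np.abs(rng.normal(0.0, 1.0, n_support))
    # rescale pairwise distances up to >= sep if the random draw fell short
    dists = np.linalg.norm(means[:, None] - means[None, :], axis=2)
    np.fill_diagonal(dists, np.inf)
    min_dist = dists.min()
    if classes > 1 and min_dist < sep:
        means *= sep / min_dist
        dists *= sep / min_dist
        min_dist = sep
    label_radius = dists.min(axis=1) / 2.0 if classes > 1 else np.full(1, np.inf)
    if noise is None:
        noise = float(label_radius.min()) / (8.0 * np.sqrt(k)) if classes > 1 else 0.1
    labels = rng.integers(0, classes, size=n)
    features = means[labels].copy()
    support_mask = features > 0
    eps = np.clip(rng.normal(0.0, noise, features.shape), -3 * noise, 3 * noise)
    features = features + eps * support_mask
    # hard threshold: cleans up any value that noise pushed near zero
    threshold = min(0.5 * floor, 0.5 * means[means > 0].min()) if classes > 0 else 0.0
    features[features < threshold] = 0.0
    realized = float((features == 0).mean())
    if abs(realized - zero_frac) > 0.02:
        raise ValueError(
            f"infeasible zero_frac/sep combination: realized zero fraction "
            f"{realized:.3f} vs target {zero_frac:.3f}"
        )
    ds = SparseFeatureDataset(features=features, labels=labels.astype(np.int64),
                              class_means=means, label_radius=label_radius)
    if classes > 1 and not np.array_equal(ds.nearest_mean_labels(features), ds.labels):
        raise ValueError("infeasible noise/sep combination: clean features not separable")
    return ds


def write_npz_layout(dataset: BlobImageDataset, path) -> Path:
    """Write the packed six-array layout (labels as N x 1 integer columns)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    arrays = {}
    for name in ("train", "val", "test"):
        images, labels = dataset.split(name)
        arrays[f"{name}_images"] = images
        arrays[f"{name}_labels"] = labels.reshape(-1, 1).astype(np.int64)
    np.savez(path, **arrays)
    return path


def read_npz_layout(path) -> dict[str, np.ndarray]:
    """Load the packed layout, verifying all six arrays are present."""
    with np.load(path) as data:
        missing = [key for key in NPZ_KEYS if key not in data.files]
        if missing:
            raise ValueError(f"packed array file is missing key(s): {', '.join(missing)}")
        return {key: np.asarray(data[key]) for key in NPZ_KEYS}
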