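"""Feature-space augmentation core.

Augmented features are built as ``a_tilde = a + I[a != 0] * d * m`` where
``d`` is an elementwise Bernoulli(lambda) direction mask and ``m = sigma * eps``
is a reparameterized draw from a zero-mean Gaussian whose per-dimension scale
``sigma`` is predicted from the feature vector itself. The regularizer that
trains the scale estimator is a closed-form KL divergence to a unit Gaussian
plus (optionally) a reconstruction MSE through a decoder that maps ``m``
back to ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "FeatureBatch",
    "MagnitudeDistribution",
    "DirectionMask",
    "AugmentedBatch",
    "BSDAConfig",
    "make_estimator",
    "make_reconstructor",
    "sample_direction",
    "estimate_sigma",
    "sample_magnitude",
    "augment",
    "reconstruct",
    "kl_term",
    "recon_term",
    "bsda_loss",
    "total_loss",
    "alpha_schedule",
    "BSDAModule",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureBatch:
    """A batch of feature vectors (B x k) with integer class labels."""

    features: np.ndarray
    labels: np.ndarray
    num_classes: int | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels).reshape(-1).astype(np.int64)
        if self.features.ndim != 2 or self.features.shape[0] < 1 or self.features.shape[1] < 1:
            raise ValueError(f"features must be a non-empty B x k matrix, got {self.features.shape}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite entries")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels length must match batch size")
        c = self.num_classes if self.num_classes is not None else int(self.labels.max()) + 1
        if self.labels.min() < 0 or self.labels.max() >= c:
            raise ValueError(f"labels must lie in [0, {c})")
        self.num_classes = c

    @property
    def batch_size(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


@dataclass
class MagnitudeDistribution:
    """Per-sample, per-dimension standard deviations of the magnitude draw."""

    sigma: Tensor

    def __post_init__(self):
        if not isinstance(self.sigma, Tensor):
            self.sigma = Tensor(np.asarray(self.sigma, dtype=np.float64))
        if self.sigma.ndim != 2:
            raise ValueError("sigma must be a B x k matrix")
        if not np.all(np.isfinite(self.sigma.data)) or np.any(self.sigma.data <= 0):
            raise ValueError("sigma must be strictly positive and finite")

    @property
    def shape(self):
        return self.sigma.shape


@dataclass
class DirectionMask:
    """Binary selection of feature dimensions to perturb."""

    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        values = np.unique(self.d)
        if not np.all(np.isin(values, (0.0, 1.0))):
            raise ValueError("direction mask entries must be exactly 0 or 1")


@dataclass
class AugmentedBatch:
    """U augmented copies of a feature batch, with the draws that made them."""

    augmented: np.ndarray  # U x B x k
    magnitudes: np.ndarray  # U x B x k
    directions: np.ndarray  # U x B x k


@dataclass
class BSDAConfig:
    """Hyperparameters of the augmentation module.

    ``lam`` is the Bernoulli rate of the direction mask, ``num_samples`` the
    number of augmented copies per feature per step, ``alpha_max`` the plateau
    of the auxiliary-loss weight after a linear warm-up. ``fixed_sigma``
    replaces the learned scale with a constant (the random-noise ablation).
    """

    feature_dim: int
    lam: float = 0.5
    num_samples: int = 1
    alpha_max: float = 0.5
    alpha_warmup_epochs: int = 5
    hidden_dim: int | None = None
    mask_zero: bool = True
    use_recon: bool = True
    fixed_sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.num_samples < 1:
            raise ValueError("num_samples must be >= 1")
        if self.alpha_max < 0:
            raise ValueError("alpha_max must be >= 0")
        if self.alpha_warmup_epochs < 0:
            raise ValueError("alpha_warmup_epochs must be >= 0")
        if self.fixed_sigma is not None and self.fixed_sigma < 0:
            raise ValueError("fixed_sigma must be >= 0")
        if self.hidden_dim is None:
            self.hidden_dim = self.feature_dim


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def _two_layer_net(k: int, hidden: int, rng: np.random.Generator,
                   zero_init_final: bool) -> nn.Module:
    # two fully connected layers with BatchNorm + GELU after the first
    return nn.Sequential(
        nn.Linear(k, hidden, rng),
        nn.BatchNorm1d(hidden),
        nn.GELU(),
        nn.Linear(hidden, k, rng, zero_init=zero_init_final),
    )


def make_estimator(k: int, hidden: int | None = None,
                   rng: np.random.Generator | None = None) -> nn.Module:
    """Scale estimator: feature vector -> log-variance of the magnitude draw.

    The final layer is zero-initialized so training starts at sigma = 1,
    i.e. zero KL penalty.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    return _two_layer_net(k, hidden or k, rng, zero_init_final=True)


def make_reconstructor(k: int, hidden: int | None = None,
                       rng: np.random.Generator | None = None) -> nn.Module:
    """Decoder: magnitude draw -> reconstructed feature vector."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return _two_layer_net(k, hidden or k, rng, zero_init_final=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sample_direction(batch_size: int, k: int, lam: float,
                     rng: np.random.Generator) -> DirectionMask:
    """Draw an elementwise Bernoulli(lam) direction mask of shape B x k."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    d = (rng.random((batch_size, k)) < lam).astype(np.float64)
    return DirectionMask(d)


def estimate_sigma(batch: FeatureBatch | np.ndarray | Tensor,
                   estimator: nn.Module) -> MagnitudeDistribution:
    """Run the estimator and map its log-variance output to sigma = exp(logvar/2)."""
    if isinstance(batch, FeatureBatch):
        x = Tensor(batch.features)
    elif isinstance(batch, Tensor):
        x = batch
    else:
        x = Tensor(np.asarray(batch, dtype=np.float64))
    if not np.all(np.isfinite(x.data)):
        raise ValueError("features contain non-finite entries")
    log_var = estimator(x)
    sigma = (log_var * 0.5).exp()
    return MagnitudeDistribution(sigma)


def sample_magnitude(sigma: MagnitudeDistribution | Tensor | np.ndarray,
                     rng: np.random.Generator) -> Tensor:
    """Reparameterized draw m = sigma * eps, eps ~ N(0, I).

    Gradients flow to sigma with d m / d sigma = eps.
    """
    if isinstance(sigma, MagnitudeDistribution):
        sigma = sigma.sigma
    elif not isinstance(sigma, Tensor):
        sigma = Tensor(np.asarray(sigma, dtype=np.float64))
    eps = rng.standard_normal(sigma.shape)
    return sigma * eps


def augment(batch: FeatureBatch | np.ndarray | Tensor,
            directions: DirectionMask | np.ndarray,
            magnitudes: Tensor | np.ndarray,
            mask_zero: bool = True):
    """a_tilde = a + [I[a != 0]] * d * m; returns the same kind as `magnitudes`.

    The zero indicator is an exact comparison: coordinates that are exactly
    zero in the input are never perturbed when ``mask_zero`` is set,
    preserving the sparsity pattern of post-activation features.
    """
    if isinstance(batch, FeatureBatch):
        a = batch.features
        a_tensor = None
    elif isinstance(batch, Tensor):
        a = batch.data
        a_tensor = batch
    else:
        a = np.asarray(batch, dtype=np.float64)
        a_tensor = None
    d = directions.d if isinstance(directions, DirectionMask) else np.asarray(directions, dtype=np.float64)
    m_data = magnitudes.data if isinstance(magnitudes, Tensor) else np.asarray(magnitudes, dtype=np.float64)
    if a.shape != d.shape or a.shape != m_data.shape:
        raise ValueError(
            f"shape mismatch: features {a.shape}, directions {d.shape}, magnitudes {m_data.shape}"
        )
    gate = d * (a != 0) if mask_zero else d
    if isinstance(magnitudes, Tensor) or a_tensor is not None:
        a_in = a_tensor if a_tensor is not None else Tensor(a)
        m_in = magnitudes if isinstance(magnitudes, Tensor) else Tensor(m_data)
        return a_in + m_in * gate
    return a + gate * m_data


def reconstruct(magnitudes: Tensor | np.ndarray, reconstructor: nn.Module) -> Tensor:
    """Decode a magnitude draw back into feature space."""
    m = magnitudes if isinstance(magnitudes, Tensor) else Tensor(np.asarray(magnitudes, dtype=np.float64))
    return reconstructor(m)


def _as_sigma_tensor(sigma) -> Tensor:
    if isinstance(sigma, MagnitudeDistribution):
        return sigma.sigma
    if isinstance(sigma, Tensor):
        t = sigma
    else:
        t = Tensor(np.asarray(sigma, dtype=np.float64))
    if np.any(t.data <= 0):
        raise ValueError("sigma must be strictly positive")
    return t


def kl_term(sigma) -> Tensor:
    """KL(N(0, sigma^2) || N(0, 1)), summed over dimensions, batch-averaged.

    Per dimension the closed form is 0.5 * (sigma^2 - 1 - log sigma^2) >= 0.
    """
    s = _as_sigma_tensor(sigma)
    if s.ndim != 2:
        raise ValueError("sigma must be a B x k matrix")
    s2 = s**2.0
    per_dim = (s2 - s2.log() - 1.0) * 0.5
    return per_dim.sum(axis=1).mean()


def recon_term(a_hat: Tensor | np.ndarray, a: np.ndarray | Tensor) -> Tensor:
    """Half the mean squared reconstruction error over all entries."""
    a_hat_t = a_hat if isinstance(a_hat, Tensor) else Tensor(np.asarray(a_hat, dtype=np.float64))
    a_t = a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))
    if a_hat_t.shape != a_t.shape:
        raise ValueError(f"shape mismatch: {a_hat_t.shape} vs {a_t.shape}")
    return ((a_hat_t - a_t) ** 2.0).mean() * 0.5


def bsda_loss(sigma, a_hat, batch: FeatureBatch | np.ndarray,
              use_recon: bool = True) -> Tensor:
    """Auxiliary loss: KL term plus (optionally) the reconstruction term."""
    loss = kl_term(sigma)
    if use_recon:
        a = batch.features if isinstance(batch, FeatureBatch) else batch
        loss = loss + recon_term(a_hat, a)
    return loss


def total_loss(task_loss_orig, task_loss_aug, bsda, alpha: float):
    """Combined objective: task loss plus alpha-weighted augmented branch."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return task_loss_orig + alpha * (bsda + task_loss_aug)


def alpha_schedule(epoch: int, config: BSDAConfig) -> float:
    """Linear ramp 0 -> alpha_max over the warm-up epochs, then constant."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    warmup = config.alpha_warmup_epochs
    if warmup == 0 or epoch >= warmup:
        return float(config.alpha_max)
    return float(config.alpha_max) * epoch / warmup


# ---------------------------------------------------------------------------
# module wrapper
# ---------------------------------------------------------------------------


class BSDAModule(nn.Module):
    """Owns the estimator/reconstructor pair and the per-step sampling logic.

    With ``fixed_sigma`` set no networks are built; the magnitude scale is a
    constant and the KL/reconstruction terms are zero (the random-noise
    ablation).
    """

    def __init__(self, config: BSDAConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        init_rng = rng if rng is not None else np.random.default_rng(config.seed)
        if config.fixed_sigma is None:
            self.estimator = make_estimator(config.feature_dim, config.hidden_dim, init_rng)
            self.reconstructor = make_reconstructor(config.feature_dim, config.hidden_dim, init_rng)
        else:
            self.estimator = None
            self.reconstructor = None

    def sigma_for(self, features: Tensor) -> Tensor:
        if self.config.fixed_sigma is not None:
            return Tensor(np.full(features.shape, float(self.config.fixed_sigma)))
        return estimate_sigma(features, self.estimator).sigma

    def augment_copies(self, features: Tensor, sigma: Tensor,
                       rng: np.random.Generator) -> tuple[list[Tensor], list[Tensor]]:
        """Draw U augmented copies; each has an independent (d, eps) pair.

        The U copies share sigma; the zero indicator depends only on the
        input features so it is shared too.
        """
        cfg = self.config
        copies: list[Tensor] = []
        magnitudes: list[Tensor] = []
        b, k = features.shape
        for _ in range(cfg.num_samples):
            d = sample_direction(b, k, cfg.lam, rng)
            m = sample_magnitude(sigma, rng)
            copies.append(augment(features, d, m, mask_zero=cfg.mask_zero))
            magnitudes.append(m)
        return copies, magnitudes

    def loss(self, sigma: Tensor, magnitudes: list[Tensor],
             features: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """(bsda, kl, recon); recon is averaged over the U magnitude draws."""
        zero = Tensor(0.0)
        if self.config.fixed_sigma is not None:
            return zero, zero, zero
        kl = kl_term(sigma)
        recon = zero
        if self.config.use_recon:
            terms = [recon_term(reconstruct(m, self.reconstructor), features)
                     for m in magnitudes]
            acc = terms[0]
            for t in terms[1:]:
                acc = acc + t
            recon = acc * (1.0 / len(terms))
        return kl + recon, kl, recon

    def draw(self, batch: FeatureBatch, rng: np.random.Generator) -> AugmentedBatch:
        """Detached U x B x k draw for analysis and visualization."""
        cfg = self.config
        features = Tensor(batch.features)
        if self.estimator is not None:
            self.estimator.eval()
        sigma = self.sigma_for(features)
        b, k = batch.features.shape
        out = np.empty((cfg.num_samples, b, k))
        mags = np.empty_like(out)
        dirs = np.empty_like(out)
        for u in range(cfg.num_samples):
            d = sample_direction(b, k, cfg.lam, rng)
            m = sample_magnitude(sigma.detach(), rng)
            out[u] = augment(batch.features, d, m.data, mask_zero=cfg.mask_zero)
            mags[u] = m.data
            dirs[u] = d.d
        return AugmentedBatch(augmented=out, magnitudes=mags, directions=dirs)
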