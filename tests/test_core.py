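"""Unit and property tests for the augmentation core."""

import numpy as np
import pytest
from scipy import integrate, stats

from bsda import nn
from bsda.core import (
    BSDAConfig,
    BSDAModule,
    FeatureBatch,
    MagnitudeDistribution,
    alpha_schedule,
    augment,
    bsda_loss,
    estimate_sigma,
    kl_term,
    make_estimator,
    make_reconstructor,
    recon_term,
    reconstruct,
    sample_direction,
    sample_magnitude,
    total_loss,
)
from bsda.nn import Tensor


def kl_numeric(sigma: float) -> float:
    """Independent oracle: numerical integration of KL(N(0, s^2) || N(0, 1))."""
    q = stats.norm(0.0, sigma)
    p = stats.norm(0.0, 1.0)

    def integrand(x):
        qx = q.pdf(x)
        return qx * (q.logpdf(x) - p.logpdf(x)) if qx > 0 else 0.0

    lim = max(10.0, 10.0 * sigma)
    value, _ = integrate.quad(integrand, -lim, lim, limit=200)
    return value


# ---------------------------------------------------------------------------
# sample_direction
# ---------------------------------------------------------------------------


def test_direction_lambda_zero_is_all_zeros(rng):
    assert not sample_direction(2, 3, 0.0, rng).d.any()


def test_direction_lambda_one_is_all_ones(rng):
    assert sample_direction(2, 3, 1.0, rng).d.all()


def test_direction_mean_matches_lambda(rng):
    d = sample_direction(1, 10**5, 0.5, rng).d
    assert abs(d.mean() - 0.5) < 0.01  # 3-sigma binomial band is ~0.005


@pytest.mark.parametrize("lam", [-0.1, 1.5])
def test_direction_lambda_out_of_range(rng, lam):
    with pytest.raises(ValueError):
        sample_direction(2, 3, lam, rng)


def test_direction_deterministic_given_rng_state():
    a = sample_direction(5, 7, 0.3, np.random.default_rng(9)).d
    b = sample_direction(5, 7, 0.3, np.random.default_rng(9)).d
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# estimate_sigma
# ---------------------------------------------------------------------------


def test_sigma_is_one_at_zero_init(rng):
    est = make_estimator(8, rng=rng)
    batch = FeatureBatch(rng.normal(size=(5, 8)), rng.integers(0, 2, 5))
    sigma = estimate_sigma(batch, est).sigma.data
    assert np.allclose(sigma, 1.0)


def test_sigma_positive_and_finite_for_random_estimator(rng):
    est = make_estimator(8, rng=rng)
    for p in est.parameters():
        p.data += rng.normal(0, 1.0, p.data.shape)
    sigma = estimate_sigma(rng.normal(size=(20, 8)), est).sigma.data
    assert np.all(np.isfinite(sigma)) and np.all(sigma > 0)


def test_sigma_rejects_nonfinite_features(rng):
    est = make_estimator(4, rng=rng)
    x = rng.normal(size=(3, 4))
    x[1, 2] = np.nan
    with pytest.raises(ValueError):
        estimate_sigma(x, est)


def test_sigma_rejects_width_mismatch(rng):
    est = make_estimator(4, rng=rng)
    with pytest.raises(ValueError):
        estimate_sigma(rng.normal(size=(3, 6)), est)


def test_kl_only_training_recovers_unit_sigma(rng):
    est = make_estimator(8, rng=np.random.default_rng(2))
    for p in est.parameters():
        p.data += rng.normal(0, 0.5, p.data.shape)
    x = rng.normal(size=(64, 8))
    opt = nn.AdamW(est.parameters(), lr=1e-2)
    for _ in range(300):
        loss = kl_term(estimate_sigma(x, est).sigma)
        opt.zero_grad()
        loss.backward()
        opt.step()
    sigma = estimate_sigma(x, est).sigma.data
    assert abs(sigma.mean() - 1.0) < 0.05


# ---------------------------------------------------------------------------
# sample_magnitude
# ---------------------------------------------------------------------------


def test_magnitude_zero_sigma_limit(rng):
    m = sample_magnitude(np.zeros((3, 4)), rng)
    assert not m.data.any()


def test_magnitude_unit_variance(rng):
    m = sample_magnitude(np.ones((10**5, 1)), rng)
    assert abs(m.data.var() - 1.0) < 0.02  # 3-sigma chi^2 band ~0.0135


def test_magnitude_deterministic_given_rng_state():
    a = sample_magnitude(np.full((4, 4), 0.7), np.random.default_rng(5)).data
    b = sample_magnitude(np.full((4, 4), 0.7), np.random.default_rng(5)).data
    assert np.array_equal(a, b)


def test_magnitude_reparameterization_gradient():
    sigma = Tensor(np.full((1, 1), 1.7), requires_grad=True)
    eps_rng = np.random.default_rng(3)
    m = sample_magnitude(sigma * np.ones((10**5, 1)), eps_rng)
    (m**2.0).mean().backward()
    # pathwise d E[m^2] / d sigma should match the analytic 2*sigma within 5%
    assert abs(sigma.grad[0, 0] - 2 * 1.7) / (2 * 1.7) < 0.05


# ---------------------------------------------------------------------------
# augment
# ---------------------------------------------------------------------------


def test_augment_indicator_masks_zero_coordinate():
    a = np.array([[1.0, 0.0, 2.0]])
    d = np.ones((1, 3))
    m = np.full((1, 3), 0.5)
    assert np.array_equal(augment(a, d, m, mask_zero=True), [[1.5, 0.0, 2.5]])


def test_augment_without_indicator():
    a = np.array([[1.0, 0.0, 2.0]])
    d = np.ones((1, 3))
    m = np.full((1, 3), 0.5)
    assert np.array_equal(augment(a, d, m, mask_zero=False), [[1.5, 0.5, 2.5]])


def test_augment_zero_directions_is_identity(rng):
    a = rng.normal(size=(6, 5))
    out = augment(a, np.zeros((6, 5)), rng.normal(size=(6, 5)), mask_zero=True)
    assert np.array_equal(out, a)


def test_augment_does_not_modify_input(rng):
    a = rng.normal(size=(3, 4))
    snapshot = a.copy()
    augment(a, np.ones((3, 4)), rng.normal(size=(3, 4)))
    assert np.array_equal(a, snapshot)


def test_augment_shape_mismatch(rng):
    with pytest.raises(ValueError):
        augment(rng.normal(size=(3, 4)), np.ones((3, 5)), np.ones((3, 4)))


def test_zero_preservation_under_many_draws(rng):
    a = rng.normal(size=(8, 16))
    a[a < 0] = 0.0
    zeros = a == 0
    for _ in range(100):
        d = sample_direction(8, 16, rng.uniform(0, 1), rng)
        m = sample_magnitude(np.full((8, 16), rng.uniform(0.1, 4.0)), rng)
        out = augment(a, d, m.data, mask_zero=True)
        assert np.array_equal(out[zeros], np.zeros(zeros.sum()))


def test_augment_first_and_second_moment(rng):
    # Var(a_tilde - a) = lambda * sigma^2 elementwise for nonzero features
    n = 10**5
    sigma, lam = 1.0, 0.5
    a = np.ones((n, 1))
    d = sample_direction(n, 1, lam, rng).d
    m = sample_magnitude(np.full((n, 1), sigma), rng).data
    delta = augment(a, d, m) - a
    se_mean = np.sqrt(lam * sigma**2 / n)
    assert abs(delta.mean()) < 3 * se_mean
    target_var = lam * sigma**2
    # kurtosis of d*eps makes the variance SE larger than the Gaussian one
    se_var = np.sqrt((3 * lam - lam**2 * 1.0) * sigma**4 / n)
    assert abs(delta.var() - target_var) < 3 * se_var


# ---------------------------------------------------------------------------
# reconstruct / losses
# ---------------------------------------------------------------------------


def test_reconstruct_shape_and_finiteness(rng):
    recon = make_reconstructor(6, rng=rng)
    out = reconstruct(np.zeros((4, 6)), recon).data
    assert out.shape == (4, 6) and np.all(np.isfinite(out))


def test_reconstruct_eval_mode_deterministic(rng):
    recon = make_reconstructor(5, rng=rng)
    recon.eval()
    m = np.vstack([np.ones((1, 5)), np.ones((1, 5))])
    out = reconstruct(m, recon).data
    assert np.array_equal(out[0], out[1])


def test_reconstruct_width_mismatch(rng):
    recon = make_reconstructor(5, rng=rng)
    with pytest.raises(ValueError):
        reconstruct(np.zeros((2, 7)), recon)


def test_trained_reconstructor_beats_mean_baseline(rng):
    # after joint optimization, MSE(a_hat, a) < MSE(batch mean, a) on train data
    k = 8
    a = rng.normal(size=(64, k)) + 3.0 * rng.integers(0, 2, size=(64, 1))
    est = make_estimator(k, rng=np.random.default_rng(0))
    recon = make_reconstructor(k, rng=np.random.default_rng(1))
    opt = nn.AdamW(est.parameters() + recon.parameters(), lr=1e-2)
    draw_rng = np.random.default_rng(2)
    for _ in range(400):
        sigma = estimate_sigma(a, est).sigma
        m = sample_magnitude(sigma, draw_rng)
        loss = kl_term(sigma) + recon_term(reconstruct(m, recon), a)
        opt.zero_grad()
        loss.backward()
        opt.step()
    est.eval()
    recon.eval()
    sigma = estimate_sigma(a, est).sigma
    a_hat = reconstruct(sample_magnitude(sigma, draw_rng), recon).data
    mse_model = ((a_hat - a) ** 2).mean()
    mse_const = ((a.mean(axis=0) - a) ** 2).mean()
    assert mse_model < mse_const


@pytest.mark.parametrize("sigma", [0.25, 0.5, 1.0, 2.0, 4.0])
def test_kl_matches_numeric_oracle(sigma):
    got = kl_term(np.full((1, 1), sigma)).item()
    assert got == pytest.approx(kl_numeric(sigma), abs=1e-6)


def test_kl_zero_at_unit_sigma():
    assert kl_term(np.ones((3, 4))).item() == 0.0


def test_kl_example_sigma_squared_e():
    got = kl_term(np.full((1, 1), np.sqrt(np.e))).item()
    assert got == pytest.approx(0.5 * (np.e - 2.0), abs=1e-12)
    assert got == pytest.approx(0.35914, abs=1e-5)


def test_kl_strictly_positive_off_unit(rng):
    sigma = np.exp(rng.normal(size=(5, 3)) * 0.5)
    sigma[np.isclose(sigma, 1.0)] = 1.3
    assert kl_term(sigma).item() > 0


def test_kl_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        kl_term(np.array([[1.0, -0.5]]))


def test_kl_batch_size_invariant(rng):
    row = np.exp(rng.normal(size=(1, 6)) * 0.3)
    tiled = np.tile(row, (10, 1))
    assert kl_term(tiled).item() == pytest.approx(kl_term(row).item(), rel=1e-12)


def test_recon_term_examples():
    a = np.zeros((1, 2))
    assert recon_term(a, a).item() == 0.0
    assert recon_term(a + 2.0, a).item() == pytest.approx(2.0)
    assert recon_term(np.array([[1.0, 3.0]]), np.array([[0.0, 0.0]])).item() == pytest.approx(2.5)


def test_recon_term_shape_mismatch():
    with pytest.raises(ValueError):
        recon_term(np.zeros((2, 3)), np.zeros((3, 2)))


def test_bsda_loss_examples(rng):
    a = rng.normal(size=(2, 3))
    assert bsda_loss(np.ones((2, 3)), a, a, use_recon=True).item() == 0.0
    a_hat = a + rng.normal(size=(2, 3))
    assert bsda_loss(np.ones((2, 3)), a_hat, a, use_recon=False).item() == 0.0
    got = bsda_loss(np.full((1, 1), np.sqrt(np.e)), a[:1, :1], a[:1, :1]).item()
    assert got == pytest.approx(0.35914, abs=1e-5)


def test_total_loss_examples():
    assert total_loss(1.3, 99.0, 99.0, alpha=0.0) == 1.3
    assert total_loss(1.0, 2.0, 0.5, alpha=0.5) == pytest.approx(2.25)
    with pytest.raises(ValueError):
        total_loss(1.0, 1.0, 1.0, alpha=-0.1)


def test_default_alpha_max_is_half():
    assert BSDAConfig(feature_dim=4).alpha_max == 0.5


def test_alpha_schedule():
    cfg = BSDAConfig(feature_dim=4, alpha_max=0.5, alpha_warmup_epochs=5)
    assert alpha_schedule(0, cfg) == 0.0
    assert alpha_schedule(5, cfg) == 0.5
    assert alpha_schedule(17, cfg) == 0.5
    assert alpha_schedule(2, cfg) == pytest.approx(0.2)
    values = [alpha_schedule(e, cfg) for e in range(10)]
    assert all(b >= a for a, b in zip(values, values[1:]))
    no_warmup = BSDAConfig(feature_dim=4, alpha_max=0.5, alpha_warmup_epochs=0)
    assert alpha_schedule(0, no_warmup) == 0.5


# ---------------------------------------------------------------------------
# gradient flow / ablation semantics / determinism
# ---------------------------------------------------------------------------


def test_estimator_parameters_receive_gradient_through_bsda_loss(rng):
    k = 6
    est = make_estimator(k, rng=np.random.default_rng(4))
    for p in est.parameters():
        p.data += rng.normal(0, 0.3, p.data.shape)
    recon = make_reconstructor(k, rng=np.random.default_rng(5))
    a = rng.normal(size=(8, k))
    draw = np.random.default_rng(6)

    def loss_value():
        sigma = estimate_sigma(a, est).sigma
        m = sample_magnitude(sigma, np.random.default_rng(7))
        return bsda_loss(MagnitudeDistribution(sigma), reconstruct(m, recon), a)

    loss = loss_value()
    for p in est.parameters():
        p.zero_grad()
    loss.backward()
    grads = [p.grad for p in est.parameters()]
    assert any(g is not None and np.abs(g).max() > 0 for g in grads)
    # finite-difference cross-check on one parameter entry
    p = est.parameters()[0]
    idx = np.unravel_index(np.abs(p.grad).argmax(), p.grad.shape)
    h = 1e-6
    p.data[idx] += h
    up = loss_value().item()
    p.data[idx] -= 2 * h
    down = loss_value().item()
    p.data[idx] += h
    assert abs((up - down) / (2 * h) - p.grad[idx]) < 1e-6


def test_random_noise_ablation_matches_direct_gaussian(rng):
    # fixed_sigma=1, no recon, no estimator: a + d*eps distributionally
    n = 10**4
    cfg = BSDAConfig(feature_dim=1, lam=0.5, fixed_sigma=1.0, use_recon=False,
                     mask_zero=False, seed=0)
    module = BSDAModule(cfg)
    batch = FeatureBatch(np.full((n, 1), 0.7), np.zeros(n, dtype=int), num_classes=2)
    drawn = module.draw(batch, np.random.default_rng(21)).augmented[0, :, 0]
    ref_rng = np.random.default_rng(22)
    d = (ref_rng.random(n) < 0.5).astype(float)
    reference = 0.7 + d * ref_rng.standard_normal(n)
    stat = stats.ks_2samp(drawn, reference)
    assert stat.pvalue > 0.01


def test_fixed_sigma_zero_is_identity(rng):
    cfg = BSDAConfig(feature_dim=4, lam=1.0, fixed_sigma=0.0, use_recon=False)
    module = BSDAModule(cfg)
    batch = FeatureBatch(rng.normal(size=(5, 4)), rng.integers(0, 2, 5))
    drawn = module.draw(batch, np.random.default_rng(0))
    assert np.array_equal(drawn.augmented[0], batch.features)


def test_lambda_zero_is_identity(rng):
    cfg = BSDAConfig(feature_dim=4, lam=0.0)
    module = BSDAModule(cfg)
    batch = FeatureBatch(rng.normal(size=(5, 4)), rng.integers(0, 2, 5))
    drawn = module.draw(batch, np.random.default_rng(0))
    assert np.array_equal(drawn.augmented[0], batch.features)


def test_seeded_module_is_deterministic(rng):
    batch = FeatureBatch(rng.normal(size=(6, 8)), rng.integers(0, 3, 6))
    outputs = []
    losses = []
    for _ in range(2):
        cfg = BSDAConfig(feature_dim=8, lam=0.5, seed=42)
        module = BSDAModule(cfg)
        draw_rng = np.random.default_rng(cfg.seed)
        drawn = module.draw(batch, draw_rng)
        sigma = estimate_sigma(batch.features, module.estimator).sigma
        m = sample_magnitude(sigma, np.random.default_rng(cfg.seed))
        loss = bsda_loss(sigma, reconstruct(m, module.reconstructor).data,
                         batch.features)
        outputs.append(drawn.augmented)
        losses.append(loss.item())
    assert np.array_equal(outputs[0], outputs[1])
    assert losses[0] == losses[1]


def test_augmented_batch_shapes(rng):
    cfg = BSDAConfig(feature_dim=5, num_samples=3)
    module = BSDAModule(cfg)
    batch = FeatureBatch(np.abs(rng.normal(size=(4, 5))), rng.integers(0, 2, 4))
    drawn = module.draw(batch, np.random.default_rng(1))
    assert drawn.augmented.shape == (3, 4, 5)
    expected = batch.features + (batch.features != 0) * drawn.directions * drawn.magnitudes
    assert np.allclose(drawn.augmented, expected)
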