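"""Loss closed forms, per-step parameter isolation, and loop determinism."""

import numpy as np
import pytest

from chemaae.chem_io import N_BITS
from chemaae.model import ModelConfig, init_model
from chemaae.training import (
    TrainConfig,
    adversarial_losses,
    fit,
    gi_regression_loss,
    manifold_loss,
    manifold_loss_from_representations,
    reconstruction_loss,
    train_iteration,
)

LN2 = np.log(2.0)


class TestReconstructionLoss:
    def test_uniform_probabilities_give_166_ln2(self):
        bits = np.random.default_rng(0).integers(0, 2, N_BITS)
        loss = reconstruction_loss(np.full(N_BITS, 0.5), np.array([-6.0]), bits, np.array([-6.0]))
        assert loss == pytest.approx(166 * LN2, abs=1e-6)

    def test_confident_correct_probabilities(self):
        bits = np.zeros(N_BITS)
        bits[:83] = 1
        probs = np.where(bits == 1, 0.9, 0.1)
        loss = reconstruction_loss(probs, np.array([0.0]), bits, np.array([0.0]))
        assert loss == pytest.approx(-166 * np.log(0.9), abs=1e-6)

    def test_clamped_perfect_probs_plus_lconc_error(self):
        eps = 1e-7
        bits = np.random.default_rng(1).integers(0, 2, N_BITS).astype(float)
        loss = reconstruction_loss(bits, np.array([-4.0]), bits, np.array([-6.0]), eps=eps)
        assert loss == pytest.approx(-166 * np.log(1 - eps) + 4.0, abs=1e-6)

    def test_batch_mean_semantics(self):
        bits = np.vstack([np.zeros(N_BITS), np.ones(N_BITS)])
        probs = np.full((2, N_BITS), 0.5)
        loss = reconstruction_loss(probs, np.array([0.0, 2.0]), bits, np.array([0.0, 0.0]))
        assert loss == pytest.approx(166 * LN2 + 2.0, abs=1e-6)


class TestGiRegressionLoss:
    def test_exact_prediction_is_zero(self):
        assert gi_regression_loss(np.array([3.0]), np.array([3.0])) == 0.0

    def test_squared_error(self):
        assert gi_regression_loss(np.array([2.0]), np.array([-1.0])) == pytest.approx(9.0)

    def test_batch_mean_of_squares(self):
        assert gi_regression_loss(np.array([1.0, 3.0]), np.array([0.0, 0.0])) == pytest.approx(5.0)


class TestManifoldLoss:
    def test_identical_representations_loss_zero(self):
        reps = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        assert manifold_loss_from_representations(reps) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_pair_loss_one(self):
        reps = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        assert manifold_loss_from_representations(reps) == pytest.approx(1.0, abs=1e-6)

    def test_antiparallel_pair_loss_two(self):
        reps = np.array([[1.0, 0, 0, 0], [-1.0, 0, 0, 0]])
        assert manifold_loss_from_representations(reps) == pytest.approx(2.0, abs=1e-6)

    def test_encoder_ignoring_lconc_gives_zero_loss(self):
        """Zeroing the LCONC input row makes all representations identical."""
        p = init_model(ModelConfig(seed=0))
        p.encoder.W[0][N_BITS, :] = 0.0
        fp = np.random.default_rng(0).integers(0, 2, N_BITS).astype(np.uint8)
        draws = np.random.default_rng(1).normal(-6, 1.2, 8)
        assert manifold_loss(p, fp, draws) == pytest.approx(0.0, abs=1e-9)


class TestAdversarialLosses:
    def test_constant_half_discriminator_gives_ln2(self):
        p = init_model(ModelConfig(seed=0))
        p.discriminator.W[-1][:] = 0.0
        p.discriminator.b[-1][:] = 0.0
        rng = np.random.default_rng(0)
        d_loss, g_loss = adversarial_losses(p, rng.normal(size=(16, 4)), rng.normal(size=(16, 4)))
        assert d_loss == pytest.approx(LN2, abs=1e-6)
        assert g_loss == pytest.approx(LN2, abs=1e-6)

    def test_perfect_discriminator_limit(self):
        """Saturated output layer: near-zero d_loss, large g_loss."""
        p = init_model(ModelConfig(seed=0))
        # map the first input coordinate through with a huge weight
        for i in range(p.discriminator.n_layers - 1):
            p.discriminator.W[i][:] = 0.0
            p.discriminator.b[i][:] = 0.0
            p.discriminator.W[i][0, 0] = 1.0
        p.discriminator.W[-1][:] = 0.0
        p.discriminator.W[-1][0, 0] = 1e4
        p.discriminator.b[-1][:] = 0.0
        prior = np.full((8, 4), 1.0)
        encoded = np.full((8, 4), -1.0)
        d_loss, g_loss = adversarial_losses(p, encoded, prior)
        assert d_loss == pytest.approx(0.0, abs=1e-3)
        assert g_loss > 5.0


@pytest.fixture
def iteration_setup(tiny_set):
    params = init_model(ModelConfig(seed=0), norm_stats=tiny_set.norm_stats)
    batch = (tiny_set.X[:16], tiny_set.lconc[:16], tiny_set.gi[:16])
    return params, batch


ZERO_LRS = dict(lr_discriminator=0.0, lr_confusion=0.0, lr_reconstruction=0.0,
                lr_gi=0.0, lr_manifold=0.0)


class TestStepIsolation:
    """Each of the five updates touches exactly its contracted parameter group."""

    @pytest.mark.parametrize(
        "active_lr, expected_changed",
        [
            ("lr_discriminator", {"discriminator"}),
            ("lr_confusion", {"encoder"}),
            ("lr_reconstruction", {"encoder", "decoder"}),
            ("lr_gi", {"encoder"}),
            ("lr_manifold", {"encoder"}),
        ],
    )
    def test_single_step_parameter_diffs(self, iteration_setup, active_lr, expected_changed):
        params, (X, lc, gi) = iteration_setup
        cfg = TrainConfig(epochs=1, **{**ZERO_LRS, active_lr: 1e-3})
        before = params.snapshot()
        train_iteration(params, X, lc, gi, cfg, np.random.default_rng(0))
        after = params.snapshot()
        changed = {k for k in before if not np.array_equal(before[k], after[k])}
        assert changed == expected_changed

    def test_zero_learning_rates_leave_parameters_unchanged(self, iteration_setup):
        params, (X, lc, gi) = iteration_setup
        cfg = TrainConfig(epochs=1, **ZERO_LRS)
        before = params.snapshot()
        losses = train_iteration(params, X, lc, gi, cfg, np.random.default_rng(0))
        after = params.snapshot()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert set(losses) == {"d_loss", "g_loss", "recon_loss", "gi_loss", "manifold_loss"}
        assert all(np.isfinite(v) for v in losses.values())

    def test_fixed_seed_fixed_minibatch_is_deterministic(self, iteration_setup):
        params, (X, lc, gi) = iteration_setup
        import copy

        p1 = copy.deepcopy(params)
        p2 = copy.deepcopy(params)
        cfg = TrainConfig(epochs=1)
        l1 = train_iteration(p1, X, lc, gi, cfg, np.random.default_rng(11))
        l2 = train_iteration(p2, X, lc, gi, cfg, np.random.default_rng(11))
        assert l1 == l2
        s1, s2 = p1.snapshot(), p2.snapshot()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)


class TestFit:
    def test_zero_epochs_returns_params_unchanged(self, tiny_set):
        params = init_model(ModelConfig(seed=0), norm_stats=tiny_set.norm_stats)
        before = params.snapshot()
        params, log = fit(tiny_set, params, TrainConfig(epochs=0))
        after = params.snapshot()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert len(log.epochs) == 0

    def test_same_seeds_identical_train_log(self, tiny_set):
        cfg = TrainConfig(epochs=3, batch_size=16, seed=9)
        p1 = init_model(ModelConfig(seed=1), norm_stats=tiny_set.norm_stats)
        p2 = init_model(ModelConfig(seed=1), norm_stats=tiny_set.norm_stats)
        _, log1 = fit(tiny_set, p1, cfg)
        _, log2 = fit(tiny_set, p2, cfg)
        assert log1.to_frame().equals(log2.to_frame())

    def test_log_has_one_row_per_epoch_all_finite(self, tiny_set):
        params = init_model(ModelConfig(seed=2), norm_stats=tiny_set.norm_stats)
        _, log = fit(tiny_set, params, TrainConfig(epochs=4, batch_size=16, seed=0))
        df = log.to_frame()
        assert len(df) == 4
        assert np.isfinite(df[["d_loss", "g_loss", "recon_loss", "gi_loss", "manifold_loss"]]).all().all()


class TestManifoldGradient:
    def test_cosine_gradient_matches_finite_differences(self):
        from chemaae.training import _cosine_stats

        rng = np.random.default_rng(5)
        reps = rng.normal(size=(2, 4, 3))
        _, grad = _cosine_stats(reps.copy())
        h = 1e-6
        for idx in [(0, 0, 1), (1, 2, 0), (0, 3, 2)]:
            up = reps.copy()
            up[idx] += h
            down = reps.copy()
            down[idx] -= h
            num = (_cosine_stats(up)[0] - _cosine_stats(down)[0]) / (2 * h)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)
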