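"""Loss, backpropagation, optimizers and the fit loop."""

import numpy as np
import pytest

import stresslstm as sl
from stresslstm.model import is_bias
from stresslstm.training import (
    TrainingConfig,
    adam_step,
    bce_l2_loss,
    finite_difference_gradients,
    fit,
    gradients,
    init_moments,
    sgd_step,
)

from conftest import perturbed_params, zeroed_params


def gradcheck_problem(seed=7):
    rng = np.random.default_rng(seed)
    params = perturbed_params(T=4, n=3, seed=11)
    X = rng.normal(size=(5, 4, 1))
    y = rng.integers(0, 2, 5).astype(float)
    return params, X, y


class TestLoss:
    def test_maximal_uncertainty_equals_ln2(self):
        assert bce_l2_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_perfect_prediction_is_near_zero(self):
        assert bce_l2_loss([1.0], [1.0 - 1e-7]) == pytest.approx(0.0, abs=1e-6)
        assert bce_l2_loss([1.0], [1.0]) < 1e-6  # clipped, stays finite

    def test_l2_penalty_adds_exact_weight_term(self):
        params = sl.init_params(T=3, n=2, m=1, seed=0)
        twos = {
            name: np.full_like(np.asarray(a), 2.0)
            for name, a in params.named_arrays()
        }
        params = params.replace_arrays(twos)
        n_weights = sum(
            np.asarray(a).size for name, a in params.named_arrays() if not is_bias(name)
        )
        base = bce_l2_loss([1, 0], [0.5, 0.5])
        full = bce_l2_loss([1, 0], [0.5, 0.5], params, l2=1e-5)
        assert full - base == pytest.approx(4e-5 * n_weights, rel=1e-10)

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            bce_l2_loss([], [])


class TestGradients:
    def test_analytic_matches_central_differences(self):
        """Backpropagation through the full architecture agrees with
        central differences (step 1e-6) to relative 1e-5; components below
        the finite-difference resolution (~1e-10 in float64) are compared
        absolutely at 1e-9."""
        params, X, y = gradcheck_problem()
        cfg = TrainingConfig(l2=1e-5, dropout_rate=0.0)
        g = gradients((X, y), params, cfg)
        ref = finite_difference_gradients((X, y), params, cfg, step=1e-6)
        for name in g:
            a, n = g[name].ravel(), ref[name].ravel()
            excess = np.abs(a - n) - 1e-5 * np.maximum(np.abs(a), np.abs(n))
            assert excess.max() <= 1e-9, name

    def test_gradcheck_with_multi_step_decoder(self):
        params, X, y = gradcheck_problem(seed=21)
        cfg = TrainingConfig(l2=0.0, dropout_rate=0.0, decoder_steps=2)
        g = gradients((X, y), params, cfg)
        ref = finite_difference_gradients((X, y), params, cfg, step=1e-6)
        for name in g:
            a, n = g[name].ravel(), ref[name].ravel()
            excess = np.abs(a - n) - 1e-5 * np.maximum(np.abs(a), np.abs(n))
            assert excess.max() <= 1e-9, name

    def test_head_bias_gradient_closed_form_at_zero_weights(self):
        """With all-zero parameters every probability is 0.5, so the head
        bias gradient is mean(0.5 - y)."""
        params = zeroed_params(T=4, n=3)
        y = np.array([1.0, 0.0, 0.0, 1.0, 1.0])
        X = np.zeros((5, 4, 1))
        g = gradients((X, y), params, TrainingConfig(l2=0.0, dropout_rate=0.0))
        assert g["head.b"] == pytest.approx(np.mean(0.5 - y), abs=1e-12)

    def test_l2_shifts_weight_gradients_by_2_lambda_w(self):
        params, X, y = gradcheck_problem()
        g0 = gradients((X, y), params, TrainingConfig(l2=0.0, dropout_rate=0.0))
        g1 = gradients((X, y), params, TrainingConfig(l2=1e-3, dropout_rate=0.0))
        arrays = dict(params.named_arrays())
        for name in g0:
            expected = 0.0 if is_bias(name) else 2e-3 * np.asarray(arrays[name])
            np.testing.assert_allclose(g1[name] - g0[name], expected, atol=1e-12)

    def test_empty_batch_raises(self):
        params = perturbed_params()
        with pytest.raises(ValueError):
            gradients((np.zeros((0, 4, 1)), np.zeros(0)), params, TrainingConfig())


class TestOptimizers:
    def test_zero_gradients_leave_params_unchanged(self):
        params = perturbed_params()
        zeros = {name: np.zeros_like(np.asarray(a)) for name, a in params.named_arrays()}
        new, _ = adam_step(params, zeros, init_moments(params), TrainingConfig(), t=1)
        for (name, a), (_, b) in zip(params.named_arrays(), new.named_arrays()):
            np.testing.assert_array_equal(a, b, err_msg=name)

    def test_adam_first_step_has_learning_rate_magnitude(self):
        """Adam's bias-corrected first step is ~lr * sign(gradient)."""
        params = perturbed_params()
        grads = {
            name: np.full_like(np.asarray(a), 0.5) for name, a in params.named_arrays()
        }
        cfg = TrainingConfig(learning_rate=0.01)
        new, _ = adam_step(params, grads, init_moments(params), cfg, t=1)
        for (name, a), (_, b) in zip(params.named_arrays(), new.named_arrays()):
            np.testing.assert_allclose(np.abs(b - a), 0.01, rtol=1e-6, err_msg=name)

    def test_sgd_step_is_plain_descent(self):
        params = perturbed_params()
        grads = {name: np.ones_like(np.asarray(a)) for name, a in params.named_arrays()}
        new = sgd_step(params, grads, TrainingConfig(learning_rate=0.1))
        for (name, a), (_, b) in zip(params.named_arrays(), new.named_arrays()):
            np.testing.assert_allclose(np.asarray(a) - b, 0.1, atol=1e-12, err_msg=name)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            TrainingConfig(optimizer="adagrad")

    def test_presets_reproduce_published_settings(self):
        c1 = TrainingConfig.preset(1)
        assert (c1.learning_rate, c1.batch_size, c1.dropout_rate) == (0.0005, 768, 0.2)
        assert (c1.epochs, c1.momentum, c1.l2) == (150, 0.1, 1e-5)
        c2 = TrainingConfig.preset(2)
        assert (c2.learning_rate, c2.batch_size, c2.dropout_rate) == (0.0003, 1024, 0.3)
        assert (c2.epochs, c2.momentum) == (100, 0.0)


@pytest.fixture(scope="module")
def small_cohort():
    return sl.generate_cohort(sl.separable_spec(80, 80), seed=5)


class TestFit:

    def test_zero_epochs_returns_initialization(self, small_cohort):
        cfg = TrainingConfig(epochs=0, n_hidden=4)
        res = fit(small_cohort, cfg, seed=3)
        init = sl.init_params(T=11, n=4, m=1, seed=_init_seed_for(3))
        for (name, a), (_, b) in zip(res.params.named_arrays(), init.named_arrays()):
            np.testing.assert_array_equal(a, b, err_msg=name)
        assert len(res.history) == 0

    def test_same_seed_reproduces_run_exactly(self, small_cohort):
        cfg = TrainingConfig(epochs=3, n_hidden=4, batch_size=32, learning_rate=0.01)
        r1 = fit(small_cohort, cfg, seed=9)
        r2 = fit(small_cohort, cfg, seed=9)
        assert r1.history.to_dict() == r2.history.to_dict()
        for (name, a), (_, b) in zip(r1.params.named_arrays(), r2.params.named_arrays()):
            np.testing.assert_array_equal(a, b, err_msg=name)

    def test_single_class_cohort_raises(self, small_cohort):
        with pytest.raises(ValueError):
            fit(small_cohort[small_cohort["stress"] == "low"], TrainingConfig(epochs=1))

    def test_split_is_stratified_and_disjoint(self, small_cohort):
        res = fit(small_cohort, TrainingConfig(epochs=0, val_fraction=0.2), seed=1)
        assert set(res.train_index) & set(res.val_index) == set()
        assert len(res.train_index) + len(res.val_index) == len(small_cohort)
        y = (small_cohort["stress"] == "high").to_numpy()
        val_rate = y[res.val_index].mean()
        assert val_rate == pytest.approx(0.5, abs=0.05)

    def test_loss_nonincreasing_without_regularization(self, small_cohort):
        """Full-batch training on a separable cohort, no dropout and no
        penalty: the epoch loss should be non-increasing almost always."""
        cfg = TrainingConfig(
            learning_rate=0.02, batch_size=256, epochs=40,
            dropout_rate=0.0, l2=0.0, n_hidden=6,
        )
        res = fit(small_cohort, cfg, seed=3)
        drops = np.diff(res.history.train_loss)
        assert np.mean(drops <= 1e-12) >= 0.9


def _init_seed_for(seed: int) -> int:
    children = np.random.SeedSequence(seed).spawn(4)
    return int(children[1].generate_state(1)[0] % (2**31))
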