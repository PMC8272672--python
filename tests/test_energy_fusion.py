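"""RBM fusion layer: forward pass, energy, exact marginals, CD training."""

import itertools
import math

import numpy as np
import pytest

from fusionacl import energy_fusion as ef
from fusionacl.errors import ConfigurationError, ExactModeError, UntrainedModelError


def _params(t, beta, w):
    return ef.RBMParams(visible_bias=np.asarray(t, float),
                        hidden_bias=np.asarray(beta, float),
                        weights=np.asarray(w, float))


# ---------------------------------------------------------------------------
# hidden forward pass
# ---------------------------------------------------------------------------

def test_zero_parameters_give_half_activations():
    p = _params([0, 0, 0], [0, 0], np.zeros((3, 2)))
    np.testing.assert_allclose(ef.hidden_forward([1.0, 0.0, 1.0], p), 0.5)


def test_hidden_activation_monotone_in_hidden_bias(rng):
    w = rng.normal(size=(4, 2))
    p0 = _params(np.zeros(4), [0.0, 0.0], w)
    p1 = _params(np.zeros(4), [1.0, 0.0], w)
    m = rng.random(4)
    a0, a1 = ef.hidden_forward(m, p0), ef.hidden_forward(m, p1)
    assert a1[0] > a0[0]
    assert a1[1] == pytest.approx(a0[1])


def test_hidden_forward_matches_hand_arithmetic():
    w = np.array([[0.5, -1.0], [2.0, 0.3], [-0.25, 1.5]])
    p = _params([0.1, 0.2, 0.3], [0.4, -0.6], w)
    m = np.array([1.0, 0.0, 1.0])
    k0 = 1.0 * 0.5 + 0.0 * 2.0 + 1.0 * -0.25 + 0.4
    k1 = 1.0 * -1.0 + 0.0 * 0.3 + 1.0 * 1.5 + -0.6
    want = [1 / (1 + math.exp(-k0)), 1 / (1 + math.exp(-k1))]
    np.testing.assert_allclose(ef.hidden_forward(m, p), want, atol=1e-12)


def test_dimension_mismatch_raises():
    p = _params([0, 0, 0], [0], np.zeros((3, 1)))
    with pytest.raises(ConfigurationError):
        ef.hidden_forward(np.zeros(4), p)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def test_energy_of_zero_states_is_zero(rng):
    p = _params(rng.normal(size=3), rng.normal(size=2), rng.normal(size=(3, 2)))
    assert ef.energy(np.zeros(3), np.zeros(2), p) == 0.0


def test_energy_single_units_hand_value():
    p = ef.RBMParams(visible_bias=np.array([0.5, 0.0]),
                     hidden_bias=np.array([0.25]),
                     weights=np.array([[2.0], [0.0]]))
    e = ef.energy(np.array([1.0, 0.0]), np.array([1.0]), p)
    assert e == pytest.approx(-0.5 - 0.25 - 2.0)


def test_energy_matches_brute_force_triple_loop(rng):
    p = _params(rng.normal(size=5), rng.normal(size=4), rng.normal(size=(5, 4)))
    for _ in range(10):
        x = (rng.random(5) < 0.5).astype(float)
        y = (rng.random(4) < 0.5).astype(float)
        want = 0.0
        for i in range(5):
            want -= p.visible_bias[i] * x[i]
        for e_ in range(4):
            want -= p.hidden_bias[e_] * y[e_]
        for i in range(5):
            for e_ in range(4):
                want -= x[i] * p.weights[i, e_] * y[e_]
        assert ef.energy(x, y, p) == pytest.approx(want, abs=1e-12)


def test_printed_variant_puts_bias_in_interaction():
    p = _params([0.5, -0.5], [0.25], [[2.0], [1.0]])
    x = np.array([1.0, 1.0])
    y = np.array([1.0])
    # standard: -(0.5-0.5) - 0.25 - (2+1) = -3.25
    assert ef.energy(x, y, p) == pytest.approx(-3.25)
    # printed: interaction uses t instead of x: -(0) - 0.25 - (0.5*2 - 0.5*1)
    assert ef.energy(x, y, p, variant="printed") == pytest.approx(-0.75)


# ---------------------------------------------------------------------------
# exact marginals
# ---------------------------------------------------------------------------

def test_zero_parameter_marginals_are_uniform():
    p = _params(np.zeros(3), np.zeros(1), np.zeros((3, 1)))
    px, py = ef.exact_marginals(p)
    np.testing.assert_allclose(px, 1 / 8, atol=1e-12)
    np.testing.assert_allclose(py, 1 / 2, atol=1e-12)


def test_marginals_normalize_for_random_parameters(rng):
    p = _params(rng.normal(size=6), rng.normal(size=3), rng.normal(size=(6, 3)))
    px, py = ef.exact_marginals(p)
    assert px.sum() == pytest.approx(1.0, abs=1e-10)
    assert py.sum() == pytest.approx(1.0, abs=1e-10)


def test_marginals_match_hand_enumeration_two_visible_one_hidden():
    p = _params([0.3, -0.2], [0.1], [[1.0], [-0.5]])
    weights = {}
    z = 0.0
    for x0, x1, y0 in itertools.product([0, 1], repeat=3):
        e = -(0.3 * x0 - 0.2 * x1) - 0.1 * y0 - (1.0 * x0 - 0.5 * x1) * y0
        weights[(x0, x1, y0)] = math.exp(-e)
        z += math.exp(-e)
    px_hand = [sum(weights[(x0, x1, y0)] for y0 in (0, 1)) / z
               for x0, x1 in itertools.product([0, 1], repeat=2)]
    px, _ = ef.exact_marginals(p)
    np.testing.assert_allclose(px, px_hand, atol=1e-12)


def test_marginal_matches_analytic_hidden_product_form(rng):
    """p(x) from joint enumeration equals the free-energy (product) form."""
    p = _params(rng.normal(size=5), rng.normal(size=3), rng.normal(size=(5, 3)))
    px, _ = ef.exact_marginals(p)
    X = ef.enumerate_states(5)
    from scipy.special import logsumexp

    log_z = logsumexp(-ef.free_energy(X, p))
    np.testing.assert_allclose(px, np.exp(-ef.free_energy(X, p) - log_z),
                               atol=1e-10)


def test_exact_mode_refuses_large_models():
    p = _params(np.zeros(18), np.zeros(5), np.zeros((18, 5)))
    with pytest.raises(ExactModeError):
        ef.exact_marginals(p)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _toy_samples(rng, n=8, nv=6):
    X = (rng.random((n, nv)) < 0.5).astype(float)
    return [ef.FusedSample(m=x, label=int(i % 2)) for i, x in enumerate(X)]


def test_cd_training_increases_exact_likelihood(rng):
    samples = _toy_samples(rng)
    cfg = ef.TrainConfig(epochs=50, n_hidden=3, seed=0)
    params = ef.train(samples, cfg)
    ll = params.history["log_likelihood"]
    assert len(ll) == 51
    assert ll[-1] >= ll[0]


def test_training_is_deterministic(rng):
    samples = _toy_samples(rng)
    cfg = ef.TrainConfig(epochs=10, n_hidden=3, seed=4)
    a = ef.train(samples, cfg)
    b = ef.train(samples, cfg)
    np.testing.assert_array_equal(a.weights, b.weights)
    np.testing.assert_array_equal(a.output_weights, b.output_weights)


def test_linearly_separable_toy_reaches_full_training_accuracy(rng):
    X = rng.random((24, 6)) * 0.3
    y = np.array([i % 2 for i in range(24)])
    X[y == 1, 0] += 0.7  # first coordinate separates the classes
    samples = [ef.FusedSample(m=x, label=int(lab)) for x, lab in zip(X, y)]
    params = ef.train(samples, ef.TrainConfig(epochs=30, n_hidden=4, seed=0,
                                              finetune_epochs=2000))
    _, calls = ef.predict_batch(X, params)
    assert np.array_equal(calls, y)


def test_single_class_data_rejected_for_finetune(rng):
    X = (rng.random((6, 5)) < 0.5).astype(float)
    samples = [ef.FusedSample(m=x, label=1) for x in X]
    with pytest.raises(ConfigurationError):
        ef.train(samples, ef.TrainConfig(epochs=2, n_hidden=2, seed=0))


def test_cd_recovery_of_generating_model_likelihood():
    """Training on samples from a known small RBM approaches its held-out
    log-likelihood (parameter-recovery-style check)."""
    gen_rng = np.random.default_rng(42)
    gen = ef.RBMParams(visible_bias=gen_rng.normal(0, 0.5, 6),
                       hidden_bias=gen_rng.normal(0, 0.5, 3),
                       weights=gen_rng.normal(0, 1.5, (6, 3)))
    train_X = ef.sample_from_model(gen, 300, seed=1)
    test_X = ef.sample_from_model(gen, 100, seed=2)
    samples = [ef.FusedSample(m=x, label=int(i % 2)) for i, x in enumerate(train_X)]
    fitted = ef.train(samples, ef.TrainConfig(epochs=300, n_hidden=3, seed=0,
                                              finetune_epochs=0,
                                              log_exact_likelihood=False))
    ll_gen = ef.exact_log_likelihood(test_X, gen)
    ll_fit = ef.exact_log_likelihood(test_X, fitted)
    assert abs(ll_fit - ll_gen) <= 0.10 * abs(ll_gen)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_zero_output_layer_predicts_half_and_calls_positive():
    p = _params(np.zeros(4), np.zeros(2), np.zeros((4, 2)))
    p.trained = True
    prob, call = ef.predict(np.zeros(4), p)
    assert prob == pytest.approx(0.5)
    assert call == 1  # threshold is >= 0.5


def test_prediction_monotone_in_output_bias(rng):
    p = _params(np.zeros(4), np.zeros(2), rng.normal(size=(4, 2)))
    p.trained = True
    m = rng.random(4)
    p.output_bias = 0.0
    w0, _ = ef.predict(m, p)
    p.output_bias = 1.0
    w1, _ = ef.predict(m, p)
    assert w1 > w0


def test_prediction_matches_hand_computed_sigmoid():
    p = _params(np.zeros(3), np.array([0.0, 0.0]), np.zeros((3, 2)))
    p.output_weights = np.array([1.0, -2.0])
    p.output_bias = 0.25
    p.trained = True
    # hidden activations are sigma(0) = 0.5 each
    k = 0.5 * 1.0 + 0.5 * -2.0 + 0.25
    want = 1 / (1 + math.exp(-k))
    prob, call = ef.predict(np.zeros(3), p)
    assert prob == pytest.approx(want, abs=1e-12)
    assert call == int(want >= 0.5)


def test_untrained_parameters_are_flagged():
    p = _params(np.zeros(3), np.zeros(1), np.zeros((3, 1)))
    with pytest.raises(UntrainedModelError):
        ef.predict(np.zeros(3), p)
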