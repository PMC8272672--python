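"""Feature head: batch norm, pooling, projection, traditional features."""

import numpy as np
import pytest

from fusionacl import head
from fusionacl.errors import ConfigurationError, SizeError


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def test_bn_standardizes_simple_batch():
    params = head.BNParams.identity(1)
    x = np.array([[1.0], [2.0], [3.0]])
    out = head.batch_normalize(x, params, mode="train")
    assert out.mean() == pytest.approx(0.0, abs=1e-12)
    assert out.var() == pytest.approx(1.0, abs=1e-4)  # 1/(1+eps/var)


def test_bn_constant_batch_collapses_to_shift():
    params = head.BNParams(scale=np.array([2.0]), shift=np.array([3.0]))
    out = head.batch_normalize(np.full((3, 1), 5.0), params, mode="train")
    np.testing.assert_allclose(out, 3.0)


def test_bn_matches_direct_formula(rng):
    params = head.BNParams(scale=rng.normal(size=4), shift=rng.normal(size=4),
                           eps=1e-5)
    x = rng.normal(size=(7, 4))
    out = head.batch_normalize(x, params, mode="train")
    want = params.scale * (x - x.mean(0)) / np.sqrt(x.var(0) + 1e-5) + params.shift
    np.testing.assert_allclose(out, want, atol=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bn_train_mode_output_is_standardized(seed):
    r = np.random.default_rng(seed)
    x = r.normal(loc=3.0, scale=2.0, size=(20, 5))
    out = head.batch_normalize(x, head.BNParams.identity(5), mode="train")
    np.testing.assert_allclose(out.mean(0), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.var(0), 1.0, atol=1e-4)


def test_bn_eval_mode_uses_running_statistics(rng):
    params = head.BNParams.identity(3)
    params.momentum = 1.0
    x = rng.normal(size=(10, 3))
    head.batch_normalize(x, params, mode="train")
    out = head.batch_normalize(x[:2], params, mode="eval")
    want = (x[:2] - x.mean(0)) / np.sqrt(x.var(0) + params.eps)
    np.testing.assert_allclose(out, want, atol=1e-10)


def test_relu_trivials():
    np.testing.assert_array_equal(head.relu(np.array([-2.0, 0.0, 7.0])),
                                  np.array([0.0, 0.0, 7.0]))


# ---------------------------------------------------------------------------
# adaptive max pooling
# ---------------------------------------------------------------------------

def _naive_adaptive_pool(x, out_size):
    h = x.shape[0]
    stride = h // out_size
    kernel = h - (out_size - 1) * stride
    out = np.empty((out_size, out_size))
    for i in range(out_size):
        for j in range(out_size):
            out[i, j] = x[i * stride: i * stride + kernel,
                          j * stride: j * stride + kernel].max()
    return out


def test_adaptive_pool_identity_when_sizes_match(rng):
    x = rng.normal(size=(7, 7))
    np.testing.assert_array_equal(head.adaptive_max_pool(x, 7), x)


def test_adaptive_pool_geometry():
    assert head.adaptive_pool_geometry(7, 7) == (1, 1)
    assert head.adaptive_pool_geometry(14, 7) == (2, 2)
    assert head.adaptive_pool_geometry(10, 3) == (3, 4)


def test_adaptive_pool_matches_naive_oracle_exhaustively(rng):
    for in_size in range(1, 17):
        x = rng.normal(size=(in_size, in_size))
        for out_size in range(1, in_size + 1):
            got = head.adaptive_max_pool(x, out_size)
            np.testing.assert_array_equal(got, _naive_adaptive_pool(x, out_size))


def test_adaptive_pool_rejects_upsampling():
    with pytest.raises(SizeError):
        head.adaptive_max_pool(np.zeros((4, 4)), 5)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_projection_zero_input_zero_bias_gives_zero_vector():
    params = head.init_projection(16, out_dim=head.DEEP_DIM, seed=0)
    out = head.project_deep_features(np.zeros((1, 4, 4)), params)
    assert out.shape == (1026,)
    assert np.all(out == 0.0)


def test_projection_output_length_is_configured_deep_dim(rng):
    for in_dim in (8, 32, 50):
        params = head.init_projection(in_dim, seed=1)
        out = head.project_deep_features(rng.random(in_dim), params)
        assert out.shape == (head.DEEP_DIM,)


def test_projection_matches_hand_computed_affine():
    params = head.ProjectionParams(
        weight=np.array([[1.0, 2.0], [0.0, -1.0], [3.0, 0.5]]),
        bias=np.array([0.5, 0.0, -10.0]))
    out = head.project_deep_features(np.array([1.0, 2.0]), params)
    # rows: 1*1+2*2+0.5=5.5 ; -2 -> relu 0 ; 3+1-10=-6 -> relu 0
    np.testing.assert_allclose(out, [5.5, 0.0, 0.0])


def test_projection_dimension_mismatch_raises():
    params = head.init_projection(16, seed=0)
    with pytest.raises(ConfigurationError):
        head.project_deep_features(np.zeros(15), params)


# ---------------------------------------------------------------------------
# traditional features
# ---------------------------------------------------------------------------

def test_traditional_feature_vector_shape_and_names():
    vec = head.extract_traditional_features(np.full((32, 32), 0.4))
    assert vec.values.shape == (32,)
    assert len(vec.names) == 32
    assert np.all(np.isfinite(vec.values))


def test_constant_image_degenerate_conventions():
    vec = head.extract_traditional_features(np.full((32, 32), 0.5)).as_dict()
    assert vec["intensity_std"] == 0.0
    assert vec["intensity_entropy"] == 0.0
    assert vec["intensity_skewness"] == 0.0
    assert vec["glcm_correlation_d1"] == 0.0
    assert vec["dark_area_fraction"] == 0.0
    assert vec["dark_component_count"] == 0.0


def test_traditional_features_deterministic(rng):
    img = rng.random((40, 40))
    a = head.extract_traditional_features(img).values
    b = head.extract_traditional_features(img).values
    np.testing.assert_array_equal(a, b)


def test_half_black_half_white_mean_intensity():
    img = np.zeros((32, 32))
    img[:, 16:] = 1.0
    vec = head.extract_traditional_features(img).as_dict()
    assert vec["intensity_mean"] == pytest.approx(0.5)


def test_documented_offset_invariant_subset(rng):
    img = 0.2 + 0.4 * rng.random((32, 32))  # offset keeps pixels in [0,1]
    base = head.extract_traditional_features(img).as_dict()
    shifted = head.extract_traditional_features(img + 0.2).as_dict()
    for name in head.OFFSET_INVARIANT_FEATURES:
        assert shifted[name] == pytest.approx(base[name], abs=1e-10), name
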