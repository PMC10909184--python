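import numpy as np
import pytest

from graylift import (
    ConfigError,
    InvalidInputError,
    ModelBundle,
    NetworkConfig,
    extract_features,
    infer,
    predict_residual_pmf,
    predict_subimage,
)
from graylift.model import PredictorNet

from .conftest import TINY_NET


def _net(config=None, seed=0):
    return PredictorNet(config or TINY_NET, rng=np.random.default_rng(seed))


def test_middle_matrix_shape_contract():
    net = PredictorNet(
        NetworkConfig(base_channels=32, n_scales=2), rng=np.random.default_rng(0)
    )
    rng = np.random.default_rng(1)
    mm = extract_features([rng.integers(0, 256, (16, 16))], net)
    assert mm.shape == (16, 16, 32)


def test_feature_extraction_is_deterministic_and_validates():
    net = _net()
    rng = np.random.default_rng(2)
    sub = rng.integers(0, 256, (12, 9))
    mm1 = extract_features([sub], net)
    mm2 = extract_features([sub], net)
    assert np.array_equal(mm1, mm2)
    with pytest.raises(ConfigError):
        extract_features([sub, sub], net)  # N mismatch
    with pytest.raises(InvalidInputError):
        extract_features([sub, rng.integers(0, 256, (9, 12))], _net(TINY_NET.with_inputs(2)))


def test_zero_parameters_give_zero_features():
    net = _net()
    net.set_all_zero()
    mm = extract_features([np.zeros((8, 8), dtype=np.uint8)], net)
    assert np.all(mm == 0)


def test_prediction_head_shape_and_determinism():
    net = _net()
    rng = np.random.default_rng(3)
    mm = extract_features([rng.integers(0, 256, (7, 11))], net)
    p1 = predict_subimage(mm, net)
    p2 = predict_subimage(mm, net)
    assert p1.values.shape == (7, 11)
    assert np.array_equal(p1.values, p2.values)


@pytest.mark.parametrize("shape", [(10, 10), (16, 16), (5, 7), (1, 1)])
def test_probability_head_511_channels_and_simplex(shape):
    """Output has 511 channels, sums to 1 per pixel, at any spatial size."""
    net = _net(seed=shape[0] * 100 + shape[1])
    rng = np.random.default_rng(4)
    mm = extract_features([rng.integers(0, 256, shape)], net)
    pmf = predict_residual_pmf(mm, net)
    assert pmf.probs.shape == (*shape, 511)
    pmf.validate(atol=1e-5)


def test_softmax_simplex_for_random_parameter_draws():
    rng = np.random.default_rng(5)
    for trial in range(25):
        net = _net(seed=1000 + trial)
        sub = rng.integers(0, 256, (6, 10))
        pmf = predict_residual_pmf(extract_features([sub], net), net)
        s = pmf.probs.sum(axis=-1)
        assert np.all(np.abs(s - 1.0) <= 1e-5)
        assert np.all(pmf.probs >= 0)


def test_four_scale_unet_pads_non_multiple_of_16():
    net = PredictorNet(
        NetworkConfig(base_channels=4, n_scales=4), rng=np.random.default_rng(6)
    )
    rng = np.random.default_rng(7)
    mm = extract_features([rng.integers(0, 256, (10, 10))], net)
    pmf = predict_residual_pmf(mm, net)
    assert pmf.probs.shape == (10, 10, 511)
    pmf.validate()


def test_infer_equals_composed_heads_and_counts(untrained_bundle):
    rng = np.random.default_rng(8)
    sub = rng.integers(0, 256, (9, 14)).astype(np.uint8)
    before = untrained_bundle.inference_count
    pred, pmf = infer([sub], untrained_bundle)
    assert untrained_bundle.inference_count == before + 1

    net = untrained_bundle.nets[1]
    mm = extract_features([sub], net)
    assert np.array_equal(predict_subimage(mm, net).values, pred.values)
    assert np.array_equal(predict_residual_pmf(mm, net).probs, pmf.probs)


def test_infer_requires_known_input_count(untrained_bundle):
    with pytest.raises(ConfigError):
        infer([np.zeros((4, 4))] * 4, untrained_bundle)


def test_bundle_hash_tracks_parameters(tmp_path):
    b = ModelBundle.create(TINY_NET, seed=1)
    h0 = b.version_hash
    assert h0 == ModelBundle.create(TINY_NET, seed=1).version_hash
    b.nets[2].params()[0].data += 1.0
    assert b.version_hash != h0

    path = tmp_path / "bundle.npz"
    b.save(path)
    loaded = ModelBundle.load(path)
    assert loaded.version_hash == b.version_hash
    sub = np.full((6, 6), 40, dtype=np.uint8)
    p1, _ = infer([sub], b)
    p2, _ = infer([sub], loaded)
    assert np.array_equal(p1.values, p2.values)


def test_networks_share_no_parameters(untrained_bundle):
    ids = set()
    for n in (1, 2, 3):
        for p in untrained_bundle.nets[n].params():
            assert id(p.data) not in ids
            ids.add(id(p.data))


def test_backprop_matches_finite_differences():
    """Analytic gradients agree with central differences (float64 net)."""
    cfg = NetworkConfig(base_channels=3, n_scales=1, n_classes=5, resblock_depth=1)
    net = PredictorNet(cfg, rng=np.random.default_rng(9), dtype=np.float64)
    rng = np.random.default_rng(10)
    # move biases (zero-initialized) off the ReLU knife edge, where the
    # subgradient convention and finite differences legitimately disagree
    for p in net.params():
        p.data += 0.05 * rng.standard_normal(p.data.shape)
    x = rng.random((2, 1, 4, 4))
    gp = rng.standard_normal((2, 4, 4))
    gl = rng.standard_normal((2, 5, 4, 4))

    def loss():
        mm = net.extract_features(x)
        return float(
            (net.predict_head(mm) * gp).sum() + (net.pmf_logits(mm) * gl).sum()
        )

    mm = net.extract_features(x)
    net.predict_head(mm)
    net.pmf_logits(mm)
    net.zero_grad()
    net.backward(gp, gl)

    eps = 1e-6
    params = net.params()
    rngp = np.random.default_rng(11)
    for p in params:
        flat = p.data.ravel()
        for idx in rngp.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss()
            flat[idx] = orig - eps
            down = loss()
            flat[idx] = orig
            fd = (up - down) / (2 * eps)
            an = p.grad.ravel()[idx]
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-6), p.name
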