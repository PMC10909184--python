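import math

import numpy as np
import pytest

from graylift import (
    InvalidInputError,
    TrainingConfig,
    WeightSchedule,
    default_weight_schedule,
    ppl_loss,
    spl_loss,
    total_loss,
    unit_weight_schedule,
)

from .oracles import scalar_mad, scalar_weighted_ce


class TestSplLoss:
    def test_zero_on_identity(self):
        y = np.arange(12.0).reshape(3, 4)
        assert spl_loss(y, y) == 0.0

    def test_direct_example(self):
        assert spl_loss(np.array([0.0, 10.0]), np.array([1.0, 8.0])) == 1.5

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.uniform(0, 255, (9, 7))
            yh = rng.uniform(-20, 280, (9, 7))
            assert spl_loss(y, yh) == pytest.approx(scalar_mad(y, yh), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            spl_loss(np.zeros(3), np.zeros(4))


class TestPplLoss:
    def test_one_hot_exact_match_is_zero(self):
        q = np.array([7, 300])
        pmf = np.zeros((2, 511))
        pmf[np.arange(2), q] = 1.0
        assert ppl_loss(q, pmf, default_weight_schedule()) == 0.0

    def test_uniform_single_pixel(self):
        pmf = np.full((1, 511), 1 / 511)
        assert ppl_loss(np.array([255]), pmf, unit_weight_schedule()) == pytest.approx(
            math.log(511), rel=1e-12
        )

    def test_weighted_endpoint_example(self):
        # one pixel, true class in the weight-8 band, p = 0.5 -> 8 * ln 2
        pmf = np.full((1, 511), (1 - 0.5) / 510)
        pmf[0, 50] = 0.5
        got = ppl_loss(np.array([50]), pmf, default_weight_schedule())
        assert got == pytest.approx(8 * math.log(2), rel=1e-12)

    def test_unit_weights_equal_plain_cross_entropy(self):
        rng = np.random.default_rng(1)
        q = rng.integers(0, 511, 200)
        pmf = rng.dirichlet(np.ones(511), 200)
        ours = ppl_loss(q, pmf, unit_weight_schedule())
        plain = -np.mean(np.log(np.maximum(pmf[np.arange(200), q], 1e-12)))
        assert abs(ours - plain) < 1e-9

    def test_matches_scalar_loop_with_weights(self):
        rng = np.random.default_rng(2)
        q = rng.integers(0, 511, 50)
        pmf = rng.dirichlet(np.full(511, 0.2), 50)
        w = default_weight_schedule()
        assert ppl_loss(q, pmf, w) == pytest.approx(
            scalar_weighted_ce(q, pmf, w.as_array()), rel=1e-12
        )

    def test_class_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ppl_loss(np.array([511]), np.full((1, 511), 1 / 511), unit_weight_schedule())

    def test_nonnegative_and_floor(self):
        pmf = np.zeros((1, 511))
        pmf[0, 0] = 1.0
        val = ppl_loss(np.array([255]), pmf, unit_weight_schedule())
        assert val == pytest.approx(-math.log(1e-12))


class TestWeightSchedule:
    def test_paper_anchor_weights(self):
        w = default_weight_schedule()
        assert all(w.weight(c) == 8 for c in (0, 50, 99, 411, 510))
        assert all(w.weight(c) == 1 for c in (200, 255, 300))

    def test_symmetry(self):
        arr = default_weight_schedule().as_array()
        assert np.array_equal(arr, arr[::-1])

    def test_monotone_in_distance_from_center(self):
        arr = default_weight_schedule().as_array()
        assert np.all(np.diff(arr[255:]) >= 0)

    def test_rejects_gapped_partition(self):
        with pytest.raises(InvalidInputError):
            WeightSchedule(boundaries=((0, 100), (102, 510)), weights=(1.0, 1.0))

    def test_rejects_asymmetric_schedule(self):
        with pytest.raises(InvalidInputError):
            WeightSchedule(
                boundaries=((0, 99), (100, 510)), weights=(8.0, 1.0)
            )


class TestTotalLoss:
    def test_unit_lambdas_sum(self):
        cfg = TrainingConfig()
        assert cfg.lambda_spl == 1.0 and cfg.lambda_ppl == 1.0
        assert total_loss(2.5, 3.5, cfg) == 6.0

    def test_ppl_disabled(self):
        cfg = TrainingConfig(lambda_ppl=0.0)
        assert total_loss(2.5, 99.0, cfg) == 2.5

    def test_linearity(self):
        cfg = TrainingConfig(lambda_spl=2.0, lambda_ppl=0.5)
        assert total_loss(3.0, 4.0, cfg) == pytest.approx(2 * 3 + 0.5 * 4)
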