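import math

import numpy as np
import pytest

from graylift import (
    ConfigError,
    CorruptStreamError,
    InvalidInputError,
    QuantizedCDF,
    decode,
    encode,
    ideal_code_length,
    quantize_pmf,
)
from graylift.coder import quantize_pmf_batch

from .oracles import exact_ac_roundtrip

TOTAL = 1 << 16


def random_cdfs(rng, n, concentration=0.05):
    pmfs = rng.dirichlet(np.full(511, concentration), size=n)
    return quantize_pmf_batch(pmfs), pmfs


class TestQuantizePmf:
    def test_uniform_counts_differ_by_at_most_one(self):
        cdf = quantize_pmf(np.full(511, 1 / 511))
        counts = np.diff(cdf.cumulative)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == TOTAL

    def test_zero_probability_class_still_gets_a_count(self):
        pmf = np.zeros(511)
        pmf[255] = 1.0
        counts = np.diff(quantize_pmf(pmf).cumulative)
        assert counts.min() == 1
        assert counts[255] == TOTAL - 510

    def test_largest_remainder_l1_bound(self):
        """Rows with no starved classes obey the pure rounding-error bound."""
        rng = np.random.default_rng(0)
        pmfs = rng.dirichlet(np.full(511, 50.0), size=100)  # all classes well above 1/total
        counts = np.diff(quantize_pmf_batch(pmfs), axis=1)
        assert counts.min() >= 1
        err = np.abs(counts / TOTAL - pmfs / pmfs.sum(1, keepdims=True)).sum(axis=1)
        assert err.max() <= 511 * 2**-16 + 1e-12

    def test_floor_repair_l1_bound(self):
        """Starved classes cost at most two extra counts of L1 error each."""
        rng = np.random.default_rng(1)
        pmfs = rng.dirichlet(np.full(511, 0.01), size=100)
        counts = np.diff(quantize_pmf_batch(pmfs), axis=1)
        assert counts.min() >= 1
        err = np.abs(counts / TOTAL - pmfs / pmfs.sum(1, keepdims=True)).sum(axis=1)
        assert err.max() <= 3 * 511 * 2**-16 + 1e-12

    def test_precision_bounds(self):
        with pytest.raises(ConfigError):
            quantize_pmf(np.full(511, 1 / 511), precision=9)
        cdf = quantize_pmf(np.full(511, 1 / 511), precision=10)
        assert cdf.total == 1024 and np.diff(cdf.cumulative).min() >= 1

    def test_invalid_cdf_rejected(self):
        cum = np.zeros(512, dtype=np.int64)
        cum[-1] = TOTAL  # zero-mass classes inside
        with pytest.raises(InvalidInputError):
            QuantizedCDF(cum, TOTAL)


class TestRoundTrip:
    def test_empty_sequence(self):
        stream = encode([], np.zeros((0, 512), np.int64))
        assert len(stream) <= 8
        assert decode(stream, np.zeros((0, 512), np.int64), 0).size == 0

    def test_random_round_trips(self):
        rng = np.random.default_rng(2)
        for trial in range(300):
            n = int(rng.integers(1, 64))
            cdfs, _ = random_cdfs(rng, n)
            syms = rng.integers(0, 511, n)
            assert np.array_equal(decode(encode(syms, cdfs), cdfs, n), syms), trial

    def test_skewed_model_wrong_symbols_still_lossless(self):
        # worst case: encoding symbols the model considers nearly impossible
        rng = np.random.default_rng(3)
        pmf = np.zeros(511)
        pmf[255] = 1.0
        cdfs = np.repeat(quantize_pmf(pmf).cumulative[None], 200, axis=0)
        syms = rng.integers(0, 511, 200)
        assert np.array_equal(decode(encode(syms, cdfs), cdfs, 200), syms)

    def test_truncated_stream_raises(self):
        rng = np.random.default_rng(4)
        cdfs, _ = random_cdfs(rng, 500)
        syms = rng.integers(0, 511, 500)
        stream = encode(syms, cdfs)
        with pytest.raises(CorruptStreamError):
            decode(stream[: len(stream) // 2], cdfs, 500)

    def test_out_of_range_symbol_rejected(self):
        cdfs, _ = random_cdfs(np.random.default_rng(5), 1)
        with pytest.raises(InvalidInputError):
            encode([511], cdfs)

    def test_quantized_cdf_list_interface(self):
        rng = np.random.default_rng(6)
        cdf = quantize_pmf(rng.dirichlet(np.ones(511)))
        syms = [3, 508, 255]
        stream = encode(syms, [cdf, cdf, cdf])
        assert decode(stream, [cdf, cdf, cdf], 3).tolist() == syms


class TestCodeLength:
    def test_uniform_length_near_entropy(self):
        rng = np.random.default_rng(7)
        n = 2000
        cdfs = np.repeat(quantize_pmf(np.full(511, 1 / 511)).cumulative[None], n, 0)
        syms = rng.integers(0, 511, n)
        stream = encode(syms, cdfs)
        counts = np.diff(cdfs, axis=1)
        ideal = -np.log2(counts[np.arange(n), syms] / TOTAL).sum()
        assert len(stream) * 8 <= ideal + 64 + 0.01 * n
        # and the entropy itself is n*log2(511) up to quantization
        assert ideal == pytest.approx(n * math.log2(511), rel=1e-3)

    def test_efficiency_bound_random_models(self):
        rng = np.random.default_rng(8)
        n = 3000
        cdfs, _ = random_cdfs(rng, n, concentration=0.3)
        syms = rng.integers(0, 511, n)
        stream = encode(syms, cdfs)
        counts = np.diff(cdfs, axis=1)
        ideal = -np.log2(counts[np.arange(n), syms] / TOTAL).sum()
        assert len(stream) * 8 <= ideal + 64 + 0.01 * n


class TestIdealCodeLength:
    def test_closed_forms(self):
        pmf = np.zeros((1, 511))
        pmf[0, 10] = 0.5
        assert ideal_code_length(pmf, [10]) == 1.0
        ones = np.zeros((3, 511))
        ones[:, 42] = 1.0
        assert ideal_code_length(ones, [42, 42, 42]) == 0.0
        uni = np.full((4, 511), 1 / 511)
        assert ideal_code_length(uni, [0, 1, 2, 3]) == pytest.approx(4 * math.log2(511))

    def test_zero_probability_gives_infinity(self):
        pmf = np.zeros((1, 511))
        pmf[0, 0] = 1.0
        assert ideal_code_length(pmf, [300]) == math.inf


class TestExactOracle:
    def test_equivalence_with_big_integer_arithmetic_coder(self):
        """Both coders are lossless on the same instances and within a few
        bytes of each other's (near-optimal) code length."""
        rng = np.random.default_rng(9)
        for trial in range(40):
            n = int(rng.integers(1, 33))
            cdfs, _ = random_cdfs(rng, n, concentration=0.2)
            syms = rng.integers(0, 511, n)

            oracle_syms, oracle_bits = exact_ac_roundtrip(syms, cdfs, TOTAL)
            assert oracle_syms == syms.tolist()

            stream = encode(syms, cdfs)
            assert np.array_equal(decode(stream, cdfs, n), syms)

            counts = np.diff(cdfs, axis=1)
            ideal = -np.log2(counts[np.arange(n), syms] / TOTAL).sum()
            assert oracle_bits <= ideal + 3
            assert len(stream) * 8 <= oracle_bits + 64 + 0.01 * n
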