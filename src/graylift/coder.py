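"""Static range coding of residual classes under per-symbol 511-way models.

Two layers:

* :func:`quantize_pmf` turns a floating-point probability vector into a
  :class:`QuantizedCDF` — integer counts summing to ``2**precision``
  (default 16 bits), obtained by largest-remainder rounding with a floor of
  one count per class so that every class stays encodable.

* :func:`encode` / :func:`decode` run a byte-oriented, carry-propagating
  range coder (32-bit range, 64-bit low accumulator, byte renormalization
  when the range drops below 2^24). Each symbol may use its own CDF, which
  is how the per-pixel model probabilities are consumed. The realized code
  length exceeds the quantized-CDF ideal Σ -log2(count/total) by at most a
  constant flush cost (≤ 64 bits) plus ~0.006 bit/symbol of renormalization
  truncation.

The exact bitstream rules are documented in FORMAT.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, CorruptStreamError, InvalidInputError

__all__ = [
    "QuantizedCDF",
    "quantize_pmf",
    "quantize_pmf_batch",
    "encode",
    "decode",
    "ideal_code_length",
    "DEFAULT_PRECISION",
]

DEFAULT_PRECISION = 16
_TOP = 1 << 24
_MASK32 = (1 << 32) - 1


@dataclass(frozen=True)
class QuantizedCDF:
    """512 nondecreasing integers from 0 to ``total`` with strictly positive steps."""

    cumulative: np.ndarray  # (512,) int64
    total: int

    def __post_init__(self):
        c = np.asarray(self.cumulative, dtype=np.int64)
        if c.shape != (512,) or c[0] != 0 or c[-1] != self.total:
            raise InvalidInputError("cumulative must run from 0 to total over 512 entries")
        if np.any(np.diff(c) < 1):
            raise InvalidInputError("every class must carry strictly positive mass")
        object.__setattr__(self, "cumulative", c)


def quantize_pmf_batch(pmfs: np.ndarray, precision: int = DEFAULT_PRECISION) -> np.ndarray:
    """Vectorized CDF quantization; (n, 511) pmf rows -> (n, 512) cumulative rows.

    Largest-remainder rounding to counts summing to ``2**precision``; classes
    that land on zero get one count, borrowed from the heaviest classes.
    """
    if precision < 10:
        raise ConfigError("precision below 10 bits cannot resolve 511 classes")
    if precision > 24:
        raise ConfigError("precision above 24 bits would stall the range coder")
    pmfs = np.asarray(pmfs, dtype=np.float64)
    if pmfs.ndim != 2 or pmfs.shape[1] != 511:
        raise InvalidInputError(f"expected (n, 511) pmf array, got {pmfs.shape}")
    if np.any(pmfs < 0):
        raise InvalidInputError("probabilities must be nonnegative")
    total = 1 << precision
    norm = pmfs.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise InvalidInputError("pmf rows must have positive mass")
    scaled = pmfs / norm * total
    counts = np.floor(scaled).astype(np.int64)
    rem = scaled - counts
    deficit = total - counts.sum(axis=1)

    # distribute the (nonnegative part of the) deficit to largest remainders
    order = np.argsort(-rem, axis=1, kind="stable")
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(511)[None, :].repeat(len(pmfs), 0), axis=1)
    counts += rank < np.maximum(deficit, 0)[:, None]
    # float round-off can overshoot by a count or two; take it back from the top
    for r in np.nonzero(deficit < 0)[0]:
        need = int(-deficit[r])
        while need:
            j = int(np.argmax(counts[r]))
            take = min(need, int(counts[r, j] - 1))
            if take <= 0:
                raise InvalidInputError("cannot normalize degenerate pmf row")
            counts[r, j] -= take
            need -= take

    # floor of one count per class, borrowed from the heaviest classes
    zeros = counts == 0
    nz = zeros.sum(axis=1)
    for r in np.nonzero(nz)[0]:
        counts[r, zeros[r]] = 1
        need = int(nz[r])
        while need:
            j = int(np.argmax(counts[r]))
            take = min(need, int(counts[r, j] - 1))
            if take <= 0:
                raise ConfigError("precision too low to give every class a count")
            counts[r, j] -= take
            need -= take

    out = np.zeros((len(pmfs), 512), dtype=np.int64)
    np.cumsum(counts, axis=1, out=out[:, 1:])
    return out


def quantize_pmf(pmf_row: np.ndarray, precision: int = DEFAULT_PRECISION) -> QuantizedCDF:
    """Quantize a single 511-entry pmf to a :class:`QuantizedCDF`."""
    cum = quantize_pmf_batch(np.asarray(pmf_row)[None, :], precision)[0]
    return QuantizedCDF(cum, 1 << precision)


def _as_cdf_matrix(cdfs, n: int) -> tuple[np.ndarray, int]:
    if isinstance(cdfs, np.ndarray):
        mat = cdfs
        if mat.ndim != 2 or mat.shape[1] != 512:
            raise InvalidInputError("cdf matrix must be (n, 512)")
        total = int(mat[0, -1]) if len(mat) else 0
    else:
        cdfs = list(cdfs)
        if cdfs and not isinstance(cdfs[0], QuantizedCDF):
            raise InvalidInputError("cdfs must be QuantizedCDF instances or an array")
        totals = {c.total for c in cdfs}
        if len(totals) > 1:
            raise InvalidInputError("all CDFs in one stream must share a total")
        total = totals.pop() if totals else 0
        mat = np.stack([c.cumulative for c in cdfs]) if cdfs else np.zeros((0, 512), np.int64)
    if len(mat) != n:
        raise InvalidInputError(f"need one CDF per symbol: {len(mat)} CDFs for {n} symbols")
    return mat.astype(np.int64, copy=False), total


class _RangeEncoder:
    """Carry-propagating byte-wise range encoder (32-bit range)."""

    def __init__(self):
        self.low = 0
        self.range = _MASK32
        self.cache = 0
        self.cache_size = 1  # the first shifted byte is a leading dummy
        self.out = bytearray()

    def encode(self, cum: int, freq: int, total: int):
        r = self.range // total
        self.low += cum * r
        self.range = r * freq
        while self.range < _TOP:
            self.range <<= 8
            self._shift()

    def _shift(self):
        # emit one byte of low, deferring bytes that a pending carry could flip
        if self.low < 0xFF000000 or self.low > _MASK32:
            carry = self.low >> 32
            self.out.append((self.cache + carry) & 0xFF)
            for _ in range(self.cache_size - 1):
                self.out.append((0xFF + carry) & 0xFF)
            self.cache_size = 0
            self.cache = (self.low >> 24) & 0xFF
        self.cache_size += 1
        self.low = (self.low << 8) & _MASK32

    def finish(self) -> bytes:
        for _ in range(5):
            self._shift()
        return bytes(self.out)


class _RangeDecoder:
    def __init__(self, stream: bytes):
        self.stream = stream
        self.pos = 0
        self.range = _MASK32
        self._next_byte()  # leading dummy byte
        self.code = 0
        for _ in range(4):
            self.code = (self.code << 8) | self._next_byte()

    def _next_byte(self) -> int:
        if self.pos >= len(self.stream):
            raise CorruptStreamError("compressed stream truncated")
        b = self.stream[self.pos]
        self.pos += 1
        return b

    def decode(self, cum_row: np.ndarray, total: int) -> int:
        r = self.range // total
        v = min(self.code // r, total - 1)
        sym = int(np.searchsorted(cum_row, v, side="right")) - 1
        cum = int(cum_row[sym])
        freq = int(cum_row[sym + 1]) - cum
        self.code -= cum * r
        self.range = r * freq
        while self.range < _TOP:
            self.code = ((self.code << 8) | self._next_byte()) & _MASK32
            self.range <<= 8
        return sym


def encode(symbols, cdfs) -> bytes:
    """Range-encode a class sequence, one :class:`QuantizedCDF` per symbol.

    ``cdfs`` may be a list of :class:`QuantizedCDF` or an (n, 512) cumulative
    matrix as produced by :func:`quantize_pmf_batch`.
    """
    symbols = np.asarray(symbols, dtype=np.int64)
    if symbols.ndim != 1:
        symbols = symbols.ravel()
    mat, total = _as_cdf_matrix(cdfs, len(symbols))
    if len(symbols) and (symbols.min() < 0 or symbols.max() > 510):
        raise InvalidInputError("symbols must lie in [0, 510]")
    enc = _RangeEncoder()
    if len(symbols):
        idx = np.arange(len(symbols))
        cums = mat[idx, symbols]
        freqs = mat[idx, symbols + 1] - cums
        for c, f in zip(cums.tolist(), freqs.tolist()):
            enc.encode(c, f, total)
    return enc.finish()


def decode(stream: bytes, cdfs, n: int) -> np.ndarray:
    """Inverse of :func:`encode`; returns the n decoded classes."""
    mat, total = _as_cdf_matrix(cdfs, n)
    out = np.empty(n, dtype=np.int64)
    if n == 0:
        return out
    dec = _RangeDecoder(stream)
    for i in range(n):
        out[i] = dec.decode(mat[i], total)
    return out


def ideal_code_length(pmf_rows: np.ndarray, symbols) -> float:
    """Shannon code length Σ -log2 p̂_i(q_i) in bits; inf if any p is zero."""
    pmf_rows = np.asarray(pmf_rows, dtype=np.float64)
    symbols = np.asarray(symbols, dtype=np.intp).ravel()
    if pmf_rows.shape[0] != len(symbols):
        raise InvalidInputError("one pmf row per symbol required")
    p = pmf_rows[np.arange(len(symbols)), symbols]
    if np.any(p <= 0):
        return math.inf
    return float(-np.log2(p).sum())
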