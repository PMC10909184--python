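"""Independent brute-force oracles used only by the test suite.

These are deliberately naive implementations — exact integer arithmetic
coding, double-loop polyphase indexing, scalar loss loops — kept free of
any code from the package paths they check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# exact arithmetic coder over big integers
# ---------------------------------------------------------------------------

def exact_ac_encode(symbols, cdf_rows, total: int) -> tuple[int, int]:
    """Encode with exact (unbounded-integer) arithmetic coding.

    Returns ``(code_value, n_bits)`` such that ``code_value / 2**n_bits``
    lies inside the final subinterval. Only practical for short inputs.
    """
    lo, width, den = 0, 1, 1
    for s, row in zip(symbols, cdf_rows):
        s = int(s)
        lo = lo * total + width * int(row[s])
        width *= int(row[s + 1]) - int(row[s])
        den *= total
    if width == den:  # empty input: whole interval
        return 0, 0
    # smallest k with a dyadic point strictly inside [lo/den, (lo+width)/den)
    k = max(0, (den // width).bit_length())
    while True:
        v = -((-lo * (1 << k)) // den)  # ceil(lo * 2^k / den)
        if v * den < (lo + width) * (1 << k):
            return v, k
        k += 1


def exact_ac_decode(code: int, n_bits: int, cdf_rows, total: int, n: int):
    """Exact inverse of :func:`exact_ac_encode`."""
    lo, width, den = 0, 1, 1
    out = []
    for i in range(n):
        row = cdf_rows[i]
        # value position scaled to the current interval:
        # find s with cdf[s] <= pos < cdf[s+1], where
        # pos/total = (code/2^k - lo/den) / (width/den)
        num = code * den - lo * (1 << n_bits)  # numerator of (pos/total) * ...
        # s satisfies: cdf[s] * width * 2^k <= num * total < cdf[s+1] * width * 2^k
        lhs = num * total
        scale = width * (1 << n_bits)
        s = 0
        for j in range(511):
            if int(row[j]) * scale <= lhs:
                s = j
            else:
                break
        out.append(s)
        lo = lo * total + width * int(row[s])
        width *= int(row[s + 1]) - int(row[s])
        den *= total
    return out


def exact_ac_roundtrip(symbols, cdf_rows, total: int):
    """Encode then decode; returns (decoded symbols, code length in bits)."""
    code, k = exact_ac_encode(symbols, cdf_rows, total)
    return exact_ac_decode(code, k, cdf_rows, total, len(symbols)), k


# ---------------------------------------------------------------------------
# polyphase indexing by double loop
# ---------------------------------------------------------------------------

def brute_force_phases(values: np.ndarray):
    """Assign each pixel to its phase grid with explicit 1-based index tests."""
    h, w = values.shape
    out = {"a": {}, "b": {}, "c": {}, "d": {}}
    for i in range(h):       # 0-based; 1-based row = i + 1
        for j in range(w):
            row_odd = (i + 1) % 2 == 1
            col_odd = (j + 1) % 2 == 1
            if row_odd and col_odd:
                out["a"][(i // 2, j // 2)] = values[i, j]
            elif row_odd:
                out["b"][(i // 2, j // 2)] = values[i, j]
            elif col_odd:
                out["c"][(i // 2, j // 2)] = values[i, j]
            else:
                out["d"][(i // 2, j // 2)] = values[i, j]
    return out


# ---------------------------------------------------------------------------
# scalar loss loops
# ---------------------------------------------------------------------------

def scalar_mad(y, y_hat) -> float:
    y, y_hat = np.asarray(y).ravel(), np.asarray(y_hat).ravel()
    return sum(abs(float(a) - float(b)) for a, b in zip(y, y_hat)) / len(y)


def scalar_weighted_ce(q, pmf, weights, floor=1e-12) -> float:
    q = np.asarray(q).ravel()
    pmf = np.asarray(pmf).reshape(len(q), -1)
    acc = 0.0
    for i, cls in enumerate(q):
        p = max(float(pmf[i, int(cls)]), floor)
        acc += float(weights[int(cls)]) * math.log(p)
    return -acc / len(q)


def scalar_round_half_away(x: float) -> float:
    return math.copysign(math.floor(abs(x) + 0.5), x)
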