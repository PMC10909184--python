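"""Lossless residual formation and exact reconstruction.

The real-valued pixel prediction is integerized *first* (round
half-away-from-zero, clip to [0, 255]); the residual is then the exact
integer difference shifted by +255:

    Q = (real - pred_int) + 255          with Q in [0, 510]
    real = pred_int + Q - 255            (exact inverse)

Integerizing the prediction before differencing — rather than rounding a
float residual — makes the round trip an integer identity, independent of
any floating-point tie behaviour, while preserving the 511-class range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorruptStreamError, InvalidInputError, NumericError
from .image import round_half_away
from .model import PredictedSubimage

__all__ = [
    "IntegerPrediction",
    "QuantizedResidual",
    "quantize_prediction",
    "compute_quantized_residual",
    "reconstruct",
    "RESIDUAL_OFFSET",
    "N_RESIDUAL_CLASSES",
]

RESIDUAL_OFFSET = 255
N_RESIDUAL_CLASSES = 511


@dataclass(frozen=True)
class IntegerPrediction:
    """Integer pixel prediction, clipped to [0, 255]."""

    values: np.ndarray  # int16 (h, w)


@dataclass(frozen=True)
class QuantizedResidual:
    """Offset residual classes in [0, 510]."""

    classes: np.ndarray  # int16 (h, w)


def quantize_prediction(pred: PredictedSubimage | np.ndarray) -> IntegerPrediction:
    """Round half-away-from-zero, then clip to [0, 255]."""
    v = pred.values if isinstance(pred, PredictedSubimage) else np.asarray(pred)
    if not np.all(np.isfinite(v)):
        raise NumericError("prediction contains non-finite values")
    r = np.clip(round_half_away(v.astype(np.float64)), 0, 255)
    return IntegerPrediction(r.astype(np.int16))


def compute_quantized_residual(
    real: np.ndarray, pred_i: IntegerPrediction
) -> QuantizedResidual:
    """Q = (real - pred) + 255 elementwise; result provably in [0, 510]."""
    real = np.asarray(real)
    if real.shape != pred_i.values.shape:
        raise InvalidInputError(
            f"shape mismatch: real {real.shape} vs prediction {pred_i.values.shape}"
        )
    q = real.astype(np.int16) - pred_i.values + RESIDUAL_OFFSET
    return QuantizedResidual(q)


def reconstruct(pred_i: IntegerPrediction, q: QuantizedResidual) -> np.ndarray:
    """real = pred + Q - 255; exact inverse of :func:`compute_quantized_residual`."""
    if pred_i.values.shape != q.classes.shape:
        raise InvalidInputError("prediction and residual shapes differ")
    real = pred_i.values + q.classes.astype(np.int16) - RESIDUAL_OFFSET
    if np.any(real < 0) or np.any(real > 255):
        raise CorruptStreamError("reconstructed pixel out of [0, 255]")
    return real.astype(np.uint8)
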