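"""Training losses and the residual-class weight schedule.

Two terms drive training:

* the subimage prediction loss — mean absolute deviation between predicted
  and true pixel values,

      L_SPL = (1/N) Σ |y_i - ŷ_i|

* the probability prediction loss — weighted cross-entropy over the 511
  residual classes,

      L_PPL = -(1/N) Σ_i w_{q_i} · log p̂_{i, q_i}

  where q_i is the realized residual class and w is a per-class weight that
  counters the heavy concentration of residuals around class 255 (a good
  predictor makes most residuals tiny, starving the rare classes of
  gradient signal under plain cross-entropy).

The total is L = λ_SPL·L_SPL + λ_PPL·L_PPL with both λ defaulting to 1.

The default weight schedule puts weight 8 on the rare outer classes
(0–99 and 411–510), weight 1 on the common centre (200–310), and a
symmetric, monotone staircase (4, 2) in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .residual import N_RESIDUAL_CLASSES

__all__ = [
    "WeightSchedule",
    "default_weight_schedule",
    "unit_weight_schedule",
    "spl_loss",
    "ppl_loss",
    "total_loss",
    "PROB_FLOOR",
]

#: probabilities are clamped below by this before the log.
PROB_FLOOR = 1e-12

_CENTER = (N_RESIDUAL_CLASSES - 1) // 2  # 255


@dataclass(frozen=True)
class WeightSchedule:
    """Per-class loss weights given as a partition of [0, 510] into intervals.

    Invariants: the intervals exactly tile [0, 510]; weights are symmetric
    about class 255 and non-decreasing in |class - 255|.
    """

    boundaries: tuple[tuple[int, int], ...]
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if len(self.boundaries) != len(self.weights):
            raise InvalidInputError("one weight per interval required")
        ivs = sorted(self.boundaries)
        if ivs[0][0] != 0 or ivs[-1][1] != N_RESIDUAL_CLASSES - 1:
            raise InvalidInputError("intervals must cover [0, 510]")
        for (a0, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 != b0 + 1:
                raise InvalidInputError("intervals must partition [0, 510] without gaps")
        if any(w <= 0 for w in self.weights):
            raise InvalidInputError("weights must be positive")
        arr = self.as_array()
        if not np.array_equal(arr, arr[::-1]):
            raise InvalidInputError("schedule must be symmetric about class 255")
        right = arr[_CENTER:]
        if np.any(np.diff(right) < 0):
            raise InvalidInputError("weights must be non-decreasing in |class - 255|")

    def as_array(self) -> np.ndarray:
        out = np.empty(N_RESIDUAL_CLASSES, dtype=np.float64)
        for (lo, hi), w in zip(self.boundaries, self.weights):
            out[lo : hi + 1] = w
        return out

    def weight(self, cls: int) -> float:
        if not 0 <= cls < N_RESIDUAL_CLASSES:
            raise InvalidInputError(f"class {cls} outside [0, 510]")
        return float(self.as_array()[cls])


def default_weight_schedule() -> WeightSchedule:
    """Symmetric staircase: 8 | 4 | 2 | 1 | 2 | 4 | 8.

    Weight 8 on classes 0–99 and 411–510 (|residual| ≥ 156: very rare),
    weight 1 on 200–310 (|residual| ≤ 55: the bulk), with 4 and 2 filling
    the flanks symmetrically.
    """
    return WeightSchedule(
        boundaries=(
            (0, 99),
            (100, 149),
            (150, 199),
            (200, 310),
            (311, 360),
            (361, 410),
            (411, 510),
        ),
        weights=(8.0, 4.0, 2.0, 1.0, 2.0, 4.0, 8.0),
    )


def unit_weight_schedule() -> WeightSchedule:
    """All-ones schedule (plain cross-entropy); the ablation baseline."""
    return WeightSchedule(boundaries=((0, N_RESIDUAL_CLASSES - 1),), weights=(1.0,))


def spl_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute deviation between true and predicted pixel values."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise InvalidInputError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.mean(np.abs(y - y_hat)))


def ppl_loss(
    q: np.ndarray, pmf: np.ndarray, w: WeightSchedule | np.ndarray
) -> float:
    """Weighted cross-entropy of the realized residual classes.

    ``q``: integer classes, any shape; ``pmf``: matching shape + a trailing
    511 axis; ``w``: a :class:`WeightSchedule` or a length-511 array.
    """
    q = np.asarray(q)
    pmf = np.asarray(pmf, dtype=np.float64)
    if np.any(q < 0) or np.any(q >= N_RESIDUAL_CLASSES):
        raise InvalidInputError("residual class outside [0, 510]")
    if pmf.shape[:-1] != q.shape or pmf.shape[-1] != N_RESIDUAL_CLASSES:
        raise InvalidInputError(
            f"pmf shape {pmf.shape} incompatible with classes {q.shape}"
        )
    warr = w.as_array() if isinstance(w, WeightSchedule) else np.asarray(w, dtype=np.float64)
    p_true = np.take_along_axis(pmf, q[..., None].astype(np.intp), axis=-1)[..., 0]
    p_true = np.maximum(p_true, PROB_FLOOR)
    return float(-np.mean(warr[q] * np.log(p_true)))


def total_loss(l_spl: float, l_ppl: float, cfg) -> float:
    """λ_SPL·L_SPL + λ_PPL·L_PPL (λ from the training config, default 1)."""
    if not (np.isfinite(l_spl) and np.isfinite(l_ppl)):
        raise InvalidInputError("losses must be finite")
    return float(cfg.lambda_spl * l_spl + cfg.lambda_ppl * l_ppl)
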