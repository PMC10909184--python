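"""Residual analytics and the loss-ablation harness.

:func:`residual_report` runs a real compression pass and reports the
511-bin residual-class histogram together with a per-subimage bits-per-pixel
accounting (all BPP figures are relative to the *original* pixel count, so
base + D + B + C + header sums to the total stream BPP exactly).

:func:`ablation_run` trains two models that differ only in their residual
class-weight schedule (typically plain vs. weighted cross-entropy) and
tabulates the per-subimage BPP of both on an evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .container import BaseCodec, PngCodec, _HEADER_SIZE, _compress_parts, bpp
from .errors import InvalidInputError
from .image import GrayImage
from .model import ModelBundle
from .residual import N_RESIDUAL_CLASSES

__all__ = ["ResidualReport", "residual_report", "AblationTable", "ablation_run"]


@dataclass(frozen=True)
class ResidualReport:
    """Histogram + BPP accounting from one compression run."""

    histogram: np.ndarray            # (511,) counts over D, B, C residuals
    subimage_bpp: dict               # {"b": .., "c": .., "d": ..}
    base_bpp: float
    header_bpp: float
    total_bpp: float

    @property
    def mode_class(self) -> int:
        return int(np.argmax(self.histogram))


def residual_report(
    image: GrayImage, bundle: ModelBundle, base: BaseCodec | None = None
) -> ResidualReport:
    """Compress ``image`` and account for where the bits went."""
    base = base or PngCodec()
    header, payloads, residuals = _compress_parts(image, bundle, base)
    n_px = image.width * image.height

    hist = np.zeros(N_RESIDUAL_CLASSES, dtype=np.int64)
    for q in residuals.values():
        hist += np.bincount(q.classes.ravel(), minlength=N_RESIDUAL_CLASSES)

    sub_bpp = {k: bpp(len(payloads[k]), image.width, image.height) for k in ("b", "c", "d")}
    total = _HEADER_SIZE + sum(len(p) for p in payloads.values())
    return ResidualReport(
        histogram=hist,
        subimage_bpp=sub_bpp,
        base_bpp=bpp(len(payloads["a"]), image.width, image.height),
        header_bpp=bpp(_HEADER_SIZE, image.width, image.height),
        total_bpp=bpp(total, image.width, image.height),
    )


@dataclass(frozen=True)
class AblationTable:
    """Per-subimage BPP for two models, in the standard B/C/D/Total layout."""

    rows: tuple[str, ...]            # ("B", "C", "D", "Total")
    model1: dict                     # row -> BPP
    model2: dict
    labels: tuple[str, str] = ("Model1", "Model2")

    def to_text(self) -> str:
        lines = [f"{'Subimage':<10}{self.labels[0]:>10}{self.labels[1]:>10}"]
        for r in self.rows:
            lines.append(f"{r:<10}{self.model1[r]:>10.4f}{self.model2[r]:>10.4f}")
        return "\n".join(lines)

    def to_csv(self) -> str:
        lines = [f"subimage,{self.labels[0]},{self.labels[1]}"]
        for r in self.rows:
            lines.append(f"{r},{self.model1[r]:.6f},{self.model2[r]:.6f}")
        return "\n".join(lines)


def _mean_subimage_bpp(images, bundle) -> dict:
    acc = {"B": 0.0, "C": 0.0, "D": 0.0}
    for img in images:
        rep = residual_report(img, bundle)
        for k in acc:
            acc[k] += rep.subimage_bpp[k.lower()]
    out = {k: v / len(images) for k, v in acc.items()}
    out["Total"] = sum(out.values())
    return out


def ablation_run(train_dataset, cfg1, cfg2, eval_images=None) -> AblationTable:
    """Train two configs differing only in weight schedule; tabulate BPP.

    ``eval_images`` defaults to the training images. No direction of the
    difference is asserted — at reduced scale either model may win.
    """
    from .training import train, _load_pool  # local import to avoid a cycle

    base1 = replace(cfg1, weight_schedule=None)
    base2 = replace(cfg2, weight_schedule=None)
    if base1 != base2:
        raise InvalidInputError(
            "ablation configs must differ only in their weight schedule"
        )
    if eval_images is None:
        eval_images = [GrayImage(v) for v in _load_pool(train_dataset)]

    bundles = (train(train_dataset, cfg1), train(train_dataset, cfg2))
    m1, m2 = (_mean_subimage_bpp(eval_images, b) for b in bundles)
    return AblationTable(rows=("B", "C", "D", "Total"), model1=m1, model2=m2)
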