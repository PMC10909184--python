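"""Patch sampling and the training loop for the three predictor networks.

Training crops random square grayscale patches from a pool of images,
decomposes each into its four phase grids, and supervises the three
networks on their own targets with ground-truth inputs (equivalent to
coded inputs, since coding is lossless):

* net 1: {A} -> D,   * net 2: {A, D} -> B,   * net 3: {A, D, B} -> C.

Each network minimizes L = λ_SPL·L_SPL + λ_PPL·L_PPL with Adam. Defaults
follow the reference recipe: batch 24, 2000 epochs, initial learning rate
1e-3 halved every 500 epochs, 128×128 patches, λ = 1. Desk-scale smoke
training uses far smaller values of everything; the defaults are the
full-scale recipe, not a practical CPU setting.

Everything is driven by one integer seed: patch sampling, parameter
initialization, and hence the resulting bundle's version hash are all
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .decompose import decompose
from .errors import DataError, TrainingError
from .image import GrayImage, load_image
from .losses import WeightSchedule, default_weight_schedule, ppl_loss, spl_loss, total_loss
from .model import ModelBundle, NetworkConfig, softmax_channels
from .residual import compute_quantized_residual, quantize_prediction

__all__ = ["TrainingConfig", "PatchTuple", "make_patches", "train"]

logger = logging.getLogger("graylift.train")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the training run (defaults = full-scale recipe)."""

    batch_size: int = 24
    epochs: int = 2000
    lr_initial: float = 1e-3
    lr_halving_period: int = 500
    patch_size: int = 128
    lambda_spl: float = 1.0
    lambda_ppl: float = 1.0
    seed: int = 0
    patches_per_epoch: int = 240
    network: NetworkConfig = field(default_factory=NetworkConfig)
    weight_schedule: WeightSchedule | None = None  # None -> default schedule

    def __post_init__(self):
        for f in ("batch_size", "epochs", "lr_halving_period", "patch_size",
                  "patches_per_epoch"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")
        if self.patch_size % 2 or (self.patch_size // 2) % 2**self.network.n_scales:
            raise ValueError(
                "patch_size/2 must be divisible by 2**n_scales so training "
                "patches need no internal padding"
            )

    def learning_rate(self, epoch: int) -> float:
        """Learning rate at 1-based epoch number (halved every period)."""
        return self.lr_initial * 0.5 ** ((epoch - 1) // self.lr_halving_period)


class PatchTuple(NamedTuple):
    """The four phase grids of one training patch, in coding order."""

    a: np.ndarray
    d: np.ndarray
    b: np.ndarray
    c: np.ndarray


def _load_pool(dataset) -> list[np.ndarray]:
    if isinstance(dataset, (str, Path)):
        paths = sorted(
            p for p in Path(dataset).iterdir()
            if p.suffix.lower() in (".png", ".pgm", ".ppm", ".jpg", ".jpeg")
        )
        images = []
        for p in paths:
            try:
                images.append(load_image(p).values)
            except Exception:  # unreadable file: skip, fail only if none load
                logger.warning("skipping unreadable image %s", p)
        if not images:
            raise DataError(f"no readable images in {dataset}")
        return images
    pool = [im.values if isinstance(im, GrayImage) else np.asarray(im) for im in dataset]
    if not pool:
        raise DataError("empty training dataset")
    return pool


def make_patches(
    dataset, cfg: TrainingConfig, seed: int, n_patches: int | None = None
) -> Iterator[PatchTuple]:
    """Yield random decomposed patches, reproducibly under the seed.

    ``dataset`` is a directory of images or a sequence of grayscale arrays /
    :class:`GrayImage`. Images smaller than the patch size are edge-padded.
    """
    pool = _load_pool(dataset)
    rng = np.random.default_rng(seed)
    ps = cfg.patch_size
    n = cfg.patches_per_epoch if n_patches is None else n_patches
    for _ in range(n):
        img = pool[int(rng.integers(len(pool)))]
        h, w = img.shape
        if h < ps or w < ps:
            img = np.pad(img, ((0, max(0, ps - h)), (0, max(0, ps - w))), mode="edge")
            h, w = img.shape
        y = int(rng.integers(h - ps + 1))
        x = int(rng.integers(w - ps + 1))
        subs = decompose(GrayImage(img[y : y + ps, x : x + ps]))
        yield PatchTuple(subs.a, subs.d, subs.b, subs.c)


def _train_step(net, opt, inputs: np.ndarray, target: np.ndarray, w: np.ndarray,
                cfg: TrainingConfig, lr: float) -> tuple[float, float]:
    """One Adam step on one network; returns (L_SPL, L_PPL)."""
    x = inputs.astype(np.float32) / np.float32(255.0)
    mm = net.extract_features(x)
    pred = net.predict_head(mm)            # (n, h, w), 0..255 scale
    logits = net.pmf_logits(mm)            # (n, K, h, w)

    n_tot = float(target.size)
    # residual classes from the integerized prediction (targets, no gradient)
    q = compute_quantized_residual(target.reshape(pred.shape),
                                   quantize_prediction(pred)).classes

    probs = softmax_channels(logits)
    l_spl = spl_loss(target.reshape(pred.shape), pred)
    l_ppl = ppl_loss(q, np.moveaxis(probs, 1, -1), w)

    # dL/d(pred): λ_SPL · (-sign(y - ŷ)) / N
    diff = target.reshape(pred.shape).astype(np.float32) - pred
    g_pred = (-np.sign(diff) * np.float32(cfg.lambda_spl / n_tot)).astype(np.float32)

    # dL/d(logits): λ_PPL · w_q · (p - onehot(q)) / N
    onehot_sub = np.take_along_axis(probs, q[:, None].astype(np.intp), axis=1)
    wq = w.astype(np.float32)[q][:, None]
    g_logits = probs * wq
    np.put_along_axis(
        g_logits, q[:, None].astype(np.intp),
        (onehot_sub - 1.0) * wq, axis=1,
    )
    g_logits *= np.float32(cfg.lambda_ppl / n_tot)

    net.zero_grad()
    net.backward(g_pred, g_logits.astype(np.float32))
    opt.step(lr)
    return l_spl, l_ppl


def train(dataset, cfg: TrainingConfig) -> ModelBundle:
    """Train the three networks; returns the bundle (seed-deterministic).

    Raises :class:`TrainingError` if any loss goes non-finite. Per-epoch
    losses are emitted on the ``graylift.train`` logger.
    """
    bundle = ModelBundle.create(cfg.network, seed=cfg.seed)
    schedule = cfg.weight_schedule or default_weight_schedule()
    w = schedule.as_array()
    opts = {n: bundle.nets[n].make_optimizer() for n in (1, 2, 3)}
    pool = _load_pool(dataset)

    history = []
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.learning_rate(epoch)
        patches = list(make_patches(pool, cfg, seed=np.random.SeedSequence(
            [cfg.seed, epoch]).generate_state(1)[0] % (2**31)))
        epoch_losses = np.zeros(2)
        n_batches = 0
        for start in range(0, len(patches), cfg.batch_size):
            batch = patches[start : start + cfg.batch_size]
            a = np.stack([p.a for p in batch])
            d = np.stack([p.d for p in batch])
            b = np.stack([p.b for p in batch])
            c = np.stack([p.c for p in batch])
            for n, (inputs, target) in enumerate(
                ((a[:, None], d), (np.stack([a, d], 1), b), (np.stack([a, d, b], 1), c)),
                start=1,
            ):
                ls, lp = _train_step(bundle.nets[n], opts[n], inputs, target, w, cfg, lr)
                if not (np.isfinite(ls) and np.isfinite(lp)):
                    raise TrainingError(f"non-finite loss at epoch {epoch} (net {n})")
                epoch_losses += (ls, lp)
            n_batches += 1
        epoch_losses /= max(n_batches * 3, 1)
        history.append(total_loss(epoch_losses[0], epoch_losses[1], cfg))
        logger.info(
            "epoch %d lr=%.2e L_SPL=%.4f L_PPL=%.4f total=%.4f",
            epoch, lr, epoch_losses[0], epoch_losses[1], history[-1],
        )
    bundle.loss_history = history
    return bundle
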