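"""The learned predictor: one shared feature pass, two heads.

Each network takes the already-coded subimages (N ∈ {1, 2, 3} half-resolution
grids, normalized to [0, 1]) and produces, from a single shared latent grid
(the *Middle Matrix*):

* a real-valued prediction of the next subimage's pixels, and
* a 511-way softmax probability field over the offset residual classes,
  computed by a U-Net with skip connections.

Three independent networks are kept — one per input count — because the
statistics of predicting D from {A} differ from predicting C from {A, D, B};
they share no parameters.

Architecture choices (the published description leaves them open): residual
blocks are two 3×3 convolutions with an additive skip; a downward process is
a stride-2 convolution followed by residual blocks; an upward process is
nearest-neighbour upsampling, a 3×3 convolution, concatenation of the
matching encoder scale, and a residual block. Channels double per scale,
capped at 512. Spatial dims are mirror-padded to a multiple of ``2**n_scales``
before the U-Net and cropped after, so any subimage size is accepted.

Inference runs in float32 with plain NumPy operations, so the encoder and
decoder compute bit-identical predictions — the property losslessness
rests on.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from .errors import ConfigError, CorruptStreamError, InvalidInputError
from .nnet import (
    Adam,
    Conv2d,
    NearestUp2,
    Param,
    ReLU,
    ResBlock,
    mirror_pad2d,
    mirror_pad2d_backward,
)

__all__ = [
    "NetworkConfig",
    "PredictedSubimage",
    "ResidualPMF",
    "PredictorNet",
    "ModelBundle",
    "extract_features",
    "predict_subimage",
    "predict_residual_pmf",
    "infer",
    "softmax_channels",
]

#: Number of residual classes: (real - pred) + 255 with both in [0,255].
N_CLASSES = 511

#: Channel cap when doubling per scale.
_CH_CAP = 512


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters shared by the three networks."""

    n_inputs: int = 1
    base_channels: int = 64
    n_scales: int = 4
    n_classes: int = N_CLASSES
    resblock_depth: int = 1

    def __post_init__(self):
        if self.n_inputs not in (1, 2, 3):
            raise ConfigError(f"n_inputs must be 1, 2 or 3, got {self.n_inputs}")
        for f in ("base_channels", "n_scales", "n_classes", "resblock_depth"):
            if getattr(self, f) < 1:
                raise ConfigError(f"{f} must be positive")
        if self.base_channels < 2:
            raise ConfigError("base_channels must be >= 2 (one channel is the DC shortcut)")

    def with_inputs(self, n: int) -> "NetworkConfig":
        return replace(self, n_inputs=n)

    def channels_at(self, scale: int) -> int:
        return min(self.base_channels * 2**scale, _CH_CAP)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class PredictedSubimage:
    """Real-valued (unclipped) pixel prediction for one subimage."""

    values: np.ndarray  # (h, w) float32, nominally on the 0..255 scale


@dataclass(frozen=True)
class ResidualPMF:
    """Per-pixel probability field over the 511 residual classes, (h, w, 511)."""

    probs: np.ndarray

    def validate(self, atol: float = 1e-5) -> None:
        if self.probs.shape[-1] != N_CLASSES:
            raise InvalidInputError(f"expected {N_CLASSES} classes")
        if np.any(self.probs < 0):
            raise InvalidInputError("negative probability")
        s = self.probs.sum(axis=-1)
        if np.any(np.abs(s - 1.0) > atol):
            raise InvalidInputError("per-pixel probabilities do not sum to 1")


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over axis 1 of an (n, K, h, w) array."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


class PredictorNet:
    """One network: preprocessing trunk, pixel head, U-Net probability head."""

    def __init__(self, config: NetworkConfig, *, rng: np.random.Generator, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        cfg = config
        C = cfg.base_channels
        S = cfg.n_scales
        depth = cfg.resblock_depth

        # preprocessing trunk: C-1 learned feature channels; the Middle
        # Matrix's last channel is the mean of the input subimages (a DC
        # shortcut), so an untrained predictor already outputs the
        # neighbour average and training only learns corrections.
        self.pre_conv = Conv2d(cfg.n_inputs, C - 1, 3, rng=rng, dtype=dtype, name="pre.conv")
        self.pre_relu = ReLU()
        self.pre_blocks = [
            ResBlock(C - 1, C - 1, rng=rng, dtype=dtype, name=f"pre.res{i}")
            for i in range(depth)
        ]

        # pixel-prediction head (small conv stack, separate from the U-Net)
        self.ph_conv1 = Conv2d(C, C, 3, rng=rng, dtype=dtype, name="ph.conv1")
        self.ph_relu = ReLU()
        self.ph_conv2 = Conv2d(C, 1, 1, rng=rng, dtype=dtype, name="ph.conv2")

        # U-Net probability head
        self.enc0_blocks = [
            ResBlock(C, C, rng=rng, dtype=dtype, name=f"enc0.res{i}") for i in range(depth)
        ]
        self.down_convs, self.down_relus, self.down_blocks = [], [], []
        for s in range(1, S + 1):
            ci, co = cfg.channels_at(s - 1), cfg.channels_at(s)
            self.down_convs.append(
                Conv2d(ci, co, 3, stride=2, rng=rng, dtype=dtype, name=f"down{s}.conv")
            )
            self.down_relus.append(ReLU())
            self.down_blocks.append(
                [ResBlock(co, co, rng=rng, dtype=dtype, name=f"down{s}.res{i}") for i in range(depth)]
            )
        self.up_ups, self.up_convs, self.up_relus, self.up_blocks = [], [], [], []
        for s in range(S, 0, -1):
            ci, co = cfg.channels_at(s), cfg.channels_at(s - 1)
            self.up_ups.append(NearestUp2())
            self.up_convs.append(Conv2d(ci, co, 3, rng=rng, dtype=dtype, name=f"up{s}.conv"))
            self.up_relus.append(ReLU())
            blocks = [ResBlock(2 * co, co, rng=rng, dtype=dtype, name=f"up{s}.res0")]
            blocks += [
                ResBlock(co, co, rng=rng, dtype=dtype, name=f"up{s}.res{i}")
                for i in range(1, depth)
            ]
            self.up_blocks.append(blocks)
        self.final = Conv2d(C, cfg.n_classes, 1, rng=rng, dtype=dtype, name="final")

        self._unet_cache = None

    # -- parameter plumbing ------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []

        def add(m):
            out.extend(m.params())

        add(self.pre_conv)
        for b in self.pre_blocks:
            add(b)
        add(self.ph_conv1)
        add(self.ph_conv2)
        for b in self.enc0_blocks:
            add(b)
        for conv, blocks in zip(self.down_convs, self.down_blocks):
            add(conv)
            for b in blocks:
                add(b)
        for conv, blocks in zip(self.up_convs, self.up_blocks):
            add(conv)
            for b in blocks:
                add(b)
        add(self.final)
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def set_all_zero(self) -> None:
        """Zero every parameter (used to exercise linearity contracts)."""
        for p in self.params():
            p.data[...] = 0

    # -- forward -----------------------------------------------------------

    def extract_features(self, x: np.ndarray) -> np.ndarray:
        """Input stack (n, N, h, w) in [0, 1] -> Middle Matrix (n, C, h, w)."""
        if x.ndim != 4:
            raise InvalidInputError(f"expected (n, N, h, w) input, got shape {x.shape}")
        if x.shape[1] != self.config.n_inputs:
            raise ConfigError(
                f"network expects {self.config.n_inputs} input subimages, got {x.shape[1]}"
            )
        x = x.astype(self.dtype, copy=False)
        h = self.pre_relu.forward(self.pre_conv.forward(x))
        for b in self.pre_blocks:
            h = b.forward(h)
        dc = x.mean(axis=1, keepdims=True, dtype=self.dtype)
        return np.concatenate([h, dc], axis=1)

    def predict_head(self, mm: np.ndarray) -> np.ndarray:
        """Middle Matrix -> pixel prediction (n, h, w) on the 0..255 scale.

        The head adds the DC channel (mean of the coded subimages) to its
        convolutional output, so it predicts a correction to the neighbour
        average rather than an absolute intensity.
        """
        r = self.ph_conv2.forward(self.ph_relu.forward(self.ph_conv1.forward(mm)))
        return 255.0 * (r[:, 0] + mm[:, -1])

    def pmf_logits(self, mm: np.ndarray) -> np.ndarray:
        """Middle Matrix -> residual-class logits (n, K, h, w) via the U-Net."""
        n, c, h, w = mm.shape
        S = self.config.n_scales
        mult = 2**S
        ph, pw = (-h) % mult, (-w) % mult
        if ph or pw:
            x, idx = mirror_pad2d(mm, ph, pw)
        else:
            x, idx = mm, None

        feats = []
        for b in self.enc0_blocks:
            x = b.forward(x)
        feats.append(x)
        for conv, relu, blocks in zip(self.down_convs, self.down_relus, self.down_blocks):
            x = relu.forward(conv.forward(x))
            for b in blocks:
                x = b.forward(x)
            feats.append(x)
        x = feats[-1]
        for i, (up, conv, relu, blocks) in enumerate(
            zip(self.up_ups, self.up_convs, self.up_relus, self.up_blocks)
        ):
            skip = feats[S - 1 - i]
            x = relu.forward(conv.forward(up.forward(x)))
            x = np.concatenate([x, skip], axis=1)
            for b in blocks:
                x = b.forward(x)
        logits_pad = self.final.forward(x)
        self._unet_cache = (h, w, ph, pw, idx, logits_pad.shape)
        return logits_pad[:, :, :h, :w]

    def forward(self, x: np.ndarray):
        """One pass: (Middle Matrix, pixel prediction, residual logits)."""
        mm = self.extract_features(x)
        return mm, self.predict_head(mm), self.pmf_logits(mm)

    # -- backward (training) -------------------------------------------------

    def backward(self, g_pred: np.ndarray, g_logits: np.ndarray) -> None:
        """Accumulate parameter gradients for both heads and the trunk.

        ``g_pred`` is dL/d(prediction) of shape (n, h, w); ``g_logits`` is
        dL/d(logits) of shape (n, K, h, w). Must follow a :meth:`forward`.
        """
        # pixel head (conv path plus the additive DC skip)
        g_raw = (g_pred * np.asarray(255.0, dtype=self.dtype))[:, None]
        g_mm = self.ph_conv1.backward(
            self.ph_relu.backward(self.ph_conv2.backward(g_raw))
        )
        g_mm[:, -1] += g_raw[:, 0]

        # U-Net head
        h, w, ph, pw, idx, pad_shape = self._unet_cache
        S = self.config.n_scales
        if ph or pw:
            gpad = np.zeros(pad_shape, dtype=g_logits.dtype)
            gpad[:, :, :h, :w] = g_logits
        else:
            gpad = g_logits
        g = self.final.backward(gpad)

        g_levels: list[np.ndarray | None] = [None] * (S + 1)
        # decoder stages, reverse execution order (the i-th executed stage
        # handled scale s = S - i; backward walks i = last .. first)
        for i in range(S - 1, -1, -1):
            s = S - i  # scale whose features this stage consumed
            blocks = self.up_blocks[i]
            for b in reversed(blocks):
                g = b.backward(g)
            co = self.config.channels_at(s - 1)
            g_main, g_skip = g[:, :co], g[:, co:]
            lvl = s - 1
            if g_levels[lvl] is None:
                g_levels[lvl] = g_skip.copy()
            else:
                g_levels[lvl] += g_skip
            g = self.up_ups[i].backward(
                self.up_convs[i].backward(self.up_relus[i].backward(g_main))
            )
            if i > 0:
                # grad w.r.t. decoder feature at scale s continues to the
                # previously executed stage -- nothing to stash
                continue
        # g is now the gradient w.r.t. feats[S] (the encoder bottom)
        if g_levels[S] is None:
            g_levels[S] = g
        else:
            g_levels[S] += g

        for s in range(S, 0, -1):
            ge = g_levels[s]
            for b in reversed(self.down_blocks[s - 1]):
                ge = b.backward(ge)
            ge = self.down_convs[s - 1].backward(self.down_relus[s - 1].backward(ge))
            if g_levels[s - 1] is None:
                g_levels[s - 1] = ge
            else:
                g_levels[s - 1] += ge
        g0 = g_levels[0]
        for b in reversed(self.enc0_blocks):
            g0 = b.backward(g0)
        if idx is not None:
            g0 = mirror_pad2d_backward(g0, (h, w), idx)
        g_mm += g0

        # shared trunk (the DC channel is parameter-free: its grad stops here)
        g_trunk = g_mm[:, :-1]
        for b in reversed(self.pre_blocks):
            g_trunk = b.backward(g_trunk)
        self.pre_conv.backward(self.pre_relu.backward(g_trunk))

    def make_optimizer(self) -> Adam:
        return Adam(self.params())


# ---------------------------------------------------------------------------
# bundle of the three networks
# ---------------------------------------------------------------------------

class ModelBundle:
    """Three independent networks keyed by their input-subimage count.

    ``inference_count`` increments on every :func:`infer` call, so callers
    can verify the one-inference-per-subimage accounting.
    """

    def __init__(self, nets: dict[int, PredictorNet], config: NetworkConfig):
        if set(nets) != {1, 2, 3}:
            raise ConfigError("bundle must hold networks for n_inputs = 1, 2, 3")
        for n, net in nets.items():
            if net.config.n_inputs != n:
                raise ConfigError(f"network under key {n} expects {net.config.n_inputs} inputs")
        self.nets = nets
        self.config = config
        self.inference_count = 0

    @classmethod
    def create(cls, config: NetworkConfig | None = None, seed: int = 0) -> "ModelBundle":
        config = config or NetworkConfig()
        nets = {}
        for n in (1, 2, 3):
            rng = np.random.default_rng([seed, n])
            nets[n] = PredictorNet(config.with_inputs(n), rng=rng)
        return cls(nets, config)

    @property
    def version_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.config.to_json().encode())
        for n in (1, 2, 3):
            for p in self.nets[n].params():
                h.update(p.name.encode())
                h.update(np.ascontiguousarray(p.data, dtype=np.float32).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        arrays = {}
        for n in (1, 2, 3):
            for i, p in enumerate(self.nets[n].params()):
                arrays[f"net{n}.{i:04d}.{p.name}"] = p.data
        meta = json.dumps({"config": self.config.to_json(), "hash": self.version_hash})
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
        with open(path, "wb") as f:
            f.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            config = NetworkConfig.from_json(meta["config"])
            bundle = cls.create(config, seed=0)
            for n in (1, 2, 3):
                for i, p in enumerate(bundle.nets[n].params()):
                    key = f"net{n}.{i:04d}.{p.name}"
                    if key not in z:
                        raise CorruptStreamError(f"checkpoint missing parameter {key}")
                    data = z[key]
                    if data.shape != p.data.shape:
                        raise CorruptStreamError(f"checkpoint shape mismatch for {key}")
                    p.data[...] = data
        if bundle.version_hash != meta["hash"]:
            raise CorruptStreamError("checkpoint hash does not match its parameters")
        return bundle


# ---------------------------------------------------------------------------
# functional operations on subimage stacks
# ---------------------------------------------------------------------------

def _stack_inputs(subimages) -> np.ndarray:
    """Normalize a sequence of (h, w) grids in [0, 255] to a (1, N, h, w) stack."""
    grids = [np.asarray(g) for g in subimages]
    if not grids:
        raise InvalidInputError("at least one input subimage required")
    shape = grids[0].shape
    for g in grids:
        if g.ndim != 2 or g.shape != shape:
            raise InvalidInputError("input subimages must all share one 2-D shape")
    x = np.stack(grids).astype(np.float32) / np.float32(255.0)
    return x[None]


def extract_features(subimages, net: PredictorNet) -> np.ndarray:
    """Run the preprocessing trunk; returns the Middle Matrix as (h, w, C)."""
    mm = net.extract_features(_stack_inputs(subimages))
    return np.transpose(mm[0], (1, 2, 0))


def predict_subimage(mm: np.ndarray, net: PredictorNet) -> PredictedSubimage:
    """Pixel prediction from an (h, w, C) Middle Matrix."""
    x = np.transpose(np.asarray(mm, dtype=np.float32), (2, 0, 1))[None]
    return PredictedSubimage(net.predict_head(x)[0])


def predict_residual_pmf(mm: np.ndarray, net: PredictorNet) -> ResidualPMF:
    """Residual-class probabilities from an (h, w, C) Middle Matrix."""
    x = np.transpose(np.asarray(mm, dtype=np.float32), (2, 0, 1))[None]
    logits = net.pmf_logits(x)
    probs = softmax_channels(logits)[0]
    return ResidualPMF(np.transpose(probs, (1, 2, 0)))


def infer(subimages, bundle: ModelBundle) -> tuple[PredictedSubimage, ResidualPMF]:
    """Single-pass inference: one trunk evaluation feeds both heads."""
    n = len(subimages)
    if n not in bundle.nets:
        raise ConfigError(f"bundle has no network for {n} input subimages")
    net = bundle.nets[n]
    x = _stack_inputs(subimages)
    mm = net.extract_features(x)
    pred = net.predict_head(mm)[0]
    probs = softmax_channels(net.pmf_logits(mm))[0]
    bundle.inference_count += 1
    return PredictedSubimage(pred), ResidualPMF(np.transpose(probs, (1, 2, 0)))
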