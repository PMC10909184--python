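"""Deterministic synthetic grayscale images for tests and examples.

Five families stand in for real CT/X-ray material, chosen to exercise both
residual regimes a learned codec meets in practice: piecewise-smooth content
the predictor handles well (constant, gradient, blobs, phantom interiors)
and content it cannot (uniform noise, phantom edges).

* ``constant`` — a single intensity.
* ``gradient`` — a monotone ramp down the rows (strictly increasing or
  decreasing row means for images up to ~127 rows) plus a mild column tilt.
* ``gaussian-blobs`` — a few soft Gaussian bumps on a dark background.
* ``uniform-noise`` — i.i.d. uniform pixels; incompressible by design.
* ``ct-phantom`` — a bright elliptical rim around a mid-intensity interior
  with embedded lesion-like disks, on a dark background, plus additive
  Gaussian noise: sharp edges and smooth regions in one image.

Generation is pure NumPy, sub-second, and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .image import GrayImage

__all__ = ["SyntheticSpec", "generate", "KINDS"]

KINDS = ("constant", "gradient", "gaussian-blobs", "uniform-noise", "ct-phantom")


@dataclass(frozen=True)
class SyntheticSpec:
    kind: str
    width: int
    height: int
    seed: int = 0
    noise_sigma: float = 0.0
    value: int | None = None  # fixed intensity for the constant kind

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidInputError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        if self.width < 1 or self.height < 1:
            raise InvalidInputError("width and height must be positive")


def _add_noise(img: np.ndarray, sigma: float, rng) -> np.ndarray:
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, img.shape)
    return img


def generate(spec: SyntheticSpec) -> GrayImage:
    """Render the specified synthetic image (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    if spec.kind == "constant":
        v = spec.value if spec.value is not None else int(rng.integers(0, 256))
        img = np.full((h, w), float(v))

    elif spec.kind == "gradient":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # step >= 2 makes row means strictly monotone after rounding; for
        # taller images the ramp is stretched across the full range instead
        row_step = 2.0 if h <= 128 else 254.0 / (h - 1)
        base = yy * row_step * sign
        base -= base.min()
        tilt = xx * (rng.uniform(0.1, 0.5) / max(w, 1))
        img = np.clip(base + tilt, 0, 255)

    elif spec.kind == "gaussian-blobs":
        img = np.full((h, w), 20.0)
        for _ in range(int(rng.integers(2, 6))):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            s = rng.uniform(max(2.0, min(h, w) / 10), max(3.0, min(h, w) / 3))
            amp = rng.uniform(60, 200)
            img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
        img = _add_noise(img, spec.noise_sigma, rng)

    elif spec.kind == "uniform-noise":
        img = rng.integers(0, 256, (h, w)).astype(np.float64)

    else:  # ct-phantom
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        ry, rx = max(h * 0.42, 1.0), max(w * 0.42, 1.0)
        r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
        img = np.full((h, w), 5.0)          # air
        img[r < 1.0] = 220.0                 # skull-like rim
        img[r < 0.88] = 90.0                 # soft tissue
        for _ in range(int(rng.integers(1, 4))):  # lesion-like inclusions
            ly = cy + rng.uniform(-0.4, 0.4) * ry
            lx = cx + rng.uniform(-0.4, 0.4) * rx
            lr = rng.uniform(0.05, 0.18) * min(ry, rx)
            mask = (yy - ly) ** 2 + (xx - lx) ** 2 < lr * lr
            img[mask] = rng.uniform(120, 180)
        sigma = spec.noise_sigma if spec.noise_sigma > 0 else 2.0
        img = _add_noise(img, sigma, rng)

    return GrayImage(np.clip(np.rint(img), 0, 255).astype(np.uint8))
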