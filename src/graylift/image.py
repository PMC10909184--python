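"""8-bit grayscale image I/O and the GrayImage container.

Images are held as ``numpy.uint8`` arrays of shape ``(height, width)``.
PNG and PGM are read and written through Pillow; RGB(A) inputs are reduced
to luma with the ITU-R BT.601 coefficients, rounded half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidInputError

__all__ = ["GrayImage", "load_image", "save_image", "rgb_to_gray", "round_half_away"]

#: ITU-R BT.601 luma coefficients for R, G, B.
_BT601 = np.array([0.299, 0.587, 0.114])


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest integer with halves going away from zero.

    This is the single rounding convention used throughout the codec
    (``numpy.round`` rounds halves to even, which is avoided on purpose).
    """
    x = np.asarray(x)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """A W×H grid of integer intensities in [0, 255].

    Attributes
    ----------
    values:
        ``uint8`` array of shape ``(height, width)``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise InvalidInputError(
                f"GrayImage requires a non-empty 2-D grid, got shape {v.shape}"
            )
        if v.dtype != np.uint8:
            if np.any(v < 0) or np.any(v > 255):
                raise InvalidInputError("pixel values must lie in [0, 255]")
            v = v.astype(np.uint8)
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return int(self.values.shape[0])

    @property
    def width(self) -> int:
        return int(self.values.shape[1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) uint8 RGB array to uint8 luma (BT.601).

    ``Y = 0.299 R + 0.587 G + 0.114 B``, rounded half-away-from-zero.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise InvalidInputError(f"expected (H, W, 3) RGB array, got shape {rgb.shape}")
    y = rgb[..., :3].astype(np.float64) @ _BT601
    return np.clip(round_half_away(y), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> GrayImage:
    """Load a PNG or PGM file as a grayscale image.

    Color inputs are converted to grayscale via BT.601 luma; palette images
    are expanded first. 16-bit inputs are not supported.
    """
    with Image.open(path) as im:
        if im.mode in ("L",):
            arr = np.asarray(im, dtype=np.uint8)
        elif im.mode in ("P", "RGB", "RGBA", "LA"):
            arr = rgb_to_gray(np.asarray(im.convert("RGB"), dtype=np.uint8))
        else:
            raise InvalidInputError(f"unsupported image mode {im.mode!r} in {path}")
    return GrayImage(arr)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write a grayscale image as PNG or PGM, chosen by file extension."""
    path = Path(path)
    pil = Image.fromarray(img.values, mode="L")
    fmt = {".png": "PNG", ".pgm": "PPM"}.get(path.suffix.lower())
    if fmt is None:
        raise InvalidInputError(f"unsupported output extension {path.suffix!r}")
    pil.save(path, format=fmt)
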