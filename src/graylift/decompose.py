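"""Bijective 2×2 polyphase decomposition of a grayscale image.

The image is split on its 2×2 sampling lattice into four half-resolution
phase grids:

* ``A`` — odd rows, odd columns (1-based), i.e. the top-left pixel of every
  2×2 block,
* ``B`` — odd rows, even columns,
* ``C`` — even rows, odd columns,
* ``D`` — even rows, even columns.

Odd image dimensions are edge-replicated to even size before splitting; the
padding flags and original dimensions travel with the result so that
:func:`recompose` can crop back and ``recompose(decompose(x)) == x`` holds
for every image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .image import GrayImage

__all__ = ["SubimageSet", "decompose", "recompose", "SUBIMAGE_ORDER"]

#: Coding order used throughout the codec: A is base-coded, then D, B, C are
#: predicted from {A}, {A, D} and {A, D, B} respectively.
SUBIMAGE_ORDER = ("a", "d", "b", "c")


@dataclass(frozen=True)
class SubimageSet:
    """The four phase grids of an image plus the bookkeeping to invert.

    All four grids share the shape ``(ceil(H/2), ceil(W/2))``.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    orig_width: int
    orig_height: int
    row_padded: bool
    col_padded: bool

    def __post_init__(self) -> None:
        shapes = {g.shape for g in (self.a, self.b, self.c, self.d)}
        if len(shapes) != 1:
            raise InvalidInputError(f"subimage grids differ in shape: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.a.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


def decompose(image: GrayImage) -> SubimageSet:
    """Split an image into its four polyphase subimages.

    Odd height/width is first extended by replicating the last row/column,
    so all four grids come out the same size.
    """
    v = image.values
    h, w = v.shape
    row_padded = h % 2 == 1
    col_padded = w % 2 == 1
    if row_padded:
        v = np.concatenate([v, v[-1:, :]], axis=0)
    if col_padded:
        v = np.concatenate([v, v[:, -1:]], axis=1)
    return SubimageSet(
        a=v[0::2, 0::2].copy(),
        b=v[0::2, 1::2].copy(),
        c=v[1::2, 0::2].copy(),
        d=v[1::2, 1::2].copy(),
        orig_width=w,
        orig_height=h,
        row_padded=row_padded,
        col_padded=col_padded,
    )


def recompose(subs: SubimageSet) -> GrayImage:
    """Interleave the four phase grids back into the original image."""
    gh, gw = subs.grid_shape
    full = np.empty((2 * gh, 2 * gw), dtype=np.uint8)
    full[0::2, 0::2] = subs.a
    full[0::2, 1::2] = subs.b
    full[1::2, 0::2] = subs.c
    full[1::2, 1::2] = subs.d
    out = full[: subs.orig_height, : subs.orig_width]
    if out.shape != (subs.orig_height, subs.orig_width):
        raise InvalidInputError(
            "subimage grids too small for the recorded original dimensions"
        )
    return GrayImage(out.copy())
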