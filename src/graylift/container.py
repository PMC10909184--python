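"""End-to-end codec pipeline and the .glc container.

Compression: decompose the image on its 2×2 lattice; code subimage A with a
conventional lossless base codec (PNG by default, JPEG-XL when the external
cjxl/djxl binaries are available); then, in the fixed order D, B, C, run one
network inference per subimage to get the pixel prediction and the per-pixel
511-way residual probabilities, integerize the prediction, form the offset
residual classes, quantize the probabilities to 16-bit CDFs, and range-code
the classes. The container stores the header, the base payload and the three
residual payloads.

Decompression mirrors this exactly: decode A, then for D, B, C re-run the
same inference on the already-decoded subimages (bit-identical to the
encoder's, since inference is deterministic float32), decode the classes and
reconstruct. The header carries a hash of the model bundle (the decoder
refuses a mismatched model before touching pixels) and a checksum of the
original pixels, so losslessness is verified on every decode.

The byte layout is specified in FORMAT.md.
"""

from __future__ import annotations

import hashlib
import io
import shutil
import struct
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .coder import DEFAULT_PRECISION, decode as rc_decode, encode as rc_encode, quantize_pmf_batch
from .decompose import SubimageSet, decompose, recompose
from .errors import (
    CodecError,
    ConfigError,
    CorruptStreamError,
    InvalidInputError,
    ModelMismatchError,
)
from .image import GrayImage
from .model import ModelBundle, infer
from .residual import (
    QuantizedResidual,
    compute_quantized_residual,
    quantize_prediction,
    reconstruct,
)

__all__ = [
    "BaseCodec",
    "PngCodec",
    "JxlCodec",
    "get_base_codec",
    "compress",
    "decompress",
    "bpp",
    "MAGIC",
    "FORMAT_VERSION",
]

MAGIC = b"GLC1"
#: version 1 pins the coding order A -> D -> B -> C.
FORMAT_VERSION = 1

_HEADER_FMT = "<4sBBBB II 16s 16s IIII"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)


class BaseCodec:
    """Lossless codec interface for subimage A."""

    codec_id: int = -1

    def encode(self, sub: np.ndarray) -> bytes:
        raise NotImplementedError

    def decode(self, data: bytes) -> np.ndarray:
        raise NotImplementedError


class PngCodec(BaseCodec):
    """PNG through Pillow; always available, always lossless."""

    codec_id = 0

    def encode(self, sub: np.ndarray) -> bytes:
        buf = io.BytesIO()
        Image.fromarray(sub, mode="L").save(buf, format="PNG", optimize=True)
        return buf.getvalue()

    def decode(self, data: bytes) -> np.ndarray:
        with Image.open(io.BytesIO(data)) as im:
            return np.asarray(im.convert("L"), dtype=np.uint8)


class JxlCodec(BaseCodec):
    """Lossless JPEG-XL via external cjxl/djxl binaries, when installed."""

    codec_id = 1

    def __init__(self):
        if shutil.which("cjxl") is None or shutil.which("djxl") is None:
            raise CodecError("cjxl/djxl binaries not found on PATH")

    def _run(self, args, indata: bytes, inname: str, outname: str) -> bytes:
        with tempfile.TemporaryDirectory() as td:
            ip, op = Path(td) / inname, Path(td) / outname
            ip.write_bytes(indata)
            proc = subprocess.run(
                [args[0], str(ip), str(op), *args[1:]], capture_output=True
            )
            if proc.returncode != 0:
                raise CodecError(f"{args[0]} failed: {proc.stderr.decode(errors='replace')}")
            return op.read_bytes()

    def encode(self, sub: np.ndarray) -> bytes:
        buf = io.BytesIO()
        Image.fromarray(sub, mode="L").save(buf, format="PNG")
        return self._run(["cjxl", "-d", "0"], buf.getvalue(), "in.png", "out.jxl")

    def decode(self, data: bytes) -> np.ndarray:
        png = self._run(["djxl"], data, "in.jxl", "out.png")
        with Image.open(io.BytesIO(png)) as im:
            return np.asarray(im.convert("L"), dtype=np.uint8)


def get_base_codec(name: str) -> BaseCodec:
    if name == "png":
        return PngCodec()
    if name == "jxl":
        return JxlCodec()
    raise ConfigError(f"unknown base codec {name!r} (choose png or jxl)")

_CODECS_BY_ID = {0: PngCodec, 1: JxlCodec}


def _image_checksum(img: GrayImage) -> bytes:
    h = hashlib.sha256()
    h.update(struct.pack("<II", img.width, img.height))
    h.update(np.ascontiguousarray(img.values).tobytes())
    return h.digest()[:16]


def _model_hash16(bundle: ModelBundle) -> bytes:
    return bytes.fromhex(bundle.version_hash)[:16]


@dataclass(frozen=True)
class ContainerHeader:
    version: int
    row_padded: bool
    col_padded: bool
    base_codec_id: int
    precision: int
    orig_width: int
    orig_height: int
    model_hash: bytes
    image_checksum: bytes
    payload_lengths: tuple[int, int, int, int]  # A, D, B, C

    def pack(self) -> bytes:
        flags = int(self.row_padded) | (int(self.col_padded) << 1)
        return struct.pack(
            _HEADER_FMT,
            MAGIC,
            self.version,
            flags,
            self.base_codec_id,
            self.precision,
            self.orig_width,
            self.orig_height,
            self.model_hash,
            self.image_checksum,
            *self.payload_lengths,
        )

    @classmethod
    def unpack(cls, data: bytes) -> "ContainerHeader":
        if len(data) < _HEADER_SIZE:
            raise CorruptStreamError("stream shorter than the container header")
        (magic, version, flags, codec_id, precision, w, h, mh, chk, la, ld, lb, lc) = (
            struct.unpack_from(_HEADER_FMT, data)
        )
        if magic != MAGIC:
            raise CorruptStreamError("bad magic bytes; not a .glc stream")
        if version != FORMAT_VERSION:
            raise CorruptStreamError(f"unsupported format version {version}")
        return cls(
            version=version,
            row_padded=bool(flags & 1),
            col_padded=bool(flags & 2),
            base_codec_id=codec_id,
            precision=precision,
            orig_width=w,
            orig_height=h,
            model_hash=mh,
            image_checksum=chk,
            payload_lengths=(la, ld, lb, lc),
        )


def _predict_and_model(inputs, bundle: ModelBundle):
    """One inference; returns (integer prediction, (n_pix, 512) cdf matrix, pmf rows)."""
    pred, pmf = infer(inputs, bundle)
    pred_i = quantize_prediction(pred)
    rows = pmf.probs.reshape(-1, pmf.probs.shape[-1])
    cdfs = quantize_pmf_batch(rows, DEFAULT_PRECISION)
    return pred_i, cdfs, rows


def _compress_parts(image: GrayImage, bundle: ModelBundle, base: BaseCodec):
    """Core encoder; returns (header, payloads dict, residual classes dict)."""
    subs = decompose(image)

    a_payload = base.encode(subs.a)
    if not np.array_equal(base.decode(a_payload), subs.a):
        raise ConfigError("base codec is not lossless on this input; refusing to code")

    payloads = {"a": a_payload}
    residuals: dict[str, QuantizedResidual] = {}
    coded = [subs.a]
    for name in ("d", "b", "c"):
        target = subs.as_dict()[name]
        pred_i, cdfs, _ = _predict_and_model(coded, bundle)
        q = compute_quantized_residual(target, pred_i)
        payloads[name] = rc_encode(q.classes.ravel(), cdfs)
        residuals[name] = q
        coded.append(target)

    header = ContainerHeader(
        version=FORMAT_VERSION,
        row_padded=subs.row_padded,
        col_padded=subs.col_padded,
        base_codec_id=base.codec_id,
        precision=DEFAULT_PRECISION,
        orig_width=image.width,
        orig_height=image.height,
        model_hash=_model_hash16(bundle),
        image_checksum=_image_checksum(image),
        payload_lengths=(
            len(payloads["a"]),
            len(payloads["d"]),
            len(payloads["b"]),
            len(payloads["c"]),
        ),
    )
    return header, payloads, residuals


def compress(image: GrayImage, bundle: ModelBundle, base: BaseCodec | None = None) -> bytes:
    """Compress a grayscale image into a self-describing .glc byte string."""
    base = base or PngCodec()
    header, payloads, _ = _compress_parts(image, bundle, base)
    return header.pack() + b"".join(payloads[k] for k in ("a", "d", "b", "c"))


def decompress(stream: bytes, bundle: ModelBundle) -> GrayImage:
    """Decode a .glc stream; verifies model identity and the pixel checksum."""
    header = ContainerHeader.unpack(stream)
    if header.model_hash != _model_hash16(bundle):
        raise ModelMismatchError(
            "stream was encoded with a different model bundle (version hash mismatch)"
        )
    offset = _HEADER_SIZE
    parts = []
    for length in header.payload_lengths:
        end = offset + length
        if end > len(stream):
            raise CorruptStreamError("declared payload lengths exceed the stream")
        parts.append(stream[offset:end])
        offset = end
    a_bytes, d_bytes, b_bytes, c_bytes = parts

    codec_cls = _CODECS_BY_ID.get(header.base_codec_id)
    if codec_cls is None:
        raise CorruptStreamError(f"unknown base codec id {header.base_codec_id}")
    base = codec_cls()

    gh = (header.orig_height + 1) // 2
    gw = (header.orig_width + 1) // 2
    a = base.decode(a_bytes)
    if a.shape != (gh, gw):
        raise CorruptStreamError("base payload dimensions do not match the header")

    coded = [a]
    decoded: dict[str, np.ndarray] = {"a": a}
    for name, payload in (("d", d_bytes), ("b", b_bytes), ("c", c_bytes)):
        pred_i, cdfs, _ = _predict_and_model(coded, bundle)
        classes = rc_decode(payload, cdfs, gh * gw).reshape(gh, gw)
        sub = reconstruct(pred_i, QuantizedResidual(classes.astype(np.int16)))
        decoded[name] = sub
        coded.append(sub)

    subs = SubimageSet(
        a=decoded["a"],
        b=decoded["b"],
        c=decoded["c"],
        d=decoded["d"],
        orig_width=header.orig_width,
        orig_height=header.orig_height,
        row_padded=header.row_padded,
        col_padded=header.col_padded,
    )
    image = recompose(subs)
    if _image_checksum(image) != header.image_checksum:
        raise CorruptStreamError("pixel checksum mismatch after decode")
    return image


def bpp(stream_length: int, width: int, height: int) -> float:
    """Bits per pixel of a compressed representation."""
    if width < 1 or height < 1:
        raise InvalidInputError("image dimensions must be positive")
    return 8.0 * stream_length / (width * height)
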