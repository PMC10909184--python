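# The .glc container and bitstream, version 1

All multi-byte header integers are little-endian. Version 1 fixes the
subimage coding order to A → D → B → C.

## Header (64 bytes)

| offset | size | field |
|-------:|-----:|-------|
| 0 | 4 | magic `GLC1` |
| 4 | 1 | format version (1) |
| 5 | 1 | flags: bit 0 = last image row was replicated before splitting, bit 1 = last column |
| 6 | 1 | base codec id: 0 = PNG, 1 = JPEG-XL |
| 7 | 1 | CDF precision in bits (default 16) |
| 8 | 4 | original width (pixels) |
| 12 | 4 | original height (pixels) |
| 16 | 16 | model hash: first 16 bytes of the bundle's SHA-256 version hash |
| 32 | 16 | image checksum: first 16 bytes of SHA-256 over `width (u32 LE) ∥ height (u32 LE) ∥ row-major pixel bytes` |
| 48 | 4×4 | payload byte lengths for A, D, B, C |

Total header size: 64 bytes. The four payloads follow immediately, in the
order A, D, B, C, with no padding. A decoder must refuse the stream if the
model hash differs from its bundle's, and must fail if the recomposed
image's checksum differs from the stored one.

## Payload A — base codec

Subimage A (the ⌈H/2⌉×⌈W/2⌉ grid of odd-row/odd-column pixels, 1-based,
after even-size edge replication) is stored verbatim as a complete PNG or
JPEG-XL file, 8-bit grayscale.

## Payloads D, B, C — range-coded residual classes

Each payload encodes the `⌈H/2⌉·⌈W/2⌉` residual classes of one subimage in
row-major order. The class of a pixel is `(real − pred) + 255 ∈ [0, 510]`,
where `pred` is the network's pixel prediction rounded half-away-from-zero
and clipped to `[0, 255]`.

### Per-symbol probability model

For each symbol the decoder recomputes the same 511-entry probability
vector the encoder used (deterministic float32 inference on the already
decoded subimages) and quantizes it identically:

1. normalize the row to sum 1 in float64;
2. scale by `total = 2^precision` and take floors;
3. distribute the remaining `total − Σfloor` counts to the largest
   fractional remainders (ties broken by lower class index — stable sort);
4. raise every zero count to 1, borrowing the shortfall from the largest
   count(s), largest first.

The resulting counts `f_k` define the cumulative table
`C_0 = 0, C_{k+1} = C_k + f_k`, with `C_511 = total`.

### Range coder

Byte-oriented carry-propagating range coder (LZMA-family):

Encoder state: `low` (unbounded non-negative integer, logically 33 bits),
`range` (32 bits, initialized `0xFFFFFFFF`), one pending `cache` byte and a
pending-0xFF counter; the first emitted byte is a leading zero (dummy).

To encode symbol `s` with table `(C, total)`:

```
r     = range // total
low  += C[s] * r
range = (C[s+1] - C[s]) * r
while range < 2^24:  range <<= 8;  shift_low()
```

`shift_low()` emits `cache + carry` and any pending `0xFF + carry` bytes
when `low < 0xFF000000` or `low ≥ 2^32` (with `carry = low >> 32`),
otherwise defers one more byte; then `low = (low << 8) mod 2^32`. Flushing
performs five `shift_low()` calls, so total overhead is ≤ 6 bytes
(≤ 48 bits) per payload.

Decoder: skip the dummy byte, read 4 bytes into `code`, and mirror the
encoder: `r = range // total`, `v = min(code // r, total − 1)`, find `s`
with `C[s] ≤ v < C[s+1]`, then `code −= C[s]·r`, `range = (C[s+1]−C[s])·r`,
refilling one byte per 8-bit renormalization. Reading past the end of the
payload is a corrupt-stream error.

The empty sequence encodes to the 6 flush bytes and decodes to the empty
sequence without reading.
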